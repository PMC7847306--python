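"""Pathway over-representation analysis of significant metabolites.

Each pathway is tested with a one-sided hypergeometric test (Fisher
exact upper tail): given ``n_sig`` significant metabolites drawn from a
universe of ``n_universe`` detected metabolites of which ``n_path``
belong to the pathway, the p-value is the probability of an overlap at
least as large as observed.  P-values are BH-adjusted across the tested
pathways; a pathway is enriched at FDR < 0.01 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, ValidationError
from .io import PathwaySet

MIN_PATHWAY_UNIVERSE_MEMBERS = 2  # skip degenerate single-member tests


@dataclass
class EnrichmentResult:
    pathway_id: str
    n_universe: int
    n_pathway_in_universe: int
    n_significant: int
    n_overlap: int
    p_value: float
    fdr: float
    enriched: bool


def hypergeom_tail(
    overlap: int, n_sig: int, n_path: int, n_universe: int
) -> float:
    """P(X >= overlap) for X hypergeometric(n_universe, n_path, n_sig)."""
    if not (
        0 <= overlap <= min(n_sig, n_path)
        and 0 <= n_sig <= n_universe
        and 0 <= n_path <= n_universe
    ):
        raise ValidationError(
            f"inconsistent counts: overlap={overlap}, n_sig={n_sig}, "
            f"n_path={n_path}, n_universe={n_universe}"
        )
    if overlap == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, n_universe, n_path, n_sig))


def enrich(
    significant_ids: set[str] | list[str],
    universe_ids: set[str] | list[str],
    pathways: list[PathwaySet],
    config: AnalysisConfig | None = None,
    min_members: int = MIN_PATHWAY_UNIVERSE_MEMBERS,
) -> pd.DataFrame:
    """Over-representation test for each pathway against the universe.

    Pathway member sets are intersected with the universe before
    testing; pathways with fewer than ``min_members`` universe members
    are skipped.  Returns one row per tested pathway with BH-adjusted
    p-values, sorted by p-value.
    """
    from .stats import benjamini_hochberg

    config = config or AnalysisConfig()
    universe = set(universe_ids)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    significant = set(significant_ids)
    stray = significant - universe
    if stray:
        raise ValidationError(
            f"significant ids outside the universe: {sorted(stray)[:5]}"
        )
    rows = []
    for pw in pathways:
        members = pw.members & universe
        if len(members) < min_members:
            continue
        overlap = len(members & significant)
        p = hypergeom_tail(overlap, len(significant), len(members), len(universe))
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "name": pw.name,
                "n_universe": len(universe),
                "n_pathway_in_universe": len(members),
                "n_significant": len(significant),
                "n_overlap": overlap,
                "p_value": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "name",
            "n_universe",
            "n_pathway_in_universe",
            "n_significant",
            "n_overlap",
            "p_value",
        ],
    )
    if len(table):
        table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy())
        table["enriched"] = table["fdr"] < config.enrichment_fdr
        table = table.sort_values(
            ["p_value", "pathway_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["fdr"] = []
        table["enriched"] = []
    return table
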