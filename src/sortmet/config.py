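"""Analysis thresholds and tolerances shared across the pipeline.

The defaults encode the significance conventions used throughout the
package: a metabolite is differentially abundant when its fold change
exceeds 2 (strictly) at a Benjamini-Hochberg FDR below 0.05; pathway
over-representation uses FDR < 0.01; library matching requires mass
accuracy within 5 ppm and retention-time agreement within 0.5 min.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


class ValidationError(ValueError):
    """Raised when an input value violates a documented contract."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass
class AnalysisConfig:
    """Thresholds governing significance calls and library matching.

    Parameters
    ----------
    fc_threshold : float
        Fold-change cutoff for differential and above-background calls.
        Strict: a fold change of exactly ``fc_threshold`` is NOT called.
    fdr_threshold : float
        BH-adjusted p-value cutoff (strict ``<``).
    fc_threshold_secondary : float
        Secondary, more stringent fold-change cutoff used for headline
        counts of strongly changed metabolites.
    enrichment_fdr : float
        FDR cutoff for pathway over-representation.
    pseudo_count : float
        Added before log2 in the above-background comparison, where raw
        zeros are kept (``log2(x + pseudo_count)``).
    ppm_tolerance : float
        Mass-accuracy window for library matching, in parts per million
        (inclusive: ``|ppm| <= tolerance`` accepts).
    rt_tolerance : float
        Retention-time window in minutes (inclusive).
    isotope_cosine_min : float
        Minimum cosine similarity between an observed and a predicted
        M..M+2 isotopologue envelope for an accepted match.
    min_spearman : float
        Minimum Spearman correlation between cell number and intensity
        for the library inclusion test.
    seed : int
        Seed for any randomized step.
    """

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    fc_threshold_secondary: float = 2.5
    enrichment_fdr: float = 0.01
    pseudo_count: float = 1.0
    ppm_tolerance: float = 5.0
    rt_tolerance: float = 0.5
    isotope_cosine_min: float = 0.95
    min_spearman: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValidationError("fc_threshold must be > 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if not 0 < self.enrichment_fdr < 1:
            raise ValidationError("enrichment_fdr must be in (0, 1)")
        if self.pseudo_count < 0:
            raise ValidationError("pseudo_count must be >= 0")
        if not self.ppm_tolerance > 0:
            raise ValidationError("ppm_tolerance must be > 0")
        if not self.rt_tolerance > 0:
            raise ValidationError("rt_tolerance must be > 0")
        if not 0 < self.isotope_cosine_min <= 1:
            raise ValidationError("isotope_cosine_min must be in (0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
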