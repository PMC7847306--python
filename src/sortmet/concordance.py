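"""Cross-protocol concordance analytics.

These summaries quantify whether two processing protocols (e.g. flow
sorting versus direct pipetting) preserve biological differences: PCA of
samples, Spearman correlation and ordinary least squares regression of
log2 fold changes between two differential analyses, overlap accounting
of their significant sets, direction agreement, and above-background
counts per group across replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .config import ValidationError
from .io import IntensityMatrix


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged).

    Returns NaN for a constant input, where the rank correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


@dataclass
class ConcordanceSummary:
    """Agreement between two differential analyses of the same contrast."""

    n_common: int
    spearman_r: float
    slope: float
    intercept: float
    n_sig_A: int
    n_sig_B: int
    n_sig_both: int
    pct_A_in_B: float  # % of A's significant set also significant in B
    pct_B_in_A: float

    def summary(self) -> str:
        return (
            f"Fold-change concordance over {self.n_common} metabolites\n"
            f"  Spearman r = {self.spearman_r:.2f}; "
            f"OLS fit: y = {self.slope:.2f} x "
            f"{'+' if self.intercept >= 0 else '-'} {abs(self.intercept):.2f}\n"
            f"  significant: {self.n_sig_A} (A), {self.n_sig_B} (B), "
            f"{self.n_sig_both} shared "
            f"({self.pct_A_in_B:.0f}% of A in B, "
            f"{self.pct_B_in_A:.0f}% of B in A)"
        )


def fc_concordance(
    resultsA: pd.DataFrame,
    resultsB: pd.DataFrame,
    restrict_to: str = "all",
) -> ConcordanceSummary:
    """Compare log2 fold changes between two result tables.

    The regression is ordinary least squares of B's log2 fold change on
    A's, over the metabolites present in both tables — optionally
    restricted to those significant in A.  Overlap percentages report
    how much of each significant set recurs in the other analysis.
    """
    if restrict_to not in ("all", "significant_in_A"):
        raise ValidationError(f"unknown restriction {restrict_to!r}")
    a = resultsA.set_index("metabolite_id")
    b = resultsB.set_index("metabolite_id")
    common = a.index.intersection(b.index)
    sig_a = set(a.index[a["significant"].astype(bool)]) & set(common)
    sig_b = set(b.index[b["significant"].astype(bool)]) & set(common)
    scope = sorted(sig_a) if restrict_to == "significant_in_A" else list(common)
    if len(scope) < 3:
        raise ValidationError(
            f"need >= 3 shared metabolites to compare ({len(scope)} found)"
        )
    x = a.loc[scope, "log2_fc"].to_numpy(dtype=float)
    y = b.loc[scope, "log2_fc"].to_numpy(dtype=float)
    fit = sps.linregress(x, y)
    both = sig_a & sig_b
    return ConcordanceSummary(
        n_common=len(scope),
        spearman_r=spearman(x, y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_sig_A=len(sig_a),
        n_sig_B=len(sig_b),
        n_sig_both=len(both),
        pct_A_in_B=100.0 * len(both) / len(sig_a) if sig_a else 0.0,
        pct_B_in_A=100.0 * len(both) / len(sig_b) if sig_b else 0.0,
    )


def pca_scores(
    matrix: IntensityMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples on a log-scale matrix.

    Metabolites are mean-centered across samples before the rotation.
    Returns (scores: samples x components, explained variance fractions).
    """
    if not matrix.log_scale:
        raise ValidationError("run PCA on log-scale data")
    n_samples = len(matrix.sample_ids)
    if n_samples < 3 or n_components > n_samples:
        raise ValidationError(
            f"PCA needs >= 3 samples and n_components <= n_samples "
            f"({n_samples} samples, {n_components} requested)"
        )
    X = matrix.data.to_numpy(dtype=float).T  # samples x metabolites
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_


def count_above_background_by_group(
    calls_per_group: dict[str, list[list[str]]],
) -> pd.DataFrame:
    """Per-group above-background counts, mean +/- SD across replicate runs.

    ``calls_per_group`` maps each group label to a list of runs, each run
    being the list of metabolite ids called above background.  SD is the
    sample (n-1) standard deviation; a single run reports SD 0.
    """
    if not calls_per_group:
        raise ValidationError("no groups supplied")
    rows = []
    for group, runs in calls_per_group.items():
        counts = np.array([len(run) for run in runs], dtype=float)
        sd = float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0
        rows.append(
            {
                "group": group,
                "n_runs": len(runs),
                "mean_above_background": float(counts.mean()),
                "sd_above_background": sd,
            }
        )
    return pd.DataFrame(rows)


def direction_agreement(
    resultsA: pd.DataFrame, resultsB: pd.DataFrame, ids: list[str]
) -> float:
    """Fraction of metabolites whose log2 fold changes share a sign.

    A zero fold change agrees only with another zero.
    """
    if not ids:
        raise ValidationError("no metabolite ids supplied")
    a = resultsA.set_index("metabolite_id")
    b = resultsB.set_index("metabolite_id")
    missing = [m for m in ids if m not in a.index or m not in b.index]
    if missing:
        raise ValidationError(f"ids absent from a result table: {missing[:5]}")
    sa = np.sign(a.loc[ids, "log2_fc"].to_numpy(dtype=float))
    sb = np.sign(b.loc[ids, "log2_fc"].to_numpy(dtype=float))
    return float(np.mean(sa == sb))


def plot_fc_scatter(resultsA, resultsB, path, restrict_to="all") -> None:
    """Scatter of B's log2 fold changes against A's with the OLS fit line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = fc_concordance(resultsA, resultsB, restrict_to)
    a = resultsA.set_index("metabolite_id")
    b = resultsB.set_index("metabolite_id")
    common = a.index.intersection(b.index)
    x = a.loc[common, "log2_fc"]
    y = b.loc[common, "log2_fc"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=8, alpha=0.6)
    grid = np.linspace(x.min(), x.max(), 10)
    ax.plot(grid, summary.slope * grid + summary.intercept, "r-", lw=1)
    ax.set_xlabel("log2 fold change (A)")
    ax.set_ylabel("log2 fold change (B)")
    ax.set_title(f"r = {summary.spearman_r:.2f}, slope = {summary.slope:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(matrix: IntensityMatrix, groups: pd.Series, path) -> None:
    """PC1/PC2 scatter of samples, colored by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores, explained = pca_scores(matrix, n_components=2)
    fig, ax = plt.subplots(figsize=(4, 4))
    for group in sorted(groups.unique()):
        idx = groups.index[groups == group]
        ax.scatter(scores.loc[idx, "PC1"], scores.loc[idx, "PC2"], label=group, s=20)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.0f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
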