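"""Statistical engine: transforms, imputation, normalization and testing.

The testing model is an ordinary Gaussian linear model per metabolite on
log2-scale intensities, with a two-level group indicator and optional
fixed-effect pair (same animal) and batch (independent experiment)
covariates; the group coefficient is the log2 fold change (a ratio of
geometric means on the raw scale) and its two-sided t-test p-value is
adjusted across metabolites by Benjamini-Hochberg.  Two model front-ends
cover the two comparisons the pipeline makes:

* :class:`BackgroundModel` — cell samples versus sheath-fluid blanks on
  ``log2(x + 1)``-transformed, non-normalized data: metabolites with
  fold change > 2 at FDR < 0.05 are called above background.
* :class:`DifferentialAbundanceModel` — cell samples versus cell
  samples after half-minimum imputation and relative log expression
  (RLE, median-of-ratios) normalization, tested on log2-transformed
  normalized data over a caller-supplied universe (typically the
  metabolites above background in at least one of the two conditions).

Both expose ``fit()`` returning a results object with the per-metabolite
table, counts and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, ValidationError
from .io import IntensityMatrix, SampleMeta, meta_frame

_DEGENERATE_TOL = 1e-12

# strict threshold comparisons are guarded against float rounding so that a
# fitted fold change of exactly the cutoff (e.g. 2^1.0000000000000002) is
# still excluded, as the strict inequality demands
_STRICT_REL_EPS = 1e-9


def _strictly_above(x, threshold: float):
    return x > threshold * (1.0 + _STRICT_REL_EPS)


def _strictly_below(x, threshold: float):
    return x < threshold * (1.0 - _STRICT_REL_EPS)


# ---------------------------------------------------------------------------
# Elementwise transforms and normalization


def log2p1(matrix: IntensityMatrix, pseudo_count: float = 1.0) -> IntensityMatrix:
    """Elementwise ``log2(x + pseudo_count)`` on a raw matrix."""
    if pseudo_count < 0:
        raise ValidationError("pseudo_count must be >= 0")
    if matrix.log_scale:
        raise ValidationError("matrix is already on the log scale")
    data = np.log2(matrix.data + pseudo_count)
    return IntensityMatrix(data, normalized=matrix.normalized, log_scale=True)


def half_min_impute(
    matrix: IntensityMatrix,
) -> tuple[IntensityMatrix, list[str]]:
    """Replace zeros by half the per-metabolite minimum nonzero value.

    The minimum is taken across all samples of the matrix (i.e. across
    the whole comparison, not per group).  Rows with no nonzero value at
    all are left unchanged and returned as the undetected list.
    """
    if matrix.log_scale:
        raise ValidationError("imputation operates on raw-scale data")
    values = matrix.data.to_numpy(dtype=float).copy()
    undetected: list[str] = []
    for i, row in enumerate(values):
        nonzero = row[row > 0]
        if nonzero.size == 0:
            undetected.append(matrix.data.index[i])
            continue
        row[row == 0] = nonzero.min() / 2.0
    out = IntensityMatrix(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        normalized=matrix.normalized,
    )
    return out, undetected


def rle_size_factors(matrix: IntensityMatrix) -> pd.Series:
    """Relative log expression (median-of-ratios) size factors.

    For each sample, the factor is the median over usable metabolites
    (rows with no zeros) of the sample's value divided by the row's
    geometric mean across samples; factors are rescaled so their
    geometric mean is 1.
    """
    if matrix.log_scale:
        raise ValidationError("size factors are computed on raw-scale data")
    values = matrix.data.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValidationError(
            "no metabolite is nonzero in every sample; impute zeros "
            "(half_min_impute) before RLE normalization"
        )
    logs = np.log(values[usable])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_geomean, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=matrix.data.columns)


def rle_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample column by its RLE size factor."""
    factors = rle_size_factors(matrix)
    data = matrix.data / factors
    return IntensityMatrix(data, normalized=True, log_scale=False)


def mean_equalize(
    matrix: IntensityMatrix, above_background_ids: set[str] | list[str]
) -> IntensityMatrix:
    """Scale samples so their mean signal over the given metabolites is equal.

    Each sample is multiplied by the factor that makes its mean intensity
    over ``above_background_ids`` equal to the grand mean of the
    per-sample means.  This is the simpler alternative to RLE: equalize
    average signal intensity of above-background metabolites across the
    samples being compared.
    """
    ids = list(above_background_ids)
    if not ids:
        raise ValidationError("mean_equalize needs a nonempty metabolite set")
    missing = [m for m in ids if m not in matrix.data.index]
    if missing:
        raise ValidationError(f"unknown metabolite ids: {missing[:5]}")
    if matrix.log_scale:
        raise ValidationError("mean_equalize operates on raw-scale data")
    sample_means = matrix.data.loc[ids].mean(axis=0)
    if (sample_means <= 0).any():
        raise ValidationError("a sample has zero mean over the reference set")
    scale = sample_means.mean() / sample_means
    return IntensityMatrix(matrix.data * scale, normalized=True, log_scale=False)


# ---------------------------------------------------------------------------
# Per-metabolite Gaussian linear model


@dataclass
class DesignSpec:
    """Two-group comparison design with optional fixed-effect covariates."""

    reference: str
    test: str
    covariates: tuple[str, ...] = ()
    transform: str = "log2_of_normalized"

    def __post_init__(self) -> None:
        if self.reference == self.test:
            raise ValidationError("reference and test groups must differ")
        bad = [c for c in self.covariates if c not in ("pair", "batch")]
        if bad:
            raise ValidationError(f"unsupported covariates: {bad}")
        if self.transform not in ("log2_plus_pseudo", "log2_of_normalized"):
            raise ValidationError(f"unknown transform {self.transform!r}")


def _dummy_block(labels: pd.Series) -> np.ndarray:
    """Drop-first indicator coding of a categorical covariate."""
    levels = sorted(labels.unique())
    return np.column_stack(
        [(labels == lvl).to_numpy(dtype=float) for lvl in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def build_design_matrix(
    meta: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + covariate dummies; checks rank.

    ``meta`` must be restricted to the samples of the comparison and must
    carry group/pair/batch columns.  Rank deficiency raises with the name
    of the collinear covariate block.
    """
    n = len(meta)
    group = (meta["group"] == design.test).to_numpy(dtype=float)
    blocks: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones((n, 1))),
        ("group", group.reshape(-1, 1)),
    ]
    for cov in design.covariates:
        labels = meta[cov].astype(str)
        if (labels == "").any():
            missing = list(meta.index[labels == ""])[:5]
            raise ValidationError(
                f"covariate {cov!r} is missing for samples {missing}"
            )
        if cov == "pair":
            for pair_id, sub in meta.groupby(labels):
                if set(sub["group"]) != {design.reference, design.test}:
                    raise ValidationError(
                        f"pair {pair_id!r} is not complete across both groups"
                    )
        blocks.append((cov, _dummy_block(labels)))
    X = np.empty((n, 0))
    rank = 0
    for name, block in blocks:
        X = np.hstack([X, block])
        new_rank = np.linalg.matrix_rank(X)
        if new_rank < rank + block.shape[1]:
            raise ValidationError(
                f"design matrix is rank deficient: covariate {name!r} is "
                "collinear with the preceding terms"
            )
        rank = new_rank
    names = ["intercept", "group"] + [
        name for name, b in blocks[2:] for _ in range(b.shape[1])
    ]
    return X, names


def _ols_group_effect(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit Y (samples x metabolites) on X; return group coef, se, p, flags.

    The group indicator is column 1 of X.  Metabolites with (numerically)
    zero residual variance get the convention p = 1 when the group effect
    is zero and p = 0 otherwise, flagged as degenerate.
    """
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValidationError(
            f"no residual degrees of freedom (n={n} samples, {p} parameters)"
        )
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv = np.linalg.inv(R.T @ R)
    c_gg = xtx_inv[1, 1]
    coef = beta[1]
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = rss <= _DEGENERATE_TOL * scale
    sigma2 = np.where(degenerate, np.nan, rss / dof)
    se = np.sqrt(sigma2 * c_gg)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coef / se
        pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    zero_effect = np.abs(coef) <= np.sqrt(_DEGENERATE_TOL * scale)
    pvals = np.where(degenerate, np.where(zero_effect, 1.0, 0.0), pvals)
    coef = np.where(degenerate & zero_effect, 0.0, coef)
    return coef, se, pvals, degenerate


def fit_group_test(
    y: pd.Series,
    meta: pd.DataFrame | list[SampleMeta],
    design: DesignSpec,
) -> tuple[float, float, float]:
    """Group effect for one metabolite: (coefficient, standard error, p).

    ``y`` holds per-sample values on the log2 scale, indexed by sample
    id.  With no covariates the p-value equals a classical pooled two-
    sample t-test; with the pair covariate it equals a paired t-test.
    """
    if isinstance(meta, list):
        meta = meta_frame(meta)
    meta = meta.loc[meta["group"].isin([design.reference, design.test])]
    meta = meta.loc[[s for s in y.index if s in meta.index]]
    for grp in (design.reference, design.test):
        if (meta["group"] == grp).sum() < 2:
            raise ValidationError(f"need >= 2 samples in group {grp!r}")
    X, _ = build_design_matrix(meta, design)
    Y = y.loc[meta.index].to_numpy(dtype=float).reshape(-1, 1)
    coef, se, p, _ = _ols_group_effect(X, Y)
    return float(coef[0]), float(se[0]), float(p[0])


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Above-background calling (cells vs sheath-fluid blanks)


class BackgroundModel:
    """Compare cell samples to sheath-fluid blanks metabolite by metabolite.

    The comparison runs on ``log2(x + pseudo_count)``-transformed,
    non-normalized, non-imputed data: a metabolite is above background
    when its fitted fold change over blanks exceeds ``fc_threshold``
    (strict) at BH FDR below ``fdr_threshold`` (strict).
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        meta: pd.DataFrame | list[SampleMeta],
        config: AnalysisConfig | None = None,
        group: str | None = None,
    ):
        if isinstance(meta, list):
            meta = meta_frame(meta)
        if matrix.normalized or matrix.log_scale:
            raise ValidationError(
                "above-background calling needs raw, non-normalized data"
            )
        self.config = config or AnalysisConfig()
        blanks = meta.index[meta["role"] == "blank"]
        cells = meta.index[meta["role"] == "cell"]
        if group is not None:
            cells = meta.index[(meta["role"] == "cell") & (meta["group"] == group)]
        blanks = [s for s in blanks if s in matrix.data.columns]
        cells = [s for s in cells if s in matrix.data.columns]
        if len(blanks) < 2:
            raise ValidationError(
                "above-background calling needs >= 2 blank samples"
            )
        if len(cells) < 2:
            raise ValidationError("above-background calling needs >= 2 cell samples")
        self.matrix = matrix.subset_samples(list(blanks) + list(cells))
        self.meta = meta.loc[self.matrix.sample_ids].copy()
        # blanks play the reference group role in the linear model
        self.meta["group"] = np.where(
            self.meta["role"] == "blank", "__blank__", "__cell__"
        )
        self.design = DesignSpec("__blank__", "__cell__")

    def fit(self) -> "BackgroundResults":
        cfg = self.config
        logged = log2p1(self.matrix, cfg.pseudo_count)
        X, _ = build_design_matrix(self.meta, self.design)
        Y = logged.data[self.meta.index].to_numpy(dtype=float).T
        coef, se, p, degenerate = _ols_group_effect(X, Y)
        fdr = benjamini_hochberg(p)
        fold = np.exp2(coef)
        above = _strictly_above(fold, cfg.fc_threshold) & _strictly_below(
            fdr, cfg.fdr_threshold
        )
        calls = pd.DataFrame(
            {
                "metabolite_id": self.matrix.metabolite_ids,
                "fold_over_blank": fold,
                "log2_fold_over_blank": coef,
                "p_value": p,
                "fdr": fdr,
                "above_background": above,
                "degenerate": degenerate,
            }
        )
        return BackgroundResults(calls, cfg)


@dataclass
class BackgroundResults:
    """Per-metabolite above-background calls and counts."""

    calls: pd.DataFrame
    config: AnalysisConfig

    @property
    def above_background_ids(self) -> list[str]:
        mask = self.calls["above_background"]
        return list(self.calls.loc[mask, "metabolite_id"])

    @property
    def n_above_background(self) -> int:
        return int(self.calls["above_background"].sum())

    def summary(self) -> str:
        cfg = self.config
        return (
            f"Above-background calling ({len(self.calls)} metabolites)\n"
            f"  thresholds: fold change > {cfg.fc_threshold}, "
            f"FDR < {cfg.fdr_threshold}\n"
            f"  above background: {self.n_above_background}"
        )


def above_background(
    matrix: IntensityMatrix,
    meta: pd.DataFrame | list[SampleMeta],
    config: AnalysisConfig | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`BackgroundModel`; returns calls."""
    return BackgroundModel(matrix, meta, config, group).fit().calls


# ---------------------------------------------------------------------------
# Differential abundance between two cell populations


class DifferentialAbundanceModel:
    """Two-group differential abundance with the full preprocessing chain.

    ``fit()`` runs half-minimum imputation, RLE normalization, a log2
    transform and a per-metabolite Gaussian linear model with the design's
    covariates, then BH-adjusts p-values across the testing universe.
    ``universe`` should hold the metabolites detected above background in
    at least one of the two conditions; it defaults to all metabolites in
    the matrix.
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        meta: pd.DataFrame | list[SampleMeta],
        design: DesignSpec,
        config: AnalysisConfig | None = None,
        universe: list[str] | set[str] | None = None,
        normalization: str = "rle",
    ):
        if isinstance(meta, list):
            meta = meta_frame(meta)
        if matrix.log_scale:
            raise ValidationError("provide raw-scale data; the model transforms")
        if normalization not in ("rle", "mean_equalize", "none"):
            raise ValidationError(f"unknown normalization {normalization!r}")
        self.config = config or AnalysisConfig()
        self.design = design
        self.normalization = normalization
        keep = meta.index[
            (meta["role"] == "cell")
            & meta["group"].isin([design.reference, design.test])
        ]
        keep = [s for s in keep if s in matrix.data.columns]
        for grp in (design.reference, design.test):
            if (meta.loc[keep, "group"] == grp).sum() < 2:
                raise ValidationError(f"need >= 2 cell samples in group {grp!r}")
        self.matrix = matrix.subset_samples(list(keep))
        self.meta = meta.loc[self.matrix.sample_ids]
        if universe is not None and len(universe) == 0:
            raise ValidationError("testing universe is empty")
        self.universe = (
            list(universe) if universe is not None else self.matrix.metabolite_ids
        )
        missing = [m for m in self.universe if m not in matrix.data.index]
        if missing:
            raise ValidationError(
                f"universe ids absent from the matrix: {missing[:5]}"
            )

    def fit(self) -> "DifferentialAbundanceResults":
        cfg = self.config
        imputed, undetected = half_min_impute(self.matrix)
        if self.normalization == "rle":
            normalized = rle_normalize(imputed)
        elif self.normalization == "mean_equalize":
            normalized = mean_equalize(imputed, self.universe)
        else:
            normalized = imputed
        testable = [m for m in self.universe if m not in set(undetected)]
        dropped = [m for m in self.universe if m in set(undetected)]
        if dropped:
            warnings.warn(
                f"{len(dropped)} universe metabolites have no nonzero value "
                "in this comparison and are not tested",
                stacklevel=2,
            )
        if not testable:
            raise ValidationError("no testable metabolite in the universe")
        sub = normalized.subset_metabolites(testable)
        logged = pd.DataFrame(
            np.log2(sub.data.to_numpy(dtype=float)),
            index=sub.data.index,
            columns=sub.data.columns,
        )
        X, _ = build_design_matrix(self.meta, self.design)
        Y = logged[self.meta.index].to_numpy(dtype=float).T
        coef, se, p, degenerate = _ols_group_effect(X, Y)
        fdr = benjamini_hochberg(p)
        fold = np.exp2(coef)
        significant = (
            _strictly_above(fold, cfg.fc_threshold)
            | _strictly_above(1.0 / fold, cfg.fc_threshold)
        ) & _strictly_below(fdr, cfg.fdr_threshold)
        ref_cols = self.meta.index[self.meta["group"] == self.design.reference]
        test_cols = self.meta.index[self.meta["group"] == self.design.test]
        results = pd.DataFrame(
            {
                "metabolite_id": testable,
                "mean_ref": logged[ref_cols].mean(axis=1).to_numpy(),
                "mean_test": logged[test_cols].mean(axis=1).to_numpy(),
                "log2_fc": coef,
                "fold_change": fold,
                "p_value": p,
                "fdr": fdr,
                "significant": significant,
                "direction": np.where(
                    coef > 0, "up", np.where(coef < 0, "down", "none")
                ),
                "degenerate": degenerate,
            }
        )
        return DifferentialAbundanceResults(
            results, self.design, cfg, undetected=dropped
        )


@dataclass
class DifferentialAbundanceResults:
    """Per-metabolite fold changes, p-values, FDR and significance calls."""

    results: pd.DataFrame
    design: DesignSpec
    config: AnalysisConfig
    undetected: list[str] = field(default_factory=list)

    @property
    def significant_ids(self) -> list[str]:
        mask = self.results["significant"]
        return list(self.results.loc[mask, "metabolite_id"])

    @property
    def n_significant(self) -> int:
        return int(self.results["significant"].sum())

    def count_significant(
        self, fc_threshold: float | None = None
    ) -> int:
        """Significant calls beyond a (possibly stricter) fold cutoff."""
        return count_significant(
            self.results,
            fc_threshold if fc_threshold is not None else self.config.fc_threshold,
            self.config.fdr_threshold,
        )

    def summary(self) -> str:
        cfg = self.config
        n25 = self.count_significant(cfg.fc_threshold_secondary)
        up = int((self.results["significant"] & (self.results["log2_fc"] > 0)).sum())
        down = self.n_significant - up
        return (
            f"Differential abundance: {self.design.test} vs "
            f"{self.design.reference} "
            f"(covariates: {', '.join(self.design.covariates) or 'none'})\n"
            f"  metabolites tested: {len(self.results)}\n"
            f"  significant (FC > {cfg.fc_threshold}, "
            f"FDR < {cfg.fdr_threshold}): {self.n_significant} "
            f"({up} up, {down} down)\n"
            f"  of which beyond {cfg.fc_threshold_secondary}-fold: {n25}"
        )


def differential_abundance(
    matrix: IntensityMatrix,
    meta: pd.DataFrame | list[SampleMeta],
    design: DesignSpec,
    config: AnalysisConfig | None = None,
    universe: list[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`DifferentialAbundanceModel`."""
    return (
        DifferentialAbundanceModel(matrix, meta, design, config, universe)
        .fit()
        .results
    )


def count_significant(
    results: pd.DataFrame,
    fc_threshold: float,
    fdr_threshold: float = 0.05,
) -> int:
    """Count results beyond a fold cutoff (either direction) at the FDR cut."""
    if len(results) == 0:
        return 0
    magnitude = np.exp2(np.abs(results["log2_fc"].to_numpy(dtype=float)))
    return int(
        (
            _strictly_above(magnitude, fc_threshold)
            & _strictly_below(results["fdr"].to_numpy(dtype=float), fdr_threshold)
        ).sum()
    )
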