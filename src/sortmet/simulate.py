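"""Synthetic sorted-cell LC-MS metabolomics data.

The generator emulates the structure of peak-intensity tables from
flow-sorted rare-cell experiments: a few hundred metabolites whose
baseline intensities span roughly 10^4-10^9 ion counts (log-uniform),
lognormal biological variation, sheath-fluid blanks in which only a
subset of metabolites carries a low contaminant signal, logistic
intensity-dependent dropout that produces zeros at low signal, planted
differentially abundant metabolites with known log2 effects, and
optional multiplicative batch and pairing effects (additive on the log2
scale).  All randomness flows from one seed through numpy's PCG64
generator, so outputs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ValidationError
from .io import IntensityMatrix, SampleMeta
from .library import ObservedFeature

LOG2_10 = np.log2(10.0)


def _sigma_log2(cv: float) -> float:
    """Log2-scale standard deviation of a lognormal with the given CV."""
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2.0))


@dataclass
class SimConfig:
    """Study conditions for a simulated two-group sorted-cell experiment.

    Defaults mirror a typical rare-cell comparison: 200 detected
    metabolites, 5 replicates per condition and 5 sheath-fluid blanks,
    baselines log-uniform over 10^4-10^9 counts with a biological CV of
    0.25, 30% of metabolites carrying blank contamination at 5% of the
    cell signal, detection dropping to 50% at 10^4 counts, and 10% of
    metabolites differential with fold changes between 2 and 16.
    """

    n_metabolites: int = 200
    n_per_group: int = 5
    n_blanks: int = 5
    groups: tuple[str, str] = ("ref", "test")
    baseline_log10_mean_range: tuple[float, float] = (4.0, 9.0)
    biological_cv: float = 0.25
    blank_fraction: float = 0.3
    blank_relative_level: float = 0.05
    dropout_midpoint: float = 1e4
    dropout_steepness: float = 2.0  # logistic slope per log10 intensity unit
    frac_differential: float = 0.1
    effect_fold_range: tuple[float, float] = (2.0, 16.0)
    n_batches: int = 1
    batch_sd_log2: float = 0.5
    paired: bool = False
    pair_sd_log2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_per_group, self.n_blanks) < 1:
            raise ValidationError("counts must be >= 1")
        if not 0 <= self.frac_differential <= 1:
            raise ValidationError("frac_differential must be in [0, 1]")
        if not 0 <= self.blank_fraction <= 1:
            raise ValidationError("blank_fraction must be in [0, 1]")
        if min(self.effect_fold_range) <= 1:
            raise ValidationError("effect folds must be > 1")
        if self.groups[0] == self.groups[1]:
            raise ValidationError("group labels must differ")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        if self.dropout_midpoint <= 0 or self.dropout_steepness < 0:
            raise ValidationError("invalid dropout parameters")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated experiment."""

    effects_log2: dict[str, float]  # differential ids -> signed log2 effect
    blank_signal_ids: list[str]
    batch_of: dict[str, str]
    pair_of: dict[str, str]
    n_dropouts: int = 0
    baselines_log2: dict[str, float] = field(default_factory=dict)

    @property
    def differential_ids(self) -> list[str]:
        return list(self.effects_log2)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.baselines_log2)
        return pd.DataFrame(
            {
                "metabolite_id": ids,
                "baseline_log2": [self.baselines_log2[m] for m in ids],
                "true_log2_effect": [self.effects_log2.get(m, 0.0) for m in ids],
                "blank_signal": [m in set(self.blank_signal_ids) for m in ids],
            }
        )


def _detection_mask(
    intensity: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli detection with logistic probability in log10 intensity."""
    with np.errstate(divide="ignore"):
        log10_i = np.where(intensity > 0, np.log10(np.maximum(intensity, 1e-300)), -np.inf)
    z = config.dropout_steepness * (log10_i - np.log10(config.dropout_midpoint))
    p_detect = np.where(np.isfinite(z), 1.0 / (1.0 + np.exp(-z)), 0.0)
    return rng.random(intensity.shape) < p_detect


def simulate_experiment(
    config: SimConfig,
) -> tuple[IntensityMatrix, list[SampleMeta], SimTruth]:
    """Simulate a two-group experiment with blanks.

    Returns the raw intensity matrix (zeros = not detected), the sample
    metadata and the ground truth (planted effects, blank-signal ids,
    batch/pair assignments, dropout count).
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    metabolite_ids = [f"met{i:04d}" for i in range(m)]

    lo, hi = config.baseline_log10_mean_range
    baselines_log2 = rng.uniform(lo, hi, size=m) * LOG2_10
    sigma = _sigma_log2(config.biological_cv)

    n_diff = round(config.frac_differential * m)
    diff_idx = rng.choice(m, size=n_diff, replace=False)
    fold_lo, fold_hi = config.effect_fold_range
    magnitudes = np.exp2(
        rng.uniform(np.log2(fold_lo), np.log2(fold_hi), size=n_diff)
    )
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    effects = np.zeros(m)
    effects[diff_idx] = signs * np.log2(magnitudes)

    n_blank_signal = round(config.blank_fraction * m)
    blank_idx = rng.choice(m, size=n_blank_signal, replace=False)
    blank_log2 = np.full(m, -np.inf)
    blank_log2[blank_idx] = baselines_log2[blank_idx] + np.log2(
        config.blank_relative_level
    )

    batch_labels = [f"batch{b + 1}" for b in range(config.n_batches)]
    batch_effects = dict(
        zip(batch_labels, rng.normal(0.0, config.batch_sd_log2, config.n_batches))
    )

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    truth_batch: dict[str, str] = {}
    truth_pair: dict[str, str] = {}
    n_dropouts = 0

    pair_effects = rng.normal(0.0, config.pair_sd_log2, config.n_per_group)

    for g, group in enumerate(config.groups):
        for r in range(config.n_per_group):
            sid = f"{group}_{r + 1}"
            batch = batch_labels[r % config.n_batches]
            pair = f"animal{r + 1}" if config.paired else ""
            log2_mu = baselines_log2 + (effects if g == 1 else 0.0)
            if config.n_batches > 1:
                log2_mu = log2_mu + batch_effects[batch]
            if config.paired:
                log2_mu = log2_mu + pair_effects[r]
            intensity = np.exp2(log2_mu + rng.normal(0.0, sigma, size=m))
            detected = _detection_mask(intensity, config, rng)
            n_dropouts += int((~detected).sum())
            columns[sid] = np.where(detected, intensity, 0.0)
            samples.append(
                SampleMeta(sid, "cell", group=group, batch=batch, pair=pair)
            )
            truth_batch[sid] = batch
            if pair:
                truth_pair[sid] = pair

    for r in range(config.n_blanks):
        sid = f"blank_{r + 1}"
        batch = batch_labels[r % config.n_batches]
        with np.errstate(invalid="ignore"):
            intensity = np.where(
                np.isfinite(blank_log2),
                np.exp2(blank_log2 + rng.normal(0.0, sigma, size=m)),
                0.0,
            )
        detected = _detection_mask(intensity, config, rng)
        n_dropouts += int(((intensity > 0) & ~detected).sum())
        columns[sid] = np.where(detected, intensity, 0.0)
        samples.append(SampleMeta(sid, "blank", batch=batch))
        truth_batch[sid] = batch

    matrix = IntensityMatrix(pd.DataFrame(columns, index=metabolite_ids))
    truth = SimTruth(
        effects_log2={
            metabolite_ids[i]: float(effects[i]) for i in sorted(diff_idx)
        },
        blank_signal_ids=[metabolite_ids[i] for i in sorted(blank_idx)],
        batch_of=truth_batch,
        pair_of=truth_pair,
        n_dropouts=n_dropouts,
        baselines_log2=dict(zip(metabolite_ids, baselines_log2.astype(float))),
    )
    return matrix, samples, truth


def simulate_titration(
    config: SimConfig,
    cell_numbers: list[int] = (10_000, 20_000, 30_000, 50_000, 100_000),
    n_contaminants: int = 0,
    noise_cv: float | None = None,
) -> tuple[list[ObservedFeature], dict[str, int], list[str]]:
    """Simulate a cell-number titration series for library inclusion tests.

    Each feature's intensity is proportional to the number of cells
    extracted, with multiplicative lognormal noise and logistic dropout;
    retention times jitter mildly around the feature's nominal RT.
    ``n_contaminants`` extra features carry a flat, cell-independent
    signal (e.g. plasticware contamination) and should fail the
    inclusion test.  Returns (features, sample -> cell number map,
    contaminant feature ids).
    """
    cell_numbers = list(cell_numbers)
    if len(cell_numbers) < 3:
        raise ValidationError("titration needs >= 3 cell numbers")
    rng = np.random.default_rng(config.seed)
    cv = config.biological_cv if noise_cv is None else noise_cv
    sigma = _sigma_log2(cv) if cv > 0 else 0.0
    sample_ids = [f"cells_{n}" for n in cell_numbers]
    series = dict(zip(sample_ids, cell_numbers))

    lo, hi = config.baseline_log10_mean_range
    # baseline is the expected intensity at the largest cell number
    baselines_log2 = rng.uniform(lo, hi, size=config.n_metabolites) * LOG2_10
    features: list[ObservedFeature] = []
    contaminant_ids: list[str] = []
    scale = np.asarray(cell_numbers, dtype=float) / max(cell_numbers)

    def _make_feature(fid: str, log2_levels: np.ndarray) -> ObservedFeature:
        noise = (
            rng.normal(0.0, sigma, size=len(cell_numbers)) if sigma > 0 else 0.0
        )
        intensity = np.exp2(log2_levels + noise)
        detected = _detection_mask(intensity, config, rng)
        intensity = np.where(detected, intensity, 0.0)
        rt = float(rng.uniform(1.0, 15.0))
        rts = rt + rng.normal(0.0, 0.02, size=len(cell_numbers))
        return ObservedFeature(
            feature_id=fid,
            mz=float(rng.uniform(80.0, 1200.0)),
            retention_time=rt,
            per_sample_intensity=dict(zip(sample_ids, intensity)),
            per_sample_rt=dict(zip(sample_ids, rts)),
        )

    for i in range(config.n_metabolites):
        levels = baselines_log2[i] + np.log2(scale)
        features.append(_make_feature(f"feat{i:04d}", levels))
    for j in range(n_contaminants):
        fid = f"contaminant{j:02d}"
        level = float(rng.uniform(lo, hi) * LOG2_10)
        features.append(_make_feature(fid, np.full(len(cell_numbers), level)))
        contaminant_ids.append(fid)
    return features, series, contaminant_ids


def simulate_blank_contamination(
    config: SimConfig,
    drying_levels: list[str] = ("none", "clean_hood", "standard"),
    level_fold_step: float = 4.0,
) -> dict[str, IntensityMatrix]:
    """Blank-only matrices with background rising across ordered levels.

    Emulates sample-drying protocols that add contamination: each level
    multiplies the blank contaminant signal by ``level_fold_step`` over
    the previous one (the first level is the configured baseline blank
    signal; a level named ``"zero"`` has no signal at all).  Useful for
    testing that above-background calls shrink as background grows.
    """
    drying_levels = list(drying_levels)
    if len(drying_levels) < 2:
        raise ValidationError("need >= 2 contamination levels")
    # shared structure across levels: same metabolites contaminate, only
    # the contaminant level changes between drying protocols
    base_rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    metabolite_ids = [f"met{i:04d}" for i in range(m)]
    lo, hi = config.baseline_log10_mean_range
    baselines_log2 = base_rng.uniform(lo, hi, size=m) * LOG2_10
    n_blank_signal = round(config.blank_fraction * m)
    blank_idx = base_rng.choice(m, size=n_blank_signal, replace=False)
    sigma = _sigma_log2(config.biological_cv)

    matrices: dict[str, IntensityMatrix] = {}
    for k, level in enumerate(drying_levels):
        rng = np.random.default_rng(config.seed + 1000 + k)
        relative = (
            0.0 if level == "zero" else config.blank_relative_level * level_fold_step**k
        )
        blank_log2 = np.full(m, -np.inf)
        if relative > 0 and blank_idx.size:
            blank_log2[blank_idx] = baselines_log2[blank_idx] + np.log2(relative)
        columns = {}
        for r in range(config.n_blanks):
            intensity = np.where(
                np.isfinite(blank_log2),
                np.exp2(blank_log2 + rng.normal(0.0, sigma, size=m)),
                0.0,
            )
            detected = _detection_mask(intensity, config, rng)
            columns[f"{level}_blank_{r + 1}"] = np.where(detected, intensity, 0.0)
        matrices[level] = IntensityMatrix(
            pd.DataFrame(columns, index=metabolite_ids)
        )
    return matrices
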