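"""Metabolite library construction and feature matching.

A library entry is accepted as the identity of an observed LC-MS feature
when the measured precursor mass lies within the ppm tolerance of the
theoretical m/z (default 5 ppm, inclusive), the retention time agrees
within the RT window, and — when an isotopologue envelope was measured —
the observed M..M+2 envelope is close (cosine similarity) to the pattern
predicted from the molecular formula.  Library inclusion additionally
requires reproducible retention times across samples and peak intensity
that increases with the number of cells extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import AnalysisConfig, ValidationError
from .io import LibraryEntry

# candidate windows: entries this far outside the acceptance windows are
# still reported (with rejection reasons) so near-misses are reviewable
CANDIDATE_PPM_FACTOR = 4.0
CANDIDATE_RT_FACTOR = 4.0

# the ppm/RT windows are inclusive; guard the comparison so a value at
# exactly the boundary is not rejected by float rounding
_BOUNDARY_REL_EPS = 1e-9


def _outside(value: float, tolerance: float) -> bool:
    return abs(value) > tolerance * (1.0 + _BOUNDARY_REL_EPS)


@dataclass
class ObservedFeature:
    """An LC-MS feature: m/z, retention time and per-sample intensities."""

    feature_id: str
    mz: float
    retention_time: float
    polarity: str = "+"
    per_sample_intensity: dict[str, float] = field(default_factory=dict)
    per_sample_rt: dict[str, float] = field(default_factory=dict)
    isotope_envelope: tuple[float, ...] | None = None  # M, M+1, M+2 with M = 1

    def __post_init__(self) -> None:
        if not 80.0 <= self.mz <= 1200.0:
            raise ValidationError(
                f"feature {self.feature_id!r}: m/z {self.mz} outside the "
                "80-1200 Da scan range"
            )
        if self.polarity not in ("+", "-"):
            raise ValidationError("polarity must be '+' or '-'")
        if self.isotope_envelope is not None and any(
            a < 0 for a in self.isotope_envelope
        ):
            raise ValidationError("isotope envelope entries must be >= 0")
        if any(v < 0 for v in self.per_sample_intensity.values()):
            raise ValidationError("negative per-sample intensity")


@dataclass
class MatchResult:
    """Outcome of comparing one feature against one library entry."""

    feature_id: str
    metabolite_id: str
    ppm_error: float
    rt_delta: float
    isotope_cosine: float | None
    accepted: bool
    rejection_reasons: list[str]


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValidationError("masses must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def match_feature(
    feature: ObservedFeature,
    library: list[LibraryEntry],
    config: AnalysisConfig | None = None,
) -> list[MatchResult]:
    """Compare a feature against a library and report candidate matches.

    Only entries of matching polarity are considered.  Entries within a
    few multiples of the ppm/RT windows are reported as candidates;
    ``accepted`` requires the mass error within ``ppm_tolerance``
    (inclusive), the RT delta within ``rt_tolerance`` (inclusive), and
    the isotope-envelope cosine at or above ``isotope_cosine_min`` when
    both an observed envelope and a formula are available.  Results are
    sorted by absolute ppm error, ties broken by absolute RT delta.
    """
    config = config or AnalysisConfig()
    from .isotopes import isotope_pattern

    results: list[MatchResult] = []
    for entry in library:
        if entry.polarity != feature.polarity:
            continue
        err = ppm_error(feature.mz, entry.theoretical_mz)
        rt_delta = feature.retention_time - entry.retention_time
        if abs(err) > CANDIDATE_PPM_FACTOR * config.ppm_tolerance:
            continue
        if abs(rt_delta) > CANDIDATE_RT_FACTOR * config.rt_tolerance:
            continue
        reasons: list[str] = []
        if _outside(err, config.ppm_tolerance):
            reasons.append("mass")
        if _outside(rt_delta, config.rt_tolerance):
            reasons.append("retention_time")
        cosine = None
        if feature.isotope_envelope is not None and entry.formula:
            predicted = isotope_pattern(
                entry.formula, max_shift=len(feature.isotope_envelope) - 1
            )
            cosine = _cosine(
                np.asarray(feature.isotope_envelope, dtype=float), predicted
            )
            if cosine < config.isotope_cosine_min:
                reasons.append("isotope_pattern")
        results.append(
            MatchResult(
                feature_id=feature.feature_id,
                metabolite_id=entry.metabolite_id,
                ppm_error=err,
                rt_delta=rt_delta,
                isotope_cosine=cosine,
                accepted=not reasons,
                rejection_reasons=reasons,
            )
        )
    results.sort(key=lambda r: (abs(r.ppm_error), abs(r.rt_delta)))
    return results


def inclusion_test(
    feature: ObservedFeature,
    cell_number_series: dict[str, int],
    config: AnalysisConfig | None = None,
) -> tuple[bool, list[str]]:
    """Library-inclusion criterion for a feature in a cell titration.

    Passes when (i) the retention time is reproducible — the max-min RT
    spread over the samples in which the feature is detected is within
    ``rt_tolerance`` — and (ii) peak intensity increases with cell
    number, operationalised as a Spearman rank correlation of at least
    ``min_spearman`` (default 0.8) between cell number and intensity.
    Requires at least 3 samples with distinct cell numbers.
    """
    config = config or AnalysisConfig()
    shared = [s for s in cell_number_series if s in feature.per_sample_intensity]
    if len(shared) < 3 or len({cell_number_series[s] for s in shared}) < 3:
        raise ValidationError(
            "inclusion_test needs >= 3 samples with distinct cell numbers"
        )
    reasons: list[str] = []

    detected = [s for s in shared if feature.per_sample_intensity[s] > 0]
    rts = [feature.per_sample_rt[s] for s in detected if s in feature.per_sample_rt]
    if len(rts) >= 2 and (max(rts) - min(rts)) > config.rt_tolerance:
        reasons.append("retention_time_spread")

    cells = np.array([cell_number_series[s] for s in shared], dtype=float)
    intensity = np.array(
        [feature.per_sample_intensity[s] for s in shared], dtype=float
    )
    if np.all(intensity == intensity[0]):
        rho = 0.0
    else:
        rho = float(stats.spearmanr(cells, intensity).statistic)
    if not rho >= config.min_spearman:
        reasons.append("not increasing with cell number")
    return (not reasons, reasons)


def restrict_library(
    high_library: list[LibraryEntry], detected_ids: set[str]
) -> list[LibraryEntry]:
    """Restrict a high-abundance library to the detected metabolites.

    Returns the sub-library whose membership equals ``detected_ids``,
    preserving the original order.  Detected ids absent from the library
    are reported as a warning, not an error.
    """
    known = {e.metabolite_id for e in high_library}
    unknown = sorted(detected_ids - known)
    if unknown:
        import warnings

        warnings.warn(
            f"{len(unknown)} detected ids not in the library: {unknown[:5]}...",
            stacklevel=2,
        )
    return [e for e in high_library if e.metabolite_id in detected_ids]
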