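"""Shared data model and file I/O for the pipeline.

The canonical in-memory layout is a metabolite x sample table of
nonnegative peak intensities (:class:`IntensityMatrix`, wrapping a pandas
DataFrame) with a per-sample metadata table (:class:`SampleMeta`).  Zero
intensity encodes "not detected"; downstream imputation targets zeros,
so empty cells in input files are read as 0 with a warning rather than
as NaN.  Pathway memberships use the tab-separated GMT set format and
metabolite libraries are plain delimited tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FormatError, ValidationError

VALID_ROLES = ("blank", "cell")
VALID_ADDUCTS = ("[M+H]+", "[M-H]-", "M")


@dataclass
class SampleMeta:
    """Annotation of one LC-MS sample.

    ``role`` distinguishes sheath-fluid blanks from cell samples; ``pair``
    links samples derived from the same animal, and ``batch`` labels the
    independent experiment a sample belongs to.
    """

    sample_id: str
    role: str
    group: str = ""
    batch: str = ""
    pair: str = ""
    cell_number: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r} "
                f"(expected one of {VALID_ROLES})"
            )
        if self.role == "cell" and not self.group:
            raise ValidationError(f"cell sample {self.sample_id!r} has no group")
        if self.role == "blank" and self.pair:
            raise ValidationError(f"blank sample {self.sample_id!r} cannot be paired")
        if self.cell_number is not None and self.cell_number < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative cell_number")


def validate_sample_meta(samples: list[SampleMeta]) -> None:
    """Check cross-sample invariants (unique ids, non-singleton pairs)."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")
    pair_counts: dict[str, int] = {}
    for s in samples:
        if s.pair:
            pair_counts[s.pair] = pair_counts.get(s.pair, 0) + 1
    singletons = sorted(p for p, c in pair_counts.items() if c < 2)
    if singletons:
        warnings.warn(f"pair labels with a single sample: {singletons}", stacklevel=2)


def meta_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Tabulate metadata records, indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "role": [s.role for s in samples],
            "group": [s.group for s in samples],
            "batch": [s.batch for s in samples],
            "pair": [s.pair for s in samples],
            "cell_number": [s.cell_number for s in samples],
        }
    )
    return df.set_index("sample_id", drop=False)


@dataclass
class IntensityMatrix:
    """Metabolite x sample peak-intensity table.

    ``data`` holds metabolites as rows and samples as columns.  Raw
    intensities are nonnegative finite ion counts; zeros mean the peak
    was not detected.  ``normalized`` and ``log_scale`` track provenance
    through the pipeline (log-scale values may be negative).
    """

    data: pd.DataFrame
    normalized: bool = False
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise FormatError(f"duplicate metabolite ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if not self.log_scale:
            bad |= values < 0
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "invalid intensity at metabolite "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}: "
                f"{values[i, j]!r} (must be a finite, nonnegative number)"
            )
        self.data = self.data.astype(float)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: list[str]) -> "IntensityMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return IntensityMatrix(
            self.data[sample_ids].copy(), self.normalized, self.log_scale
        )

    def subset_metabolites(self, metabolite_ids: list[str]) -> "IntensityMatrix":
        missing = [m for m in metabolite_ids if m not in self.data.index]
        if missing:
            raise ValidationError(f"unknown metabolite ids: {missing}")
        return IntensityMatrix(
            self.data.loc[metabolite_ids].copy(), self.normalized, self.log_scale
        )


@dataclass
class LibraryEntry:
    """One annotated metabolite: identity, formula, adduct m/z and RT."""

    metabolite_id: str
    name: str = ""
    formula: str = ""
    adduct: str = "M"
    polarity: str = "+"
    theoretical_mz: float = 0.0
    retention_time: float = 0.0
    ms2_confirmed: bool = False
    standard_confirmed: bool = False
    pathway_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.adduct not in VALID_ADDUCTS:
            raise ValidationError(
                f"{self.metabolite_id!r}: unsupported adduct {self.adduct!r}"
            )
        if self.polarity not in ("+", "-"):
            raise ValidationError(
                f"{self.metabolite_id!r}: polarity must be '+' or '-'"
            )
        if self.theoretical_mz <= 0:
            raise ValidationError(f"{self.metabolite_id!r}: theoretical_mz must be > 0")
        if self.retention_time < 0:
            raise ValidationError(f"{self.metabolite_id!r}: negative retention time")
        if self.formula and self.adduct in ("[M+H]+", "[M-H]-"):
            from .isotopes import adduct_mz

            expected = adduct_mz(self.formula, self.adduct)
            if abs(expected - self.theoretical_mz) > 1e-3:
                raise ValidationError(
                    f"{self.metabolite_id!r}: theoretical_mz {self.theoretical_mz} "
                    f"inconsistent with {self.formula} {self.adduct} "
                    f"(expected {expected:.6f})"
                )


@dataclass
class PathwaySet:
    """A named metabolite set (e.g. a KEGG pathway)."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id!r} has no members")


# ---------------------------------------------------------------------------
# Readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        # first worksheet only; the template is a single-table workbook
        return pd.read_excel(path, sheet_name=0, index_col=0)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_intensity_table(
    path: str | Path, orientation: str = "rows=metabolites"
) -> IntensityMatrix:
    """Load a peak-intensity table from CSV/TSV/XLSX.

    ``orientation`` says what the file's rows are; the returned matrix is
    always metabolites x samples.  Empty cells are read as 0 (not
    detected) with a warning; any negative, non-finite or non-numeric
    value raises with the offending cell named.
    """
    if orientation not in ("rows=metabolites", "rows=samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "rows=samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = numeric.isna() & df.notna()
    if non_numeric.to_numpy().any():
        i, j = np.argwhere(non_numeric.to_numpy())[0]
        raise ValidationError(
            f"non-numeric intensity at metabolite {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        warnings.warn(
            f"{int(numeric.isna().to_numpy().sum())} empty cells read as 0 "
            "(not detected)",
            stacklevel=2,
        )
        numeric = numeric.fillna(0.0)
    return IntensityMatrix(numeric)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    matrix.data.to_csv(path, sep=sep, index_label="metabolite_id")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Load sample metadata (requires sample_id, role, group columns)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "role", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cell_number = None
        raw_n = row.get("cell_number", "")
        if raw_n not in ("", None):
            try:
                cell_number = int(float(raw_n))
            except ValueError as exc:
                raise ValidationError(
                    f"sample {row['sample_id']!r}: bad cell_number {raw_n!r}"
                ) from exc
        records.append(
            SampleMeta(
                sample_id=row["sample_id"],
                role=row["role"],
                group=row.get("group", ""),
                batch=row.get("batch", ""),
                pair=row.get("pair", ""),
                cell_number=cell_number,
                notes=row.get("notes", ""),
            )
        )
    validate_sample_meta(records)
    return records


def write_sample_meta(samples: list[SampleMeta], path: str | Path) -> None:
    meta_frame(samples).to_csv(Path(path), index=False)


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Load pathway sets from the tab-separated GMT format."""
    sets: list[PathwaySet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs set id, description and "
                f"at least one member ({len(fields)} fields found)"
            )
        set_id, description, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: set {set_id!r} has no members")
        if set_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        sets.append(PathwaySet(set_id, description, frozenset(members)))
    return sets


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Load a metabolite library table (CSV/TSV with LibraryEntry columns)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "metabolite_id" not in df.columns or "theoretical_mz" not in df.columns:
        raise FormatError("library needs metabolite_id and theoretical_mz columns")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            LibraryEntry(
                metabolite_id=row["metabolite_id"],
                name=row.get("name", ""),
                formula=row.get("formula", ""),
                adduct=row.get("adduct", "M") or "M",
                polarity=row.get("polarity", "+") or "+",
                theoretical_mz=float(row["theoretical_mz"]),
                retention_time=float(row.get("retention_time", 0) or 0),
                ms2_confirmed=str(row.get("ms2_confirmed", "")).lower()
                in ("1", "true", "yes"),
                standard_confirmed=str(row.get("standard_confirmed", "")).lower()
                in ("1", "true", "yes"),
                pathway_ids=[
                    p for p in str(row.get("pathway_ids", "")).split(";") if p
                ],
            )
        )
    ids = [e.metabolite_id for e in entries]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate metabolite ids in library")
    return entries


RESULT_COLUMNS = [
    "metabolite_id",
    "mean_ref",
    "mean_test",
    "log2_fc",
    "fold_change",
    "p_value",
    "fdr",
    "significant",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-abundance result table as delimited text."""
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"result table is missing columns: {missing}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    results.to_csv(path, sep=sep, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"result table is missing columns: {missing}")
    return df
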