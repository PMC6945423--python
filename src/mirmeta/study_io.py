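"""Domain types and TSV I/O for study-level summary data.

The package works from three kinds of study-level records, all shipped as
packaged TSV fixtures transcribed from the source cohort tables:

* two-group expression summaries per dataset (``StudySummary``) — the atom of
  the standardized-mean-difference meta-analysis;
* 2x2 diagnostic counts per dataset (``DiagnosticCounts``) — the atom of the
  diagnostic-accuracy synthesis;
* per-stratum clinical summaries (``GroupRow``) — inputs to the
  summary-statistic t/F tests.

All files are UTF-8, tab-separated, decimal-point, with a fixed header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SPECIMENS = frozenset({"tissue", "serum"})
DISEASE_SUBSETS = frozenset({"LUAD", "LUSC", "NSCLC"})

SUMMARY_COLUMNS = [
    "study_id", "subset_label", "disease_subset", "specimen",
    "n_case", "mean_case", "sd_case",
    "n_control", "mean_control", "sd_control", "scale_note",
]
COUNTS_COLUMNS = ["study_id", "specimen", "tp", "fp", "fn", "tn"]
GROUPS_COLUMNS = ["table_id", "variable", "level", "n", "mean", "sd"]


class SchemaError(ValueError):
    """Header or column-type mismatch against a declared table schema."""


class ValidationError(ValueError):
    """A parsed row violates a domain invariant (e.g. SD <= 0)."""


@dataclass(frozen=True)
class StudySummary:
    """One dataset's two-group expression summary (case vs control arm).

    Means and SDs are in platform-native units (2^-dCq, log2 expression,
    or chip intensity); the standardized effect size removes the scale.
    ``scale_note`` records the transform the values were reported on.
    """

    study_id: str
    subset_label: str
    disease_subset: str
    specimen: str
    n_case: int
    mean_case: float
    sd_case: float
    n_control: int
    mean_control: float
    sd_control: float
    scale_note: str = ""

    def __post_init__(self) -> None:
        if self.specimen not in SPECIMENS:
            raise ValidationError(
                f"{self.study_id}: unknown specimen {self.specimen!r}")
        if self.disease_subset not in DISEASE_SUBSETS:
            raise ValidationError(
                f"{self.study_id}: unknown disease subset {self.disease_subset!r}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError(f"{self.study_id}: arm sizes must be positive")
        if self.sd_case <= 0 or self.sd_control <= 0:
            raise ValidationError(f"{self.study_id}: SDs must be strictly positive")

    @property
    def key(self) -> str:
        """Unique key; sub-platform rows of one series get distinct keys."""
        return f"{self.study_id}{self.subset_label}"

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class DiagnosticCounts:
    """One dataset's 2x2 table against the disease reference standard."""

    study_id: str
    specimen: str
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.specimen not in SPECIMENS:
            raise ValidationError(
                f"{self.study_id}: unknown specimen {self.specimen!r}")
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError(f"{self.study_id}: counts must be non-negative")
        if self.tp + self.fn < 1 or self.fp + self.tn < 1:
            raise ValidationError(
                f"{self.study_id}: each arm of the 2x2 table needs at least one subject")


@dataclass(frozen=True)
class GroupRow:
    """One clinical stratum's n/mean/SD within a cohort table."""

    table_id: str
    variable: str
    level: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"{self.variable}/{self.level}: n must be positive")
        if self.sd <= 0:
            raise ValidationError(f"{self.variable}/{self.level}: SD must be positive")


@dataclass
class StudySet:
    """Ordered collection of study summaries with optional matching 2x2 counts."""

    studies: list[StudySummary] = field(default_factory=list)
    counts: list[DiagnosticCounts] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [s.key for s in self.studies]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate study keys: {dupes}")
        known = set(keys)
        for c in self.counts:
            if c.study_id not in known:
                raise ValidationError(
                    f"counts row {c.study_id} does not match any loaded study")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def subset(self, keys: Iterable[str] | None = None, *,
               specimen: str | None = None,
               disease_subset: str | None = None) -> "StudySet":
        """Return a new StudySet filtered by key list and/or labels, order kept."""
        keep = list(self.studies)
        if keys is not None:
            keyset = set(keys)
            keep = [s for s in keep if s.key in keyset]
        if specimen is not None:
            keep = [s for s in keep if s.specimen == specimen]
        if disease_subset is not None:
            keep = [s for s in keep if s.disease_subset == disease_subset]
        kept_keys = {s.key for s in keep}
        counts = [c for c in self.counts if c.study_id in kept_keys]
        return StudySet(studies=keep, counts=counts, provenance=self.provenance)

    def counts_for(self, key: str) -> DiagnosticCounts:
        for c in self.counts:
            if c.study_id == key:
                return c
        raise KeyError(key)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _to_int(value, row_no: int, col: str, path) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{path} row {row_no}: non-numeric {col}={value!r}") from None
    if f != int(f):
        raise SchemaError(f"{path} row {row_no}: {col}={value!r} is not an integer")
    return int(f)


def _to_float(value, row_no: int, col: str, path) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{path} row {row_no}: non-numeric {col}={value!r}") from None


def read_study_table(path, schema: str):
    """Read a TSV of study records.

    Parameters
    ----------
    path
        TSV file with a header matching the declared schema.
    schema
        ``"summary"`` -> StudySet of StudySummary; ``"counts"`` -> list of
        DiagnosticCounts; ``"groups"`` -> list of GroupRow.

    Row order is preserved; malformed rows are reported with their (1-based,
    header-excluded) row number.
    """
    path = Path(path)
    if schema not in {"summary", "counts", "groups"}:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if schema == "summary":
        _require_columns(df, SUMMARY_COLUMNS, path)
        studies = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                studies.append(StudySummary(
                    study_id=row.study_id,
                    subset_label=row.subset_label,
                    disease_subset=row.disease_subset,
                    specimen=row.specimen,
                    n_case=_to_int(row.n_case, i, "n_case", path),
                    mean_case=_to_float(row.mean_case, i, "mean_case", path),
                    sd_case=_to_float(row.sd_case, i, "sd_case", path),
                    n_control=_to_int(row.n_control, i, "n_control", path),
                    mean_control=_to_float(row.mean_control, i, "mean_control", path),
                    sd_control=_to_float(row.sd_control, i, "sd_control", path),
                    scale_note=row.scale_note,
                ))
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from None
        return StudySet(studies=studies, provenance=str(path))

    if schema == "counts":
        _require_columns(df, COUNTS_COLUMNS, path)
        out = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                out.append(DiagnosticCounts(
                    study_id=row.study_id,
                    specimen=row.specimen,
                    tp=_to_int(row.tp, i, "tp", path),
                    fp=_to_int(row.fp, i, "fp", path),
                    fn=_to_int(row.fn, i, "fn", path),
                    tn=_to_int(row.tn, i, "tn", path),
                ))
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from None
        return out

    _require_columns(df, GROUPS_COLUMNS, path)
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rows.append(GroupRow(
                table_id=row.table_id,
                variable=row.variable,
                level=row.level,
                n=_to_int(row.n, i, "n", path),
                mean=_to_float(row.mean, i, "mean", path),
                sd=_to_float(row.sd, i, "sd", path),
            ))
        except ValidationError as err:
            raise ValidationError(f"{path} row {i}: {err}") from None
    return rows


def load_fixture(name: str):
    """Load one of the packaged study tables by fixture name.

    Available fixtures: ``table5_chips`` (summary), ``table5_counts``
    (counts), ``table1_groups`` .. ``table4_groups`` (groups).
    """
    schema = "summary" if name == "table5_chips" else (
        "counts" if name == "table5_counts" else "groups")
    ref = resources.files("mirmeta").joinpath("data", f"{name}.tsv")
    with resources.as_file(ref) as p:
        result = read_study_table(p, schema)
    if schema == "summary":
        result.provenance = f"fixture:{name}"
    return result


def attach_counts(studies: StudySet, counts: list[DiagnosticCounts]) -> StudySet:
    """Return a StudySet with 2x2 counts attached (validated against keys)."""
    return StudySet(studies=list(studies.studies), counts=list(counts),
                    provenance=studies.provenance)


def write_results(result, path) -> None:
    """Write an analysis result as a TSV table plus a JSON sidecar.

    ``result`` must provide ``to_frame()`` (per-study/summary rows) and
    ``to_dict()`` (all scalar fields at full precision, for the sidecar);
    the meta-analysis and SROC result types both do. The JSON sidecar
    round-trips every scalar bit-identically via repr-precision floats.
    """
    frame = result.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty result")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(result.to_dict(), indent=2, default=float) + "\n")


def summary_to_frame(studies: Iterable[StudySummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in studies])
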