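"""Data model and I/O for triplicate methylation qPCR cohorts.

A *cohort* is a collection of specimens (plasma or stool), each measured in a
fixed number of PCR replicates.  Every replicate carries two crossing points
(Cp, synonymous with Ct/Cq): one for the *ACTB* internal control, which gates
sample validity, and one for the methylated *SEPT9* marker, which may be
non-detected.  Non-detection is an explicit state in the data model (``None``),
never a sentinel number.

On disk a cohort is a long-format delimited table with one row per replicate::

    sample_id  subject_id  specimen  group  stage  replicate  actb_cp  sept9_cp

plus optional covariate columns (``age``, ``sex``, ``location``,
``size_class``).  Non-detects are written as the literal token ``ND`` and read
back from either ``ND`` (case-insensitive) or an empty field, because
instrument exports differ in which convention they use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "MAX_CYCLES",
    "Specimen",
    "Group",
    "Stage",
    "ReplicateMeasurement",
    "SampleRecord",
    "Cohort",
    "SchemaError",
    "IntegrityError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "write_calls",
    "read_calls",
]

#: Total number of PCR cycles run; the largest Cp the instrument can report.
MAX_CYCLES = 50.0

REQUIRED_COLUMNS = (
    "sample_id",
    "subject_id",
    "specimen",
    "group",
    "stage",
    "replicate",
    "actb_cp",
    "sept9_cp",
)
COVARIATE_COLUMNS = ("age", "sex", "location", "size_class")

ND_TOKENS = frozenset({"", "nd"})


class Specimen(str, Enum):
    """Specimen type the assay was run on."""

    PLASMA = "plasma"
    STOOL = "stool"


class Group(str, Enum):
    """Diagnostic group of the subject."""

    NORMAL = "normal"
    AA = "AA"  # advanced adenoma
    CRC = "CRC"


class Stage(str, Enum):
    """Tumor stage; NOT_APPLICABLE for non-CRC subjects, UNKNOWN for
    unstaged/unrecorded CRC cases."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "NA"


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (replicate counts,
    duplicate samples, inconsistent per-sample metadata)."""


class CohortParseError(ValueError):
    """A field could not be parsed; the message carries the file line."""


def _parse_cp(token: str, *, column: str, line: int) -> Optional[float]:
    token = token.strip()
    if token.lower() in ND_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        raise CohortParseError(
            f"line {line}: cannot parse {column}={token!r} as a Cp value "
            f"(use a number, 'ND' or an empty field)"
        ) from None
    if not math.isfinite(value) or value <= 0 or value > MAX_CYCLES:
        raise CohortParseError(
            f"line {line}: {column}={value} outside (0, {MAX_CYCLES}]"
        )
    return value


@dataclass(frozen=True)
class ReplicateMeasurement:
    """One PCR well pair: internal-control Cp and marker Cp.

    ``None`` means the target produced no amplification signal within the run
    (non-detected).  Detected values must lie in (0, 50] cycles.
    """

    actb_cp: Optional[float]
    sept9_cp: Optional[float]

    def __post_init__(self) -> None:
        for name, value in (("actb_cp", self.actb_cp), ("sept9_cp", self.sept9_cp)):
            if value is None:
                continue
            if not math.isfinite(value) or value <= 0 or value > MAX_CYCLES:
                raise ValueError(
                    f"{name}={value!r}: detected Cp must be finite, > 0 and "
                    f"<= {MAX_CYCLES}"
                )


@dataclass(frozen=True)
class SampleRecord:
    """One specimen with its replicate measurements and metadata.

    ``subject_id`` is shared across a plasma/stool pair from the same person;
    ``(subject_id, specimen)`` is unique within a cohort.  Covariates are
    optional and ``None`` when unrecorded, so stratified analyses can exclude
    them explicitly.
    """

    sample_id: str
    subject_id: str
    specimen: Specimen
    group: Group
    stage: Stage
    replicates: tuple[ReplicateMeasurement, ...]
    age: Optional[float] = None
    sex: Optional[str] = None
    location: Optional[str] = None  # "distal" / "proximal"
    size_class: Optional[str] = None  # "<3cm" / "3-6cm" / ">6cm"

    def __post_init__(self) -> None:
        if self.group is not Group.CRC and self.stage is not Stage.NOT_APPLICABLE:
            raise ValueError(
                f"sample {self.sample_id}: stage={self.stage.value} but "
                f"group={self.group.value}; stage applies only to CRC"
            )
        if not self.replicates:
            raise ValueError(f"sample {self.sample_id}: no replicates")


@dataclass
class Cohort:
    """A set of samples sharing one replicate count."""

    samples: list[SampleRecord]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_keys: set[tuple[str, Specimen]] = set()
        for s in self.samples:
            if len(s.replicates) != self.n_replicates:
                raise IntegrityError(
                    f"sample {s.sample_id}: {len(s.replicates)} replicates, "
                    f"expected {self.n_replicates}"
                )
            if s.sample_id in seen_ids:
                raise IntegrityError(f"duplicate sample_id {s.sample_id}")
            key = (s.subject_id, s.specimen)
            if key in seen_keys:
                raise IntegrityError(
                    f"duplicate subject/specimen pair {s.subject_id}/{s.specimen.value}"
                )
            seen_ids.add(s.sample_id)
            seen_keys.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)

    def subset(
        self,
        specimen: Optional[Specimen] = None,
        group: Optional[Group] = None,
        stage: Optional[Stage] = None,
    ) -> "Cohort":
        """Samples matching all given filters (``None`` = no filter)."""
        picked = [
            s
            for s in self.samples
            if (specimen is None or s.specimen is specimen)
            and (group is None or s.group is group)
            and (stage is None or s.stage is stage)
        ]
        return Cohort(picked, n_replicates=self.n_replicates)


def _norm_optional(token: str) -> Optional[str]:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "N/A", "NONE"}:
        return None
    return token


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_cohort(
    path: str | Path,
    *,
    delimiter: Optional[str] = None,
    n_replicates: int = 3,
) -> Cohort:
    """Read a long-format replicate table into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV or TSV file with one row per PCR replicate.
    delimiter
        Field separator; auto-detected from the header line when ``None``.
    n_replicates
        Expected replicates per sample (1-based ``replicate`` indices
        ``1..n_replicates`` must each appear exactly once per sample).

    Raises
    ------
    SchemaError
        A mandatory column is absent.
    IntegrityError
        A sample has the wrong number of replicate rows, duplicated replicate
        indices, or inconsistent metadata across its rows.
    CohortParseError
        A Cp field is neither numeric nor a non-detect token; message names
        the offending file line.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    # Group rows by sample in order of first appearance.  +2: header line and
    # 1-based numbering.
    by_sample: dict[str, list[tuple[int, pd.Series]]] = {}
    for idx, row in frame.iterrows():
        by_sample.setdefault(row["sample_id"].strip(), []).append((idx + 2, row))

    samples: list[SampleRecord] = []
    bad: list[str] = []
    for sample_id, rows in by_sample.items():
        if len(rows) != n_replicates:
            bad.append(f"{sample_id} ({len(rows)} rows)")
            continue
        reps: dict[int, ReplicateMeasurement] = {}
        metas = set()
        line0, row0 = rows[0]
        for line, row in rows:
            try:
                rep_index = int(row["replicate"])
            except ValueError:
                raise CohortParseError(
                    f"line {line}: replicate index {row['replicate']!r} is not "
                    f"an integer"
                ) from None
            if rep_index < 1 or rep_index > n_replicates or rep_index in reps:
                raise IntegrityError(
                    f"sample {sample_id}: replicate indices must be a "
                    f"permutation of 1..{n_replicates}"
                )
            reps[rep_index] = ReplicateMeasurement(
                actb_cp=_parse_cp(row["actb_cp"], column="actb_cp", line=line),
                sept9_cp=_parse_cp(row["sept9_cp"], column="sept9_cp", line=line),
            )
            metas.add(
                tuple(row[c].strip() for c in ("subject_id", "specimen", "group", "stage"))
            )
        if len(metas) > 1:
            raise IntegrityError(
                f"sample {sample_id}: inconsistent metadata across replicate rows"
            )
        try:
            specimen = Specimen(row0["specimen"].strip().lower())
            group = Group(
                {"normal": "normal", "aa": "AA", "crc": "CRC"}[row0["group"].strip().lower()]
            )
        except (ValueError, KeyError):
            raise CohortParseError(
                f"line {line0}: unrecognized specimen/group "
                f"{row0['specimen']!r}/{row0['group']!r}"
            ) from None
        stage_token = _norm_optional(row0["stage"])
        if stage_token is None:
            stage = Stage.NOT_APPLICABLE
        else:
            try:
                stage = Stage(
                    stage_token if stage_token in {"I", "II", "III", "IV"} else stage_token.lower()
                )
            except ValueError:
                raise CohortParseError(f"line {line0}: unrecognized stage {stage_token!r}") from None
        age_token = _norm_optional(row0["age"]) if "age" in frame.columns else None
        samples.append(
            SampleRecord(
                sample_id=sample_id,
                subject_id=row0["subject_id"].strip(),
                specimen=specimen,
                group=group,
                stage=stage,
                replicates=tuple(reps[i] for i in range(1, n_replicates + 1)),
                age=float(age_token) if age_token is not None else None,
                sex=_norm_optional(row0["sex"]) if "sex" in frame.columns else None,
                location=_norm_optional(row0["location"]) if "location" in frame.columns else None,
                size_class=_norm_optional(row0["size_class"])
                if "size_class" in frame.columns
                else None,
            )
        )
    if bad:
        raise IntegrityError(
            f"samples without exactly {n_replicates} replicate rows: {', '.join(bad)}"
        )
    return Cohort(samples, n_replicates=n_replicates)


def _fmt_cp(value: Optional[float]) -> str:
    return "ND" if value is None else f"{value:.4f}"


def write_cohort(cohort: Cohort, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a cohort back to the long format (Cp to 4 decimals, ``ND`` for
    non-detects); ``read_cohort`` round-trips the result."""
    rows = []
    for s in cohort:
        for i, rep in enumerate(s.replicates, start=1):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "specimen": s.specimen.value,
                    "group": s.group.value,
                    "stage": s.stage.value,
                    "age": "" if s.age is None else f"{s.age:g}",
                    "sex": s.sex or "",
                    "location": s.location or "",
                    "size_class": s.size_class or "",
                    "replicate": i,
                    "actb_cp": _fmt_cp(rep.actb_cp),
                    "sept9_cp": _fmt_cp(rep.sept9_cp),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_calls(cohort: Cohort, calls: Sequence, path: str | Path) -> None:
    """Write per-sample call results joined to sample metadata as TSV.

    One row per call: identifiers, validity, replicate detection count,
    censored mean Cp (4 decimals) and the binary call (``positive`` /
    ``negative`` / ``NA`` for invalid samples).
    """
    if not calls:
        raise ValueError("no calls to write")
    by_id = {s.sample_id: s for s in cohort}
    rows = []
    for c in calls:
        s = by_id[c.sample_id]
        rows.append(
            {
                "sample_id": c.sample_id,
                "subject_id": s.subject_id,
                "specimen": s.specimen.value,
                "group": s.group.value,
                "stage": s.stage.value,
                "valid": str(c.valid).lower(),
                "n_detected": c.n_detected,
                "mean_cp_censored": f"{c.mean_cp_censored:.4f}",
                "call": "NA" if c.positive is None else ("positive" if c.positive else "negative"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame["valid"] = frame["valid"].map({"true": True, "false": False})
    frame["n_detected"] = frame["n_detected"].astype(int)
    frame["mean_cp_censored"] = frame["mean_cp_censored"].astype(float)
    return frame
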