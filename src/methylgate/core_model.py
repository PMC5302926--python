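"""Domain types for qPCR wells plus plate-file readers/writers.

A *plate file* is delimited text (comma or tab, autodetected) with one row
per well: ``sample_id, gene, role, replicate, ct`` and optional ``input_ng``
and ``cohort`` columns.  Non-amplifying wells carry a sentinel string
(``Undetermined`` by default) in the ``ct`` column.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import DuplicateReactionError, PlateFormatError, ValidationError

__all__ = [
    "CtStatus",
    "CtValue",
    "Role",
    "ReactionRecord",
    "Detection",
    "ReplicateSummary",
    "Strandedness",
    "SpectroReading",
    "PlateDialect",
    "read_plate",
    "write_plate",
    "aggregate_replicates",
    "dna_concentration",
    "load_dialect",
]

#: Absorbance-to-concentration factors (ng/uL per A260 unit).
_CONCENTRATION_FACTORS = {"SINGLE": 33.0, "DOUBLE": 50.0}


class CtStatus(Enum):
    DETERMINED = "DETERMINED"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class CtValue:
    """A cycle-threshold reading: either a non-negative cycle count or
    an undetermined (no-amplification) flag."""

    status: CtStatus
    cycles: float | None = None

    def __post_init__(self) -> None:
        if self.status is CtStatus.DETERMINED:
            if self.cycles is None or not math.isfinite(self.cycles) or self.cycles < 0:
                raise ValidationError(f"DETERMINED Ct requires finite cycles >= 0, got {self.cycles!r}")
        elif self.cycles is not None:
            raise ValidationError("UNDETERMINED Ct must not carry a cycles value")

    @classmethod
    def determined(cls, cycles: float) -> "CtValue":
        return cls(CtStatus.DETERMINED, float(cycles))

    @classmethod
    def undetermined(cls) -> "CtValue":
        return cls(CtStatus.UNDETERMINED)

    @property
    def is_determined(self) -> bool:
        return self.status is CtStatus.DETERMINED


class Role(Enum):
    REFERENCE = "REFERENCE"
    TARGET = "TARGET"


@dataclass(frozen=True)
class ReactionRecord:
    """One qPCR well."""

    sample_id: str
    gene: str
    role: Role
    replicate: int
    ct: CtValue
    input_ng: float | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")
        if self.input_ng is not None and self.input_ng < 0:
            raise ValidationError(f"input_ng must be >= 0, got {self.input_ng}")


class Detection(Enum):
    """Replicate-set detection class: all, some, or none of the wells amplified."""

    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


@dataclass(frozen=True)
class ReplicateSummary:
    """Aggregate over the replicate wells of one (sample, gene)."""

    sample_id: str
    gene: str
    n_total: int
    n_detected: int
    mean_ct: float | None
    detection: Detection

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not 0 <= self.n_detected <= self.n_total:
            raise ValidationError("n_detected must lie in [0, n_total]")
        expected = classify_detection(self.n_detected, self.n_total)
        if self.detection is not expected:
            raise ValidationError(
                f"detection {self.detection} inconsistent with "
                f"{self.n_detected}/{self.n_total} (expected {expected})"
            )
        if (self.mean_ct is None) != (self.n_detected == 0):
            raise ValidationError("mean_ct must be present iff n_detected >= 1")


def classify_detection(n_detected: int, n_total: int) -> Detection:
    """FULL / PARTIAL / NONE classification; exhaustive and mutually exclusive."""
    if n_detected == n_total:
        return Detection.FULL
    if n_detected == 0:
        return Detection.NONE
    return Detection.PARTIAL


class Strandedness(Enum):
    SINGLE = "SINGLE"
    DOUBLE = "DOUBLE"


@dataclass(frozen=True)
class SpectroReading:
    """A260 spectrophotometer reading (already multiplied by any dilution factor)."""

    a260_times_dilution: float
    strandedness: Strandedness

    def __post_init__(self) -> None:
        if self.a260_times_dilution < 0:
            raise ValidationError(f"absorbance must be >= 0, got {self.a260_times_dilution}")


def dna_concentration(reading: SpectroReading) -> float:
    """DNA concentration in ng/uL from an A260 reading.

    Single-stranded (bisulfite-converted) DNA uses factor 33,
    double-stranded genomic DNA factor 50.
    """
    return reading.a260_times_dilution * _CONCENTRATION_FACTORS[reading.strandedness.value]


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateDialect:
    """Configuration for reading/writing plate files.

    ``delimiter=None`` autodetects comma vs tab from the header line.
    Any DETERMINED Ct above ``max_cycles`` is reclassified UNDETERMINED at
    parse time (instruments differ on whether late weak signals are reported).
    """

    delimiter: str | None = None
    undetermined_sentinels: tuple[str, ...] = ("Undetermined", "Undet", "")
    max_cycles: float = 40.0
    reference_gene: str = "COL2A1"
    target_genes: tuple[str, ...] = ()

    def is_sentinel(self, text: str) -> bool:
        return text.strip() in self.undetermined_sentinels


def load_dialect(path: str | Path) -> PlateDialect:
    """Load a :class:`PlateDialect` from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "delimiter" in raw:
        kwargs["delimiter"] = raw["delimiter"]
    if "undetermined_sentinels" in raw:
        kwargs["undetermined_sentinels"] = tuple(str(s) for s in raw["undetermined_sentinels"])
    if "max_cycles" in raw:
        kwargs["max_cycles"] = float(raw["max_cycles"])
    if "reference_gene" in raw:
        kwargs["reference_gene"] = str(raw["reference_gene"])
    if "target_genes" in raw:
        kwargs["target_genes"] = tuple(str(g) for g in raw["target_genes"])
    return PlateDialect(**kwargs)


_REQUIRED_COLUMNS = ("sample_id", "gene", "role", "replicate", "ct")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","


def _parse_ct(text: str, dialect: PlateDialect, where: str) -> CtValue:
    if dialect.is_sentinel(text):
        return CtValue.undetermined()
    try:
        cycles = float(text)
    except ValueError:
        raise PlateFormatError(f"{where}: Ct value {text!r} is neither numeric nor a sentinel") from None
    if cycles < 0:
        raise PlateFormatError(f"{where}: negative Ct {cycles}")
    if cycles > dialect.max_cycles:
        return CtValue.undetermined()
    return CtValue.determined(cycles)


def read_plate(path: str | Path, dialect: PlateDialect | None = None) -> list[ReactionRecord]:
    """Read a delimited plate file into :class:`ReactionRecord` rows.

    Raises :class:`PlateFormatError` for missing columns or malformed values
    and :class:`DuplicateReactionError` for repeated well keys.
    """
    dialect = dialect or PlateDialect()
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PlateFormatError(f"{path}: empty plate file")
    first_line = text.splitlines()[0]
    delim = dialect.delimiter or _sniff_delimiter(first_line)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    header = [h.strip() for h in (reader.fieldnames or [])]
    for col in _REQUIRED_COLUMNS:
        if col not in header:
            raise PlateFormatError(f"{path}: missing required column {col!r}")

    records: list[ReactionRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in enumerate(reader, start=2):
        where = f"{path}:{i}"
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise PlateFormatError(f"{where}: replicate {row.get('replicate')!r} is not an integer") from None
        try:
            role = Role(row["role"].strip().upper())
        except ValueError:
            raise PlateFormatError(f"{where}: unknown role {row['role']!r}") from None
        ct = _parse_ct(row["ct"] if row["ct"] is not None else "", dialect, where)
        input_ng: float | None = None
        if row.get("input_ng") not in (None, ""):
            try:
                input_ng = float(row["input_ng"])
            except ValueError:
                raise PlateFormatError(f"{where}: input_ng {row['input_ng']!r} is not numeric") from None
        key = (row["sample_id"].strip(), row["gene"].strip(), replicate)
        if key in seen:
            raise DuplicateReactionError(key)
        seen.add(key)
        records.append(
            ReactionRecord(
                sample_id=key[0],
                gene=key[1],
                role=role,
                replicate=replicate,
                ct=ct,
                input_ng=input_ng,
                cohort=(row.get("cohort") or None),
            )
        )
    return records


def write_plate(
    records: Iterable[ReactionRecord],
    path: str | Path,
    dialect: PlateDialect | None = None,
) -> None:
    """Write records as delimited text; round-trips with :func:`read_plate`."""
    dialect = dialect or PlateDialect()
    delim = dialect.delimiter or ","
    sentinel = dialect.undetermined_sentinels[0]
    records = list(records)
    has_cohort = any(r.cohort is not None for r in records)
    columns = list(_REQUIRED_COLUMNS) + ["input_ng"] + (["cohort"] if has_cohort else [])
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delim)
        writer.writerow(columns)
        for r in records:
            row = [
                r.sample_id,
                r.gene,
                r.role.value,
                r.replicate,
                f"{r.ct.cycles:g}" if r.ct.is_determined else sentinel,
                "" if r.input_ng is None else f"{r.input_ng:g}",
            ]
            if has_cohort:
                row.append(r.cohort or "")
            writer.writerow(row)


def aggregate_replicates(records: Sequence[ReactionRecord]) -> list[ReplicateSummary]:
    """Collapse wells into one :class:`ReplicateSummary` per (sample, gene).

    The mean Ct is the arithmetic mean over DETERMINED replicates only;
    order of the input records does not matter.  All replicates of one
    (sample, gene) must share the same role.
    """
    groups: dict[tuple[str, str], list[ReactionRecord]] = {}
    for record in records:
        groups.setdefault((record.sample_id, record.gene), []).append(record)

    summaries: list[ReplicateSummary] = []
    for (sample_id, gene), wells in sorted(groups.items()):
        roles = {w.role for w in wells}
        if len(roles) > 1:
            raise ValidationError(f"mixed roles for ({sample_id}, {gene}): {sorted(r.value for r in roles)}")
        detected = [w.ct.cycles for w in wells if w.ct.is_determined]
        n_detected = len(detected)
        summaries.append(
            ReplicateSummary(
                sample_id=sample_id,
                gene=gene,
                n_total=len(wells),
                n_detected=n_detected,
                mean_ct=(math.fsum(detected) / n_detected) if n_detected else None,
                detection=classify_detection(n_detected, len(wells)),
            )
        )
    return summaries
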