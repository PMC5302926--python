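"""Two-axis dilution-array design and bookkeeping.

A methylated bisulfite-DNA working solution is first diluted with an
unmethylated bisulfite-DNA solution of equal concentration (the *methylated
axis*: changes the methylated fraction, keeps total DNA constant), then with
TE buffer (the *buffer axis*: scales total and methylated DNA together,
keeps the percentage constant).  Dilution factors are kept as exact
rationals; floating arithmetic enters only at presentation time.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .core_model import Detection, ReplicateSummary, classify_detection
from .errors import PlateFormatError, ValidationError

__all__ = [
    "DilutionCondition",
    "ArrayMeasurement",
    "build_array",
    "reaction_volume_amount",
    "round_amount",
    "round_percent",
    "load_reference_array",
    "read_array_measurements",
    "write_array_design",
]

Rational = Fraction | int


def _as_fraction(value, name: str) -> Fraction:
    try:
        return Fraction(value) if not isinstance(value, float) else Fraction.from_float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be a rational number, got {value!r}") from None


def _round_double(value: float, ndigits: int) -> float:
    # Round the double-precision value half-up on its *exact* binary
    # expansion.  Lab software computes these amounts in doubles, so e.g.
    # 1.18/4 is 0.29499999999999998... and prints as 0.29, not 0.30.
    return float(Decimal(value).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))

def round_amount(value: float, ndigits: int = 2) -> float:
    """Presentation rounding for ng amounts: two decimals, extended one
    digit at a time while the rounded value would collapse to zero."""
    if value < 0:
        raise ValidationError(f"amount must be >= 0, got {value}")
    rounded = _round_double(value, ndigits)
    while rounded == 0.0 and value > 0.0 and ndigits < 12:
        ndigits += 1
        rounded = _round_double(value, ndigits)
    return rounded


def round_percent(value: float) -> float:
    """Presentation rounding for methylated percentages: one decimal."""
    return _round_double(value, 1)


@dataclass(frozen=True)
class DilutionCondition:
    """One cell of the dilution array.

    Amounts are stored as exact :class:`~fractions.Fraction` values so the
    identity ``net_meth_ng == total_ng * meth_pct / 100`` holds exactly;
    the ``*_rounded`` properties apply the presentation convention.
    """

    meth_dilution: Fraction
    te_dilution: Fraction
    total_ng: Fraction
    net_meth_ng: Fraction
    meth_pct: Fraction

    def __post_init__(self) -> None:
        if not 0 < self.meth_dilution <= 1:
            raise ValidationError(f"meth_dilution must be in (0, 1], got {self.meth_dilution}")
        if not 0 < self.te_dilution <= 1:
            raise ValidationError(f"te_dilution must be in (0, 1], got {self.te_dilution}")
        if self.total_ng <= 0:
            raise ValidationError(f"total_ng must be > 0, got {self.total_ng}")
        if self.net_meth_ng < 0:
            raise ValidationError(f"net_meth_ng must be >= 0, got {self.net_meth_ng}")
        if self.net_meth_ng > self.total_ng:
            raise ValidationError(
                f"net methylated DNA ({self.net_meth_ng}) exceeds total DNA ({self.total_ng})"
            )

    @property
    def total_ng_rounded(self) -> float:
        return round_amount(float(self.total_ng))

    @property
    def net_meth_ng_rounded(self) -> float:
        return round_amount(float(self.net_meth_ng))

    @property
    def meth_pct_rounded(self) -> float:
        return round_percent(float(self.meth_pct))


def build_array(
    base_total_ng,
    base_net_ng,
    meth_dilutions: Sequence[Rational],
    te_dilutions: Sequence[Rational],
) -> list[DilutionCondition]:
    """Cartesian product of the methylated and buffer dilution axes.

    ``base_total_ng`` / ``base_net_ng`` describe the undiluted condition.
    Conditions are returned buffer-axis major (all methylated dilutions at
    full strength first), matching the usual bench layout.
    """
    base_total = _as_fraction(base_total_ng, "base_total_ng")
    base_net = _as_fraction(base_net_ng, "base_net_ng")
    if base_net > base_total:
        raise ValidationError(f"base_net_ng ({base_net_ng}) exceeds base_total_ng ({base_total_ng})")
    if base_total <= 0:
        raise ValidationError("base_total_ng must be > 0")

    conditions: list[DilutionCondition] = []
    for te in te_dilutions:
        te_f = _as_fraction(te, "te_dilution")
        for meth in meth_dilutions:
            meth_f = _as_fraction(meth, "meth_dilution")
            total = base_total * te_f
            net = base_net * meth_f * te_f
            conditions.append(
                DilutionCondition(
                    meth_dilution=meth_f,
                    te_dilution=te_f,
                    total_ng=total,
                    net_meth_ng=net,
                    meth_pct=100 * net / total,
                )
            )
    return conditions


def reaction_volume_amount(conc_ng_per_ul: float, aliquot_ul: float) -> float:
    """DNA mass per reaction (ng) from concentration and aliquot volume."""
    if conc_ng_per_ul <= 0:
        raise ValidationError(f"concentration must be > 0, got {conc_ng_per_ul}")
    if aliquot_ul <= 0:
        raise ValidationError(f"aliquot volume must be > 0, got {aliquot_ul}")
    return conc_ng_per_ul * aliquot_ul


@dataclass(frozen=True)
class ArrayMeasurement:
    """Measured replicate summaries for one dilution condition."""

    condition: DilutionCondition
    reference: ReplicateSummary
    targets: dict[str, ReplicateSummary]

    def summary_for(self, gene: str) -> ReplicateSummary:
        if gene == self.reference.gene:
            return self.reference
        try:
            return self.targets[gene]
        except KeyError:
            raise ValidationError(f"no measurement for gene {gene!r} in this condition") from None


# ---------------------------------------------------------------------------
# Delimited-text array I/O
# ---------------------------------------------------------------------------
#
# Format (comma- or tab-separated, header required):
#   meth_dilution, te_dilution, total_ng, net_ng, meth_pct,
#   <GENE>_ct, <GENE>_detection      (one pair per assayed gene)
# Dilutions are written as exact fractions ("1", "1/4").  A missing Ct with
# detection NONE means no replicate amplified.

_CONDITION_COLUMNS = ("meth_dilution", "te_dilution", "total_ng", "net_ng", "meth_pct")

_DETECTION_COUNTS = {Detection.FULL: 3, Detection.PARTIAL: 2, Detection.NONE: 0}


def _summary(sample_id: str, gene: str, detection: Detection, mean_ct: float | None,
             n_total: int = 3) -> ReplicateSummary:
    n_detected = _DETECTION_COUNTS[detection] if n_total == 3 else {
        Detection.FULL: n_total, Detection.PARTIAL: max(1, n_total - 1), Detection.NONE: 0
    }[detection]
    return ReplicateSummary(
        sample_id=sample_id,
        gene=gene,
        n_total=n_total,
        n_detected=n_detected,
        mean_ct=mean_ct if n_detected else None,
        detection=classify_detection(n_detected, n_total),
    )


def read_array_measurements(
    source: str | Path | io.TextIOBase,
    reference_gene: str = "COL2A1",
) -> list[ArrayMeasurement]:
    """Read measured dilution-array rows from delimited text.

    Replicate counts are not stored in this format; summaries are
    reconstructed with a nominal triplicate (FULL=3/3, PARTIAL=2/3, NONE=0/3).
    Only the detection class matters downstream.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        name = str(source)
    else:
        text = source.read()
        name = "<stream>"
    if not text.strip():
        raise PlateFormatError(f"{name}: empty array file")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    header = reader.fieldnames or []
    for col in _CONDITION_COLUMNS:
        if col not in header:
            raise PlateFormatError(f"{name}: missing required column {col!r}")
    genes = [c[: -len("_ct")] for c in header if c.endswith("_ct")]
    if reference_gene not in genes:
        raise PlateFormatError(f"{name}: no {reference_gene}_ct column for the reference gene")

    measurements: list[ArrayMeasurement] = []
    for i, row in enumerate(reader, start=2):
        meth = Fraction(row["meth_dilution"])
        te = Fraction(row["te_dilution"])
        total = Fraction(row["total_ng"])
        net = Fraction(row["net_ng"])
        condition = DilutionCondition(
            meth_dilution=meth,
            te_dilution=te,
            total_ng=total,
            net_meth_ng=net,
            meth_pct=Fraction(row["meth_pct"]),
        )
        sample_id = f"array[{meth}x{te}]"
        reference = None
        targets: dict[str, ReplicateSummary] = {}
        for gene in genes:
            det_text = row.get(f"{gene}_detection", "").strip().upper()
            try:
                detection = Detection(det_text)
            except ValueError:
                raise PlateFormatError(f"{name}:{i}: bad detection {det_text!r} for {gene}") from None
            ct_text = (row.get(f"{gene}_ct") or "").strip()
            mean_ct = float(ct_text) if ct_text and detection is not Detection.NONE else None
            summary = _summary(sample_id, gene, detection, mean_ct)
            if gene == reference_gene:
                reference = summary
            else:
                targets[gene] = summary
        assert reference is not None
        measurements.append(ArrayMeasurement(condition=condition, reference=reference, targets=targets))
    return measurements


def write_array_design(conditions: Iterable[DilutionCondition], path: str | Path) -> None:
    """Emit the design (no measurements) as delimited text."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CONDITION_COLUMNS)
        for c in conditions:
            writer.writerow(
                [str(c.meth_dilution), str(c.te_dilution),
                 f"{c.total_ng_rounded:g}", f"{c.net_meth_ng_rounded:g}", f"{c.meth_pct_rounded:g}"]
            )


def load_reference_array() -> list[ArrayMeasurement]:
    """Packaged GFRA1/P16 MethyLight dilution-array validation dataset.

    28 conditions: methylated axis {1, 1/2, ..., 1/64} against buffer axis
    {1, 1/2, 1/4, 1/8}, with mean Ct and triplicate detection class for the
    COL2A1 input reference and the GFRA1 and P16 targets.
    """
    data = resources.files("methylgate").joinpath("data/gfra1_p16_dilution_array.csv")
    with resources.as_file(data) as path:
        return read_array_measurements(path, reference_gene="COL2A1")
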