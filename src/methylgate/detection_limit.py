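"""Detection-limit estimation and input-gating policy derivation.

The detection limit is the smallest methylated-template mass per reaction,
among the amounts actually present in a measured dilution array, at and
above which *every* condition — across all background (unmethylated-DNA or
buffer) contexts — shows full replicate detection.  Dividing that limit by
the chosen cutoff fraction of methylated alleles gives the minimum total
template per reaction; the matching reference-gene Ct becomes the gating
threshold for cohort samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import yaml

from .core_model import Detection
from .dilution_array import ArrayMeasurement
from .errors import NoReliableLimitError, ValidationError

__all__ = [
    "DetectionLimitResult",
    "InputPolicy",
    "estimate_detection_limit",
    "derive_policy",
    "reference_standard_points",
]


def _round1(value: float) -> float:
    return float(Decimal(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DetectionLimitResult:
    """Outcome of :func:`estimate_detection_limit` for one gene."""

    gene: str
    limit_ng: float
    n_conditions_at_limit: int
    conditions_considered: list[tuple[float, Detection]] = field(repr=False)


@dataclass(frozen=True)
class InputPolicy:
    """Template-input gating rule derived from a detection limit.

    ``min_input_ng`` is kept at full precision (``detection_limit_ng /
    cutoff_fraction``); ``min_input_ng_rounded`` applies the one-decimal
    presentation convention.  ``ct_threshold`` is the reference-gene Ct at
    the minimum input; samples with a higher reference Ct are
    methylation-non-informative.
    """

    detection_limit_ng: float
    cutoff_fraction: float
    min_input_ng: float
    ct_threshold: float | None
    n_reactions: int
    total_requirement_ng: int

    @property
    def min_input_ng_rounded(self) -> float:
        return _round1(self.min_input_ng)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "detection_limit_ng": self.detection_limit_ng,
            "cutoff_fraction": self.cutoff_fraction,
            "min_input_ng": self.min_input_ng,
            "min_input_ng_rounded": self.min_input_ng_rounded,
            "ct_threshold": self.ct_threshold,
            "n_reactions": self.n_reactions,
            "total_requirement_ng": self.total_requirement_ng,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InputPolicy":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            detection_limit_ng=float(raw["detection_limit_ng"]),
            cutoff_fraction=float(raw["cutoff_fraction"]),
            min_input_ng=float(raw["min_input_ng"]),
            ct_threshold=None if raw.get("ct_threshold") is None else float(raw["ct_threshold"]),
            n_reactions=int(raw["n_reactions"]),
            total_requirement_ng=int(raw["total_requirement_ng"]),
        )


def estimate_detection_limit(
    measurements: Sequence[ArrayMeasurement], gene: str
) -> DetectionLimitResult:
    """Smallest net methylated amount with full detection at and above it.

    Amounts are taken as given by the array (no interpolation between
    dilution steps).  Raises :class:`NoReliableLimitError` if even the
    largest amount present has a condition without full detection.
    """
    conditions: list[tuple[float, Detection]] = []
    for m in measurements:
        summary = m.summary_for(gene)
        conditions.append((float(m.condition.net_meth_ng), summary.detection))
    amounts = sorted({net for net, _ in conditions})
    if len(amounts) < 2:
        raise ValidationError("need at least 2 distinct net amounts to estimate a limit")

    limit: float | None = None
    for amount in sorted(amounts, reverse=True):
        at_amount = [det for net, det in conditions if net == amount]
        if all(det is Detection.FULL for det in at_amount):
            limit = amount
        else:
            break
    if limit is None:
        offending = [(net, det) for net, det in conditions
                     if net == amounts[-1] and det is not Detection.FULL]
        raise NoReliableLimitError(gene, offending)

    return DetectionLimitResult(
        gene=gene,
        limit_ng=limit,
        n_conditions_at_limit=sum(1 for net, _ in conditions if net == limit),
        conditions_considered=sorted(conditions, key=lambda c: (c[0], c[1].value)),
    )


def reference_standard_points(
    measurements: Sequence[ArrayMeasurement],
    undiluted_only: bool = True,
) -> list[tuple[float, float]]:
    """(total_ng, mean reference Ct) pairs from a measured array.

    With ``undiluted_only`` (default) only the conditions at full strength on
    the methylated axis are used, one point per buffer-dilution step — the
    cleanest single-measurement standard curve for the reference gene.
    """
    points = []
    for m in measurements:
        if undiluted_only and m.condition.meth_dilution != 1:
            continue
        if m.reference.mean_ct is not None:
            points.append((float(m.condition.total_ng), m.reference.mean_ct))
    return sorted(points)


def _ct_at_amount(points: list[tuple[float, float]], amount_ng: float) -> float:
    """Reference Ct at ``amount_ng``: nearest standard point within 5%
    relative distance, else linear interpolation of Ct vs log2(amount)."""
    nearest_total, nearest_ct = min(points, key=lambda p: abs(p[0] - amount_ng))
    if abs(nearest_total - amount_ng) / amount_ng <= 0.05:
        return nearest_ct
    cts = [ct for _, ct in points]
    if any(b > a for a, b in zip(cts, cts[1:])):  # points sorted by amount
        warnings.warn(
            "reference Ct is not monotonically decreasing with amount; "
            "interpolating on log2(amount) anyway",
            stacklevel=3,
        )
    logx = [math.log2(total) for total, _ in points]
    x = math.log2(amount_ng)
    if x <= logx[0]:
        lo, hi = 0, 1
    elif x >= logx[-1]:
        lo, hi = len(points) - 2, len(points) - 1
    else:
        hi = next(i for i, v in enumerate(logx) if v >= x)
        lo = hi - 1
    t = (x - logx[lo]) / (logx[hi] - logx[lo])
    return cts[lo] + t * (cts[hi] - cts[lo])


def derive_policy(
    limit: DetectionLimitResult,
    cutoff_fraction: float,
    n_reactions: int,
    standard_points: Sequence[tuple[float, float]] = (),
) -> InputPolicy:
    """Turn a detection limit into an :class:`InputPolicy`.

    ``min_input_ng = limit_ng / cutoff_fraction`` guarantees that a sample
    carrying exactly the cutoff fraction of methylated alleles still puts
    the detection-limit mass of methylated template into each reaction.
    ``total_requirement_ng`` is the per-sample total for ``n_reactions``
    reactions, ceiling-rounded to integer nanograms.
    """
    if not 0 < cutoff_fraction <= 1:
        raise ValidationError(f"cutoff_fraction must be in (0, 1], got {cutoff_fraction}")
    if n_reactions < 1:
        raise ValidationError(f"n_reactions must be >= 1, got {n_reactions}")

    min_input = limit.limit_ng / cutoff_fraction
    points = sorted(standard_points)
    ct_threshold = _round1(_ct_at_amount(points, min_input)) if points else None
    return InputPolicy(
        detection_limit_ng=limit.limit_ng,
        cutoff_fraction=cutoff_fraction,
        min_input_ng=min_input,
        ct_threshold=ct_threshold,
        n_reactions=n_reactions,
        total_requirement_ng=math.ceil(min_input * n_reactions),
    )
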