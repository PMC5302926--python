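"""Apply an input policy to cohorts: informative gating, methylation
calls, relative-quantification, and the re-analysis workflow."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .core_model import (
    Detection,
    ReactionRecord,
    ReplicateSummary,
    Role,
    aggregate_replicates,
)
from .detection_limit import InputPolicy
from .errors import IncompleteReassayError, ValidationError

__all__ = [
    "Informative",
    "Call",
    "AssayKind",
    "SampleAssayResult",
    "PmrEstimate",
    "ReanalysisSummary",
    "gate_sample",
    "call_methylation",
    "pmr",
    "analyze_samples",
    "reanalyze",
    "write_results",
]


class Informative(Enum):
    INFORMATIVE = "INFORMATIVE"
    NON_INFORMATIVE = "NON_INFORMATIVE"
    NO_REFERENCE = "NO_REFERENCE"


class Call(Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INDETERMINATE = "INDETERMINATE"  # only with partial_as_indeterminate


class AssayKind(Enum):
    METHYLIGHT = "METHYLIGHT"
    MSP = "MSP"
    DHPLC = "DHPLC"


@dataclass(frozen=True)
class SampleAssayResult:
    """Per-sample aggregate: gate status plus per-gene methylation calls."""

    sample_id: str
    cohort_label: str | None
    ref_ct: float | None
    informative: Informative
    calls: dict[str, Call]
    assay_kind: AssayKind = AssayKind.METHYLIGHT
    pass_index: int = 1

    def __post_init__(self) -> None:
        if self.pass_index < 1:
            raise ValidationError("pass_index must be >= 1")
        if (self.ref_ct is None) != (self.informative is Informative.NO_REFERENCE):
            raise ValidationError("ref_ct must be absent exactly when status is NO_REFERENCE")


@dataclass(frozen=True)
class PmrEstimate:
    """Percent of methylated reference (relative to a fully methylated calibrator)."""

    gene: str
    pmr_pct: float
    exceeds_calibrator: bool


def gate_sample(ref_summary: ReplicateSummary, policy: InputPolicy) -> Informative:
    """Classify a sample by its reference-gene Ct against the policy threshold.

    A Ct exactly at the threshold is INFORMATIVE (the rule is ``<=``).
    A reference with no detected replicate is NO_REFERENCE — an assay
    failure, deliberately distinct from non-informative.
    """
    if policy.ct_threshold is None:
        raise ValidationError("policy has no ct_threshold; cannot gate by reference Ct")
    if ref_summary.detection is Detection.NONE or ref_summary.mean_ct is None:
        return Informative.NO_REFERENCE
    if ref_summary.mean_ct <= policy.ct_threshold:
        return Informative.INFORMATIVE
    return Informative.NON_INFORMATIVE


def call_methylation(
    target_summary: ReplicateSummary, partial_as_indeterminate: bool = False
) -> Call:
    """POSITIVE iff the methylation signal is detected in every replicate.

    Partial detection is NEGATIVE by default (no cutoff value is applied;
    consistency across the whole replicate set is the positive criterion).
    Set ``partial_as_indeterminate`` for a tri-state readout.
    """
    if target_summary.detection is Detection.FULL:
        return Call.POSITIVE
    if target_summary.detection is Detection.PARTIAL and partial_as_indeterminate:
        return Call.INDETERMINATE
    return Call.NEGATIVE


def pmr(
    target_ct: float,
    ref_ct: float,
    calibrator_target_ct: float,
    calibrator_ref_ct: float,
    efficiency: float = 2.0,
    gene: str = "",
) -> PmrEstimate:
    """Relative methylated copy number versus a fully methylated calibrator.

    ``100 * efficiency ** -((target - ref) - (calibrator_target - calibrator_ref))``.
    Values above 100 are allowed and flagged.
    """
    if efficiency <= 1:
        raise ValidationError(f"efficiency must be > 1, got {efficiency}")
    ddct = (target_ct - ref_ct) - (calibrator_target_ct - calibrator_ref_ct)
    value = 100.0 * efficiency ** (-ddct)
    return PmrEstimate(gene=gene, pmr_pct=value, exceeds_calibrator=value > 100.0)


def analyze_samples(
    records: Sequence[ReactionRecord],
    policy: InputPolicy,
    reference_gene: str = "COL2A1",
    assay_kind: AssayKind = AssayKind.METHYLIGHT,
    pass_index: int = 1,
    partial_as_indeterminate: bool = False,
) -> list[SampleAssayResult]:
    """Aggregate plate records, gate each sample, and call each target gene.

    For MSP/DHPLC cohorts the target wells carry the externally supplied
    binary readout encoded as FULL/NONE detection; the gate itself is always
    driven by the qPCR reference summaries.
    """
    summaries = aggregate_replicates(records)
    by_sample: dict[str, dict[str, ReplicateSummary]] = {}
    for summary in summaries:
        by_sample.setdefault(summary.sample_id, {})[summary.gene] = summary
    cohorts = {r.sample_id: r.cohort for r in records if r.cohort is not None}

    results = []
    for sample_id, genes in sorted(by_sample.items()):
        if reference_gene not in genes:
            raise ValidationError(f"sample {sample_id!r} has no {reference_gene} reference wells")
        ref = genes[reference_gene]
        status = gate_sample(ref, policy)
        calls = {
            gene: call_methylation(summary, partial_as_indeterminate)
            for gene, summary in genes.items()
            if gene != reference_gene
        }
        results.append(
            SampleAssayResult(
                sample_id=sample_id,
                cohort_label=cohorts.get(sample_id),
                ref_ct=ref.mean_ct,
                informative=status,
                calls=calls,
                assay_kind=assay_kind,
                pass_index=pass_index,
            )
        )
    return results


@dataclass(frozen=True)
class ReanalysisSummary:
    """Positive rates among the re-analyzed subset, before and after."""

    n_reanalyzed: int
    rate_before_pct: dict[str, float]
    rate_after_pct: dict[str, float]
    still_non_informative: tuple[str, ...]


def _positive_pct(results: Iterable[SampleAssayResult], gene: str) -> float:
    calls = [r.calls[gene] for r in results if gene in r.calls]
    if not calls:
        return float("nan")
    return 100.0 * sum(c is Call.POSITIVE for c in calls) / len(calls)


def reanalyze(
    pass1_results: Sequence[SampleAssayResult],
    reassay_records: Sequence[ReactionRecord],
    policy: InputPolicy,
    reference_gene: str = "COL2A1",
) -> tuple[list[SampleAssayResult], ReanalysisSummary]:
    """Re-analyze the pass-1 non-informative samples at boosted input.

    ``reassay_records`` must cover every pass-1 NON_INFORMATIVE sample.
    The same gate and call rules are applied; samples still above the Ct
    threshold after the boost are flagged and excluded from the after-rate.
    """
    targets = {r.sample_id for r in pass1_results if r.informative is Informative.NON_INFORMATIVE}
    reassay_samples = {r.sample_id for r in reassay_records}
    missing = targets - reassay_samples
    if missing:
        raise IncompleteReassayError(sorted(missing))
    if not targets:
        return [], ReanalysisSummary(0, {}, {}, ())

    relevant = [r for r in reassay_records if r.sample_id in targets]
    pass2 = analyze_samples(relevant, policy, reference_gene=reference_gene, pass_index=2)

    pass1_subset = [r for r in pass1_results if r.sample_id in targets]
    genes = sorted({g for r in pass1_subset for g in r.calls})
    still = tuple(sorted(r.sample_id for r in pass2 if r.informative is not Informative.INFORMATIVE))
    informative_pass2 = [r for r in pass2 if r.informative is Informative.INFORMATIVE]
    summary = ReanalysisSummary(
        n_reanalyzed=len(targets),
        rate_before_pct={g: _positive_pct(pass1_subset, g) for g in genes},
        rate_after_pct={g: _positive_pct(informative_pass2, g) for g in genes},
        still_non_informative=still,
    )
    return pass2, summary


def write_results(results: Sequence[SampleAssayResult], path: str | Path) -> None:
    """One row per sample x gene x pass, as delimited text."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["sample_id", "cohort", "pass", "assay", "ref_ct", "informative", "gene", "call"]
        )
        for r in results:
            base = [
                r.sample_id,
                r.cohort_label or "",
                r.pass_index,
                r.assay_kind.value,
                "" if r.ref_ct is None else f"{r.ref_ct:.2f}",
                r.informative.value,
            ]
            if not r.calls:
                writer.writerow(base + ["", ""])
            for gene in sorted(r.calls):
                writer.writerow(base + [gene, r.calls[gene].value])
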