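"""Single-molecule stochastic simulator for bisulfite-template qPCR.

Template molecules entering a reaction are Poisson-sampled from the input
mass; bisulfite damage, strand loss, and conversion failure are collapsed
into a single per-molecule amplification probability.  A reaction with no
surviving amplifiable copy never crosses the fluorescence threshold, which
is exactly the low-input dropout mechanism that produces false-negative
methylation calls.  Unmethylated templates never produce target signal
(no false-positive mechanism).

Default parameters are a calibration: the efficiency reproduces the
~1.25-cycle spacing per 2-fold dilution seen on the packaged reference
array, and the intercept keeps single-copy reactions below the cycle cap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from math import exp, log
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import CtValue, ReactionRecord, Role, aggregate_replicates
from .dilution_array import ArrayMeasurement, build_array
from .errors import ValidationError

__all__ = [
    "AssaySimParams",
    "Tissue",
    "SyntheticSample",
    "simulate_reaction",
    "detection_probability",
    "simulate_dilution_array",
    "simulate_cohort",
    "simulate_sample_plate",
    "truth_table",
    "lognormal_dna_sampler",
    "beta_fraction_sampler",
]


@dataclass(frozen=True)
class AssaySimParams:
    """Parameterization of one simulated assay.

    ng_per_copy
        Bisulfite-template mass per amplifiable target copy.  One haploid
        genome is ~3.3 pg and only one strand is amplifiable, so the
        default is 0.0066 ng per copy.
    p_amp
        Per-molecule probability of successful amplification after
        bisulfite damage / strand loss / conversion failure.
    efficiency
        Per-cycle amplification factor; 2 is textbook doubling, the default
        1.74 matches the observed ~1.25 Ct per 2-fold dilution.
    ct_at_one_copy
        Ct intercept for a single effective starting copy.
    sigma_ct
        Gaussian replicate noise on detected Ct values.
    max_cycles
        Run length; detected Ct beyond it is reported undetermined.
    """

    ng_per_copy: float = 0.0066
    p_amp: float = 0.25
    efficiency: float = 1.74
    ct_at_one_copy: float = 38.0
    sigma_ct: float = 0.25
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        if self.ng_per_copy <= 0:
            raise ValidationError("ng_per_copy must be > 0")
        if not 0 < self.p_amp <= 1:
            raise ValidationError("p_amp must be in (0, 1]")
        if not 1 < self.efficiency <= 2:
            raise ValidationError("efficiency must be in (1, 2]")
        if self.sigma_ct < 0:
            raise ValidationError("sigma_ct must be >= 0")


class Tissue(Enum):
    FFPE = "FFPE"
    FROZEN = "FROZEN"


@dataclass(frozen=True)
class SyntheticSample:
    """Ground truth for one simulated sample."""

    sample_id: str
    true_meth_fraction: float
    available_dna_ng: float
    tissue_label: Tissue

    def __post_init__(self) -> None:
        if not 0 <= self.true_meth_fraction <= 1:
            raise ValidationError("true_meth_fraction must be in [0, 1]")
        if self.available_dna_ng <= 0:
            raise ValidationError("available_dna_ng must be > 0")


def detection_probability(lam: float, p_amp: float) -> float:
    """P(at least one amplifiable copy) = 1 - exp(-lambda * p_amp).

    Closed-form companion of :func:`simulate_reaction` (thinned Poisson);
    ignores the cycle cap, which only binds when the Ct intercept sits at
    or above ``max_cycles``.
    """
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if not 0 <= p_amp <= 1:
        raise ValidationError("p_amp must be in [0, 1]")
    return 1.0 - exp(-lam * p_amp)


def _substream(master_seed: int, *key) -> np.random.Generator:
    """Deterministic per-reaction RNG, independent of generation order."""
    digest = hashlib.sha256(repr((master_seed,) + key).encode()).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:16], "big")))


def simulate_ct(
    total_ng: float,
    meth_fraction: float,
    gene_role: Role,
    params: AssaySimParams,
    rng: np.random.Generator,
) -> CtValue:
    """Draw one Ct value.

    Target reactions see only the methylated template mass
    (``total_ng * meth_fraction``); the reference sees everything.
    """
    if total_ng < 0:
        raise ValidationError("total_ng must be >= 0")
    if not 0 <= meth_fraction <= 1:
        raise ValidationError("meth_fraction must be in [0, 1]")
    lam = total_ng / params.ng_per_copy
    if gene_role is Role.TARGET:
        lam *= meth_fraction
    n_templates = rng.poisson(lam)
    k_effective = rng.binomial(n_templates, params.p_amp) if n_templates else 0
    if k_effective == 0:
        return CtValue.undetermined()
    ct = params.ct_at_one_copy - log(k_effective) / log(params.efficiency)
    if params.sigma_ct > 0:
        ct += rng.normal(0.0, params.sigma_ct)
    if ct > params.max_cycles or ct < 0:
        return CtValue.undetermined()
    return CtValue.determined(ct)


def simulate_reaction(
    total_ng: float,
    meth_fraction: float,
    gene_role: Role,
    params: AssaySimParams,
    rng: np.random.Generator,
    sample_id: str = "sim",
    gene: str = "TARGET",
    replicate: int = 1,
    cohort: str | None = None,
) -> ReactionRecord:
    """One simulated well as a :class:`ReactionRecord`."""
    return ReactionRecord(
        sample_id=sample_id,
        gene=gene,
        role=gene_role,
        replicate=replicate,
        ct=simulate_ct(total_ng, meth_fraction, gene_role, params, rng),
        input_ng=total_ng,
        cohort=cohort,
    )


def simulate_dilution_array(
    base_total_ng: float,
    base_net_ng: float,
    meth_dilutions: Sequence,
    te_dilutions: Sequence,
    replicates: int,
    params: AssaySimParams | Mapping[str, AssaySimParams],
    seed: int,
    reference_gene: str = "COL2A1",
    target_genes: Sequence[str] = ("GFRA1",),
) -> list[ArrayMeasurement]:
    """Simulate a measured two-axis dilution array.

    The unmethylated diluent contributes template to the reference gene but
    not to the targets.  ``params`` may be a single parameter set or a
    per-gene mapping.  Triplicate (or more) wells are aggregated into
    replicate summaries per condition and gene.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")

    def params_for(gene: str) -> AssaySimParams:
        return params[gene] if isinstance(params, Mapping) else params

    conditions = build_array(base_total_ng, base_net_ng, meth_dilutions, te_dilutions)
    measurements: list[ArrayMeasurement] = []
    for idx, condition in enumerate(conditions):
        total = float(condition.total_ng)
        fraction = float(condition.meth_pct) / 100.0
        sample_id = f"array[{condition.meth_dilution}x{condition.te_dilution}]"
        records: list[ReactionRecord] = []
        for gene, role in [(reference_gene, Role.REFERENCE)] + [
            (g, Role.TARGET) for g in target_genes
        ]:
            for rep in range(1, replicates + 1):
                rng = _substream(seed, "array", idx, gene, rep)
                records.append(
                    simulate_reaction(
                        total, fraction, role, params_for(gene), rng,
                        sample_id=sample_id, gene=gene, replicate=rep,
                    )
                )
        summaries = {s.gene: s for s in aggregate_replicates(records)}
        measurements.append(
            ArrayMeasurement(
                condition=condition,
                reference=summaries[reference_gene],
                targets={g: summaries[g] for g in target_genes},
            )
        )
    return measurements


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: samplers take (rng, n) and return an array of n draws.
Sampler = Callable[[np.random.Generator, int], np.ndarray]


def lognormal_dna_sampler(median_ng: float, sigma_log: float = 1.0) -> Sampler:
    """Per-sample available-DNA sampler (ng), lognormal around ``median_ng``."""
    if median_ng <= 0:
        raise ValidationError("median_ng must be > 0")
    mu = log(median_ng)
    return lambda rng, n: rng.lognormal(mu, sigma_log, size=n)


def beta_fraction_sampler(a: float = 2.0, b: float = 18.0, floor: float = 0.0) -> Sampler:
    """Per-sample methylated-fraction sampler on [floor, 1]."""
    return lambda rng, n: floor + (1.0 - floor) * rng.beta(a, b, size=n)


def _draw_samples(
    n_samples: int,
    seed: int,
    fraction_sampler: Sampler,
    dna_samplers: Mapping[Tissue, Sampler],
    tissue_probs: Mapping[Tissue, float],
    id_prefix: str,
) -> list[SyntheticSample]:
    rng = _substream(seed, "cohort-design")
    tissues = list(tissue_probs)
    probs = np.array([tissue_probs[t] for t in tissues], dtype=float)
    probs /= probs.sum()
    labels = rng.choice(len(tissues), size=n_samples, p=probs)
    fractions = fraction_sampler(rng, n_samples)
    samples = []
    for i in range(n_samples):
        tissue = tissues[labels[i]]
        dna = float(dna_samplers[tissue](rng, 1)[0])
        samples.append(
            SyntheticSample(
                sample_id=f"{id_prefix}{i + 1:04d}",
                true_meth_fraction=float(np.clip(fractions[i], 0.0, 1.0)),
                available_dna_ng=dna,
                tissue_label=tissue,
            )
        )
    return samples


def simulate_sample_plate(
    samples: Sequence[SyntheticSample],
    input_ng: Mapping[str, float],
    params: AssaySimParams | Mapping[str, AssaySimParams],
    seed: int,
    reference_gene: str = "COL2A1",
    target_genes: Sequence[str] = ("GFRA1",),
    n_replicates: int = 3,
    pass_index: int = 1,
) -> list[ReactionRecord]:
    """Simulate reference and target wells for each sample.

    ``input_ng`` maps sample id to the template mass loaded per reaction.
    ``pass_index`` keys the random substreams so a re-assay of the same
    sample draws fresh wells.
    """

    def params_for(gene: str) -> AssaySimParams:
        return params[gene] if isinstance(params, Mapping) else params

    records: list[ReactionRecord] = []
    for sample in samples:
        total = input_ng[sample.sample_id]
        for gene, role in [(reference_gene, Role.REFERENCE)] + [
            (g, Role.TARGET) for g in target_genes
        ]:
            for rep in range(1, n_replicates + 1):
                rng = _substream(seed, "plate", pass_index, sample.sample_id, gene, rep)
                records.append(
                    simulate_reaction(
                        total, sample.true_meth_fraction, role, params_for(gene), rng,
                        sample_id=sample.sample_id, gene=gene, replicate=rep,
                        cohort=sample.tissue_label.value,
                    )
                )
    return records


def simulate_cohort(
    n_samples: int,
    params: AssaySimParams | Mapping[str, AssaySimParams],
    seed: int,
    fraction_sampler: Sampler | None = None,
    dna_samplers: Mapping[Tissue, Sampler] | None = None,
    tissue_probs: Mapping[Tissue, float] | None = None,
    reference_gene: str = "COL2A1",
    target_genes: Sequence[str] = ("GFRA1",),
    n_replicates: int = 3,
    reactions_per_sample: int = 4,
    id_prefix: str = "S",
) -> tuple[list[ReactionRecord], list[SyntheticSample]]:
    """Simulate a cohort plate plus its ground-truth table.

    Each sample's available DNA is split evenly over
    ``reactions_per_sample`` reactions, so low-DNA samples run each well
    below the input a gating policy would demand.  FFPE samples default to
    a lower available-DNA regime than frozen ones.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    fraction_sampler = fraction_sampler or beta_fraction_sampler()
    tissue_probs = tissue_probs or {Tissue.FROZEN: 1.0}
    dna_samplers = dna_samplers or {
        Tissue.FROZEN: lognormal_dna_sampler(40.0, 1.2),
        Tissue.FFPE: lognormal_dna_sampler(8.0, 1.2),
    }
    samples = _draw_samples(n_samples, seed, fraction_sampler, dna_samplers, tissue_probs, id_prefix)
    input_ng = {s.sample_id: s.available_dna_ng / reactions_per_sample for s in samples}
    records = simulate_sample_plate(
        samples, input_ng, params, seed,
        reference_gene=reference_gene, target_genes=target_genes,
        n_replicates=n_replicates, pass_index=1,
    )
    return records, samples


def truth_table(samples: Sequence[SyntheticSample]) -> pd.DataFrame:
    """Ground truth as a data frame (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "true_meth_fraction": [s.true_meth_fraction for s in samples],
            "available_dna_ng": [s.available_dna_ng for s in samples],
            "tissue": [s.tissue_label.value for s in samples],
        }
    )
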