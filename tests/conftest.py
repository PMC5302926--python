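from fractions import Fraction

import pytest

import methylgate as mg

METH_AXIS = [Fraction(1, d) for d in (1, 2, 4, 8, 16, 32, 64)]
TE_AXIS = [Fraction(1, d) for d in (1, 2, 4, 8)]
BASE_TOTAL_NG = 18.78
BASE_NET_NG = 1.18


@pytest.fixture(scope="session")
def reference_array():
    """Packaged GFRA1/P16 dilution-array measurements (28 conditions)."""
    return mg.load_reference_array()


@pytest.fixture(scope="session")
def reference_policy(reference_array):
    """Gating policy derived from the packaged array: cutoff 1.6%, 4 reactions."""
    limit = mg.estimate_detection_limit(reference_array, "GFRA1")
    points = mg.reference_standard_points(reference_array)
    return mg.derive_policy(limit, cutoff_fraction=0.016, n_reactions=4, standard_points=points)


def make_summary(sample_id, gene, n_detected, n_total=3, mean_ct=None):
    from methylgate.core_model import ReplicateSummary, classify_detection

    if n_detected and mean_ct is None:
        mean_ct = 30.0
    return ReplicateSummary(
        sample_id=sample_id,
        gene=gene,
        n_total=n_total,
        n_detected=n_detected,
        mean_ct=mean_ct if n_detected else None,
        detection=classify_detection(n_detected, n_total),
    )
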