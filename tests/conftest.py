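import numpy as np
import pytest

from crminfer import (
    BindingTable,
    CandidateCRMSet,
    ExpressionTable,
    build_compatibility,
    enumerate_candidates,
)


@pytest.fixture
def tiny_binding() -> BindingTable:
    """4 genes × 3 TFs with one background gene."""
    return BindingTable(
        ["g1", "g2", "g3", "g4"],
        ["TFa", "TFb", "TFc"],
        np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1], [0, 0, 0]]),
    )


@pytest.fixture
def tiny_expression() -> ExpressionTable:
    rng = np.random.default_rng(42)
    return ExpressionTable(
        ["g1", "g2", "g3", "g4"],
        ["s1", "s2", "s3", "s4", "s5"],
        np.exp(rng.normal(0.0, 1.0, (4, 5))),
    )


@pytest.fixture
def tiny_crms(tiny_binding) -> CandidateCRMSet:
    return enumerate_candidates(tiny_binding)


@pytest.fixture
def tiny_compat(tiny_binding, tiny_crms):
    return build_compatibility(tiny_binding, tiny_crms)
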