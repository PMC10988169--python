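import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from qtykit import BundleSpec, ProteinSequence, TMTopology

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


@st.composite
def sequence_with_topology(draw, min_len=10, max_len=120):
    """A random protein sequence plus random non-overlapping TM spans.

    Spans start at position >= 2 so the N-terminal residue (whose pKa is
    residue-specific) is never substituted; see the charge-neutrality
    invariant of the QTY rule.
    """
    n = draw(st.integers(min_len, max_len))
    residues = "".join(
        draw(st.lists(st.sampled_from(CANONICAL), min_size=n, max_size=n))
    )
    seq = ProteinSequence(id="hyp", residues=residues)
    spans = []
    pos = 2
    while pos <= n - 2 and draw(st.booleans()):
        start = draw(st.integers(pos, min(pos + 10, n - 1)))
        end = draw(st.integers(start, min(start + 25, n)))
        spans.append((start, end))
        pos = end + 2
    topo = TMTopology(sequence_id="hyp", spans=tuple(spans))
    return seq, topo


@pytest.fixture
def small_bundle_spec():
    return BundleSpec(n_helices=4, helix_len=18, loop_len=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
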