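import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_alignment(columns, reference_id="ref"):
    """Build a MultipleAlignment from a list of per-column tuples.

    ``columns[i]`` gives the characters of column i, ordered (ref, sp1, ...).
    """
    from promdiv.events import MultipleAlignment

    n = len(columns[0])
    names = ["ref"] + [f"sp{i}" for i in range(1, n)]
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return MultipleAlignment(list(zip(names, seqs)), reference_id=reference_id)


@pytest.fixture
def aln_factory():
    return make_alignment


def random_alignment(rng, n_species=4, L=120, gap_prob=0.06, sub_prob=0.08, n_prob=0.02):
    """Random gapped alignment for oracle comparisons (not biologically derived)."""
    from promdiv.events import MultipleAlignment

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=L)
    records = [("ref", "".join(ref))]
    for s in range(1, n_species):
        row = ref.copy()
        sub = rng.random(L) < sub_prob
        row[sub] = rng.choice(bases, size=int(sub.sum()))
        row[rng.random(L) < n_prob] = "N"
        row[rng.random(L) < gap_prob] = "-"
        records.append((f"sp{s}", "".join(row)))
    return MultipleAlignment(records, reference_id="ref")
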