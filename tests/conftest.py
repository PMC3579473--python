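import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic genome (10 conforming loci + 3 violators)."""
    from canemir.simulate import make_reference

    return make_reference(seed=1)


@pytest.fixture()
def tiny_genome():
    """A 2 kb background genome with one perfect planted hairpin."""
    import numpy as np

    from canemir.records import SequenceRecord, revcomp

    rng = np.random.default_rng(7)
    letters = np.array(list("ACGU"))
    bg = "".join(letters[rng.integers(0, 4, 2000)])
    arm = "".join(letters[rng.integers(0, 4, 121)])
    hairpin = arm + "AACAACAA" + revcomp(arm)
    seq = bg[:900] + hairpin + bg[900:]
    return [SequenceRecord("chr1", seq)], hairpin, 900
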