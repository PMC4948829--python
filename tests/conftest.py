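import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from telodiverge import CloneSequence, RepeatGrammar, TelomereSet, sample_telomere

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_clone(clone_id: str, bases: str, **kw) -> CloneSequence:
    meta = dict(telomere_id="TEL06R", strain_id="S1", genotype="est2", generations=30.0)
    meta.update(kw)
    return CloneSequence(clone_id=clone_id, bases=bases, **meta)


def make_set(seqs: dict[str, str], **kw) -> TelomereSet:
    clones = [make_clone(cid, seq, **kw) for cid, seq in seqs.items()]
    meta = dict(telomere_id="TEL06R", strain_id="S1", genotype="est2", generations=30.0)
    meta.update(kw)
    return TelomereSet(clones=clones, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def repeat_seq(rng):
    """A 300-nt degenerate telomere repeat stretch, fixed by the seed."""
    return sample_telomere(RepeatGrammar(), 300, rng)
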