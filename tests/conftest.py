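import numpy as np
import pytest

from piwikit.pairing import GuideRNA, TargetSite, reverse_complement

# let-7a, the 22-nt guide used as the synthetic reference piRNA
LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def let7a() -> GuideRNA:
    return GuideRNA(name="piRNA-1", sequence=LET7A)


@pytest.fixture
def let7a_perfect_target(let7a) -> TargetSite:
    return TargetSite(sequence=reverse_complement(let7a.sequence), site_start=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230621)


def random_guide(rng: np.random.Generator, length: int = 26,
                 name: str = "g") -> GuideRNA:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return GuideRNA(name=name, sequence=seq)
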