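import numpy as np
import pandas as pd
import pytest

from sncrna.core_io import CountMatrix, MirnaReference, TrnaReference

MIR375 = MirnaReference("miR-375-3p", "TTTGTTCGTTCGGCTCGCGTGA")
MIR211 = MirnaReference("miR-211-5p", "TTCCCTTTGTCATCCTTTGCCT")
MIR146A = MirnaReference("miR-146a-5p", "TGAGAACTGAATTCCATGGGTT")


@pytest.fixture
def mirna_refs():
    return [MIR375, MIR211, MIR146A]


@pytest.fixture
def synthetic_trna():
    # 75-nt tRNA; cleavage in the variable region at 48 gives a 27-nt
    # 3' fragment
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=75))
    return TrnaReference("tRNA-Ile-AAT-syn", seq, (44, 54), has_cca=False)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(11)
    counts = rng.poisson(100, size=(20, 4))
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(20)],
                      columns=["t1", "t2", "s1", "s2"])
    groups = {"t1": "TBI", "t2": "TBI", "s1": "sham", "s2": "sham"}
    return CountMatrix(df, groups)
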