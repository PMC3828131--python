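import numpy as np
import pytest

from covarcomp.alignment import AMINO_ACIDS, Alignment


@pytest.fixture
def small_aln() -> Alignment:
    return Alignment(
        ids=("s1", "s2", "s3", "s4"),
        rows=("AAVL", "AATT", "AAVL", "AATT"),
    )


def random_alignment(rng: np.random.Generator, n_seq: int, n_col: int,
                     n_symbols: int = 20) -> Alignment:
    """Uniform random gap-free alignment over the first n_symbols residues."""
    aa = np.array(list(AMINO_ACIDS[:n_symbols]))
    chars = rng.choice(aa, size=(n_seq, n_col))
    return Alignment(
        ids=tuple(f"s{k}" for k in range(n_seq)),
        rows=tuple("".join(r) for r in chars),
    )
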