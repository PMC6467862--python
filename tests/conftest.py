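import numpy as np
import pytest

import ssrdissim as sd


@pytest.fixture
def four_diploids() -> sd.Dataset:
    """Four diploid individuals at one dinucleotide locus with equal mean
    allele sizes: i1=(41,53), i2=(43,51), i3=(45,49), i4=(43,51) bp
    (11,17 / 12,16 / 13,15 / 12,16 in repeat units)."""
    return sd.build_dataset(
        ["L1"], [2], ["i1", "i2", "i3", "i4"],
        [[(41, 53)], [(43, 51)], [(45, 49)], [(43, 51)]],
        ploidy=2,
    )


@pytest.fixture
def trinucleotide_locus() -> sd.LocusDef:
    """A trinucleotide locus spanning 188-221 bp (11 repeat units)."""
    return sd.LocusDef("tri", 3, 188.0, 221.0)


def random_dataset(rng: np.random.Generator, n_ind: int = 6, n_loci: int = 4,
                   ploidy: int = 2, ltr: int = 2,
                   missing_rate: float = 0.0) -> sd.Dataset:
    """Random complete-ladder dataset for property tests."""
    calls = []
    base = 100
    for i in range(n_ind):
        row = []
        for j in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                row.append(None)
            else:
                reps = rng.integers(0, 12, size=ploidy)
                row.append(tuple(float(base + r * ltr) for r in reps))
        calls.append(row)
    # guarantee every locus typed somewhere and polymorphic
    for j in range(n_loci):
        calls[0][j] = tuple(float(base + r * ltr)
                            for r in range(ploidy))
        calls[1][j] = tuple(float(base + (r + 12) * ltr)
                            for r in range(ploidy))
    return sd.build_dataset(
        [f"L{j}" for j in range(n_loci)], [ltr] * n_loci,
        [f"ind{i}" for i in range(n_ind)], calls, ploidy=ploidy,
    )
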