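import warnings

import numpy as np
import pytest

from selsweep.io import GenotypeMatrix


def make_matrix(dosage, pos=None, chrom=None, samples=None,
                ref=None, alt=None) -> GenotypeMatrix:
    """Small-matrix builder for hand-constructed examples."""
    dosage = np.asarray(dosage, dtype=np.int8)
    S, N = dosage.shape
    pos = np.asarray(pos if pos is not None else np.arange(1, S + 1),
                     dtype=np.int64)
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * S,
                       dtype=object)
    samples = samples if samples is not None else [f"s{i}" for i in range(N)]
    ref = np.asarray(ref if ref is not None else ["A"] * S, dtype=object)
    alt = np.asarray(alt if alt is not None else ["G"] * S, dtype=object)
    return GenotypeMatrix(chrom, pos, ref, alt, dosage, list(samples))


@pytest.fixture(scope="session")
def demo():
    from selsweep.simulate import demo_scene

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return demo_scene(seed=11)


@pytest.fixture(scope="session")
def toy_genome():
    from selsweep.simulate import generate_toy_genome

    return generate_toy_genome({"chrA": 20_000, "chrB": 20_000},
                               genes_per_chrom=2, seed=4)


@pytest.fixture(scope="session")
def sweep_scene_data():
    from selsweep.simulate import sweep_scene

    return sweep_scene(seed=0)
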