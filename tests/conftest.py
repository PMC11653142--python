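import numpy as np
import pytest

from flexrestrain.fixtures import SegmentSpec, make_toy_structure
from flexrestrain.structure import ProteinStructure, Residue, SecondaryStructure


@pytest.fixture
def helix_coil_structure():
    """20 helix residues (pLDDT 95) followed by 10 coil residues (pLDDT 40)."""
    return make_toy_structure(
        [
            SegmentSpec(SecondaryStructure.HELIX, 20, 95.0, 0.0),
            SegmentSpec(SecondaryStructure.COIL, 10, 40.0, 0.0),
        ],
        seed=42,
    )


def random_toy_structure(rng: np.random.Generator, n_min: int = 6, n_max: int = 30):
    """Random compact CA cloud with random pLDDT and SS — oracle test input.

    Coordinates are a self-avoiding-ish random walk with ~3.8 Å steps, so
    plenty of pairs fall inside the 11.5 Å restraint cutoff.
    """
    n = int(rng.integers(n_min, n_max + 1))
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    ss_choices = list(SecondaryStructure)
    residues = [
        Residue(
            chain_id="A",
            res_num=i + 1,
            ca=coords[i],
            plddt=float(rng.uniform(0, 100)),
            ss=ss_choices[int(rng.integers(4))],
        )
        for i in range(n)
    ]
    return ProteinStructure(residues=residues, source_id="random-toy")
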