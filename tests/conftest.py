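import numpy as np
import pytest

from nacdyn.structio import AtomRecord, Structure


def random_structure(rng: np.random.Generator, n_res: int = 8, chains=("A", "B")) -> Structure:
    """Random small protein-like structure for brute-force comparisons."""
    resnames = ["ALA", "TRP", "ARG", "HIS", "GLY"]
    names = ["N", "CA", "C", "O", "CB", "CG", "HB1"]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "HB1": "H"}
    atoms = []
    serial = 1
    for chain in chains:
        for r in range(1, n_res + 1):
            resname = resnames[int(rng.integers(len(resnames)))]
            for name in names[: int(rng.integers(4, len(names) + 1))]:
                atoms.append(
                    AtomRecord(
                        serial=serial, name=name, altloc="", resname=resname,
                        chain=chain, resseq=r, icode="", element=elements[name],
                        coord=rng.uniform(-20, 20, 3),
                        occupancy=float(rng.uniform(0.2, 1.0)), bfactor=20.0,
                    )
                )
                serial += 1
    return Structure(atoms=atoms)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)
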