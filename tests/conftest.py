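import numpy as np
import pytest

from cryofit import gomodel, toys


@pytest.fixture(scope="session")
def toy():
    return toys.make_hinge_toy()


@pytest.fixture(scope="session")
def toy_model(toy):
    return gomodel.build_go_model(toy.state_a)


@pytest.fixture(scope="session")
def fitting_case(toy):
    return toys.make_fitting_case(toy)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_pdb(tmp_path):
    """3-residue, two-atom-per-residue PDB file."""
    lines = []
    serial = 1
    coords = np.arange(18, dtype=float).reshape(6, 3)
    for i, res in enumerate(("ALA", "GLY", "SER"), start=1):
        for name in ("CA", "CB"):
            x, y, z = coords[serial - 1]
            lines.append(
                f"ATOM  {serial:>5} {name:<4}{res:>3} A{i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    path = tmp_path / "toy3.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path
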