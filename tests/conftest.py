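import numpy as np
import pytest

from parcs import Atom, GlobuleSpec, StructureModel, gen_globule


def make_single_atom(element: str = "C") -> StructureModel:
    atom = Atom(element=element, coords=(0.0, 0.0, 0.0), residue_index=0,
                chain_id="A", name="CA", res_name="ALA")
    return StructureModel([atom], source_id=f"single_{element}")


@pytest.fixture
def single_carbon() -> StructureModel:
    return make_single_atom("C")


@pytest.fixture(scope="session")
def small_globule() -> StructureModel:
    """30-residue pseudo-protein, shared across tests for speed."""
    return gen_globule(GlobuleSpec(n_residues=30, seed=11))


@pytest.fixture(scope="session")
def medium_globule() -> StructureModel:
    """100-residue pseudo-protein at protein-like density."""
    return gen_globule(GlobuleSpec(n_residues=100, seed=5))


def write_minimal_pdb(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.00, element="C", altloc=" ", record="ATOM"):
    # single-letter-element atom names are right-shifted one column per the
    # fixed-column convention (" CA " is a carbon, "CA  " a calcium)
    padded = f"{name:<4}" if len(name) >= 4 or len(element.strip()) == 2 \
        else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {padded}{altloc}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


@pytest.fixture
def simple_pdb(tmp_path):
    """Three residues of three atoms each, one chain."""
    lines = []
    serial = 0
    rng = np.random.default_rng(3)
    for res in range(1, 4):
        for name in ("N", "CA", "CB"):
            serial += 1
            x, y, z = rng.uniform(-5, 5, 3)
            element = "N" if name == "N" else "C"
            lines.append(atom_line(serial, name, "ALA", "A", res, x, y, z,
                                   element=element))
    lines.append("END")
    return write_minimal_pdb(tmp_path / "simple.pdb", lines)
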