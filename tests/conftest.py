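import numpy as np
import pytest

from carbsite.structure import AtomRecord, ChainRecord, Residue
from carbsite.synth import SynthSpec, ideal_helix, make_toy_complex


def make_chain(residue_specs, chain_id="A", sequence=None):
    """Build a ChainRecord from a list of {atom_name: coord} dicts.

    ``residue_specs`` items may also be (one_letter, atom_dict) tuples; plain
    dicts default to alanine.
    """
    residues = []
    for i, spec in enumerate(residue_specs):
        if isinstance(spec, tuple):
            letter, atoms = spec
        else:
            letter, atoms = "A", spec
        name = {"A": "ALA", "G": "GLY", "M": "MET"}.get(letter, "ALA")
        records = [
            AtomRecord(element=a[0], name=a, coord=np.asarray(c, dtype=float),
                       het_code=name, is_heavy=not a.startswith("H"))
            for a, c in atoms.items()
        ]
        residues.append(Residue(name=name, one_letter=letter, seqid=i + 1,
                                atoms=records))
    seq = sequence or "".join(r.one_letter for r in residues)
    return ChainRecord(chain_id=chain_id, full_sequence=seq,
                       modeled_residues=residues,
                       alignment=list(range(len(residues))))


@pytest.fixture(scope="session")
def helix18():
    return ideal_helix(18)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(SynthSpec(n_residues=30, n_binding=7,
                                      geometry="coil", seed=11))


@pytest.fixture(scope="session")
def toy_complex_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy")
    return make_toy_complex(SynthSpec(n_residues=24, n_binding=6,
                                      geometry="helix", seed=4), out_dir=out)
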