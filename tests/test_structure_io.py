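"""Structure parsing, carbohydrate lookup, binding annotation, alignment,
chain filters and the annotation file format."""

import numpy as np
import pytest

from carbsite.structure import (
    AtomRecord, CarbLexicon, ChainRecord, ParsedStructure, ParseError, Residue,
    align_full_to_modeled, annotate_binding, chain_filters, collect_carb_atoms,
    parse_structure, read_annotation, write_annotation,
)
from carbsite.synth import write_complex

from conftest import make_chain


# ---------------------------------------------------------------------------
# parsing


def test_parse_round_trips_coordinates(toy_complex_files, tmp_path):
    parsed = parse_structure(toy_complex_files.pdb_path)
    assert len(parsed.chains) == 1
    chain = parsed.chains[0]
    original = toy_complex_files.chain
    assert len(chain.modeled_residues) == len(original.modeled_residues)
    for got, want in zip(chain.modeled_residues, original.modeled_residues):
        assert got.name == want.name
        np.testing.assert_allclose(got.heavy_coords(), want.heavy_coords(),
                                   atol=1e-3)


def test_het_group_kept_out_of_polymer(toy_complex_files):
    parsed = parse_structure(toy_complex_files.pdb_path)
    het_codes = {a.het_code for a in parsed.het_atoms}
    assert het_codes == {"GLC"}
    polymer_codes = {r.name for r in parsed.chains[0].modeled_residues}
    assert "GLC" not in polymer_codes


def test_pdb_and_mmcif_give_identical_chains(toy_complex, tmp_path):
    pdb = tmp_path / "cx.pdb"
    cif = tmp_path / "cx.cif"
    write_complex(toy_complex.chain, toy_complex.carb_atoms, pdb, fmt="pdb")
    write_complex(toy_complex.chain, toy_complex.carb_atoms, cif, fmt="mmcif")
    a = parse_structure(pdb, fmt="pdb")
    b = parse_structure(cif, fmt="mmcif")
    assert len(a.chains) == len(b.chains) == 1
    assert a.chains[0].modeled_sequence == b.chains[0].modeled_sequence
    for ra, rb in zip(a.chains[0].modeled_residues, b.chains[0].modeled_residues):
        np.testing.assert_allclose(ra.heavy_coords(), rb.heavy_coords(), atol=1e-3)
    ca = sorted(map(tuple, (x.coord.round(3) for x in a.het_atoms)))
    cb = sorted(map(tuple, (x.coord.round(3) for x in b.het_atoms)))
    np.testing.assert_allclose(ca, cb, atol=1e-3)


def test_unreadable_file_raises_parse_error(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(ParseError):
        parse_structure(bad, fmt="mmcif")


# ---------------------------------------------------------------------------
# carbohydrate atom collection


def _het(code, coord=(0, 0, 0), element="C", heavy=True, name="C1"):
    return AtomRecord(element=element, name=name, coord=np.asarray(coord, float),
                      het_code=code, is_heavy=heavy)


def test_collect_carb_atoms_filters_by_lexicon():
    structure = ParsedStructure(chains=[], het_atoms=[
        _het("GLC"), _het("GLC", (1, 0, 0)), _het("HOH"), _het("SO4"),
    ])
    atoms = collect_carb_atoms(structure, CarbLexicon(frozenset({"GLC"})))
    assert len(atoms) == 2 and all(a.het_code == "GLC" for a in atoms)
    # lexicon codes absent from the structure -> empty result
    assert collect_carb_atoms(structure, CarbLexicon(frozenset({"XYZ"}))) == []


def test_collect_carb_atoms_skips_hydrogens_and_blocks_water():
    atoms = [_het("GLC")] * 11 + [_het("GLC", element="H", heavy=False, name="H1")]
    structure = ParsedStructure(chains=[], het_atoms=atoms)
    assert len(collect_carb_atoms(structure, CarbLexicon(frozenset({"GLC"})))) == 11
    # HOH can never be whitelisted, so the lexicon {HOH} is effectively empty
    with pytest.raises(ValueError):
        collect_carb_atoms(structure, CarbLexicon(frozenset({"HOH"})))


def test_empty_lexicon_is_a_configuration_error():
    with pytest.raises(ValueError):
        collect_carb_atoms(ParsedStructure([], []), CarbLexicon(frozenset()))


# ---------------------------------------------------------------------------
# binding annotation


def test_cutoff_is_inclusive_at_3p5():
    chain = make_chain([{"CA": (0, 0, 0)}, {"CA": (50, 0, 0)}])
    near = annotate_binding(chain, [_het("GLC", (0, 0, 3.4))])
    assert near.labels == "10"
    far = annotate_binding(chain, [_het("GLC", (0, 0, 3.6))])
    assert far.labels == "00"
    boundary = annotate_binding(chain, [_het("GLC", (0, 0, 3.5))])
    assert boundary.labels == "10"


def test_empty_carb_list_gives_all_negative():
    chain = make_chain([{"CA": (0, 0, 0)}, {"CA": (4, 0, 0)}])
    assert annotate_binding(chain, []).labels == "00"


def test_annotation_matches_brute_force_all_pairs():
    rng = np.random.default_rng(0)
    residues = [{f"C{k}": rng.uniform(-15, 15, 3) for k in range(5)}
                for _ in range(20)]
    chain = make_chain(residues)
    carbs = [_het("GLC", rng.uniform(-15, 15, 3)) for _ in range(8)]
    got = annotate_binding(chain, carbs).labels
    expected = ""
    for res in chain.modeled_residues:
        dmin = min(
            np.linalg.norm(a.coord - c.coord)
            for a in res.atoms for c in carbs
        )
        expected += "1" if dmin <= 3.5 else "0"
    assert got == expected


def test_labels_invariant_under_atom_order_permutation():
    rng = np.random.default_rng(3)
    coords = [{f"C{k}": rng.uniform(-8, 8, 3) for k in range(4)}
              for _ in range(10)]
    carbs = [_het("GLC", rng.uniform(-8, 8, 3)) for _ in range(5)]
    base = annotate_binding(make_chain(coords), list(carbs)).labels
    shuffled = [dict(reversed(list(d.items()))) for d in coords]
    assert annotate_binding(make_chain(shuffled), carbs[::-1]).labels == base


# ---------------------------------------------------------------------------
# alignment


def test_identity_alignment():
    assert align_full_to_modeled("ACDEFG", "ACDEFG") == [0, 1, 2, 3, 4, 5]


def test_single_deletion_maps_to_gap():
    assert align_full_to_modeled("ACDEFG", "ACEFG") == [0, 1, None, 2, 3, 4]


def test_empty_modeled_sequence_is_all_gaps():
    assert align_full_to_modeled("ACD", "") == [None, None, None]


def test_alignment_is_bijection_on_random_deletions():
    rng = np.random.default_rng(5)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(25):
        n = int(rng.integers(5, 40))
        full = "".join(rng.choice(alphabet, n))
        keep = sorted(rng.choice(n, size=int(rng.integers(1, n + 1)),
                                 replace=False))
        modeled = "".join(full[i] for i in keep)
        mapping = align_full_to_modeled(full, modeled)
        mapped = [m for m in mapping if m is not None]
        assert sorted(mapped) == list(range(len(modeled)))
        for pos, m in enumerate(mapping):
            if m is not None:
                assert full[pos] == modeled[m]


def test_alignment_score_matches_biopython_optimum():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    rng = np.random.default_rng(6)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        n = int(rng.integers(4, 15))
        full = "".join(rng.choice(alphabet, n))
        keep = sorted(rng.choice(n, size=int(rng.integers(1, n + 1)),
                                 replace=False))
        modeled = "".join(full[i] for i in keep)
        mapping = align_full_to_modeled(full, modeled)
        # score of our alignment: matches/mismatches at mapped positions,
        # gap penalty for every unmapped full position
        score = sum(1 if full[i] == modeled[m] else -1
                    for i, m in enumerate(mapping) if m is not None)
        score += -2 * sum(m is None for m in mapping)
        assert score == aligner.score(full, modeled)


# ---------------------------------------------------------------------------
# chain filters


def _labeled_chain(n_pos, letter="A"):
    chain = make_chain([(letter, {"CA": (3.8 * i, 0, 0)}) for i in range(10)])
    chain.labels = "1" * n_pos + "0" * (10 - n_pos)
    return chain


def test_keep_requires_strictly_more_than_five_positives():
    keep, _ = chain_filters(_labeled_chain(6))
    assert keep
    drop, reason = chain_filters(_labeled_chain(5))
    assert not drop and "binding" in reason


def test_nonstandard_residue_drops_chain():
    chain = make_chain([("M", {"CA": (0, 0, 0)})] * 3 + [("A", {"CA": (9, 9, 9)})])
    chain.modeled_residues[0].name = "MSE"
    chain.modeled_residues[0].one_letter = "X"
    chain.labels = "1111"
    keep, reason = chain_filters(chain)
    assert not keep and "nonstandard" in reason.lower()


# ---------------------------------------------------------------------------
# annotation file format


def test_label_string_layout(tmp_path):
    chain = ChainRecord(
        chain_id="Q", full_sequence="ACD",
        modeled_residues=[Residue("ALA", "A", 1), Residue("CYS", "C", 2)],
        alignment=[0, 1, None], labels="10-",
    )
    path = tmp_path / "one.cpb.tsv"
    write_annotation([chain], path)
    assert path.read_text() == ">Q\nACD\n10-\n"


def test_write_read_round_trip_on_random_chains(tmp_path):
    rng = np.random.default_rng(9)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    chains = []
    for k in range(50):
        n = int(rng.integers(3, 60))
        seq = "".join(rng.choice(alphabet, n))
        labels = "".join(rng.choice(list("10-"), n, p=[0.2, 0.6, 0.2]))
        n_modeled = sum(c != "-" for c in labels)
        alignment, j = [], 0
        for c in labels:
            alignment.append(None if c == "-" else j)
            j += c != "-"
        residues = [Residue("ALA", "A", i + 1) for i in range(n_modeled)]
        chains.append(ChainRecord(chain_id=f"c{k}", full_sequence=seq,
                                  modeled_residues=residues,
                                  alignment=alignment, labels=labels))
    path = tmp_path / "many.cpb.tsv"
    write_annotation(chains, path)
    back = read_annotation(path)
    assert back == [(c.chain_id, c.full_sequence, c.labels) for c in chains]


def test_short_label_line_names_the_chain(tmp_path):
    path = tmp_path / "bad.cpb.tsv"
    path.write_text(">mychain\nACDEF\n10-\n")
    with pytest.raises(ParseError, match="mychain"):
        read_annotation(path)
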