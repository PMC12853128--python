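"""Synthetic fixtures: toy protein–carbohydrate complexes with planted
binding labels, PSI-BLAST-style PSSM files, and class-separable embedding
matrices.

Every generator is a pure function of its spec and seed, so fixtures are
reproducible and nothing needs to be downloaded or stored.  Toy complexes are
poly-alanine/glycine chains with ideal backbone geometry; a rigid six-atom
pseudo-carbohydrate ring is planted next to each chosen binding residue so
that its nearest ring atom sits 3.4 Å from the residue's CA while every
non-binding residue stays at least 3.7 Å from all ring atoms — straddling the
3.5 Å annotation cutoff from both sides, which makes boundary behavior
testable.  Embedding fixtures are two-class isotropic Gaussians whose means
differ by an effect size ``d`` along a random direction of each embedding
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .imbalance import LabeledSet
from .sequence import (
    ESM2_WIDTH, PROTT5_WIDTH, WINDOW_ALPHABET, assemble_fnn_input,
    window_encode_all,
)
from .structure import AtomRecord, ChainRecord, ONE_TO_THREE, Residue

# ideal backbone internal coordinates (lengths in Å, angles in degrees)
BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
         "CA-C-O": 120.5, "N-CA-CB": 110.4}
OMEGA = 180.0
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)

RING_RADIUS = 1.4     # pseudo-pyranose C–C ring radius
CONTACT_DIST = 3.4    # planted positives sit inside the 3.5 Å cutoff
CLEAR_DIST = 3.7      # planted negatives stay outside it


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A, B, C
    (natural extension reference frame): |C–D| = bond, ∠BCD = angle,
    dihedral(A,B,C,D) = torsion."""
    theta, tau = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta),
         bond * math.sin(theta) * math.cos(tau),
         bond * math.sin(theta) * math.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(sequence: str, phis: np.ndarray, psis: np.ndarray) -> list[Residue]:
    """Construct N/CA/C/O (and CB for non-glycine) atoms for a chain with the
    given backbone torsions; phi[0] and psi[-1] are ignored (undefined)."""
    n_res = len(sequence)
    assert len(phis) == len(psis) == n_res
    coords: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n_pos = np.zeros(3)
            ca = np.array([BOND["N-CA"], 0.0, 0.0])
            th = math.radians(ANGLE["N-CA-C"])
            c = ca + BOND["CA-C"] * np.array([-math.cos(th), math.sin(th), 0.0])
        else:
            prev = coords[i - 1]
            n_pos = nerf(prev["N"], prev["CA"], prev["C"],
                         BOND["C-N"], ANGLE["CA-C-N"], psis[i - 1])
            ca = nerf(prev["CA"], prev["C"], n_pos,
                      BOND["N-CA"], ANGLE["C-N-CA"], OMEGA)
            c = nerf(prev["C"], n_pos, ca,
                     BOND["CA-C"], ANGLE["N-CA-C"], phis[i])
        coords.append({"N": n_pos, "CA": ca, "C": c})
    for i in range(n_res):
        psi = psis[i] if i < n_res - 1 else -40.0
        coords[i]["O"] = nerf(coords[i]["N"], coords[i]["CA"], coords[i]["C"],
                              BOND["C-O"], ANGLE["CA-C-O"], psi - 180.0)
        if sequence[i] != "G":
            coords[i]["CB"] = nerf(coords[i]["C"], coords[i]["N"], coords[i]["CA"],
                                   BOND["CA-CB"], ANGLE["N-CA-CB"], -122.6)
    residues = []
    for i, letter in enumerate(sequence):
        name = ONE_TO_THREE.get(letter, "UNK")
        atoms = [
            AtomRecord(element=atom_name[0], name=atom_name, coord=xyz,
                       het_code=name, is_heavy=True)
            for atom_name, xyz in coords[i].items()
        ]
        residues.append(Residue(name=name, one_letter=letter, seqid=i + 1,
                                atoms=atoms))
    return residues


def ideal_helix(n_residues: int, sequence: str | None = None) -> ChainRecord:
    """Poly-alanine α-helix with canonical φ = −57°, ψ = −47° geometry."""
    seq = sequence or "A" * n_residues
    phis = np.full(n_residues, HELIX_PHI_PSI[0])
    psis = np.full(n_residues, HELIX_PHI_PSI[1])
    residues = build_backbone(seq, phis, psis)
    return ChainRecord(chain_id="A", full_sequence=seq,
                       modeled_residues=residues,
                       alignment=list(range(n_residues)))


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one toy complex."""

    n_residues: int = 30
    n_binding: int = 5
    geometry: str = "helix"        # "helix" or "coil"
    class_separation: float = 4.0  # effect size d for embedding fixtures
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_binding <= self.n_residues:
            raise ValueError("need 0 <= n_binding <= n_residues")
        if self.class_separation < 0:
            raise ValueError("class separation d must be >= 0")
        if self.geometry not in ("helix", "coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class ToyComplex:
    chain: ChainRecord
    carb_atoms: list[AtomRecord]
    expected_labels: str
    pdb_path: Path | None = None
    fasta_path: Path | None = None
    labels_path: Path | None = None


def _plant_ring(ca: np.ndarray, direction: np.ndarray,
                perp: np.ndarray) -> np.ndarray:
    """Six ring atoms in the plane spanned by (direction, perp); the vertex
    nearest the CA sits exactly CONTACT_DIST away."""
    center = ca + (CONTACT_DIST + RING_RADIUS) * direction
    pts = []
    for k in range(6):
        theta = math.radians(60.0 * k)
        pts.append(center + RING_RADIUS * (-math.cos(theta) * direction
                                           + math.sin(theta) * perp))
    return np.array(pts)


def make_toy_complex(spec: SynthSpec, out_dir: str | Path | None = None,
                     het_code: str = "GLC") -> ToyComplex:
    """Build a toy complex whose binding labels are known by construction.

    Exactly ``spec.n_binding`` residues end up with a heavy atom within
    3.4 Å of a pseudo-carbohydrate atom; every other residue is at least
    3.7 Å away from all of them (verified by brute force, with retries over
    fresh random placements).  Optionally writes ``complex.pdb``,
    ``chain.fasta`` and ``expected.cpb.tsv`` into ``out_dir``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    seq = "".join(rng.choice(list("AG"), p=[0.8, 0.2]) for _ in range(n))
    if spec.geometry == "helix":
        phis = np.full(n, HELIX_PHI_PSI[0])
        psis = np.full(n, HELIX_PHI_PSI[1])
    else:
        phis = STRAND_PHI_PSI[0] + rng.uniform(-15, 15, size=n)
        psis = STRAND_PHI_PSI[1] + rng.uniform(-15, 15, size=n)
    residues = build_backbone(seq, phis, psis)
    chain_coords = np.vstack([r.heavy_coords() for r in residues])
    cas = np.array([r.atom("CA").coord for r in residues])

    offsets = np.cumsum([0] + [len(r.heavy_coords()) for r in residues])

    def outward(i: int) -> np.ndarray:
        """Local radial direction: CA minus a windowed centroid, with the
        local chain-axis component removed so the ring leaves the surface."""
        lo, hi = max(0, i - 3), min(n, i + 4)
        radial = cas[i] - cas[lo:hi].mean(axis=0)
        axis = cas[hi - 1] - cas[lo]
        nrm = np.linalg.norm(axis)
        if nrm > 1e-9:
            axis /= nrm
            radial = radial - np.dot(radial, axis) * axis
        nrm = np.linalg.norm(radial)
        return radial / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])

    def ring_clears(ring: np.ndarray, selected: set[int]) -> bool:
        d = np.linalg.norm(chain_coords[:, None, :] - ring[None, :, :], axis=-1)
        for j in range(n):
            if j in selected:
                continue
            if d[offsets[j]:offsets[j + 1]].min() < CLEAR_DIST:
                return False
        return True

    for _attempt in range(50):
        selected = np.sort(rng.choice(n, size=spec.n_binding, replace=False))
        sel = set(selected.tolist())
        rings, ok = [], True
        for i in selected:
            base = outward(i)
            placed = False
            for trial in range(60):
                tilt = 0.0 if trial == 0 else 0.4
                direction = base + tilt * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                perp = np.cross(direction, rng.normal(size=3))
                perp /= max(np.linalg.norm(perp), 1e-9)
                ring = _plant_ring(cas[i], direction, perp)
                if ring_clears(ring, sel):
                    rings.append(ring)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not place pseudo-carbohydrates with clean margins")
    carb_coords = np.vstack(rings) if rings else np.empty((0, 3))

    carb_atoms = [
        AtomRecord(element="C", name=f"C{j + 1}", coord=xyz,
                   het_code=het_code, is_heavy=True)
        for j, xyz in enumerate(carb_coords)
    ]
    chain = ChainRecord(chain_id="A", full_sequence=seq,
                        modeled_residues=residues,
                        alignment=list(range(n)))
    expected = "".join("1" if i in set(selected.tolist()) else "0"
                       for i in range(n)) if spec.n_binding else "0" * n
    toy = ToyComplex(chain=chain, carb_atoms=carb_atoms, expected_labels=expected)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        toy.pdb_path = out_dir / "complex.pdb"
        write_complex(chain, carb_atoms, toy.pdb_path, fmt="pdb")
        toy.fasta_path = out_dir / "chain.fasta"
        toy.fasta_path.write_text(f">{chain.chain_id}\n{seq}\n")
        toy.labels_path = out_dir / "expected.cpb.tsv"
        toy.labels_path.write_text(f">{chain.chain_id}\n{seq}\n{expected}\n")
    return toy


# ---------------------------------------------------------------------------
# serialization of synthetic structures


def _as_gemmi_structure(chain: ChainRecord,
                        carb_atoms: list[AtomRecord] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id)
    for res in chain.modeled_residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seqid, " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coord)
            ga.occ = 1.0
            gres.add_atom(ga)
        gchain.add_residue(gres)
    if carb_atoms:
        by_group: dict[str, list[AtomRecord]] = {}
        for a in carb_atoms:
            by_group.setdefault(a.het_code, []).append(a)
        seqid = len(chain.modeled_residues) + 10
        for code, atoms in by_group.items():
            gres = gemmi.Residue()
            gres.name = code
            gres.seqid = gemmi.SeqId(seqid, " ")
            gres.het_flag = "H"
            seqid += 1
            for atom in atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_complex(chain: ChainRecord, carb_atoms: list[AtomRecord],
                  path: str | Path, fmt: str = "pdb") -> None:
    """Serialize a synthetic chain (+ HET atoms) as PDB or mmCIF."""
    st = _as_gemmi_structure(chain, carb_atoms)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def chain_to_pdb_string(chain: ChainRecord) -> str:
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".pdb", mode="r") as fh:
        _as_gemmi_structure(chain).write_pdb(fh.name)
        return Path(fh.name).read_text()


# ---------------------------------------------------------------------------
# PSSM and embedding fixtures

_PSSM_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts\n"
    "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F"
    "   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I"
    "   L   K   M   F   P   S   T   W   Y   V\n"
)


def make_synth_pssm(length: int, seed: int = 0,
                    path: str | Path | None = None,
                    sequence: str | None = None) -> tuple[str, np.ndarray]:
    """A synthetic PSI-BLAST ASCII PSSM: (file text, L×20 log-odds matrix)."""
    rng = np.random.default_rng(seed)
    letters = list(WINDOW_ALPHABET[:20])
    seq = sequence or "".join(rng.choice(letters) for _ in range(length))
    if len(seq) != length:
        raise ValueError("sequence length disagrees with requested length")
    scores = rng.integers(-10, 13, size=(length, 20))
    percents = rng.integers(0, 101, size=(length, 20))
    lines = [_PSSM_HEADER.rstrip("\n")]
    for i in range(length):
        row = f"{i + 1:5d} {seq[i]} "
        row += "".join(f"{v:4d}" for v in scores[i])
        row += "".join(f"{v:4d}" for v in percents[i])
        row += "  0.36 0.08"
        lines.append(row)
    lines.append("")
    lines.append("                      K         Lambda")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, scores.astype(float)


@dataclass
class SeparableEmbeddings:
    """Two-class Gaussian embedding fixture standing in for language-model
    outputs, plus valid structural vectors and window encodings."""

    prott5: np.ndarray
    esm2: np.ndarray
    structural: np.ndarray
    windows: np.ndarray
    labels: np.ndarray

    def to_labeled_set(self) -> LabeledSet:
        features = assemble_fnn_input(self.prott5, self.structural, self.esm2)
        return LabeledSet(self.windows, features, self.labels)


def _random_structural(rng: np.random.Generator, n: int) -> np.ndarray:
    ss = np.zeros((n, 9))
    ss[np.arange(n), rng.integers(9, size=n)] = 1.0
    bins = np.zeros((n, 10))
    bins[np.arange(n), rng.integers(10, size=n)] = 1.0
    phi_psi = rng.uniform(-math.pi, math.pi, size=(n, 2))
    counts = rng.integers(0, 25, size=(n, 1)).astype(float)
    vsa = rng.uniform(10.0, 120.0, size=(n, 1))
    relseq = 1.0 / rng.integers(1, 200, size=(n, 1))
    relspa = 1.0 / rng.uniform(1.0, 40.0, size=(n, 1))
    vecs = rng.normal(size=(n, 3, 3))
    vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
    angles = rng.uniform(0, math.pi, size=(n, 2))
    return np.hstack([ss, bins, phi_psi, counts, vsa, relseq, relspa,
                      vecs.reshape(n, 9), angles])


def make_separable_embeddings(
    n_pos: int,
    n_neg: int,
    widths: tuple[int, int] = (PROTT5_WIDTH, ESM2_WIDTH),
    d: float = 4.0,
    seed: int = 0,
) -> SeparableEmbeddings:
    """Class-separable embedding fixture.

    In each embedding space the two class means differ by ``d`` along a
    random unit direction, with unit isotropic Gaussian noise; ``d = 0``
    yields indistinguishable classes.
    """
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    matrices = []
    for width in widths:
        direction = rng.normal(size=width)
        direction /= np.linalg.norm(direction)
        base = rng.normal(size=(n, width))
        base[labels == 1] += (d / 2) * direction
        base[labels == 0] -= (d / 2) * direction
        matrices.append(base)
    structural = _random_structural(rng, n)
    windows = rng.integers(0, 21, size=(n, 31))
    perm = rng.permutation(n)
    return SeparableEmbeddings(
        prott5=matrices[0][perm], esm2=matrices[1][perm],
        structural=structural[perm], windows=windows[perm], labels=labels[perm],
    )
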