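"""Per-residue geometric descriptors for modeled protein chains.

The structural feature vector has 36 components per residue:

====================  =====  =======================================
block                 width  meaning
====================  =====  =======================================
secondary structure   9      one-hot over the nine classes below
RSA bins              10     one-hot decile of relative accessibility
phi, psi              2      backbone torsions, radians
neighbor count        1      residues with center atom within 12 Å
virtual surface area  1      convex-hull area of the residue's atoms
relative positions    2      1/index and 1/(distance to centroid)
direction vectors     9      unit vectors to prev/next centers, CA→CB
C=O angle             1      angle between consecutive carbonyl bonds
CA–CA angle           1      backbone bend at the residue's CA
====================  =====  =======================================

Secondary structure uses an internal hydrogen-bond-energy assignment in the
DSSP spirit (Kabsch–Sander electrostatic model); an external DSSP executable
can be dropped in through the same nine-class contract.  Accessibility uses an
internal Shrake–Rupley estimator (960 sphere points, 1.4 Å probe) normalized
by theoretical maximum-ASA constants.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial import QhullError

from .structure import ChainRecord, Residue

SS_CLASSES = (
    "Alpha helix",
    "Isolated beta-bridge residue",
    "Strand",
    "3-10 helix",
    "Pi helix",
    "Turn",
    "Bend",
    "None",
    "Irregular SS",
)

#: map from DSSP one-letter codes onto the nine classes
DSSP_CODE_TO_CLASS = {
    "H": "Alpha helix", "B": "Isolated beta-bridge residue", "E": "Strand",
    "G": "3-10 helix", "I": "Pi helix", "T": "Turn", "S": "Bend",
    "-": "Irregular SS", " ": "Irregular SS", "P": "Irregular SS",
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4
SASA_POINTS = 960
HB_ENERGY_CUTOFF = -0.5  # kcal/mol, Kabsch–Sander bond criterion
EPS_DIST = 1e-6

_MAX_ASA: dict[str, float] | None = None


def max_asa_table() -> dict[str, float]:
    """Residue-type maximum ASA (Å²), loaded from the shipped data file."""
    global _MAX_ASA
    if _MAX_ASA is None:
        table = {}
        with resources.as_file(resources.files("carbsite.data") / "max_asa.tsv") as p:
            for line in Path(p).read_text().splitlines():
                if line.startswith("#") or not line.strip():
                    continue
                letter, value = line.split("\t")
                table[letter] = float(value)
        _MAX_ASA = table
    return _MAX_ASA


# ---------------------------------------------------------------------------
# elementary geometry


def torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in (−π, π] of the four points (IUPAC
    convention), radians."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.atan2(y, x)
    return math.pi if ang <= -math.pi + 1e-15 else ang


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in [0, π] between two vectors; 0 if either is (near) zero."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < EPS_DIST or nv < EPS_DIST:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.acos(c))


def center_atom(residue: Residue) -> np.ndarray | None:
    """CA coordinate, or the heavy-atom centroid when CA is absent."""
    ca = residue.atom("CA")
    if ca is not None:
        return ca.coord
    heavy = residue.heavy_coords()
    return heavy.mean(axis=0) if heavy.size else None


def _centers(chain: ChainRecord) -> np.ndarray:
    out = []
    for res in chain.modeled_residues:
        c = center_atom(res)
        out.append(c if c is not None else np.full(3, np.nan))
    return np.array(out).reshape(-1, 3)


# ---------------------------------------------------------------------------
# secondary structure (internal Kabsch–Sander-style backend)


def _backbone(chain: ChainRecord) -> list[dict[str, np.ndarray] | None]:
    bb = []
    for res in chain.modeled_residues:
        atoms = {n: res.atom(n) for n in ("N", "CA", "C", "O")}
        if any(a is None for a in atoms.values()):
            bb.append(None)
        else:
            bb.append({n: a.coord for n, a in atoms.items()})
    return bb


def _hbond_matrix(chain: ChainRecord) -> np.ndarray:
    """hb[i, j]: backbone N–H of residue i donates to C=O of residue j."""
    bb = _backbone(chain)
    n = len(bb)
    hb = np.zeros((n, n), dtype=bool)
    # amide H placed along the previous residue's carbonyl direction
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if bb[i] is None or bb[i - 1] is None:
            continue
        if chain.modeled_residues[i].name == "PRO":
            continue  # proline nitrogen has no amide hydrogen
        co = bb[i - 1]["C"] - bb[i - 1]["O"]
        nrm = np.linalg.norm(co)
        if nrm > EPS_DIST:
            h_pos[i] = bb[i]["N"] + co / nrm
    for i in range(n):
        if h_pos[i] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2 or bb[j] is None:
                continue
            d_on = np.linalg.norm(bb[i]["N"] - bb[j]["O"])
            d_ch = np.linalg.norm(h_pos[i] - bb[j]["C"])
            d_oh = np.linalg.norm(h_pos[i] - bb[j]["O"])
            d_cn = np.linalg.norm(bb[i]["N"] - bb[j]["C"])
            if min(d_on, d_ch, d_oh, d_cn) < EPS_DIST:
                continue
            energy = 0.084 * 332.0 * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            hb[i, j] = energy < HB_ENERGY_CUTOFF
    return hb


def secondary_structure(chain: ChainRecord) -> list[str]:
    """Assign one of the nine secondary-structure classes to every residue.

    Chains with fewer than three residues (no pattern can exist) and residues
    lacking backbone atoms are classed "None"; residues that were evaluated but
    match no pattern fall into the "Irregular SS" catch-all.
    """
    n = len(chain.modeled_residues)
    bb = _backbone(chain)
    if n < 3:
        return ["None"] * n
    hb = _hbond_matrix(chain)
    # turn[d][i]: C=O of residue i bonds N–H of residue i+d
    turn = {d: np.array([i + d < n and hb[i + d, i] for i in range(n)]) for d in (3, 4, 5)}

    cls = ["Irregular SS"] * n
    for i, b in enumerate(bb):
        if b is None:
            cls[i] = "None"

    def mark(indices, label):
        for k in indices:
            if 0 <= k < n and cls[k] == "Irregular SS":
                cls[k] = label

    # helices: two consecutive n-turns make a minimal helix (alpha first)
    for d, label in ((4, "Alpha helix"), (3, "3-10 helix"), (5, "Pi helix")):
        for i in range(1, n):
            if turn[d][i] and turn[d][i - 1]:
                mark(range(i, i + d), label)

    # beta bridges and ladders
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i, j - 1] and hb[j + 1, i]) or (hb[j, i - 1] and hb[i + 1, j])
            anti = (hb[i, j] and hb[j, i]) or (hb[i + 1, j - 1] and hb[j + 1, i - 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    for i in range(n):
        partners = np.flatnonzero(bridge[i])
        if partners.size and cls[i] == "Irregular SS":
            extended = any(
                bridge[i + di, j + dj]
                for j in partners
                for di in (-1, 1)
                for dj in (-1, 1)
                if 0 <= i + di < n and 0 <= j + dj < n
            )
            cls[i] = "Strand" if extended else "Isolated beta-bridge residue"

    # turns: interior residues of any n-turn
    for d in (3, 4, 5):
        for i in np.flatnonzero(turn[d]):
            mark(range(i + 1, i + d), "Turn")

    # bends: CA-trace curvature above 70 degrees
    for i in range(2, n - 2):
        if any(bb[k] is None for k in (i - 2, i, i + 2)):
            continue
        u = bb[i]["CA"] - bb[i - 2]["CA"]
        v = bb[i + 2]["CA"] - bb[i]["CA"]
        if vector_angle(u, v) > math.radians(70):
            mark([i], "Bend")
    return cls


def dssp_backend(executable: str | Path) -> Callable[[ChainRecord], list[str]]:
    """Wrap an external DSSP executable as a nine-class assignment backend."""

    def assign(chain: ChainRecord) -> list[str]:
        from .synth import chain_to_pdb_string  # local import: avoids cycle

        with tempfile.TemporaryDirectory() as tmp:
            pdb = Path(tmp) / "chain.pdb"
            pdb.write_text(chain_to_pdb_string(chain))
            out = subprocess.run(
                [str(executable), str(pdb)], capture_output=True, text=True, check=True
            ).stdout
        codes: dict[int, str] = {}
        seen_header = False
        for line in out.splitlines():
            if line.startswith("  #  RESIDUE"):
                seen_header = True
                continue
            if seen_header and len(line) > 16 and line[13] != "!":
                codes[int(line[5:10])] = line[16]
        return [
            DSSP_CODE_TO_CLASS.get(codes.get(r.seqid, " "), "None")
            for r in chain.modeled_residues
        ]

    return assign


def ss_onehot(classes: Sequence[str]) -> np.ndarray:
    out = np.zeros((len(classes), len(SS_CLASSES)))
    for i, c in enumerate(classes):
        out[i, SS_CLASSES.index(c)] = 1.0
    return out


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_per_atom(
    coords: np.ndarray,
    elements: Sequence[str],
    n_points: int = SASA_POINTS,
    probe: float = PROBE_RADIUS,
) -> np.ndarray:
    """Shrake–Rupley accessible surface area per heavy atom, Å²."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    rmax = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
        out[i] = accessible.mean() * 4 * math.pi * radii[i] ** 2
    return out


def rsa(chain: ChainRecord, n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-residue relative solvent accessibility in [0, 1] (clamped)."""
    coords, elements, owner = [], [], []
    for idx, res in enumerate(chain.modeled_residues):
        for a in res.atoms:
            if a.is_heavy:
                coords.append(a.coord)
                elements.append(a.element)
                owner.append(idx)
    values = np.zeros(len(chain.modeled_residues))
    if not coords:
        return values
    per_atom = sasa_per_atom(np.array(coords), elements, n_points=n_points)
    np.add.at(values, owner, per_atom)
    table = max_asa_table()
    for idx, res in enumerate(chain.modeled_residues):
        values[idx] /= table.get(res.one_letter, 200.0)
    return np.minimum(values, 1.0)


def rsa_binning(value: float) -> np.ndarray:
    """One-hot decile for an RSA value: bin 1 is [0, 0.1], bin k is
    ((k−1)/10, k/10]."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"RSA value {value} outside [0, 1]")
    k = max(1, math.ceil(value * 10 - 1e-9))
    out = np.zeros(10)
    out[k - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# backbone torsions, counts, hulls, positions, vectors, angles


def dihedrals(chain: ChainRecord) -> np.ndarray:
    """Per-residue (phi, psi) in radians; 0 where undefined (termini, gaps)."""
    bb = _backbone(chain)
    n = len(bb)
    out = np.zeros((n, 2))
    for i in range(n):
        if bb[i] is None:
            continue
        if i > 0 and bb[i - 1] is not None:
            out[i, 0] = torsion(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
        if i < n - 1 and bb[i + 1] is not None:
            out[i, 1] = torsion(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
    return out


def neighbor_count(chain: ChainRecord, radius: float = 12.0) -> np.ndarray:
    """Number of other residues with center atom within ``radius`` (inclusive)."""
    centers = _centers(chain)
    valid = ~np.isnan(centers).any(axis=1)
    counts = np.zeros(len(centers), dtype=int)
    idx = np.flatnonzero(valid)
    if idx.size > 1:
        d = np.linalg.norm(centers[idx, None] - centers[None, idx], axis=-1)
        counts[idx] = ((d <= radius).sum(axis=1)) - 1
    return counts


def virtual_surface_area(atom_coords: np.ndarray) -> float:
    """Surface area of the 3-D convex hull of the residue's atoms, Å²;
    degenerate point sets (fewer than 4 affinely independent points) give 0."""
    pts = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts[0], tol=1e-9) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).area)
    except QhullError:
        return 0.0


def relative_positions(chain: ChainRecord) -> np.ndarray:
    """(1/index, 1/distance-to-centroid) per modeled residue."""
    centers = _centers(chain)
    valid = ~np.isnan(centers).any(axis=1)
    centroid = centers[valid].mean(axis=0) if valid.any() else np.zeros(3)
    n = len(centers)
    out = np.zeros((n, 2))
    for i in range(n):
        out[i, 0] = 1.0 / (i + 1)
        if valid[i]:
            d = np.linalg.norm(centers[i] - centroid)
            out[i, 1] = 1.0 / max(d, EPS_DIST)
    return out


def direction_vectors(chain: ChainRecord) -> np.ndarray:
    """Per-residue unit vectors: toward previous center, toward next center,
    CA→CB; zero triples where undefined (termini, glycine, missing atoms)."""
    centers = _centers(chain)
    n = len(centers)
    out = np.zeros((n, 9))

    def unit(v):
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > EPS_DIST else np.zeros(3)

    for i in range(n):
        if np.isnan(centers[i]).any():
            continue
        if i > 0 and not np.isnan(centers[i - 1]).any():
            out[i, 0:3] = unit(centers[i - 1] - centers[i])
        if i < n - 1 and not np.isnan(centers[i + 1]).any():
            out[i, 3:6] = unit(centers[i + 1] - centers[i])
        res = chain.modeled_residues[i]
        ca, cb = res.atom("CA"), res.atom("CB")
        if ca is not None and cb is not None:
            out[i, 6:9] = unit(cb.coord - ca.coord)
    return out


def backbone_angles(chain: ChainRecord) -> np.ndarray:
    """(C=O/C=O angle with the previous residue, CA-trace angle at CA(i));
    zeros where undefined."""
    n = len(chain.modeled_residues)
    out = np.zeros((n, 2))
    bb = _backbone(chain)
    centers = _centers(chain)
    for i in range(n):
        if i > 0 and bb[i] is not None and bb[i - 1] is not None:
            out[i, 0] = vector_angle(
                bb[i - 1]["O"] - bb[i - 1]["C"], bb[i]["O"] - bb[i]["C"]
            )
        if 0 < i < n - 1 and not np.isnan(centers[i - 1 : i + 2]).any():
            ca_prev = chain.modeled_residues[i - 1].atom("CA")
            ca_here = chain.modeled_residues[i].atom("CA")
            ca_next = chain.modeled_residues[i + 1].atom("CA")
            if None not in (ca_prev, ca_here, ca_next):
                out[i, 1] = vector_angle(
                    ca_here.coord - ca_prev.coord, ca_next.coord - ca_here.coord
                )
    return out


# ---------------------------------------------------------------------------
# assembly

STRUCTURAL_WIDTH = 36

COLUMN_NAMES = (
    [f"ss_{c.lower().replace(' ', '_').replace('-', '_')}" for c in SS_CLASSES]
    + [f"rsa_bin_{k}" for k in range(1, 11)]
    + ["phi", "psi", "neighbor_count", "virtual_surface_area",
       "rel_seq_pos", "rel_spa_pos"]
    + [f"vec_prev_{ax}" for ax in "xyz"]
    + [f"vec_next_{ax}" for ax in "xyz"]
    + [f"vec_cacb_{ax}" for ax in "xyz"]
    + ["co_angle", "caca_angle"]
)


def assemble_structural(
    chain: ChainRecord,
    ss_assign: Callable[[ChainRecord], list[str]] | None = None,
    sasa_points: int = SASA_POINTS,
) -> np.ndarray:
    """The full (n_modeled × 36) structural feature matrix for a chain."""
    ss = ss_onehot((ss_assign or secondary_structure)(chain))
    rsa_values = rsa(chain, n_points=sasa_points)
    bins = np.stack([rsa_binning(v) for v in rsa_values])
    phipsi = dihedrals(chain)
    counts = neighbor_count(chain).reshape(-1, 1).astype(float)
    vsa = np.array(
        [
            virtual_surface_area(np.array([a.coord for a in r.atoms]))
            for r in chain.modeled_residues
        ]
    ).reshape(-1, 1)
    relpos = relative_positions(chain)
    vectors = direction_vectors(chain)
    angles = backbone_angles(chain)
    blocks = [ss, bins, phipsi, counts, vsa, relpos, vectors, angles]
    widths = [9, 10, 2, 1, 1, 2, 9, 2]
    for b, w in zip(blocks, widths):
        if b.shape != (len(chain.modeled_residues), w):
            raise ValueError(
                f"structural block has shape {b.shape}, expected width {w}"
            )
    out = np.hstack(blocks)
    assert out.shape[1] == STRUCTURAL_WIDTH
    return out
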