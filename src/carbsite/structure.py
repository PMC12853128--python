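"""Structure parsing, carbohydrate-contact annotation, and sequence mapping.

A residue is a *binding* residue when at least one of its heavy atoms lies
within a distance cutoff (default 3.5 Å, inclusive) of any heavy atom of a
carbohydrate HET group in the complex.  Full (FASTA) sequences are mapped onto
the modeled residues of the structure by global alignment; unmodeled positions
carry a gap label.  Annotations are serialized as three-line records over the
label alphabet ``{1, 0, -}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: HET codes never treated as carbohydrates, whatever the lexicon says.
RESERVED_CODES = frozenset({"HOH"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ParseError(ValueError):
    """Raised for unreadable or malformed structure / annotation files."""


@dataclass
class AtomRecord:
    """One atom: element symbol, atom name, coordinates in Å, parent HET code."""

    element: str
    name: str
    coord: np.ndarray
    het_code: str
    is_heavy: bool

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite triple")
        if not self.het_code:
            raise ValueError("atom with empty residue/HET code")


@dataclass
class Residue:
    """A modeled polymer residue with its atoms."""

    name: str                     # 3-letter residue code as found in the file
    one_letter: str               # 'X' for nonstandard types
    seqid: int                    # author residue number (informational only)
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.is_heavy]
        return np.array(coords) if coords else np.empty((0, 3))

    @property
    def is_standard(self) -> bool:
        return self.one_letter in STANDARD_AA


GAP = None  # sentinel used in ChainRecord.alignment for unmodeled positions


@dataclass
class ChainRecord:
    """One protein chain: full sequence, modeled residues, mapping, labels.

    ``alignment[i]`` holds the modeled-residue index for 1-based full-sequence
    position ``i+1``, or ``None`` where the position is unmodeled.  ``labels``
    is a string over ``{1, 0, -}`` of the same length as ``full_sequence``
    (empty until :func:`annotate_binding` runs).
    """

    chain_id: str
    full_sequence: str
    modeled_residues: list[Residue]
    alignment: list[int | None]
    labels: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.alignment) != len(self.full_sequence):
            raise ValueError(
                f"chain {self.chain_id}: alignment covers {len(self.alignment)} "
                f"positions for a sequence of length {len(self.full_sequence)}"
            )
        mapped = [i for i in self.alignment if i is not None]
        if sorted(mapped) != list(range(len(self.modeled_residues))):
            raise ValueError(
                f"chain {self.chain_id}: alignment is not a bijection onto "
                f"the {len(self.modeled_residues)} modeled residues"
            )
        if self.labels:
            if len(self.labels) != len(self.full_sequence):
                raise ValueError(f"chain {self.chain_id}: label length mismatch")
            for pos, (lab, ali) in enumerate(zip(self.labels, self.alignment), 1):
                if (lab == "-") != (ali is None):
                    raise ValueError(
                        f"chain {self.chain_id} position {pos}: gap label and "
                        "alignment disagree"
                    )

    @property
    def modeled_sequence(self) -> str:
        return "".join(r.one_letter for r in self.modeled_residues)

    def n_positive(self) -> int:
        return self.labels.count("1")


@dataclass
class CarbLexicon:
    """Set of 3-letter HET codes treated as carbohydrates."""

    het_codes: frozenset[str]

    def __post_init__(self) -> None:
        codes = frozenset(c.upper() for c in self.het_codes)
        self.het_codes = codes - RESERVED_CODES

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.het_codes

    def __len__(self) -> int:
        return len(self.het_codes)

    @classmethod
    def from_file(cls, path: str | Path) -> "CarbLexicon":
        codes = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                codes.append(line.upper())
        return cls(frozenset(codes))

    @classmethod
    def default(cls) -> "CarbLexicon":
        with resources.as_file(
            resources.files("carbsite.data") / "carb_lexicon.txt"
        ) as p:
            return cls.from_file(p)


@dataclass
class ParsedStructure:
    """Polymer chains plus the heteroatoms retained for ligand lookup."""

    chains: list[ChainRecord]
    het_atoms: list[AtomRecord]


def _keep_best_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name (first wins on ties)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def _to_atom_record(atom: gemmi.Atom, het_code: str) -> AtomRecord:
    el = atom.element.name
    return AtomRecord(
        element=el,
        name=atom.name,
        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        het_code=het_code,
        is_heavy=el not in ("H", "D"),
    )


def parse_structure(path: str | Path, fmt: str | None = None) -> ParsedStructure:
    """Parse a PDB or mmCIF file into chains plus a heteroatom pool.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is inferred from the
    file extension.  The full sequence of each returned chain is initially the
    modeled sequence with an identity alignment; use :func:`attach_full_sequence`
    to map a FASTA sequence onto the chain.
    """
    path = Path(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            raise ParseError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    chains: list[ChainRecord] = []
    het_atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        polymer = chain.get_polymer()
        polymer_ids = {(r.seqid.num, r.name) for r in polymer}
        residues: list[Residue] = []
        for res in chain:
            atoms = [_to_atom_record(a, res.name) for a in _keep_best_altloc(res)]
            if (res.seqid.num, res.name) in polymer_ids:
                one = THREE_TO_ONE.get(res.name, "X")
                residues.append(
                    Residue(name=res.name, one_letter=one,
                            seqid=res.seqid.num, atoms=atoms)
                )
            else:
                het_atoms.extend(atoms)
        if not residues:
            warnings.warn(f"chain {chain.name}: no polymer residues, skipped")
            continue
        seq = "".join(r.one_letter for r in residues)
        chains.append(
            ChainRecord(
                chain_id=chain.name,
                full_sequence=seq,
                modeled_residues=residues,
                alignment=list(range(len(residues))),
            )
        )
    return ParsedStructure(chains=chains, het_atoms=het_atoms)


def collect_carb_atoms(
    structure: ParsedStructure, lexicon: CarbLexicon
) -> list[AtomRecord]:
    """Heavy atoms of every HET group whose code is in the lexicon."""
    if len(lexicon) == 0:
        raise ValueError("empty carbohydrate lexicon (configuration mistake)")
    return [a for a in structure.het_atoms if a.is_heavy and a.het_code in lexicon]


def annotate_binding(
    chain: ChainRecord,
    carb_atoms: list[AtomRecord],
    cutoff: float = 3.5,
) -> ChainRecord:
    """Label each full-sequence position as binding (1) / non-binding (0) / gap.

    A modeled residue is positive iff any of its heavy atoms lies within
    ``cutoff`` Å (inclusive) of any carbohydrate heavy atom.
    """
    carb_coords = np.array([a.coord for a in carb_atoms if a.is_heavy])
    positive = np.zeros(len(chain.modeled_residues), dtype=bool)
    if carb_coords.size:
        tree = cKDTree(carb_coords)
        for idx, res in enumerate(chain.modeled_residues):
            coords = res.heavy_coords()
            if coords.size:
                dmin = tree.query(coords, k=1)[0].min()
                positive[idx] = dmin <= cutoff
    labels = "".join(
        "-" if ali is None else ("1" if positive[ali] else "0")
        for ali in chain.alignment
    )
    chain.labels = labels
    chain.validate()
    return chain


def align_full_to_modeled(
    full_sequence: str, modeled_sequence: str
) -> list[int | None]:
    """Global (Needleman–Wunsch) map of full-sequence positions onto modeled
    residues.

    Scoring: match +1, mismatch −1, gap −2, linear.  Traceback from the
    bottom-right corner prefers diagonal > up (skip a full-sequence position)
    > left, which places gaps as late as possible in the full sequence.
    Positions of the full sequence not matched to a modeled residue map to
    ``None``.
    """
    n, m = len(full_sequence), len(modeled_sequence)
    if m == 0:
        return [None] * n
    MATCH, MISMATCH, GAP_PEN = 1, -1, -2
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP_PEN * np.arange(n + 1)
    score[0, :] = GAP_PEN * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(
            np.frombuffer(modeled_sequence.encode(), dtype=np.uint8)
            == ord(full_sequence[i - 1]),
            MATCH, MISMATCH,
        )
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + GAP_PEN,
                score[i, j - 1] + GAP_PEN,
            )
    mapping: list[int | None] = [None] * n
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            MATCH if full_sequence[i - 1] == modeled_sequence[j - 1] else MISMATCH
        ):
            mapping[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP_PEN:
            i -= 1
        else:
            j -= 1
    consumed = sorted(k for k in mapping if k is not None)
    if consumed != list(range(m)):
        raise ValueError(
            "alignment failed to consume every modeled residue "
            f"({len(consumed)} of {m}); is the full sequence complete?"
        )
    return mapping


def attach_full_sequence(chain: ChainRecord, full_sequence: str) -> ChainRecord:
    """Replace the chain's full sequence and recompute the alignment map."""
    chain.full_sequence = full_sequence
    chain.alignment = align_full_to_modeled(full_sequence, chain.modeled_sequence)
    chain.labels = ""
    chain.validate()
    return chain


def chain_filters(chain: ChainRecord, min_binding: int = 5) -> tuple[bool, str]:
    """Keep/drop decision: keep needs > ``min_binding`` positives (strict) and
    only standard amino-acid types among the modeled residues."""
    nonstandard = sorted({r.name for r in chain.modeled_residues if not r.is_standard})
    if nonstandard:
        return False, f"nonstandard residue types: {', '.join(nonstandard)}"
    n_pos = chain.n_positive()
    if n_pos <= min_binding:
        return False, f"only {n_pos} binding residues (need > {min_binding})"
    return True, f"kept: {n_pos} binding residues, all-standard sequence"


def write_annotation(chains: list[ChainRecord], path: str | Path) -> None:
    """Write three-line records: FASTA-style header, sequence, label string."""
    with open(path, "w") as fh:
        for chain in chains:
            if not chain.labels:
                raise ValueError(f"chain {chain.chain_id}: labels unset")
            fh.write(f">{chain.chain_id}\n{chain.full_sequence}\n{chain.labels}\n")


def read_annotation(path: str | Path) -> list[tuple[str, str, str]]:
    """Inverse of :func:`write_annotation`: (chain_id, sequence, labels) triples."""
    lines = Path(path).read_text().splitlines()
    if len(lines) % 3:
        raise ParseError(f"{path}: record count not a multiple of 3")
    out = []
    for k in range(0, len(lines), 3):
        header, seq, labels = lines[k], lines[k + 1], lines[k + 2]
        if not header.startswith(">"):
            raise ParseError(f"{path}: expected header at line {k + 1}")
        name = header[1:].strip()
        if len(labels) != len(seq):
            raise ParseError(
                f"{path}: chain {name}: label line length {len(labels)} "
                f"!= sequence length {len(seq)}"
            )
        if set(labels) - set("10-"):
            raise ParseError(f"{path}: chain {name}: labels outside {{1,0,-}}")
        out.append((name, seq, labels))
    return out
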