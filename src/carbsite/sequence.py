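"""Sequence-derived features: PSSM ingestion and transforms, physicochemical
lookup, residue-window index encoding, and embedding-matrix ingestion.

The PSSM is the L×20 log-odds profile written by ``psiblast -out_ascii_pssm``.
Derived features are the per-residue monogram (row sum) and the dipeptide
composition (DPC): for residue k the 20×20 outer products with its sequence
neighbors,

    DPC(k, i, j) = P[k,i] P[k+1,j]                 for k = 1,
                 = P[k,i] P[k-1,j] + P[k,i] P[k+1,j]  for 1 < k < L,
                 = P[k,i] P[k-1,j]                 for k = L,

flattened row-major to width 400.  Window encoding maps a 31-residue window
(15 on each side of the target) onto integer indices over the alphabet
``ARNDCQEGHILKMFPSTWYV-`` (A=0 … V=19, '-'=20); out-of-sequence positions pad
with 20.  Pre-computed language-model embedding matrices (widths 1024 and
1280) are ingested from TSV or ``.npy`` files, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

WINDOW_ALPHABET = "ARNDCQEGHILKMFPSTWYV-"
GAP_INDEX = 20
WINDOW_FLANK = 15
WINDOW_LEN = 2 * WINDOW_FLANK + 1  # 31

PROTT5_WIDTH = 1024
ESM2_WIDTH = 1280
STRUCTURAL_WIDTH = 36
FNN_INPUT_WIDTH = PROTT5_WIDTH + STRUCTURAL_WIDTH + ESM2_WIDTH  # 2340

_INDEX = {c: i for i, c in enumerate(WINDOW_ALPHABET)}


class PSSMFormatError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM file."""


@dataclass
class PSSM:
    """L×20 position-specific scoring matrix (PSI-BLAST column order)."""

    scores: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM must be L×20, got {self.scores.shape}")
        if self.scores.shape[0] < 1 or not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM needs at least one row of finite values")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class EmbeddingMatrix:
    """Pre-computed per-residue language-model embedding (rows = residues)."""

    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or not np.all(np.isfinite(self.values)):
            raise ValueError("embedding must be a finite 2-D matrix")


def read_pssm(path: str | Path, expected_sequence: str | None = None) -> PSSM:
    """Parse a ``psiblast -out_ascii_pssm`` file into an L×20 matrix.

    Data rows carry the residue index, the residue letter, 20 log-odds and 20
    weighted-percentage columns; the first 20 numeric columns are kept.  When
    ``expected_sequence`` is given the file's residue letters are checked
    against it.
    """
    rows, letters = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue  # header / footer lines
        numeric = parts[2:]
        if len(numeric) < 40:
            raise PSSMFormatError(
                f"{path}:{lineno}: expected 40 numeric fields per residue row, "
                f"found {len(numeric)}"
            )
        try:
            rows.append([float(x) for x in numeric[:20]])
        except ValueError as exc:
            raise PSSMFormatError(f"{path}:{lineno}: {exc}") from exc
        letters.append(parts[1])
    if not rows:
        raise PSSMFormatError(f"{path}: no PSSM rows found")
    seq = "".join(letters)
    if expected_sequence is not None:
        for pos, (a, b) in enumerate(zip(seq, expected_sequence), 1):
            if a != b:
                raise PSSMFormatError(
                    f"{path}: sequence mismatch at position {pos}: "
                    f"file has {a!r}, expected {b!r}"
                )
        if len(seq) != len(expected_sequence):
            raise PSSMFormatError(
                f"{path}: file has {len(seq)} residues, expected "
                f"{len(expected_sequence)}"
            )
    return PSSM(np.array(rows), sequence=seq)


def normalize_pssm(pssm: PSSM, mode: str = "sigmoid") -> PSSM:
    """Scale PSSM entries: ``raw`` keeps log-odds, ``sigmoid`` maps them to
    (0, 1) elementwise."""
    if mode == "raw":
        return PSSM(pssm.scores.copy(), pssm.sequence)
    if mode == "sigmoid":
        return PSSM(1.0 / (1.0 + np.exp(-pssm.scores)), pssm.sequence)
    raise ValueError(f"unknown PSSM normalization mode {mode!r}")


def monogram(pssm: PSSM) -> np.ndarray:
    """Per-residue sum of the 20 PSSM columns (width-1 feature)."""
    return pssm.scores.sum(axis=1)


def dpc(pssm: PSSM) -> np.ndarray:
    """Dipeptide composition: L×400 matrix of flattened neighbor outer
    products (row-major: i outer, j inner)."""
    P = pssm.scores
    L = P.shape[0]
    if L < 2:
        raise ValueError("DPC needs at least two residues")
    out = np.zeros((L, 20, 20))
    out[0] = np.outer(P[0], P[1])
    out[L - 1] = np.outer(P[L - 1], P[L - 2])
    if L > 2:
        inner = P[1:-1, :, None]
        # sum of the two products, not a factored form, so the result is
        # bit-identical to the elementwise definition
        out[1:-1] = inner * P[:-2, None, :] + inner * P[2:, None, :]
    return out.reshape(L, 400)


_PHYSICO: dict[str, np.ndarray] | None = None
PHYSICO_COLUMNS = (
    "polarizability", "steric", "isoelectric_point", "hydrophobicity",
    "helix_prob", "vdw_volume", "sheet_prob",
)


def physico_table() -> dict[str, np.ndarray]:
    global _PHYSICO
    if _PHYSICO is None:
        table = {}
        with resources.as_file(resources.files("carbsite.data") / "physico.tsv") as p:
            for line in Path(p).read_text().splitlines():
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split("\t")
                table[parts[0]] = np.array([float(x) for x in parts[1:8]])
        _PHYSICO = table
    return _PHYSICO


def physico(residue_letter: str) -> np.ndarray:
    """The seven physicochemical scale values for a standard amino acid."""
    table = physico_table()
    if residue_letter not in table:
        raise ValueError(f"no physicochemical values for residue {residue_letter!r}")
    return table[residue_letter].copy()


def window_encode(sequence: str, position: int) -> np.ndarray:
    """31 alphabet indices for the window centered at 1-based ``position``.

    ``sequence`` may contain '-' characters (unmodeled positions); those and
    out-of-sequence window slots encode as the gap index 20.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} out of bounds for length {len(sequence)}")
    out = np.full(WINDOW_LEN, GAP_INDEX, dtype=np.int64)
    for k, pos in enumerate(range(position - WINDOW_FLANK, position + WINDOW_FLANK + 1)):
        if 1 <= pos <= len(sequence):
            out[k] = _INDEX.get(sequence[pos - 1], GAP_INDEX)
    return out


def window_encode_all(sequence: str) -> np.ndarray:
    """Window encodings for every position of a sequence, as an L×31 matrix."""
    return np.stack([window_encode(sequence, p) for p in range(1, len(sequence) + 1)])


def read_embedding(
    path: str | Path,
    expected_length: int | None = None,
    expected_width: int | None = None,
    source_tag: str = "",
) -> EmbeddingMatrix:
    """Load a per-residue embedding matrix from a ``.npy`` or TSV file and
    check its shape against the expectation."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    values = np.asarray(values, dtype=float)
    if expected_length is not None and values.shape[0] != expected_length:
        raise ValueError(
            f"{path}: expected {expected_length} rows, found {values.shape[0]}"
        )
    if expected_width is not None and values.shape[1] != expected_width:
        raise ValueError(
            f"{path}: expected width {expected_width}, found {values.shape[1]}"
        )
    return EmbeddingMatrix(values, source_tag=source_tag or path.stem)


def assemble_fnn_input(
    prott5: EmbeddingMatrix | np.ndarray,
    structural: np.ndarray,
    esm2: EmbeddingMatrix | np.ndarray,
) -> np.ndarray:
    """Concatenate ProtT5 (1024) ‖ structural (36) ‖ ESM-2 (1280) per residue
    into the 2340-wide dense-branch input."""
    a = prott5.values if isinstance(prott5, EmbeddingMatrix) else np.asarray(prott5)
    b = np.asarray(structural, dtype=float)
    c = esm2.values if isinstance(esm2, EmbeddingMatrix) else np.asarray(esm2)
    for name, m, width in (("prott5", a, PROTT5_WIDTH),
                           ("structural", b, STRUCTURAL_WIDTH),
                           ("esm2", c, ESM2_WIDTH)):
        if m.shape[1] != width:
            raise ValueError(f"{name} block has width {m.shape[1]}, expected {width}")
    if not (a.shape[0] == b.shape[0] == c.shape[0]):
        raise ValueError(
            f"row-count mismatch: prott5 {a.shape[0]}, structural {b.shape[0]}, "
            f"esm2 {c.shape[0]}"
        )
    return np.hstack([a, b, c])
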