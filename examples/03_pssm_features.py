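"""PSSM-derived sequence features: sigmoid scaling, monogram, and dipeptide
composition (DPC).

Writes a synthetic PSI-BLAST ASCII profile, parses it back, and derives the
per-residue features used in the feature-group study.
"""

import tempfile
from pathlib import Path

from carbsite.sequence import dpc, monogram, normalize_pssm, read_pssm
from carbsite.synth import make_synth_pssm

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pssm"
    make_synth_pssm(length=8, seed=3, path=path)
    pssm = read_pssm(path)

print(f"PSSM: {pssm.scores.shape[0]} residues x {pssm.scores.shape[1]} scores")
scaled = normalize_pssm(pssm, mode="sigmoid")
mg = monogram(scaled)
pairs = dpc(scaled)
print("monogram (per-residue sum of the 20 scaled scores):")
print("  ", [round(float(v), 3) for v in mg])
print(f"DPC: per-residue width {pairs.shape[1]} "
      "(20x20 neighbor outer products, flattened)")
# Interior residues combine products with both neighbors; the two chain ends
# use their single neighbor only, so DPC is defined for every position.
assert pairs.shape == (8, 400)
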