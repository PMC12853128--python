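# Methods

This note documents the models and numerical choices behind `carbsite`, what
the synthetic fixtures do and do not emulate, and the design decisions taken
where the problem statement left room.

## Binding annotation

A modeled residue is labeled positive when any of its heavy atoms lies within
the cutoff (default 3.5 Å) of any heavy atom of a carbohydrate HET group.
The comparison is **inclusive** (≤) and exposed as a parameter; hydrogens are
ignored on both sides even when present. Carbohydrate identity comes from an
editable lexicon of 3-letter HET codes; the shipped file is a curated list of
common PDB saccharide codes and is explicitly a stand-in — users with a
definitive code list should pass their own file. Water (`HOH`) is refused
regardless of lexicon content. Distances use a k-d tree over carbohydrate
atoms; tests pin the result to a brute-force all-pairs scan.

Structure parsing (gemmi) keeps the highest-occupancy conformer per atom
name. Chains with zero polymer residues are skipped with a warning.

FASTA-to-structure mapping is a global Needleman–Wunsch alignment with match
+1, mismatch −1, linear gap −2. These sequences are near-identical (the
modeled sequence is normally a subsequence of the full one), so any sane
scheme agrees; the values are fixed for reproducibility. Traceback from the
bottom-right corner prefers diagonal > up > left, a deterministic rule that
places gaps as late as possible in the full sequence. Full-sequence positions
are 1-based; author numbering is ignored after alignment. Chain filtering is
strict: keeping a chain requires *more than* `min_binding` (default 5)
positives, and any nonstandard modeled residue type drops the chain.

## Structural descriptor (36 values per residue)

Block layout (fixed order): SS one-hot (9), RSA bins (10), φ, ψ, neighbor
count, virtual surface area, relative sequence/spatial position (2),
direction vectors (9), C=O angle, CA–CA angle.

- **Center atom** is CA, falling back to the residue's heavy-atom centroid
  when CA is missing. This definition feeds the neighbor count, the relative
  spatial position, and the prev/next direction vectors.
- **Secondary structure** uses an internal hydrogen-bond-energy assignment in
  the Kabsch–Sander spirit: the amide H is placed 1 Å from N along the
  previous carbonyl direction, the electrostatic bond energy is
  0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a −0.5
  threshold, and helices (α, 3₁₀, π), bridges/strands, turns and bends
  (CA-trace curvature > 70°) are derived from the bond pattern. The nine
  output classes are fixed; "Irregular SS" is the catch-all for residues that
  were evaluated but match no pattern, while "None" covers residues whose
  backbone is incomplete and chains shorter than three residues, where no
  pattern can exist. An external DSSP executable can be dropped in as a
  backend through the same nine-class contract (`geometry.dssp_backend`);
  the internal assignment is the default and the test backend.
- **RSA** is Shrake–Rupley SASA (960 deterministic golden-spiral sphere
  points, probe 1.4 Å, Bondi-type element radii) normalized by theoretical
  maximum-ASA constants (Tien et al. 2013 values, shipped as an editable
  table) and clamped to 1. Tests compare against an independent
  Shrake–Rupley implementation (biotite) at higher resolution; mean absolute
  deviation stays within 0.02. Because the sphere grid is lab-fixed, RSA is
  rotation-invariant only to ~1e-3, which can flip a value across a bin
  boundary; the bins are exact deciles, bin 1 = [0, 0.1], bin k =
  ((k−1)/10, k/10], with a 1e-9 guard against decimal round-off.
- **Torsions** follow the IUPAC sign convention and are kept raw in radians
  (width 1 per angle, no sin/cos expansion); termini and incomplete
  quadruples give 0.
- **Neighbor count** uses an inclusive 12 Å boundary, self excluded.
- **Virtual surface area** is the 3-D convex-hull area of the residue's
  atoms; degenerate sets (fewer than 4 affinely independent points) give 0.
- **Direction vectors** are unit-normalized; undefined cases (termini,
  glycine CB) give the zero triple. Relative spatial position is
  1/max(d, 1e-6 Å) to avoid division by zero at the centroid.

## Sequence features

PSSMs are the L×20 log-odds block of `psiblast -out_ascii_pssm` files.
Default scaling is elementwise sigmoid (raw mode available); the choice of
scaling before the derived features is a package convention. The monogram is
the row sum; the DPC of residue k is the 20×20 products with its sequence
neighbors (single neighbor at the chain ends), flattened row-major (i outer,
j inner) to 400, and the implementation sums the two products exactly as
written so it is bit-identical to the elementwise definition. The
physicochemical table (polarizability, steric parameter, isoelectric point,
hydrophobicity, helix probability, van der Waals volume, sheet probability)
ships with Meiler-scale values as an editable stand-in.

PSSM, DPC, monogram and the physicochemical vector exist for feature-group
studies; the final model input is ProtT5-type (1024) ‖ structural (36) ‖
ESM-2-type (1280) = 2340, selected by all three selection routes. Embedding
matrices are ingested from `.npy` or TSV files with strict shape checks —
running the language models is out of scope by design.

## Network

Architecture constants live in `NetConfig`; defaults give the published
configuration and the parameter shapes are verified stage-by-stage in tests
(21-dim trainable embedding of the 31-window; three concatenating residual
blocks with 10-filter kernel-3 convs; pooled lengths 15/7/3; 153→32;
2340→512→256; fused 288→128→1 sigmoid). Two open details are resolved as
follows: batch normalization sits after every conv and linear layer before
the activation (the dense-layer placement follows the stated
linear→BN→dropout→ReLU order; the conv placement is this package's choice,
without dropout inside blocks), and the fusion head's hidden width defaults
to 128. With that width the ensemble totals 3 × 1 378 072 = 4 134 216
parameters, within 0.005 % of the published 4 134 048; the residual 56
parameters per model remain unexplained and the discrepancy is documented
rather than hidden.

The layers are implemented directly on numpy with hand-written backward
passes and an Adam optimizer. Backpropagation is verified against central
finite differences (rel. 1e-4) on a small configuration, and a test asserts
that one optimization step moves every parameter block. All randomness
(initialization, dropout, batch order, resampling) flows through explicit
`numpy.random.Generator` seeds, so CPU runs are bit-reproducible; an
identical-seed run yields a bitwise-identical loss trajectory.

## Imbalance strategies and ensemble

RU keeps all positives and an equal-size random negative subset; WO draws
each epoch with replacement using inverse-class-frequency probabilities; CWL
weights the per-sample loss by (freq_neg/freq_pos, 1). SMOTE and ADASYN
interpolate only the continuous 2340-wide block between a minority sample
and one of its k=5 nearest minority neighbors; the discrete window-index
vector is copied from the seed sample, since interpolating categorical
indices is meaningless. ADASYN allocates synthetics proportionally to the
majority fraction among each minority sample's k nearest neighbors in the
full set, with the rounding remainder given to the hardest samples.

The ensemble is the fixed 2:1:1 probability average with RU doubled. The
decision threshold is 0.5 throughout.

Published training defaults are kept as module defaults: Adam at learning
rate 1e-5, batch 2048, binary cross-entropy, epochs RU:180 / WO:100 /
CWL:325. Desk-scale runs (tests, examples, pipeline defaults) use batch 64,
≤ 30 epochs and learning rate 1e-3 — a standard small-problem Adam rate —
on fixtures of ≤ 200 residues and ≤ 4000 samples, sizes chosen so the whole
suite runs in minutes on one CPU.

## Metrics

Confusion-matrix metrics follow the standard formulas; BACC ≡ (SN+SP)/2 by
construction. Ratios with empty denominators (including MCC) report 0 by
convention. ROC AUC is trapezoidal over all distinct thresholds and equals
the normalized Mann–Whitney statistic on tie-free scores; AUPR uses
step-wise precision interpolation (no linear interpolation), the appropriate
convention under heavy class imbalance. Single-class label vectors make
AUC/AUPR NaN with a warning.

## Synthetic fixtures: what they do and do not show

`make_toy_complex` builds poly-Ala/Gly chains with ideal internal
coordinates (NeRF construction from φ/ψ; helix −57°/−47° or jittered
extended coil) and plants one rigid six-atom ring per chosen binding residue
so that the nearest ring atom is exactly 3.4 Å from the residue's CA while
every non-chosen residue stays ≥ 3.7 Å from all ring atoms (verified by
brute force with retries). The margins straddle the 3.5 Å cutoff, making
boundary behavior testable and the planted labels exactly recoverable.

`make_separable_embeddings` draws two isotropic unit-variance Gaussian
classes whose means differ by an effect size d along one random direction
per embedding space; d = 4 gives a theoretical single-space linear AUC of
Φ(4/√2) ≈ 0.998, d = 0 chance level. Structural vectors in the fixture are
structurally valid (one-hot blocks, unit vectors, plausible ranges) but
carry no class signal; window indices are uniform noise.

Consequences: passing tests demonstrate that the annotation geometry,
feature algebra, network mechanics and training loops are correct, and that
the pipeline learns when the signal is linearly accessible. They say nothing
about predictive performance on real protein–carbohydrate complexes, which
depends on real embeddings, real structures and much harder class geometry.
The fixtures deliberately do not mimic language-model covariance structure,
residue-composition statistics, or structural correlations between features.

## Known limitations

- The internal secondary-structure assignment approximates the DSSP program;
  class boundaries on real, irregular structures will differ in places. The
  backend is pluggable for users who need exact DSSP output.
- SASA uses a fixed sphere-point grid; values carry ~1e-3 orientation noise.
- The greedy selection equals the exhaustive optimum score for monotone
  submodular oracles (tested), not for arbitrary score functions.
- SMOTE/ADASYN on the mixed discrete/continuous representation is resolved
  by copying window indices; alternatives (oversampling full rows) would
  change borderline behavior.
- The exact saccharide lexicon, physicochemical constants and max-ASA table
  are editable data files; results depend on them.
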