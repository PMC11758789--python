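# Methods

## Angle extraction

Structures are parsed with gemmi (PDB and mmCIF, auto-detected). Only the
first model of a multi-model file is kept; waters, amino acids and
non-nucleotide ligands are dropped. A residue counts as RNA-like if gemmi's
chemical-component tables mark it as a nucleic acid or if it carries ribose
atoms (C1′ plus C4′/O4′); modified residues map to their parent base
through the same tables (PSU → U, DNA thymine → U), with N as the fallback
letter. Alternate locations are resolved per atom name: highest occupancy
wins, ties go to the lexicographically smallest altloc code.

Dihedrals use the two-argument arctangent convention on (−180°, +180°];
a quadruple whose consecutive triple is collinear (plane-normal norm
< 1e−9 Å²) is undefined. Every angle with a missing atom is undefined, not
an error. The pseudorotation phase is reported on [0°, 360°), undefined
when all of ν₀–ν₄ are not available or when both the numerator and the
denominator of its atan2 vanish.

Two consecutive residues are treated as a chain break when the
O3′(i−1)–P(i) distance exceeds 2.5 Å **or** the author numbering is not
consecutive; angles spanning a break (α, ε, ζ, η, θ across that junction)
are undefined. The distance guard prevents nonsense dihedrals across gaps;
the numbering guard catches gaps modelled with spuriously close atoms.
Residues are indexed 0-based internally; author numbers are carried only
for reporting.

## MCQ

Tables are aligned positionally on the 0-based index after checking that
the sequences agree over the overlap (N matches anything); r is the size of
the positional overlap. Residues present in only one table are therefore
outside r — full structural alignment is deliberately out of scope. The
arctangent is the two-argument form on (Σ sin Δ, Σ cos Δ); because every
Δ ∈ [0°, 180°] the sine sum is nonnegative and the result is automatically
a deviation in [0°, 180°]. Both-undefined pairs contribute Δ = 0 to the
sums — they are counted, not skipped. P enters the torsion set T as one
angle type computed from the ν's; if P is undefined on one side (e.g. a
single missing ν) the one-undefined rule Δ = 180° applies to P only, while
the ν's themselves are not members of T. All user-facing output is in
degrees.

## Sequence-to-angles regressor

Tokenization: U→T, overlapping k-mers (k ∈ {1, 3, 4, 5, 6}, default 3,
which is the best-performing k-mer size for this task), a CLS token
prepended, k-mers containing N mapped to an unknown token. Sequences longer
than 512 nt are cropped to their first 512 nt (or rejected when cropping is
disabled).

The encoder is a post-layer-norm transformer (token + learned positional
embeddings, multi-head self-attention, GELU feed-forward) implemented
directly in numpy with hand-derived backpropagation; a finite-difference
gradient check in the test suite guards every parameter group. The
regression head is LayerNorm → Linear(hidden → 1024) → GELU →
Linear(1024 → 28) → Tanh: a (sin, cos) pair for each of the 14 angle kinds
per token. Config defaults keep the reference dimensions (hidden 768, head
1024, 28 outputs, 512-token limit) while encoder depth/heads default to a
small desk-scale setting (2 layers, 4 heads) and are freely adjustable;
tests use even smaller encoders.

Label alignment for k > 1 is the package's own rule: the token covering
nucleotides i … i+k−1 is assigned to the central nucleotide
i + ⌊(k−1)/2⌋, and the uncovered leading/trailing positions copy the
nearest assigned prediction. Training targets are built with the same rule.

Loss is mean squared error on the (sin, cos) components restricted to
defined targets (mask-true). The Tanh head makes this the natural choice;
nothing about the loss is angle-wrapped because the codec already removes
the discontinuity. Optimization is Adam with one step per example,
examples shuffled per epoch; a single integer seed governs initialization
and shuffling, and the forward pass has no stochastic component, so runs
are bit-reproducible. Angles are decoded with atan2(sin, cos), which is
scale-invariant, so unnormalized predictions decode correctly; an exact
(0, 0) pair decodes to undefined. P is derived from the decoded ν's, never
predicted directly.

## TB-MCQ scoring

`score_structure` composes the pieces: extract sequence and angles, predict
angles from the sequence, return MCQ(predicted, extracted) over T (the
pseudo-torsion set PT is available behind a flag; T is the default since
the score is torsion-based). Sequences longer than the model limit are
cropped with the prediction aligned to the cropped prefix. With an oracle
predictor that returns the native structure's own angle table, the score
equals the reference-based MCQ exactly — the degeneracy that motivates the
construction, asserted as a test. Directory scoring caches one prediction
per unique sequence, skips unparseable files with a logged record, and
sorts ascending (best first).

## Evaluation statistics

PCC is the Pearson product-moment correlation on **raw** energy and metric
values (a rank-based variant would be Spearman; the raw-value form is the
printed definition this package follows). ES takes the ⌊0.10·N⌋ lowest
decoys by metric and by energy (ties broken by stable input order — a
deterministic choice where any rule would do) and reports
100·|intersection|/N, so 10 is perfect, 1 is the expectation for an
independent scoring function (hypergeometric mean m²/N with m = N/10), and
0 means disjoint top sets. Fewer than 1/fraction decoys is an error; PCC
additionally requires nonzero variance on both sides.

## Synthetic data generator

The generator emulates the statistical shape of real per-angle
distributions at the crudest useful level: each angle kind has a single
wrapped-normal mode (`ANGLE_MODES`), centred on A-form-helix-like values
(e.g. α −68°, γ 54°, δ 82°, ν₂ 37°), spreads 5°–25°. This is a synthetic
artifact table, not measured data. Decoys add independent wrapped-Gaussian
noise of a stated scale (degrees) to every defined angle — wrapped normal
rather than von Mises because the scale is then directly interpretable in
degrees — and record the true scale as ground-truth quality. Chain-end
undefined rules (α, η first residue; ε, ζ, θ last) are enforced, and an
`undefined_rate` knocks out further entries so both undefined branches of
the Δ case analysis are exercised.

What the fixtures do **not** emulate: multi-modal angle distributions
(syn/anti χ, C2′-endo pucker), sequence- and context-dependence of angles,
correlated backbone noise, and the physics of real decoy generators.
Passing tests therefore certify the formulas, contracts and invariances,
not predictive performance on experimental structures.

The backbone builder realizes angle tables as coordinates by NeRF-style
internal-coordinate extension with fixed standard bond lengths/angles (the
tables in `build.py`); only torsions vary. α…ζ and χ round-trip through
extraction to well below 1e−4°; the ribose ring is placed with a fixed
near-C3′-endo local geometry, so extracted ν's (and hence P) are
essentially constant across residues — sufficient for definedness and
plumbing tests, not a model of pucker variability. Undefined requested
torsions fall back to A-form values so a chain is always buildable.

## Problem sizes

Defaults keep everything desk-scale: test decoy sets use 15–25 nt chains
with ≤ 60 decoys; the overfit check trains a 2-layer, 32-hidden encoder on
five 30-nt examples for 200 epochs (seconds on one CPU); the
enrichment-score calibration uses 2000 replicates of 500 decoys. Larger
models and sets are a matter of raising the config values.

## Known limitations

- No structural alignment: tables must describe the same sequence
  positionally.
- NMR ensembles collapse to model 1; insertion codes are ignored by the
  numbering-gap break rule.
- The regressor ships untrained by default (`--weights none` gives a
  random-initialized network); meaningful TB-MCQ scores require training
  on real angle tables or oracle mode.
- PCC/ES assume "lower is better" on both inputs.
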