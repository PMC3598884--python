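# Methods

## Model

`sdrpred` scores peptide binding to HLA-DR allotypes with an additive
position-weight model over the nonameric binding core. The binding
groove's five pockets (P1, P4, P6, P7, P9) each engage one core residue
(nonamer positions 1, 4, 6, 7, 9); interactions are treated as
independent across positions, which is the model's central simplifying
assumption. The pan-specific step rests on a second assumption: pocket
chemistry is determined by a small set of polymorphic β1-domain contact
positions (specificity-determining residues, SDRs), so allotypes whose
SDR residues at a pocket are interchangeable — every aligned pair
scoring strictly positive in BLOSUM62 — share that pocket's peptide
preference and can donate binding data to each other pocket by pocket.

Given a query allotype, each pocket independently pools the nonamer
cores of all similar database allotypes and estimates residue
frequencies at its anchored core position with pseudocounts:

    f_adj(a) = (count_a + n/20) / (2n) = ½·f_raw(a) + ½·(1/20)

where n is the pool size. The mixture form shows the estimator shrinks
the empirical frequency halfway to uniform at every n and is bounded
below by 1/40, so the log-odds weights

    w(a) = log( f_adj(a) / p(a) )

are always finite. A nonamer's raw score is the sum of its anchored
residues' weights; raw scores are mapped linearly onto [1, 100] using
the theoretical extremes s_min = Σ rows min w and s_max = Σ rows max w,
with 60 as the default binder cutoff. The normalized score is invariant
to the logarithm base (a base change rescales w, s_min and s_max by one
constant, which the linear map cancels) — this is property-tested, so
the natural-log default carries no compatibility risk.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| affinity cutoff | 50 nM IC50, boundary inclusive | high-affinity ligand selection; chosen because immunodominant epitopes associate with very stable pMHC complexes |
| SDR similarity | BLOSUM62, all pairs > 0 | conservative per-pair rule; zero counts as *not* similar; a "sum positive" mode is available |
| background p(a) | uniform 1/20 | alternative composition tables can be supplied |
| binder cutoff | 60 (normalized) | discriminates binders on the 1–100 scale |
| PWM shape | 5 pocket rows | unanchored nonamer positions contribute 0; a 9-row mode estimates positions 2, 3, 5, 8 from the P1 pool |
| Gibbs sampler | 5 restarts × 100 sweeps, linear cooling 1.5→0.2, greedy finish | see below |

The pocket → β-position map is configuration, not code. The shipped
default is a stand-in assembled from published DR pocket-contact
residues (TEPITOPE-style definitions), trimmed to 15 disjoint positions:
P1 {85, 86}, P4 {13, 70, 71, 74, 78}, P6 {11, 30}, P7 {28, 61, 67},
P9 {9, 37, 57}, with 1-based mature-protein numbering on a pre-trimmed
β1 domain. All science code reads only the configuration, so replacing
the map with a different position set is a JSON edit. Overlapping
pockets (one β residue serving two pockets) are supported and validated.

The half-life ↔ rate conversions use k_off = 0.693/t½ and
K_d = k_off/k_on with the conventional three-figure ln 2; a 100 h
half-life gives k_off = 1.925e-6 s⁻¹ and, with diffusion-limited
on-rates of 1e4–1e5 M⁻¹s⁻¹, K_d between ~0.2 and ~0.02 nM — the
kinetic rationale for driving the model with high-affinity data only.

## Core alignment

Variable-length class II ligands are aligned to a common nonamer
register by leave-one-out Gibbs sampling: hold one ligand out, score its
windows against the pseudocounted log-odds of the remaining cores
(same smoothing rule as the PWM engine), resample its offset from the
Boltzmann distribution under a cooling temperature, and finish each
restart with a deterministic greedy pass that accepts only moves
improving the global objective (sum of core log-odds) — making the
closing trace provably non-decreasing and the result reproducible from
one seed. Defaults (5 restarts × 100 sweeps) recover ≥ 96% of planted
core offsets on 50-ligand sets across seeds; larger settings gave no
measurable improvement at the database sizes this package targets.
Degenerate inputs: a set of exact nonamers has a single register and
bypasses sampling; tied windows resolve to the smallest offset; an
allele with a single ligand takes its offset-0 window and is flagged
`low_support` in store metadata.

## Evaluation protocol

Leave-one-allele-out cross-validation excludes one allele's cores *and
profile* entirely, builds its matrix from the remaining alleles via the
SDR transfer, and scores the excluded allele's cores as positives. This
is the honest test of pan-specificity; a provenance audit (each matrix
row records its contributing allotypes) verifies the exclusion. The AUC
is the Mann–Whitney estimator with midrank tie handling; balanced AUCs
resample |positives| negatives without replacement, ten times by
default, under per-repeat seeds spawned from one master seed. Negatives
default to residue-shuffled copies of the positive cores
(composition-preserving); when source proteins exist, the per-protein
construction (all same-length windows except the annotated epitope) is
used instead — both constructions are explicit in the API. Per-allele
and pooled AUCs are both reported since they differ on unbalanced
panels. The fractional AUC integrates the ROC over false-positive rate
∈ [0, 0.2] (specificity 0.8–1.0) with boundary interpolation. Epitope
retrieval is summarized by the ranking percentage — the competition rank
of the epitope's best fully-contained nonamer window among all windows
of its source protein — binned into (0,1], (1,3], (3,5], (5,100]%.

An allele whose exclusion empties every pocket pool receives an all-zero
matrix (permissive default; strict mode raises instead): every score
then ties at the 50.5 midpoint and the midrank AUC is exactly 0.5. The
result is computed but flagged `evaluable=False`.

## Synthetic data

The generator emulates exactly the structure the method exploits: each
(pocket, sharing-group) gets an independent categorical preference over
the 20 residues drawn from a symmetric Dirichlet (concentration 0.1 by
default — sharp, high-affinity-like preferences; smaller is sharper),
and SDR positions are written so that same-group allotypes are
BLOSUM62-identical and different-group allotypes pairwise negative at
every pocket position (using the mutually dissimilar residue set
L/D/G/W/P, which caps designs at five groups per pocket). Cores draw
anchored positions from the pocket distributions and unanchored
positions uniformly; ligands pad cores with uniform flanks and record
true offsets; antigens are uniform-random backbones with one consensus
epitope inserted, flagged if a background window happens to tie the
planted one.

What passing tests on this world do **not** show: real binding data have
correlated positions, peptide-flanking effects, length preferences,
assay noise and database biases, none of which are simulated; real SDR
similarity is graded rather than block-structured; and real pocket
preferences are not Dirichlet-sharp. The synthetic results validate the
machinery (transfer, estimation, scoring, ranking, cross-validation
bookkeeping), not field performance on experimental repositories.

Problem sizes used by the automated checks — 5-allotype panels with 200
cores per allotype for transfer recovery, 50 15-mer ligands for
alignment recovery, 100 150-residue antigens for ranking — are the
smallest at which the statistical assertions are stable across seeds.

## Numerical and design choices

- "1–100" is read literally: the map is [s_min, s_max] → [1, 100], so a
  degenerate matrix maps everything to the midpoint 50.5 (with a
  warning), and the midpoint of a healthy matrix is 50.5, not 50.
- Ties in epitope ranking use competition ranking (best tied position);
  repeated epitope occurrences all count, best kept.
- `X` residues: flagged on input; an X at an SDR position is an error in
  strict mode and a match-nothing wildcard in permissive mode; an X in a
  scanned antigen contributes 0 to the affected rows with a warning, so
  real sequences with rare ambiguity codes still scan.
- Pooling is uniform over similar allotypes. Weighting by SDR-similarity
  strength is a possible extension, deliberately not implemented: the
  similarity rule is binary by design and a graded variant would need
  its own calibration data.
- Store serialization is sorted TSV + JSON (diff-able and hash-stable;
  byte-identical across rebuilds with equal inputs and seed).
- Filters apply in a fixed order (length → composition → assay →
  affinity) and their rejection counts partition the input, so filter
  provenance is auditable from store metadata.

## Known limitations

Position independence ignores anchor-anchor coupling; binding is treated
as the sole determinant of immunogenicity (antigen processing and T-cell
repertoire effects are out of scope); DQ/DP are rejected rather than
modelled, since their specificity involves both chains; the default SDR
map is a literature-informed stand-in, and predictions are only as good
as the position map and the similarity rule; quantitative IC50
regression is not attempted — the model is a binary high-affinity
classifier with a continuous score.
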