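# Methods

This note documents the modelling and numerical choices behind
`epitopegnn`: what is computed, under which conventions, and what the
synthetic experiments do and do not demonstrate.

## Problem setting

A conformational B-cell epitope is a set of antigen surface residues that
an antibody contacts; the defining interaction is geometric, so the ground
truth here is geometric too: residue *i* is labelled positive iff the
minimum distance between any of its heavy atoms and any antibody atom is
≤ 4 Å (boundary inclusive — "within" is read inclusively, and the choice
is fixed so results are bit-reproducible). Hydrogens are parsed but never
enter distance computations. Surface residues are those with relative
solvent accessibility rASA ≥ 0.15 (inclusive).

## Structure handling

PDB and mmCIF files are read through gemmi. Polymer residues with at
least one heavy atom are kept in file order; waters and ligands are
dropped; only the first model of multi-model files is used; alternate
locations resolve to the highest-occupancy conformer, ties to altloc 'A'
(a deterministic-parsing rule, not a physical claim). Internally residues
are indexed 0-based and contiguous per chain — all graph math uses
positional indices — while author numbering is carried for reporting
only. Nonstandard residues map to 'X' and remain graph nodes.

## Per-residue features

The structural descriptor per residue is 14-dimensional:

* a 9-state one-hot over the 8 DSSP secondary-structure states
  (H, B, E, G, I, T, S, -) plus an "unknown" state in position 9
  (used for residues missing from the DSSP file, unrecognized codes, and
  lowercase disulfide-bridge letters);
* rASA = min(ASA / maxASA(aa), 1). The maxASA table is the Tien et
  al. (2013) theoretical maxima; any fixed published table preserves the
  ordering, so the choice is recorded here as a constant. The cap at 1 is
  this package's decision for exposed conformers whose measured ASA
  exceeds the theoretical maximum;
* [sin φ, cos φ, sin ψ, cos ψ]. Torsions are computed from coordinates
  with the standard sign convention (anti = ±π; verified against an
  independent structural library). Undefined angles — chain termini,
  missing backbone atoms — encode as (0, 0), a point off the unit circle,
  so the model can distinguish "undefined" from every real angle.

DSSP is consumed as a file (classic text or mmCIF dialect); secondary
structure and ASA are not recomputed internally, torsions are.

## Graph construction

Three edge types with defaults d_seq = 3, d_r = 10 Å, k = 10, d_long = 5
(d_long > d_seq enforced): sequential edges for 0 < |i−j| < d_seq (strict,
as the inequality is written), radius edges for Cα distance strictly
< d_r with |i−j| ≥ d_long, and k-NN edges restricted the same way,
symmetrized to an undirected union with distance ties broken toward the
smaller index. Pairs in the separation gap d_seq ≤ |i−j| < d_long can
only be connected spatially. Edge type tags are retained in the data
model, but propagation runs over the untyped union graph: the multi-scale
update has no edge-type term, so a typed-weight variant is noted as an
extension rather than guessed at.

"k-hop neighbourhood" is read as the BFS ball (within ≤ k hops) of the
union graph, with self-loops added before normalization — the
GCN-style symmetric normalization presupposes self-inclusive propagation,
and the within-k reading yields the intended nested receptive fields
A₁ ⊆ A₂ ⊆ A₃.

## Network

Each modality is projected by its own linear map to 256-d, layer-normalized
per row (ε = 1e-5) and passed through ReLU before concatenation (X₀,
768-d). The attention branch computes eᵢ = Vᵀ tanh(W xᵢ) and a softmax
over residues; since prediction is per-residue but attention pools to a
single context vector Z, the branch output is defined as [xᵢ | Z] — the
minimal reading that gives every residue access to global context while
keeping the MLP input per-residue.

Each GCN layer runs three parallel convolutions ReLU(D_k⁻¹ᐟ² A_k D_k⁻¹ᐟ²
H W_k), degrees taken per scale with self-loops included, concatenates the
three outputs and fuses them with a linear map + ReLU. Two layers are
stacked. The residual combination H = λH₀ + (1−λ)H_deep uses
λ = σ(θ) with θ unconstrained and initialized at 0 (λ = 0.5): the convex
constraint is kept by reparameterization because a raw scalar clipped to
[0, 1] would have dead gradients at the boundary. H₀ is X₀ passed through
a dimension-matching linear map when the widths differ.

The MLP head uses two hidden layers (256, 64) with ReLU and dropout 0.3,
emitting one logit per residue. Head widths, dropout, and the Adam
settings (lr 1e-3, β = (0.9, 0.999), up to 100 epochs, early stopping on
validation AUPR with patience 10) are this package's recorded defaults;
weights initialize Glorot-uniform from a seeded generator, so every run
is reproducible.

The network and its gradients run on a small in-package reverse-mode
autodiff engine over numpy (`epitopegnn.autodiff`), float64 throughout;
gradient correctness is tested against central finite differences, and
every layer's algebra against independent dense-matrix oracles.

## Imbalance handling

`resample` implements the hybrid strategy on a flat feature matrix:
positives are augmented by SMOTE (uniform interpolation toward one of the
5 nearest positive neighbours) and negatives randomly under-sampled to an
exact 1:2 positive:negative ratio. The target sizes are
final_pos = min(2·n_pos, ⌊n_neg/2⌋), final_neg = min(n_neg, 2·final_pos);
this reproduces the canonical 100/5000 → 200/400 (33.33% positive)
example and leaves a set already at or below 1:2 unchanged. Inside graph
training the same 1:2 balance is applied as a per-protein loss mask with
negatives under-sampled instead: SMOTE-synthesized residues have no
coordinates and hence no edges, so they cannot participate in message
passing. Both routes are exposed; the mask is the training default.

## Evaluation and statistics

Confusion metrics follow the standard formulas with explicit zero-division
conventions (precision 0 when TP+FP = 0, F1 = 0 when pre+rec = 0, MCC 0
when any denominator factor vanishes). AUC is the Mann–Whitney rank
statistic with half credit for ties; AUPR is the step-wise
precision–recall integral without linear interpolation — both are
implemented directly in this form and cross-checked against scikit-learn
in the tests. The decision threshold scans −∞, +∞ and midpoints between
consecutive sorted unique validation scores, maximizing F1 with ties
resolved to the lowest threshold; with no positive labels the threshold
is +∞ (predict all-negative).

Cross-validation partitions at the protein level into folds differing by
at most one protein. Two fold-model selection protocols exist: selection
by held-out-fold AUC (default, leak-free) and selection by external-test
AUC (provided for protocol compatibility; it is optimistic because the
test set influences model choice).

The DeLong test compares two correlated AUCs via mid-rank placement
values and a two-sided normal p; identical score vectors return p = 1.
Stratified bootstrap resamples positives and negatives separately with
replacement (default B = 2000), reports percentile 95% CIs, and — for
paired model comparison — a two-sided p from the sign distribution of the
resampled metric difference.

## Synthetic data

The fixture generator produces everything the pipeline consumes:

* backbones built by internal-coordinate (NeRF) chaining with ideal bond
  geometry and trans peptide bonds, so recomputing torsions recovers the
  generating (φ, ψ) to machine precision — the parameter-recovery oracle;
* toy antigen–antibody complexes: an extended-strand antigen with
  pseudo-atoms placed at exactly the requested gap from chosen residues
  and ≥ 4.5 Å clear of all others. The clearance default reflects a
  geometric fact: on a connected backbone adjacent residues sit ~3.8 Å
  apart, capping achievable clearance near 5 Å; 4.5 Å keeps a margin
  above the 4 Å labeling cutoff so planted contacts are recovered exactly;
* class-conditional Gaussian embeddings: unit-variance rows, with the
  positive-class mean shifted by δ (in pooled-SD units) along one fixed
  random unit direction per modality shared across proteins — shared so
  that a signal learned on training proteins transfers to validation
  proteins; δ = 0 is the no-signal control;
* spatially clustered labels: positives are the residues nearest a random
  patch centre, with the patch radius adapted to hit the target positive
  fraction (default 25% — generous relative to the few-percent epitope
  prevalence of real surface residues, chosen so desk-scale proteins
  contain enough positives to train on).

Default study conditions for the planted-signal experiment: 30 proteins
of 40–60 residues, embedding dims reduced to 64/32 (every operation is
dimension-agnostic; the reduction keeps the full training loop in seconds
on one CPU), δ = 2, 24/6 train/validation split, 60-epoch cap. Under
these conditions validation AUC reaches ≥ 0.95, the label-permuted and
δ = 0 controls stay at chance, and AUC is monotone in δ over
{0, 0.5, 1, 2}.

What passing these tests shows: the full pipeline — featurization, graph
construction, both branches, training, thresholding, metrics — is wired
correctly and can extract a linear class-conditional mean shift through
the network. What it does not show: performance on real antigens. The
generator does not mimic real embedding covariance, real epitope
prevalence (3–7% of surface residues), structural correlations between
embeddings and geometry, or predicted-structure error; benchmark-scale
claims require the curated antigen datasets and frozen large embedders
that are out of scope here.

## Known limitations

* One feature-dimension bookkeeping point: the structural descriptor is
  14-d (9 + 1 + 4); some descriptions of this feature family count it as
  13. The projection layer is width-agnostic, so nothing downstream
  depends on the count.
* Edge types are recorded but not used in propagation.
* NMR-style multi-model files use the first model only; biological
  assemblies are not expanded; multi-chain antigens are handled per
  declared chain.
* The autodiff engine is dense and single-threaded; proteins of a few
  hundred residues are fine, very large complexes are not the target.
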