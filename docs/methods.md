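# Methods

## Problem and model

The package addresses binary classification of protein sequences as
bioluminescent (BLP) or not. BLPs are hard to annotate by homology — the
family is functionally defined and sequence-diverse — so the classifier
works from alignment-free representations of the primary sequence and a
gradient-boosted tree ensemble. The modelling surface follows the
model/results convention: `BLPClassifier` holds the data and
configuration, `fit()` returns a `ModelBundle` that carries the fitted
booster, the encoder configuration, the column-layout fingerprint and
persistence/summary methods.

## Encoders

### Natural vector

Positions are measured as offsets from the first residue: the residue at
1-based position `p` has offset `s = p − 1`. For each amino acid `k` with
`n_k` occurrences at offsets `s₁ < … < s_{n_k}`:

* count `n_k`,
* mean offset `μ_k = (Σ sᵢ)/n_k` (0 when absent),
* second normalized central moment `D₂ᵏ = Σ (sᵢ − μ_k)² / (n_k · L)`
  (0 when absent).

The 60-vector interleaves `(n, μ, D₂)` in alphabetical amino-acid order.
Two useful identities hold for every sequence and are enforced as
property tests: `Σ_k n_k = L` and `Σ_k n_k μ_k = L(L−1)/2` (every offset
counted once). The offset-from-origin convention is fixed by the
reference peptide MCRAACGECFR, whose alanines at positions 4 and 5 give
`T_A = 3 + 4 = 7`; an alternative 1-based-position reading would give 9
and is rejected by that example.

### CTD

Each of 13 physicochemical attributes (seven hydrophobicity scales,
normalized Van der Waals volume, polarity, polarizability, charge,
secondary-structure propensity, solvent accessibility) partitions the
alphabet into three disjoint groups; the partition table ships as
checksummed package data. Per attribute the encoder emits:

* composition — the fraction of residues in each group (sums to 1);
* transition — for each unordered group pair, the number of adjacent
  residue pairs crossing the two groups in either order, divided by
  `L − 1` (same-group adjacencies contribute nothing);
* distribution — per group, the 1-based sequence positions of the first,
  `⌈0.25·n⌉`-th, `⌈0.50·n⌉`-th, `⌈0.75·n⌉`-th and last occurrence, scaled
  by `100/L`; an unoccupied group emits five zeros.

The ceiling convention for the quartile occurrence index is the dominant
one in the CTD literature; it makes a homopolymer of four residues emit
landmarks (25, 25, 50, 75, 100). 3 + 3 + 15 descriptors × 13 attributes
= 273.

### g-gap dipeptide composition

`f⁽ᵍ⁾(a,b) = n⁽ᵍ⁾(a,b)/(L − g − 1)` over the 400 ordered pairs in
lexicographic order, where `n⁽ᵍ⁾(a,b)` counts positions `i` with residues
`(a, b)` at `(i, i + g + 1)`. Every pair window is counted exactly once,
so the 400 frequencies sum to 1; `g = 0` reproduces adjacent dipeptide
composition, which the unit tests check against an independent
enumeration oracle. Sequences shorter than `g + 2` are rejected.

### Type-II PseAAC

The first 400 components are adjacent dipeptide frequencies. For tier
`k = 1..λ` and property `p = 1..9` the encoder computes a separate
sequence-correlation factor

    φ_{9(k−1)+p} = (1/(L−k)) · Σ_{i=1}^{L−k} (h_p(Rᵢ) − h_p(Rᵢ₊ₖ))²

where `h_p` are the property values z-standardized over the 20 residues
(zero mean, unit population SD). Components are jointly normalized by
`Z = Σf + ω·Σφ`, giving `x_u = f_u/Z` (u ≤ 400) and
`x_{400+j} = ω·φ_j/Z`, so `Σ x = 1` exactly. The squared-difference
correlation function was chosen over the signed product of standardized
values: products make `Σφ` a zero-mean random walk over the 9λ factors,
so `Z` becomes non-positive for a non-negligible fraction of ordinary
sequences once `ω` is large (the tuning protocol runs ω up to 1 and λ up
to 48), which would make the encoder partial for no scientific reason.
With squared differences φ ≥ 0 always, `Z ≥ 1`, and the ω-monotonicity of
the correlation-component mass holds unconditionally. A `Z ≤ 0` guard is
retained for defence in depth.

Property table (9 × 20, shipped as checksummed package data):
hydrophobicity (Tanford-style scale standard in PseAAC work),
hydrophilicity (Hopp–Woods), side-chain mass, pK1 (α-COOH), pK2 (α-NH₃⁺),
pI (standard reference values), flexibility (Bhaskaran–Ponnuswamy average
flexibility), rigidity (Chou–Fasman β-sheet propensity, used as a
documented proxy for side-chain rigidity), and irreplaceability (inverse
Dayhoff relative mutability — residues that mutate rarely are the least
replaceable). The last three scales are proxies chosen because no single
canonical table exists for them in machine-readable form; since every
property is z-standardized before use, only the profile of each scale
across residues matters, not its units or offset.

## Classifier and protocol

XGBoost binary classifier with the tuned defaults `n_estimators = 280`,
`max_depth = 12`, `learning_rate = 0.1`, `gamma = 0`; all other
parameters at library defaults; `scale_pos_weight` set to the
negative/positive count ratio (1 on balanced data). Training is
single-threaded and seeded, so refits are bit-reproducible.

Species presets (the best-performing feature combinations per taxon):
general = NV+CTD+GGAP+PSEAAC with (g, λ, ω) = (3, 18, 0.2); bacteria =
CTD+GGAP+PSEAAC with (3, 11, 0.1); eukaryote = CTD+GGAP with g = 6;
archaea = NV+CTD+GGAP with g = 1.

Encoder-parameter selection (`grid_search_encoding`) evaluates each grid
point by stratified k-fold cross-validated AUC (default k = 10) on folds
fixed by seed *before* the grid loop, so all points are compared on
identical splits. Stratification is used because AUC on small minority
folds is otherwise unstable. Ties break toward the lower-dimensional
configuration (smaller λ, then g, then ω). Grid points with λ ≥ the
shortest sequence length are skipped with a warning, since the deepest
correlation tier would be undefined. The protocol grids are g ∈ 1..9,
ω ∈ {0.1, …, 1.0}, λ ∈ 1..38 (general, bacteria), 1..42 (eukaryote),
1..48 (archaea).

## Metrics

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N, MCC with the standard
0-on-zero-denominator convention, and ROC/AUC computed over all score
thresholds with trapezoidal area; tied scores are crossed diagonally so
the AUC equals the Mann–Whitney U statistic with ties counted one half
(verified exactly against a brute-force pair-counting oracle in the
tests). Fold averaging is the unweighted mean of per-fold metrics. The
decision threshold is 0.5, with a score exactly at the threshold called
positive; the threshold is exposed on the CLI.

`cross_species_matrix` scores every model on every species' dataset,
encoding each dataset under the model's own config; the self-cell
evaluates a model on its own training data and is therefore an
interpolation check (≈100% accuracy), matching the protocol this matrix
reproduces. `compare_classifiers` runs decision-tree, random-forest and
AdaBoost baselines at scikit-learn defaults on folds identical to the
booster's (the shared fold hash is recorded in each result).

## Synthetic corpora

Negatives are drawn residue-wise i.i.d. from the background (uniform by
default; a natural-abundance background is available). Positives are
drawn from a first-order chain: when the residue `gap + 1` positions
back is one of the favoured residues (default {A, R, P, G}), the next
residue is drawn with favoured-residue probabilities multiplied by
`dipeptide_boost` and renormalized. This plants an ordered-pair
enrichment exactly at offset `gap + 1`, detectable by the g-gap encoder
at `g = gap`; `boost = 1` collapses the chain to the background, making
the classes exchangeable. Side effects worth knowing: the boost also
raises the overall favoured-residue frequency in positives (so
composition-only encoders see some signal at any g), and the chain
induces weaker second-order correlations at multiples of `gap + 1` —
visible as a secondary AUC bump at `g = 2·gap + 1` in grid searches.
Default lengths are uniform on [50, 100]: long enough for every preset
(λ ≤ 29 needs L ≥ 30) while keeping desk-scale runs fast. What passing
tests on these corpora show is that the pipeline can extract a planted
compositional/pair signal at the correct offset; they say nothing about
the harder, lower-signal structure of real BLP families, domains or
evolutionary correlations, which the generator does not model.

## Problem sizes used by the test suite

Learnability checks run at n = 500+500 sequences with 10-fold CV and the
tuned booster (AUC ≥ 0.9 at boost 5; 0.5 ± 0.05 at boost 1). The
gap-recovery experiment runs the 9-point g grid at n = 250+250, k = 3,
with a 60-tree depth-4 booster over five corpus seeds — sizes chosen to
keep the full suite around a minute while leaving the recovery
unambiguous (the planted gap wins the grid in 5/5 seeds at these
settings). Numerical tolerances: probability-normalization invariants at
1e−9; AUC-vs-oracle agreement at 1e−12; stochastic checks (chance-level
AUC) at ±0.02 with n = 10,000.

## Known limitations

* The packaged property/grouping tables are literature-standard stand-ins
  for tables distributed only through the original tool's site; rankings,
  not exact values, are what the encoders consume after standardization.
* No evolutionary/profile features (PSSM), motifs or structure — out of
  scope by design.
* Bundles refuse to load across xgboost major versions rather than
  risking silent mispredictions.
* The synthetic generator's first-order chain cannot represent
  long-range or family-specific structure; benchmark performance on real
  corpora must be established on real data.
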