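# Methods

## Pipeline overview

`roinet` analyzes two-group resting-state cohorts as binary functional
connectomes. Per subject: regional BOLD time series (T×N, after any
upstream preprocessing) → N×N Pearson correlation matrix → binarization
over a sparsity sweep → global and nodal graph metrics → AUC across the
sweep. Per cohort: covariate residualization → permutation group
comparison with Bonferroni correction → hubs and viewer exports.
The package assumes preprocessing (slice timing, normalization, nuisance
regression, band-pass filtering) happened upstream; its inputs are
delimited-text matrices.

## Network construction

- **Correlation**: sample Pearson correlation between all region pairs;
  the diagonal is set to exactly 1 and the matrix symmetrized against
  floating-point asymmetry. Zero-variance regions are an error (they
  indicate broken extraction, not data).
- **Sparsity**: the fraction of retained edges out of N(N−1)/2. At level
  s the K = floor(s·N(N−1)/2) strongest edges are kept. Floor rounding
  guarantees realized sparsity ≤ requested and makes edge sets nest
  exactly across the sweep. For N = 90 and s = 0.10 this keeps 400 of
  4005 edges.
- **Ranking policy**: edges rank by signed correlation by default
  (positive correlations fill the graph first), the common connectome
  default; ranking by |r| is available (`rank="absolute"` /
  `--edge-rank absolute`) and every report names the policy only through
  the options used. No Fisher z transform is applied — thresholding is
  rank-based, so any strictly monotone transform selects the same edges
  (a property the tests assert).
- **Ties** at the cutoff break by lexicographic (i, j) node order, for
  bit-identical results across platforms. Ties have measure zero on real
  data.
- **Sweep**: default 0.05–0.50 in steps of 0.05 (10 levels), covering
  very sparse to half-dense graphs.

## Graph metrics

Computed on dense 0/1 adjacency matrices with a level-synchronous
multi-source BFS expressed as boolean matrix products, giving all-pairs
distances and shortest-path counts in a handful of N×N multiplications.
Betweenness uses the path-counting identity: a shortest h→j path passes
through i iff d(h,i)+d(i,j)=d(h,j), contributing σ(h,i)·σ(i,j)/σ(h,j).
This evaluates the betweenness definition directly and is validated
exactly against exhaustive path enumeration (all graphs with N ≤ 8) and
against networkx at realistic sizes.

Conventions for degenerate cases (all documented because the textbook
formulas are undefined there, and sparse thresholds do produce
disconnected graphs):

- `Lp` averages over *finite* (connected) ordered pairs only; a graph
  with no edges raises an error. Note this makes Lp — and hence λ —
  smaller on fragmented graphs than intuition suggests: a graph of many
  small components has only short finite paths. λ well below 1 at sparse
  thresholds is a signature of this convention, not a bug.
- Efficiency-type metrics (`Eg`, `Eloc`, `NEi`) score disconnected pairs
  as 1/∞ = 0, so they remain defined everywhere.
- Nodes with degree < 2 contribute 0 to clustering and local efficiency
  (avoids 0/0).
- `NBi` is normalized by (N−1)(N−2) over ordered pairs, equivalently
  (N−1)(N−2)/2 over unordered pairs; values lie in [0, 1] with the star
  center at exactly 1.

**Random references**: γ, λ, σ compare each graph with the mean
clustering (Cr) and path length (Lr) of an ensemble of degree-preserving
randomizations (Maslov–Sneppen double-edge swaps, ≥ 10× edge-count
successful swaps per reference, candidate pairs drawn in batches from a
seeded generator). Default ensemble size is 100 references; seeded per
subject × sparsity so tables are reproducible and order-independent. A
complete graph admits no swap; it returns its own (Cp, Lp) with a
warning. If an ensemble's mean clustering or path length is 0 (possible
for very sparse, tiny graphs whose references are triangle-free) the
ratios are undefined and an error is raised rather than a silent NaN.

**Hubs**: a node is a hub when its metric exceeds the across-node mean
by more than one standard deviation (sample SD, N−1 denominator; the
choice of denominator is a convention we fix and document). Group-level
hubs use the group-mean nodal AUC per node.

## Group inference

1. **AUC**: each metric curve is integrated over the sweep by the
   trapezoid rule, giving one threshold-free number per subject.
2. **Covariates**: AUC values are residualized on [intercept, age,
   gender, education] by OLS before any permutation — the adjustment is
   estimated once on the pooled sample, matching the
   regress-then-permute order. Rank-deficient designs are rejected with
   the collinear columns named.
3. **Permutation test**: pooled-variance two-sample t (patient −
   control); the null is built by randomly reassigning group labels
   (default 10,000 reshuffles, shared across variables of a family for
   speed); two-tailed p with the add-one (Phipson–Smyth) estimator
   p = (1 + #{|t*| ≥ |t|})/(n_perm + 1), which cannot be 0. Note the
   smallest achievable p is 1/(n_perm+1): resolving a Bonferroni
   threshold of α/m requires n_perm + 1 > m/α (e.g. m = 90 at α = 0.05
   needs more than 1,800 permutations; the 10,000 default is safe).
4. **Correction**: Bonferroni per family — the 7 global metrics form one
   family; each nodal metric forms a family of N node-level tests
   (`nodal_family="pooled"` corrects over all 3N nodal tests instead).
   Per-metric families are the default because nodal metrics answer
   separate questions and are reported separately.
5. **Direction**: significant results are labelled patient_gt /
   patient_lt by the sign of t.

## Synthetic cohorts

The generator draws each subject's T×N series i.i.d. in time from a
multivariate normal whose correlation matrix has block (community)
structure: `within_block_r` (default 0.5) inside each of `n_blocks`
(default 6) contiguous communities, `between_block_r` (default 0.1)
elsewhere. In the patient group the between-community correlations of
`effect_nodes` (default 3 nodes spread across communities) are shifted
by `effect_delta_r` (default +0.3), then the matrix is projected to the
nearest positive-definite correlation matrix (eigenvalue clipping at
1e-6, diagonal rescaled — this perturbs targets slightly, which the
tests tolerate). Independent Gaussian noise (`noise_sd`, default 0.2)
attenuates all correlations by 1/(1+noise_sd²). Defaults emulate a
27-per-group, 90-region study with 190 retained time points (200
acquired minus 10 discarded).

A positive between-community shift turns the effect nodes into
connector nodes after thresholding: their degree and especially their
betweenness rise sharply in the patient group, which is the planted
ground truth that recovery tests check. Covariates: age uniform on 5–14
years, gender balanced within group, education ≈ age − 6 with 1 year of
noise (clipped at 0), so the covariate regression has realistic
structure.

What the generator does **not** emulate: hemodynamic response and
temporal autocorrelation (an optional AR(1) coefficient exists for
robustness checks and preserves the cross-sectional covariance), scanner
noise spectra, motion artifacts, spatial smoothness, and non-Gaussian
tails. Passing tests therefore demonstrate the statistical machinery is
calibrated and sensitive under the stated distributional model, not that
effect sizes transfer to real BOLD data.

## Motion QC

Subjects are excluded when the maximum absolute frame-wise realignment
parameter exceeds 1.5 mm (translation) or 1.5° (rotation); comparisons
are strict ("more than"), so a subject exactly at a limit is retained.
The limits apply to the realignment parameters themselves, not to
derived frame-wise displacement; both limits are exposed as options.
Records without motion traces pass QC with a logged warning, since
simulated cohorts carry no motion.

## Problem sizes and numerical choices

- Calibration checks run 500 null studies at 10 subjects/group, 30
  regions, 1,000 permutations — sizes chosen so the whole suite runs on
  a laptop while keeping Monte-Carlo error on the type-I rate near
  0.002; the acceptance script uses 100 null studies and 20 recovery
  replicates for the same reason. Recovery replicates keep the full
  default geometry (27/group, 90 regions, 10,000 permutations).
- The acceptance script's global-metric stage uses 10 random references
  per graph; ensemble means over 10 references per graph × 10 sparsity
  levels, averaged again over 27 subjects, are stable to well under the
  between-subject spread.
- All randomness flows through numpy Generators seeded from explicit
  integers; derived seeds stay below 2³¹. Fixed seeds reproduce every
  table byte-for-byte.

## Known limitations

- Binary undirected graphs only: no weighted, directed, partial-
  correlation or negative-network variants.
- The finite-pairs Lp convention makes Lp (and λ) non-monotone across
  sparsity when components merge; AUC summaries inherit this.
- Permutation families share one set of label permutations per family,
  which is standard but means p-values within a family are correlated
  through the null draws as well as through the data.
- The hub definition (mean + 1 SD) is threshold-like and sensitive to
  the metric's skew; hub counts should be read comparatively, not as
  absolute anatomy.
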