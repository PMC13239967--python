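# Methods

## The decomposition

The quantity of interest is the marker-positive fraction of keratinocytes,
P^c = Σ_s π_s^c p_s^c, with positivity defined on raw UMIs (count > 0),
never on normalized values. The between-condition difference is split with
the symmetric two-fold (Kitagawa) convention: cross-condition average
weights π̄_s and p̄_s make the split exact and interaction-free, and the
additivity identity `within + composition = ΔP` is enforced to 1e−12 in
the tests. The symmetric convention was chosen over baseline-weighted
(Oaxaca-Blinder-style) variants because it is the unique two-term split
with no leftover interaction term, so the two reported components always
account for the whole difference; baseline-weighted conventions differ
from it by at most the interaction term and are easy to derive from the
per-state table the result carries.

Degenerate tables are handled so the identity never breaks: a state with
cells in only one condition enters with π = 0 in the missing condition and
its rate taken from the observed one; a state observed nowhere contributes
nothing; a condition with zero cells overall is an error, never a NaN.

Two aggregation modes are reported. `pooled` pools cells across donors
within each condition before computing π and p — appropriate when the
target is the cohort-level percentage. `per_donor` decomposes each donor
separately and averages components with equal weights — appropriate when
donors are the unit of inference. Both appear in every run report because
they estimate genuinely different estimands under donor imbalance.

Donor-level inference is a paired Student t-test implemented from the
definition: t = mean(d)/(sd(d)/√n) with the n−1 standard deviation, and
the two-sided p-value through the regularized incomplete beta function
I_{ν/(ν+t²)}(ν/2, 1/2). Degenerate inputs give defined outputs (t = 0,
p = 1 for no signal and no variance; p = 0 flagged `degenerate` for a
nonzero difference with zero variance) rather than NaNs. Agreement with
`scipy.stats.ttest_rel` to 1e−10 is asserted on a thousand random inputs;
scipy is the cross-check, not the implementation.

## The synthetic cohort generator

The generator exists to provide exact ground truth for the estimation
pipeline; it makes no claim to model lymphedema skin. Structure: each of
`n_donors` donors contributes one sample per condition (the paired
design is enforced); each sample draws a state composition from a
condition-specific Dirichlet(α); cells are assigned to states
multinomially; each gene count is negative-binomial with mean depending on
the cell's state and condition, scaled by a per-cell log-normal library
factor.

The NB is parameterized by mean μ and size θ with Var = μ + μ²/θ, so
P(count > 0) = 1 − (θ/(θ+μ))^θ. The designated marker gene (feature index
0, named F2RL1) carries state × condition means chosen by inverting this
zero-probability formula from target positive rates; `expected_decomposition`
computes the analytic truth from Dirichlet means and the closed-form rates
with no sampling. Restriction of the truth to keratinocyte states uses the
Dirichlet aggregation property (a renormalized subvector is Dirichlet with
the subset α), so it is exact. Because the library factor multiplies every
gene mean, the closed-form rates are exact only when the library log-sd is
0; truth-critical presets set it to 0 and the default cohort's 0.25
introduces a small (Jensen) deviation that the stochastic tolerances
absorb.

Mitochondrial and ribosomal content is realized structurally: fixed index
ranges are named MT-*, RPS*/RPL*, a per-cell Beta-distributed fraction of
the expected library is diverted into those blocks (jointly capped at 90%
of the library), and QC then operates on gene-name prefixes exactly as on
real data. All states share the single dispersion θ (default 2.0);
per-state signature gene blocks (disjoint by construction from the
marker/MT/ribosomal blocks) are up-regulated by a single fold factor, and
an optional keratinocyte-signature block (keratin-like names) is
up-regulated in all keratinocyte states to give the annotation step a real
discrimination task — the default cohort includes a 15% immune-like
population for this reason.

Default study conditions: 3 donors × 1500 cells per sample, 400 genes,
background mean 2.0 (a typical cell has ≈1500 UMIs and ≈300 expressed
genes, so the fixed QC thresholds bite realistically), Dirichlet
concentration 100 (sample-to-sample compositional sd of a 30% state
≈ 4.5 pp), θ = 2, signature fold 6. The default truth is placed at the
observed clinical pattern (41.6% → 36.4% positive, −4.62 pp within-state,
−0.62 pp compositional, K3 expanding, K0 contracting, K6/K8 losing the
most positivity) by exact inversion, so end-to-end runs are read against a
familiar reference point.

What the generator does *not* emulate — and what passing tests therefore do
not establish for real data: doublets, ambient RNA, batch effects beyond a
donor location shift in PC space, gene-gene correlation beyond the block
signatures, zero-inflation beyond NB, and continuous differentiation
gradients between states (states are discrete by construction).

## Pipeline and numerical choices

- **QC** (all boundaries inclusive, matching the stated "minimum"/
  "maximum" wording): ≥200 genes, ≥500 UMIs, ≤50% ribosomal, ≤20%
  mitochondrial. Percentages are computed on raw UMIs; a zero-count cell
  gets 0% by convention. Ribosomal prefixes RPS/RPL deliberately exclude
  the mitochondrial-ribosomal MRPS/MRPL families; explicit masks override
  the prefix rule when gene sets are known.
- **Normalization**: counts-per-10k then log1p. The target sum is
  configurable; 10 000 is the field's convention.
- **HVG selection**: per-gene dispersion (var/mean of log-normalized
  values), z-scored within equal-width mean bins, ranked descending with
  ties broken by gene index. 20 bins by default, capped at n_genes/10
  because z-scores in bins of one or two genes carry no information (a
  two-gene bin yields z = ±1 regardless of how extreme the dispersion is).
- **PCA**: genes standardized to unit variance and clipped at 10 before a
  full SVD (configurable off); components ordered by variance with the
  largest-magnitude loading forced positive, making the embedding
  reproducible across cell orderings.
- **Integration**: donor batch-centering in PC space — each donor's
  centroid is translated onto the global centroid, exactly preserving
  within-donor geometry, idempotent, deterministic. This removes location
  shifts only; it is a deliberate, inspectable stand-in where an iterative
  mixture-based integration method would be used on real multi-donor data,
  and the pipeline exposes the embedding so such a method can be swapped
  in.
- **Clustering**: symmetrized kNN graph (k = 15 default) and Leiden on
  RB-configuration modularity at resolution 0.5, fixed seed, 2 iterations.
  Sub-states re-cluster the keratinocyte subset with the same algorithm
  and are labelled K0, K1, … by decreasing size (ties by original cluster
  id).
- **Annotation**: a cell is "up-regulated" when its marker score (mean
  log-normalized expression of the marker set) exceeds the cohort-wide
  median; a cluster is keratinocyte when a strict majority of its cells
  are. Median/majority were chosen because they are parameter-free and
  scale-invariant; the rule's discrimination is validated on cohorts with
  a known non-keratinocyte population.
- **Seeding**: one run seed fans out to fixed per-stage offsets (cohort
  +0, clustering +11, sub-states +12, mod 2³¹), so stages re-run in
  isolation reproduce the full run's stream. Reports are bit-identical
  under a fixed config and seed; wall-clock timestamps appear only in the
  side log.

## Test problem sizes

Simulation-backed tests are sized so their tolerance bands sit at roughly
3σ of the relevant sampling noise, keeping the default suite under a
minute: parameter recovery uses 100 replicates of 10 donors × 2 × 2000
cells with Dirichlet concentration 1000 and no library noise — that
benchmark isolates estimator consistency, so donor compositional noise is
deliberately set small relative to the ±1 pp band (at realistic
concentrations ~100 the donor-sampling variance alone exceeds that band
with 10 donors, which is a statement about cohort sizes, not about the
estimator); clustering recovery uses 3 donors × 500 cells at signature
fold 4; closed-form positivity checks use 50 000-cell samples with 3
Monte-Carlo-SE bands; null-uniformity checks 100 seeds of a 4-donor
cohort with a KS test at α = 0.01.

## Known limitations

- The fraction decomposition carries no uncertainty: bootstrap confidence
  intervals for the components are future work; only the overall fraction
  difference gets a (donor-level) test.
- The truncated-cone tail-volume estimator sums adjacent-product terms
  h·CᵢCⱼ/(4π) — each a geometric-mean-radius cylinder — with the segment
  height h fixed at 10 mm by the 1-cm measurement protocol. Note the sum
  of adjacent products is invariant under reversing the measurement order,
  so base-to-tip and tip-to-base series give identical volumes. Inputs are
  circumferences (a caliper diameter d converts as C = πd).
- Sub-state count is an emergent property of the Leiden resolution, not a
  fixed taxonomy; on data with more or fewer natural states the K-labels
  simply enumerate what the graph supports at resolution 0.5.
- Leiden on *low-dimensional* spatial kNN graphs over-partitions diffuse
  clouds (spatial graphs are intrinsically modular); the pipeline always
  clusters in ≥10-dimensional PC space, where this does not arise at the
  default resolution.
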