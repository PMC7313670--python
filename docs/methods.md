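# Methods

`famevol` models the evolution of multicopy (ampliconic) gene families on
the great-ape Y chromosome along two axes: family **size** (copy number per
genome, estimated per individual by ddPCR-style assays) and family
**expression** (normalized testis RNA-Seq counts).  Both analyses run on a
time-calibrated, ultrametric Y-chromosome species tree with branch lengths
in thousands of years (ky).

## Trees and time

TMRCA between two sequences is estimated from pairwise identity as
`TMRCA = ln(L / matches) / (2 mu)` with `mu` the per-position per-year
Y-chromosome mutation rate.  A clock tree is built from a TMRCA matrix by
average-linkage (UPGMA) agglomeration, in which the height of each merge is
the average TMRCA of the joined groups and becomes the node age directly;
scipy's deterministic linkage implementation provides the merge order, and
exact ultrametric matrices are inverted exactly.  Equal-TMRCA ties resolve
arbitrarily through zero-length internal edges, which the tree class permits
(tip branches must be strictly positive).  The two calibrated trees the
analyses actually use are bundled verbatim as fixtures (`paper_fixture
("tree6")`, `paper_fixture("tree5")`); the 5-taxon tree drops the Sumatran
orangutan, for which only one expression sample exists.  Branch lengths are
kept in ky as calibrated and divided by 1000 inside every rate computation,
since both evolutionary rates below are quoted per million years (My).

## Copy-number evolution: linear birth-death model

Each gene copy independently duplicates or is lost at rate `lambda` (events
per gene per My); zero copies is absorbing.  Over a branch of `t` My the
transition probability from `s >= 1` to `c` copies is

    P(c | s, t) = sum_{j=0}^{min(s,c)} C(s,j) C(s+c-j-1, s-1)
                  a^(s+c-2j) (1-2a)^j,        a = lambda t / (1 + lambda t).

Rows of the transition matrix are computed as s-fold convolutions of the
single-copy offspring distribution `p(0)=a, p(k)=(1-a)^2 a^(k-1)` — an
identical but sign-free and O(n_max^2) evaluation; the scalar closed form
and the convolution agree to machine precision and both match a truncated
generator matrix exponential to 1e-8 (a standing test).

* **Likelihood.** Felsenstein pruning over states `0..n_max` with per-node
  rescaling; the root is marginalized against a uniform prior on
  `{1, .., root_max}` (the family existed at the root, so 0 is excluded).
  Defaults: `n_max = max(100, 3 x largest observed count)` (tail mass below
  ~1e-10 at the study's rates), `root_max = 2 x largest observed count`.
* **Rate estimation.** One `lambda` shared across families, maximized by
  bounded scalar search on `log10 lambda` in `[-6, 2]` (tolerance 1e-8).
  All-constant data drives the estimate to the lower bound and emits a
  warning rather than failing.  On data simulated at 0.05/My under the
  study design (9 families, 6 species) the mean estimate over 200 replicates
  is within 1% of truth.
* **Ancestral states.** Joint ML assignment by max-product dynamic
  programming; ties break toward the smaller count (the argmax scan runs in
  ascending count order).
* **Branch-shift test.** Exact two-sided tail: the probability of any
  parent-to-child transition whose probability is less than or equal to that
  of the observed one.  The most likely child returns p = 1 by construction.
  Medians are rounded half up to integers before analysis.
* **Family-wide conservation test.** Monte Carlo: `n_sim` (default 1000)
  families are simulated from the fitted model (root drawn from the prior,
  then per-branch transition sampling) and the reported p is
  `(count + 1) / (n_sim + 1)` of simulated families with likelihood at or
  below the observed one — so the smallest reportable p at the default is
  ~0.001.  Under the generating model these p-values are uniform
  (KS-checked at 500 simulated families).
* **Subsampling robustness.** Per replicate, k individuals per species
  (default 5, 100 replicates) are attached as a star below their species
  node at epsilon = 1 ky, the rate is refit on the expanded tree, and each
  species-level branch shift is re-tested at the Bonferroni cutoff
  0.05/10; support is the count of significant replicates.

Report-time multiple-testing cutoffs mirror the study design: 0.05/9 for the
nine family-wide tests, 0.05/10 for the ten branches, 0.05/5 and 0.05/8 for
the sister-species permutation batteries.

## Expression conservation: stationary OU with a within-species ratio

For one family, species-mean log-expression follows a stationary
Ornstein-Uhlenbeck process with optimum `theta`, selection strength `alpha`
(per My) and drift variance `sigma^2` (per My): stationary variance
`v = sigma^2 / (2 alpha)`, between-species covariance
`v exp(-2 alpha T_ik)` with `T_ik` the divergence time in My.  Individual
samples add independent within-species noise of variance `beta v`, making
`beta` the ratio of within-species to phylogenetically corrected
between-species expression variance — a phylogenetic ANOVA F-ratio.
Expression enters on natural log after adding a pseudocount of 1
(multiplicative noise; zero counts remain finite).

The conservation test contrasts H0: all families share one `beta` against
H1: the focal family has its own `beta_i` (others still share); twice the
log-likelihood ratio is referred to chi-square(1).  `theta` (GLS mean) and
the scale `v` are profiled analytically, so numeric optimization runs over
`(alpha, beta)` only — mathematically the full 4-parameter ML, but each
profile evaluation is O(n) after a per-alpha eigendecomposition of the
correlation matrix.  Optimization bounds: `alpha` in [1e-4, 1e2]/My, `beta`
in [1e-4, 1e3], maximized over a deterministic log-spaced grid with bounded
local refinement (no stochastic restarts are needed; the 1-D profiles are
well behaved).  With two samples per species `alpha` and `sigma^2` are only
weakly identified individually — the likelihood constrains `v` and the
correlation decay; estimates of the pair should be read as a profile, not
as separate quantities.

Measured operating characteristics at the study design (5 families, 5
species, 12 samples): per-test type-I error 0.040 on 1000 nulls at nominal
0.05; shared-`beta` recovery within ~11% (median, 500 replicates).  The
single-family `beta` estimator carries the classic upward ratio bias of ML
with only five species (the between-species variance has 4 df in the
denominator), of order +50% in the median regardless of per-species
sampling; pooling families in the shared fit is what makes `beta`
well estimated.

**Calibration of the conservation call.**  A simulated dataset is scored
correctly conserved when no family is called divergent.  Following the
study's uniform Bonferroni convention for family batteries, the per-family
cutoff defaults to the family-wise 0.05/5 = 0.01 (`bonferroni=False`
restores a raw per-family 0.05).  Under the shared-beta null with
`theta = 2`, `v = 0.3` (`alpha = 0.5`/My, `sigma^2 = 0.3`/My) and
`beta = 0.5` — chosen once as a realistic mid-range operating point: weak
phylogenetic correlation at great-ape divergence times, log-scale
expression spread of ~0.55, within-species noise half the between-species
variance — 95-100 of 100 null datasets are called conserved across seeds.
At a raw per-family 0.05 the expected all-conserved rate of a calibrated
5-test battery cannot exceed ~0.95^5 ≈ 0.77, so the family-wise convention
is also what makes the calibration target coherent.

## Resampling and correlation statistics

* **Sister-species permutation test.** Statistic `|mean(a) - mean(b)|`;
  species labels permuted (default 1e6 times, chunked and vectorized);
  p = count / n_perm with no +1 correction, a zero count printing as
  "< 1/n_perm".  Sidedness is absolute (two-sided) by convention.
* **Spearman correlation.** Average ranks for ties.  For n <= 9 the
  two-sided p is exact, by enumeration of all n! rank orders — required to
  reproduce p = 0.0833 at n = 5, rho = 0.9, where the asymptotic
  approximation does not; larger n uses the asymptotic p.
* **Size-variance relation.** ln(median) vs ln(variance) per species across
  families; zero-median and zero-variance families are excluded (log
  undefined).
* **Copy number vs expression.** ln median copy number vs ln median
  expression, per species (across families) or per family (across species);
  zero-copy or unexpressed entries excluded; groups with fewer than three
  usable points are flagged, not fatal.
* **PCA.** Covariance PCA (column-centered, unscaled) of the individuals x
  families matrix by default; a correlation-PCA variant sits behind
  `scale=True` since the original scaling convention is not recorded.

## Synthetic data

`generate_cn_dataset` simulates species-level counts with the birth-death
kernel down the tree (root uniform on 1..40 by default, rate 0.05/My) and
adds individual-level noise: rounded Gaussian with variance
`dispersion x count` (default dispersion 0.5), floored at zero and using
the study's per-species sample sizes (7 bonobos, 9 chimpanzees, 10 humans,
14 gorillas, 7 Bornean and 5 Sumatran orangutans).  The noise model is a
deliberate stand-in for ddPCR measurement error — no error model is
published — chosen to reproduce the observed coupling between family size
and variance; it does not emulate droplet counting statistics, replicate
structure, or primer efficiency differences, so passing tests demonstrate
correct recovery under this idealized noise, not robustness to real assay
artifacts.  `generate_expression_dataset` draws from the exact OU model
covariance with the study's 2-3 samples per species (12 total).  All
generators are bit-reproducible under a fixed seed.

Fixtures embed only values printed in the study text: the two Newick trees,
the gene presence/absence pattern, and a per-species median table whose
unprinted cells are left missing rather than imputed.  Full per-individual
tables are user-supplied inputs, never shipped.

## Known limitations

* The branch-shift test is the exact two-sided likelihood tail of a single
  parent-to-child transition.  Published branch p-values computed by other
  birth-death implementations can condition on more of the tree and are not
  generally reproducible to better than order of magnitude by any
  single-transition tail statistic; this package's values are
  self-consistent and oracle-verified, and agreement with externally
  printed values should be judged on that scale.
* One global `lambda` (no per-branch rates), no gene-conversion or sequence
  evolution of copies, and no measurement-error model beyond median
  rounding.
* The OU machinery assumes an ultrametric tree and a stationary process
  from the root; branch-specific expression shifts are out of scope.
* Problem sizes in the test suite (e.g. 200 rate-recovery replicates, 200
  five-family null datasets for type-I, 100 calibration datasets, Monte
  Carlo n_sim = 400-1000) are the package's chosen operating points for
  routine verification; all scale linearly if larger batteries are wanted.
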