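# Methods

This note documents the models, estimators and numerical choices behind
`phyloregime`, and what the synthetic study design does and does not
emulate.

## The study design the package targets

The motivating system is the Elegans group of *Caenorhabditis*
nematodes: ~11 chromosome-scale genomes in which self-fertility
(androdioecy) evolved three times independently from outcrossing
(dioecy), with conspicuous differences in genome size, transposable-element
(TE) content and gene-family (orthogroup) sizes between the two
reproductive modes. Analyses take four inputs: a rooted phylogeny with
branch lengths, a tip trait table (genome size in Mb, repeat classes in %
of genome, GC%), a tip reproductive-mode table, and a family × taxon
count matrix. The synthetic generator (`phyloregime.simulate`) replaces
the genome-derived inputs so every stage is testable end to end.

## Tree model and surgeries (`tree`)

Trees are rooted, may contain polytomies, and permit zero-length branches
everywhere (all likelihood code evaluates `exp(-a*0) = 1` without special
cases). Newick parsing goes through dendropy; emission is a local writer
with 12 significant digits so round trips are lossless. Three surgeries
mirror common pre-processing:

* `graft_tips_as_polytomy` — attach conspecific strains to a species tip;
  the original tip stays at branch length 0 by default so all
  pre-existing patristic distances (and hence likelihoods) are unchanged,
  and the grafted strains default to length 0 as well (no strain branch
  lengths are assumed; both lengths are configurable).
* `resolve_polytomies` — deterministic left-to-right resolution with
  zero-length inserted branches; trait covariance matrices are unchanged.
* `make_ultrametric(extend)` — extend terminal branches to the maximum
  root-to-tip depth. Deterministic, order-independent, never shortens a
  branch and touches only terminal branches. (Other ultrametricization
  methods — rate smoothing, penalized likelihood — deliberately out of
  scope.)

## Regime inference (`mk`)

Reproductive mode is a binary character (0 = outcrosser, 1 = selfer)
evolving under a continuous-time Markov (Mk) model with closed-form
transition probabilities `P00(t) = pi0 + pi1 exp(-(q01+q10) t)`. Three
constraints are compared by AICc: ER (one rate), SYM (symmetric) and ARD
(two rates). For two states ER and SYM impose the same constraint, so the
fitted likelihoods and AICc agree identically — asserted as an exact
property in the tests. Likelihoods use Felsenstein pruning (verified
against exhaustive enumeration on small trees); marginal ancestral states
use the standard upward/downward re-rooting pass. Defaults:

* root prior flat (0.5, 0.5); a stationary prior is available;
* AICc sample size n = number of tips;
* rate bounds [1e-8, 1e3] per unit branch length, optimized in log space
  from three deterministic start points (0.1, 1, 10 per tree height);
* branch regime = argmax marginal at the branch's *child* node (a
  branch's regime is what the lineage is by the time it ends); exact ties
  inherit the parent state (root ties fall to outcrosser) and are
  flagged; observed tip branches always match the observed state.

## Ancestral genome size (`ancestral`)

Genome size evolves by Brownian motion; tip covariance is
`sigma^2 x (shared root-to-MRCA depth)` on the tree as given (branch
lengths may be substitutions/site — no ultrametric assumption). The rate
is estimated by REML, which for BM has the closed form
`sigma2 = r' C^{-1} r / (n-1)` (the mean squared standardized
independent contrast). Node states are universal-kriging (GLS) estimates
with a flat prior on the root value; node variance includes the
root-mean-uncertainty term, so a two-tip tree reproduces the textbook
`var(root) = sigma^2 / sum(1/t_i)`. Intervals are mean ± 1.96·sd,
conditioning on the REML rate. At 11 tips the plug-in variance costs
real coverage: the nominal 95% interval covers simulated truth at ~92%
(the t-with-10-df effect); the multiplier is kept at 1.96 rather than
inflated. Tips at zero patristic distance (grafted strains) get a 1e-12
variance floor, with a warning.

## Adaptation models (`adaptation`)

Trait adaptation follows the Hansen framework: within a regime the trait
obeys the Ornstein–Uhlenbeck dynamics
`dy = -alpha (y - theta) dt + sigma dW`, with the primary optimum theta
attached to the branch regime. Reported derived quantities are the
phylogenetic half-life `t1/2 = ln 2 / alpha` (also as % of tree height)
and the stationary variance `v = sigma^2 / (2 alpha)`. Three nested
hypotheses are compared by AICc (n = tips): BM (no pull; k = 2), OU1 (one
optimum; k = 3), OU2 (selfer and outcrosser optima; k = 4). The root
value is tied to the root regime's optimum by default (no extra
parameter); `y0_rule='estimate'` frees it and increments k.

Tip moments on a painted tree (valid for non-ultrametric trees): the
expectation accumulates `exp(-alpha ...)` weights over the
constant-regime segments of each root-to-tip path (weights over
{y0, theta_s} sum to 1); the covariance is
`v e^{-a(T_i-d)} e^{-a(T_j-d)} (1 - e^{-2ad})` with `d` the MRCA depth.

Fitting: alpha is profiled on a deterministic 50-point log grid of
half-lives spanning [1e-4, 10] tree heights with golden-section
refinement (OU surfaces are flat in alpha; a deterministic grid keeps
runs reproducible); optima by GLS and v by the profiled ML residual
variance inside the likelihood. Reported v and the optima standard
errors use the df-corrected GLS residual variance `RSS/(n-p)` (the ML
profile divides by n and is noticeably biased low at n = 11). r² is
`1 - RSS/TSS` in the GLS metric. Fits whose half-life lands on the grid
boundary are flagged. Traits are analyzed on their natural scale (Mb, %
of genome) with no transform. Model ranking applies the conventional
2-AICc indistinguishability rule; AICc ties sort the simpler model first.

Small-sample caveat: at 11 tips the ML surface genuinely prefers a weak
pull (long half-life) in roughly 15% of datasets simulated under a
strong-pull two-optimum process, and the conditional GLS standard errors
do not reflect alpha uncertainty; joint ±2 SE recovery of both optima
runs near 80% rather than the ~90% a naive normal calculation suggests.
The validation experiments report this honestly rather than widening
intervals.

## Gene-family turnover (`turnover`)

Each gene duplicates and dies independently at the same rate lambda (the
critical linear birth–death process); the count transition along a
branch depends only on `a = lambda t / (1 + lambda t)`:

    P(c | s, t) = sum_j C(s,j) C(s+c-j-1, s-1) a^{s+c-2j} (1-2a)^j,

zero absorbing. Dense transition matrices are built by s-fold convolution
of the per-gene offspring distribution `p(0)=a, p(k>=1)=(1-a)^2 a^{k-1}`
(algebraically identical to the sum; verified against both the closed
form and the matrix exponential of the generator). Family likelihoods
prune over count states {0..N_max} with `N_max = max(2 x max count, 30)`
and a uniform root prior on {1..N_max} (a family must have at least one
ancestral representative). Tip observation error is a symmetric ±1
miscount with probability eps (a deliberate simplification of richer
error matrices; zero counts are never perturbed — an absent family
yields no gene calls to miscount), profiled over the grid
{0, 0.01, ..., 0.2} when requested. One or two rate classes are
supported; the default two-class partition is selfer vs outcrosser
branches from the painting, and models are compared by AICc with
n = families. Only high-confidence families (present in at least half
the taxa) enter the fit by default.

**Significance.** Per-family p-values are conditional Monte-Carlo tests:
families are stratified by the bucket of their marginal-ML root count
(singletons to 10, then geometrically widening), and each bucket's
reference ensemble is simulated under the fitted model and passed
through the *same* root-estimation operator, keeping draws that land in
the bucket. Because the conditioning statistic is identical on both
sides, `p = (1 + #{ref lnL <= obs lnL}) / (n_ref + 1)` is calibrated
(null KS distance from uniform ≈ 0.02 at n = 1000); conditioning on
family size is what gives power against families whose *pattern* is
aberrant rather than merely large or small. q-values use Storey's
procedure (lambda grid 0.05..0.95, cubic smoother, automatic BH fallback
when pi0 is unstable); the downstream significance threshold is
q < 0.01.

**Ancestral counts and classification.** Joint ML ancestral counts come
from a max-product dynamic program (ties take the smallest count and are
flagged); per-branch deltas aggregate into per-branch
expansion/contraction tables. A *lineage* is the path from the node
where the tip's current regime began (the start of the earliest branch
in its contiguous same-state chain; chains reaching the root start at
the root) to the tip, and its net change is tip count minus origin-node
count. Significant families are classified by Boolean rules over those
nets: stable-or-down in every selfing lineage and stable-or-up in every
outcrossing lineage is *DecreasingInSelfers*, with the three
permutations defining the other directed categories; all-zero nets are
*Stable*; mixed signs within a regime are *Unclassified*; when both
regimes change strictly in opposite directions the selfer-relative label
wins (the published rule text assigns one label to two patterns — an
apparent typo — so the four categories here are kept distinct).
Enrichment uses the two-sided Fisher exact test (scipy), whose p-value
definition (summing hypergeometric outcomes no more probable than
observed) and sample odds ratio match the package contract.

## Synthetic data (`simulate`)

All simulators are exact (no Euler discretization) and deterministic
given a seed:

* regime histories: exponential waiting times of a two-state chain along
  branches;
* traits: BM `N(parent, sigma^2 t)`; OU per constant-regime branch with
  the exact transition density;
* gene families: per-gene Gillespie birth–death (birth = death =
  lambda·n), a shifted-geometric(mean 5) root prior by default, and the
  ±1 miscount model at tips; extinct-everywhere families are retained
  and flagged. Simulated truth at internal nodes can be recorded for
  calibration experiments.

The study fixture is an 11-tip, height-1.0, ultrametric binary tree with
the Elegans-group shape: selfers *C. elegans*, *C. briggsae* and two
*C. tropicalis* strains arising from three independent origins among
seven outcrossing relatives (three *C. remanei* strains, *C. latens*,
*C. nigoni*, *C. inopinata*, *C. sinica*). Fixture parameters, chosen
once: TE-like percent trait under OU2 with theta_selfer = 2.97,
theta_outcrosser = 6.19, t1/2 = 0.05 of tree height and v = 1.35 (the
magnitudes estimated for the Mutator DNA transposon, the one TE class
with regime-specific optima in this system); genome-size-like trait
under BM from 150 Mb with sigma^2 = 2500 Mb² per unit height, giving a
roughly 60–300 Mb spread; 1000 families at lambda = 0.43 per gene per
unit length (the magnitude reported for Elegans-group orthogroups).
Percent traits are simulated untruncated — the inference model is
Gaussian and truncation would bias estimator tests — with a display-only
truncate-at-zero view.

What the generator does *not* emulate: assembly and annotation error
structure (beyond the ±1 miscount), contamination, correlated evolution
among TE classes, among-family rate variation, and non-equilibrium root
states. Passing recovery tests therefore demonstrates estimator
correctness under the assumed models, not robustness to annotation
artifacts.

Planted parallel-loss families (used to calibrate the classifier) start
from 10 genes (parallel-loss families in this system — serpentine
receptors, C-type lectins — are large), evolve at the background rate
with per-gene survival 0.2 applied on each selfing branch, and are
rejection-sampled until the true trajectory realizes the parallel-loss
pattern; recovery at q < 0.01 is 100% at the default settings.

## Pipeline and reproducibility

`phyloregime run` chains simulate/load → regimes → ancestral → adapt →
turnover → classify and writes per-stage tables, `report.md` and
`manifest.json` (seed, config hash, version). All randomness derives
from the single config seed; identical (config, seed) gives
byte-identical tables.

Problem sizes in the validation experiments: 100 replicates per recovery
or calibration experiment on the 11-tip fixture, 200 trees for the
likelihood oracles, 2000 node-replicates for interval coverage, 1000
null families (M = 1000 references per bucket) for p-value calibration,
and 1000 + 50 families for planted-loss recovery.

## Known limitations

* Two regimes only; no multi-predictor OU regressions, no measurement
  error in traits, no stochastic character mapping.
* The OU optima SEs condition on the fitted alpha; see the small-sample
  caveat above.
* Birth–death inference assumes equal birth and death rates per gene and
  a truncated state space; families whose counts approach N_max/2 are
  re-truncated conservatively rather than adaptively.
* Storey's pi0 smoother uses a cubic polynomial rather than a natural
  spline; with the BH fallback this only ever makes q-values more
  conservative.
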