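# Methods

This note documents the models implemented in `lignevo`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Gene-family birth–death model (`lignevo.bdp`)

Each gene family evolves independently along the dated species tree as a
linear birth–death process on its copy number: every gene copy duplicates
at rate λ and is lost at rate λ (a single global rate, birth = death, in
events · gene⁻¹ · My⁻¹). Zero copies is absorbing. The transition
probability over a branch of t My has the classical closed form in
α = λt/(1+λt) given in the README; `transition_matrix` evaluates it for
all (s, c) pairs at once by caching the α-independent combinatorial tensor
per state cap, so likelihood evaluations cost gathers plus a j-sum.

Choices:

- **State cap.** n_max = min(2·max observed count, max + 50), floor 10,
  per family. The truncation loss of the kernel is monotone in the parent
  count and negligible (< 1e-3) for counts below a fifth of the cap; the
  cap keeps the largest observed state in the lower half of the space.
- **Root prior.** Uniform over {1..n_max}: the family is conditioned on
  presence at the root. Exposed on `BDPModel`.
- **λ estimation.** Bounded scalar ML search on [1e-6, 10] (Brent),
  summing the pruning log-likelihood over all families, grouped by state
  cap so each group is evaluated vectorized.
- **Ancestral counts.** Joint most-probable assignment by max-product
  dynamic programming with backtracking; ties break toward the smaller
  count (deterministic).
- **Family-wide p.** Monte-Carlo: n_sim families are forward-simulated
  from the fitted model and p = (1 + #{sim loglik ≤ observed})/(n_sim+1).
  The per-family operation draws its own null; the whole-matrix driver
  (`analyze_families`) shares one null sample per state-cap group across
  families, which is statistically equivalent under the global model and
  two orders of magnitude cheaper. Default n_sim = 1000, α = 0.01.
- **Per-branch p.** For the Viterbi states (s*, c*) of a branch, p is the
  exact "as-or-less-likely" tail: the summed probability of child states
  whose transition probability from s* does not exceed that of c*.
  A modal transition therefore has p = 1 by construction.

## Diversity and group tests (`lignevo.divstats`)

The repertoire diversity is a Brillouin-type index in bits per gene,
D = (1/N)[log₂N! − Σ log₂nᵢ!]. Group-average counts are non-integer, so
factorials are evaluated through log Γ(n+1); for integers this equals the
factorial form exactly, zero-count families drop out, and D = 0 iff one
family holds all genes. N is always computed as Σnᵢ.

Exact binomial and Fisher tests wrap scipy's implementations (tail sums
of the binomial pmf and the fixed-margins hypergeometric); Bonferroni is
min(1, m·p). How a copy-number comparison is mapped onto binomial trials
and successes is left to the caller — the operations are primitives.

The phylogenetic ANOVA computes the classical one-way F statistic and
obtains its null distribution by simulating the trait under Brownian
motion on the tree, with the rate set to its ML (GLS) estimate from the
data; p uses the add-one rule. On a star tree this reduces to an ordinary
simulation ANOVA (verified against a permutation oracle).

## Phylogenetic ordination (`lignevo.ordination`)

pPCA follows the evolutionary-covariance construction: C is the
Brownian-motion species covariance (shared root-to-MRCA path lengths), the
phylogenetic mean is the GLS mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X, the evolutionary
covariance R = (X−1a)ᵀC⁻¹(X−1a)/(n−1) is eigendecomposed, and scores are
(X−1a)V. Covariance mode is the default (correlation mode is a switch);
counts enter untransformed by default. A 1e-8 ridge handles a singular C.
Eigenvector signs are fixed deterministically (largest-magnitude loading
positive). When C = I (star tree) all of this reduces to ordinary PCA,
which the tests assert numerically.

Ancestral scores are the ML Brownian-motion estimates
ŷ(v) = μ̂ + C_vT C_TT⁻¹ (y − μ̂), equal to the re-rooted GLS mean at each
node (asserted against a re-rooting oracle); the root estimate is the
phylogenetic mean itself.

PERMANOVA partitions squared Euclidean distances between the retained PC
scores (pseudo-F with k−1 and n−k degrees of freedom) and permutes labels
completely, seeded, with the add-one p; scikit-bio's PERMANOVA serves as
an independent oracle in the tests, never as the implementation. Pairwise
comparisons run per group pair with Benjamini–Hochberg adjustment and a
deterministic pair order. All-identical points are reported as a
degenerate result with an explicit flag rather than an arbitrary F.

## Weighted-kNN lifestyle classifier (`lignevo.wknn`)

The classifier reproduces the kknn-style algorithm: features are z-scored
with parameters learned from the training fold only (switchable);
distances are Minkowski with exponent d; the (k+1)-th neighbor's distance
normalizes the k nearest (u = d_i/d_(k+1)); a kernel maps u to a weight —
rectangular ½·1(u≤1), triangular (1−u), epanechnikov ¾(1−u²), gaussian
exp(−u²/2), rank (k+1−rank), and Samworth-optimal weights on ranks
(clipped at zero). The class with the largest summed weight wins;
deterministic alphabetical tie-break; if every weight vanishes (possible
for compact kernels when all u = 1) the plain nearest neighbor decides.
When the k-th and (k+1)-th distances tie, all points at that distance join
with u = 1. Tuning evaluates k = 1..25 × 6 kernels × d ∈ {1, 2} — 300
models — by leave-one-out cross-validation and keeps the best (ties:
smaller k, kernel order as listed, smaller d). The fitted model applied
to reconstructed ancestral count vectors yields one lifestyle per internal
node plus the full class-weight table for audit.

## POD toolkit (`lignevo.pod`)

Typing reads eight catalytic positions and the C-terminal tail length from
a site map (1-based alignment columns). Decision order: (1) distal
His/His → NPOD; any other non-His/Arg pair → unclassified; (2) Mn-triad
lookup (EED canonical, ESD, DGD, DED, else none); (3) with the catalytic
Trp: canonical → VP, a partial triad with exactly two acidic residues →
VP-a, a complete three-acidic variant triad (DED) → VP, none → LiP;
(4) without Trp: canonical → MnP-l/MnP-s by tail length (default
threshold 16 residues past the tail anchor, config-exposed), variant
triads → the matching MnP subfamily, none → GP. A surface Tyr without the
His/His pair is an annotation, not a type. The function is total and
deterministic; non-decisive residues never change the call.

Ancestral catalytic residues come from marginal posteriors by Felsenstein
pruning (down-pass/up-pass) under WAG (embedded published
exchangeabilities and frequencies, rate matrix normalized to one expected
substitution per site) or a uniform 20-state model; stationary root prior;
a single rate class (no Γ heterogeneity — a documented divergence from
what richer ML packages offer); gaps and X are missing data (unit partial
likelihoods). Ancestors are typed from modal residues; when any decisive
column's modal posterior falls below 0.7 the runner-up type (second-best
residue at the weakest column) is reported alongside — the 0.7 threshold
is a package decision. Ancestors have no tail, so a tail policy supplies
one: a fixed integer or the median over descendant tips (default). Type
origins are the nodes whose parent bears a different type, all reported
(convergent appearances included) with node ages from the dated tree.

## Synthetic data (`lignevo.synth`)

The generators emulate the statistical structure the analyses assume, not
real genomes:

- **Trees.** Yule, rescaled to an exact root age (default 52 tips,
  192 My — the scale of a comparative Agaricomycetes data set).
- **Lifestyles.** Symmetric 6-state Mk jump process (uniform root,
  Poisson(q·t) jumps per branch). Default q = 0.006/My.
- **Counts.** Exact continuous-time Gillespie birth–death per family and
  branch; the lifestyle in force at the child node scales the birth rate
  by a per-family multiplier g (death stays at baseline) — this is how
  lifestyle signal enters, keeping ancestral counts and lifestyles jointly
  coherent ground truth. A per-family rate multiplier models fast
  families. Copy numbers are capped at 150 (far above real repertoire
  sizes) to guard supercritical branches. `require_presence` redraws a
  family absent from more than a set fraction of species, mirroring the
  fact that empirical matrices only contain observed families.
- **Presets.** `agaricales_preset`: 52 tips, 192 My, 62 focal families
  (seven carrying a realistic overlapping lifestyle-bias pattern) + 24
  neutral background families, λ = 0.002/My. `strong_signal_preset`: one
  marker family per lifestyle (gain ×5 at home, ×0.15 elsewhere) on an
  8× clock with a 150-My pre-root burn-in under the root lifestyle, so
  every node's repertoire reflects the lifestyle in force above it —
  calibrated once so the classifier benchmark has strong signal, then
  frozen. `fast_family_preset`: 7 of 62 families at 10× rate, presence
  ≥ 50%.
- **POD alignments.** Catalytic columns set deterministically from
  per-type residue templates; all other columns evolved under the ASR
  substitution model; tail lengths encoded as residues-then-gaps after
  the tail anchor so profiles round-trip exactly.

What passing these benchmarks shows: the estimators recover the parameters
of their own generating model at realistic scale, the detectors are
calibrated (uniform null p-values, nominal type-I error), and every rule
path of the POD classifier round-trips. What they do not show: robustness
to model misspecification in real data — asymmetric gain/loss, per-family
rates, annotation error in count matrices, alignment error in POD columns,
or lifestyle labels that are themselves uncertain.

## Problem sizes and numerics

The default test-suite and acceptance problem sizes — 52 tips, 62 + 24
families, n_sim = 1000 for family-wide p, 999 permutations, 500 replicates
for type-I-error checks, 10⁵ Gillespie draws for the kernel check — are
the package's chosen desk scale; they complete in minutes on one core.
Likelihoods are rescaled per node to avoid underflow; transition matrices
are clipped to [0, 1] after the signed j-sum; optimizer tolerance is
relative 1e-6 on λ; PERMANOVA and Mk/Gillespie streams derive from a
single integer seed, and every stochastic API requires one.
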