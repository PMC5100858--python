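# Methods

This note records the model as implemented, the numerical and design
choices that were genuinely open, and what the bundled simulator does and
does not emulate.

## Coefficients

**Coancestry and inbreeding.** Malécot coancestry *f* is computed by the
tabular method in topological order: for a new individual X with parents
P1, P2, f(X, Y) = ½[f(P1, Y) + f(P2, Y)] for every earlier Y and
f(X, X) = ½[1 + f(P1, P2)]; founder diagonal ½. F(X) = f(sire, dam).
Unknown parents are treated as anonymous, unrelated, noninbred,
*unpurged* founders (the base-population convention of the IP model);
they enter every recursion as a zero row/column.

**Purged coancestry.** The overlapping-generation recursion is

    γ(X, Y) = ½[γ(P1, Y) + γ(P2, Y)](1 − d·F_X),
    γ(X, X) = ½(1 + g_X)(1 − 2d·F_X),   g_X = γ(P1, P2),

with X the *younger* member of each pair. The derivation defines
"younger" by age; with overlapping generations calendar age is usually
unavailable, so the implementation uses topological rank (graph depth,
ties broken by input order) — each individual is expanded against all
individuals processed before it. This is the one genuinely open choice
in the recursion: at knots where neither member is an ancestor of the
other the expansion order is not dictated by the theory, and topological
rank is this package's rule. An explicit age column can replace the
depth ordering at the pedigree level by pre-sorting rows.

The computation is full-matrix O(n²) per d value (pedigrees of managed
populations are small); a d-vectorized variant evaluates a grid of d
values in chunks. Tests verify the tabular computation against an
independent memoized recursive-descent evaluation of the same equations.

**Discrete-generation variant.** For layered pedigrees the grandparental
form γ(A,B) = ¼[γ(C,E) + γ(D,E) + γ(C,H) + γ(D,H)]·[1 − d(F_A + F_B)]
is also provided. The overlapping form accumulates (1 − dF_A)(1 − dF_B)
instead of the joint factor and therefore overrates γ by the cross term
d²F_A F_B; on simulated N = 10 bottleneck pedigrees (10 generations) the
two agree with Pearson r > 0.999 across d ∈ [0, 0.5] when all
within-generation pairs (self-coancestries included) are pooled. For
strictly off-diagonal pairs under extreme inbreeding (F ≈ 0.5, d = 0.5)
r can dip to ≈ 0.997.

**Reliability.** IP predictions assume purging dominates drift
(d·N_e > 1). The per-interval inbreeding rate ΔF = (F′ − F)/(1 − F) is
computed over bins of one generation interval (topological depth by
default, an age vector optionally) and each interval is flagged reliable
when d > 2ΔF. A negative raw ΔF (possible when new founders enter) is
floored at zero.

## Estimation

**Why the intercept is fixed first.** Estimating ln W₀ (or W₀) jointly
with b₁ and d lets the model overfit — a too-low intercept compensated
by a too-shallow slope and too-small d — destroying predictive value.
Both methods therefore fix the intercept in a first step as the mean
(log-)fitness of individuals with F = F_a = 0 and recorded fitness, or
accept a user-supplied value. The reference set uses the definition
literally: any individual with F = F_a = 0 qualifies, founders or not.

**LR.** Y = ln W − ln W₀ is regressed through the origin on g(d) (plus
covariates as given, unstandardized; optionally the dam's g at the same
candidate d). The d grid is 0(0.01)0.5; golden-section search then
refines within ±0.01 (clipped) to 1e−4 in d, and the refined point is
accepted only if its RSS does not exceed the grid optimum. Records with
missing or nonpositive fitness are dropped with a logged count (zeros
belong to NNLR). Statistics assume normal independent residuals; R² and
adjusted R² use the uncentered total sum of squares, the standard
definition for through-origin regression.

**AICc.** AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), where k counts the
regression coefficients, the error variance, and d when d was estimated
(the parameter count covers the whole two-stage search, not only the
final regression). The d = 0 comparison fit omits the d parameter. This
convention is a package choice; only RSS-based comparisons at equal n
are meaningful across conventions.

**NNLR.** RSS = Σ(W_i − W₀ e^{b₁g_i + …})² is minimized jointly over
(d, b) by an artificial bee colony: half the colony are food sources;
per cycle each source gets one employed-bee move (one random dimension
perturbed toward/away from a random partner), onlooker moves are
allocated by fitness-proportional roulette, and sources that fail to
improve `limit` times (default colony_size × dimensions) are re-seeded
uniformly (scouts). Phases are vectorized over the colony; when several
onlookers select the same source in one cycle the best improving
candidate is applied. Defaults: 250 bees, 500 cycles, d ∈ [0, 0.5],
b₁ ∈ [−20, 0], covariate coefficients ∈ [−20, 20] — wide, configurable
bounds. Runs are deterministic given a seed; `restarts` independent
colonies can be run, keeping the best solution and reporting the RSS
spread as a stability diagnostic. The d = 0 comparison is a separate
profile optimization over b alone. No t/F statistics are produced for
NNLR; RSS and AICc measure fit quality.

Inside the ABC, g(d) is taken from a precomputed grid (step 0.001 in d)
with linear interpolation rather than recomputed exactly per candidate:
g is a smooth piecewise-polynomial function of d, the interpolation
error (≲1e−7) is far below estimation noise, and the grid turns ~10⁵
objective evaluations per fit from O(n²) each into O(n). The public
`rss_objective` recomputes g exactly and is what the tests use to verify
the interpolated optimum.

## Simulator

The generator emulates the validation design for these estimators: a
monoecious diploid base population of N = 1000 evolved to
mutation–selection–drift balance under completely recessive (h = 0)
deleterious mutations with homozygous effect s = 0.3 arising at 0.1 per
gamete per generation at fresh unlinked loci (infinite sites, free
recombination), multiplicative fitness, fitness-proportional parent
sampling; then 50 replicate lines of N = 10 founded from the base and
maintained 50 generations either with selection (purging operates) or
with uniform parent sampling (relaxed). Ground truth: the purging
coefficient d = s(½ − h) = 0.15 and the base load δ = Σ 2dq(1−q) over
segregating loci.

Choices where the design was open:

- **Mating.** Monoecious random pairing with selfing excluded (distinct
  sire and dam per offspring); configurable. With selfing excluded the
  neutral inbreeding trajectory follows F′ = f, f′ = (1+F)/(2N) +
  (1−1/N)f rather than the ideal 1 − (1 − 1/2N)^t; tests use the exact
  recursion as oracle.
- **Burn-in.** Defaults are conservative (cap 10·N generations,
  convergence declared when the windowed mean of δ changes < 5% between
  consecutive windows of N generations). The acceptance script and test
  suite use a 300-generation window with a 600-generation minimum: δ
  plateaus after ≈ 600–800 generations at these parameters (measured
  final δ = 4.32 ± 0.17 SD over replicate burn-ins, ~1900 segregating
  loci), and the shorter window keeps a full replicate study within
  minutes on one CPU.
- **Environmental noise.** ε = 0 by default: recorded fitness is
  genotypic fitness. The model's (1 − ε) factor is a property of the
  analysis, not of the validation data.
- **Mutation in lines.** Mutation continues during line maintenance (it
  is a per-generation process, not a property of the base). New
  mutations add depression that the IP prediction from base parameters
  does not include; per-line fitted parameters absorb most of it.
- **Representation.** Boolean haplotype matrices over segregating loci;
  lost loci are pruned each generation and fixed loci fold into a
  constant fitness factor, so matrices stay at the ~2000-column
  steady state.

A selection-free shortcut generator is also provided: n_i ~
Poisson(F_i δ / 2d), W = W₀(1 − 2d)^{n_i}, whose regression behavior is
known in closed form (slope of log fitness on F equals δ·ln(1−2d)/2d);
it underpins the analytic recovery tests. At d = 0 the Poisson mean is
undefined and the deterministic limit W = W₀e^{−δF} is offered
explicitly.

## What the tests do and do not show

The simulator validates the estimators under the stated mutational model
with a single (s, h) class, no linkage, no environmental noise, discrete
generations, and pedigree founders treated as unrelated even though base
individuals at equilibrium are not. Passing tests show the method
recovers its own model's parameters and discriminates purged from
relaxed regimes under these conditions; they do not certify performance
under distributed mutational effects, overlapping-generation demography,
or real measurement noise. The scaled-down study (10 burn-ins, 12–20
lines per regime instead of 50) widens the sampling error of replicate
means accordingly; comparisons are made in units of empirical standard
errors.

Known limitations: the purged-coancestry recursion is approximate (it
assumes slow inbreeding, q′_E ≈ ½(q′_A + q′_E)) and conservative, so
joint estimates of δ and d are biased downward on strongly drifting
lines (d·N ≈ 1); the estimators themselves reproduce this documented
behavior (replicate means d̂ ≈ 0.09–0.13 against a true 0.15 for purged
N = 10 lines). The LR method additionally estimates the inflated
log-fitness slope b rather than δ, and converting b back to δ requires
a d value; using the fitted d̂ rather than the (unknown) true d inherits
its bias.
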