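# Methods

## Model

`phyloshift` detects convergent shifts in substitution rate on a set of
*foreground* lineages — species sharing a convergently evolved
phenotype — relative to a neutral model of sequence evolution.  The
neutral model is a time-reversible nucleotide rate matrix Q with
stationary frequencies π and a phylogeny with branch lengths in expected
substitutions per site (PHAST `.mod` style).  Q is unit-normalized
(−Σᵢ πᵢ qᵢᵢ = 1) at load so scale factors read as multiples of the
neutral rate; if an input matrix is not unit-rate, Q is rescaled and the
tree's branch lengths are multiplied by the original rate, which leaves
every Q·t product, and therefore the likelihood, exactly unchanged.

Two nested models are fitted to the alignment of a genomic element by
maximum likelihood (Felsenstein pruning):

* **null** — every branch is scaled by a single factor ρ₀;
* **alternative** — background branches are scaled by ρ₁ and foreground
  branches by ρ₁·λ.

The foreground branch set is the terminal branches of the foreground
tips plus every internal branch whose entire descendant tip set is
foreground (the branches of all maximal foreground-only subtrees).  This
handles sister foreground species without double counting.

Evidence for a shift is the likelihood-ratio statistic 2·(logL₁ − logL₀)
referred to a χ²(1) upper tail.  The signed parametric score is
−log₁₀(p) with positive sign for deceleration (λ < 1, increased
constraint) and negative for acceleration (λ > 1, relaxed constraint);
λ̂ = 1 exactly gives score 0.  The χ²(1) reference is nominal — the
statistic sits at a two-sided alternative in λ so there is no boundary
mixture at λ = 1, but residual miscalibration is expected and is
absorbed by the empirical correction below, which is the reason the
parametric p is treated only as an intermediate statistic.

### Optimization

Both fits maximize the pruning log-likelihood in log-parameter space
with bounds ρ ∈ [10⁻⁴, 20] and λ ∈ [10⁻⁴, 100]: the null by bounded
scalar search, the alternative by L-BFGS-B started at (ρ₀, 1).  Because
the starting point's likelihood equals the null optimum, logL₁ ≥ logL₀
holds exactly on every input; a perturbed restart is attempted on
non-convergence, and boundary endpoints are checked for the scalar fit
(a fully conserved element pins ρ₀ at the lower bound).  Tolerance is
10⁻⁶ in log-likelihood.  Transition matrices come from the symmetric
eigendecomposition of π½ Q π⁻½ (exact for reversible Q), computed once
per model and reused for every branch, scale, and optimizer step.
Identical column patterns are collapsed and weighted once per element.
Gaps (`-`) and missing bases (`N`) are carried as distinct states in the
containers but both marginalize to a partial-likelihood vector of ones:
substitution models have no gap state, so an all-missing column
contributes exactly zero log-likelihood.  Tree tips absent from an
alignment are treated as all-missing; alignment rows absent from the
tree are dropped with a warning.

## Permulation (phylogeny-aware trait permutation)

Permuting foreground labels uniformly ignores phylogenetic dependence,
so null traits are generated by *permulation*: a Brownian-motion draw
down the tree (independent Gaussian increments per branch, variance
equal to branch length; σ² = 1 since ranking is scale-invariant) assigns
each tip a value, the k largest-valued tips become the candidate
foreground (k = observed foreground count), and rejection sampling
keeps only candidates whose number of maximal foreground-only clades
equals the observed count.  Clade-count matching is this package's
operationalization of "matching the trait's phylogenetic dependence";
it is exposed as a toggle (`match_clades`).  Ties in simulated values
are broken by tip order (a measure-zero event).  Each draw uses an
independent substream derived from (seed, draw index), so streams are
reproducible and order-independent, and duplicate foreground sets
across draws are allowed (sampling with replacement).

## Empirical calibration

The observed element's signed parametric score is compared with the
scores of N permulated null traits (default N = 1000; α = 0.05).

**Two-sided conditional p.**  With null scores S′ (n = |S′|, mean m),
the one-sided plus-one p-value of the observation's side,
p₁ = (1 + #{s′ at or beyond the observation}) / (n + 1), is divided by
that side's empirical weight w = #{s′ on the observation's side of
m}/n, capped at 1.  For a symmetric null (w = ½) this reduces exactly
to doubling the one-sided p; the plus-one form guarantees p > 0.  The
partition at the empirical mean is the sample analogue of partitioning
at the null expectation.

**Adaptive pruning.**  A hypothesis can only reach significance at
level α if fewer than T = ⌈αN⌉ null scores are as extreme as the
observation.  After each draw the counts of null scores ≥ obs and
≤ obs are tracked; once **both** exceed T the element stops early
("pruned") and p is computed from the draws so far.  Counting both
directions rather than one running tail is deliberate: the side of the
observation relative to the running null mean can flip as draws
accumulate, and the two-count rule makes the early-stopping decision
provably consistent with a full-N run.  Sketch: counts only grow, so if
both exceed T at draw i they exceed T at N, giving
p₁ > (1 + αN)/(N + 1) > α on whichever side the observation ends up,
and p ≥ p₁; conversely a full-N significant element has its relevant
count below α(N+1) − 1 < T, so it is never pruned and both modes see
identical draws.  The suite asserts exact agreement of significance
calls on a 200-element panel.  Clearly null elements stop after roughly
2T draws; strongly shifted elements always run all N, which is where
the p-value resolution is needed.

The calibrated score is scorr = −log₁₀(pcorr) signed by the direction
of the fitted shift (positive for deceleration).  Since pcorr never
reaches 0, scorr is always finite; its resolution is bounded by
log₁₀(N + 1).

**Leave-one-out robustness.**  For each foreground species, the
alternative model is refitted with that species removed.  The signal is
robust only if every reduced fit keeps the direction of the shift
(sign of 1 − λ̂) and a nominal LRT p ≤ 0.05 (configurable).  With one
foreground species robustness is undefined (NA).  A shift carried by a
single lineage typically flips direction when that lineage is removed:
the background rate estimate has absorbed the outlier lineage's extra
substitutions, so the remaining foregrounds look decelerated — either
way the robust flag correctly goes to false.

## Scanning resolutions

* **Elements** (`score`): each BED region is extracted from the FASTA
  or MAF input, fitted, calibrated, and annotated with robustness.
  Failures are never fatal: uncovered regions, regions with fewer than
  `min_species` informative rows, or permulation failures yield NA
  records with a reason code, so output rows always equal input
  regions.
* **Windows** (`track`): the reference coverage is tiled with sliding
  windows, each scored as an element; output is a bedGraph of scorr.
  With `--no-calibration` the uncalibrated signed LRT score is emitted
  instead — appropriate for exploratory tracks where N permulations per
  window would be prohibitive.
* **Motifs** (`motifs`/`enrich`): PWMs (HOCOMOCO-style count matrices;
  pseudocount 0.01, background = model π) are slid over both strands of
  the reference row; hits require a log₂-odds score of at least
  `threshold_frac` (default 0.8) of the motif's maximum achievable
  score, with greedy best-score resolution of overlapping same-motif
  hits (ties: leftmost, then + strand).  Windows containing N are
  skipped.  Each hit's alignment slice is scored as an element.  Global
  enrichment per motif uses the 2×2 table (this motif vs all others) ×
  (significant vs not), one-sided Fisher exact tests, and
  Benjamini–Hochberg correction across motifs at q ≤ 0.05; a hit counts
  as significant when pcorr ≤ 0.05, the robustness flag is set, and the
  shift direction matches the requested one.

Coordinates are 0-based half-open throughout.  MAF extraction keeps
reference-gap (insertion) columns strictly internal to the requested
interval and fills species absent from a block with N.  Element scoring
ignores strand (a reversible model is strand-symmetric only for
complement-symmetric π, so strand is used only by the PWM scanner).

## Synthetic data

The simulator runs the likelihood's generative process forward: root
state from π, each branch's child state through exp(Q·b·ρ[·λ]), with
i.i.d. per-cell missingness.  It therefore emulates exactly the model
the method fits — rate shifts enter as branch-length multiplication on
the same foreground branch set used in inference.  What it does *not*
emulate: indel structure (missingness in real alignments is run-shaped,
not i.i.d.), context-dependent mutation, rate variation across sites,
or the conservation mosaic of real conserved noncoding elements.
Passing tests therefore demonstrate correctness and calibration of the
method under its own model class, not performance on real genomes.

Default study conditions in the test suite and acceptance script:
10-tip (calibration panels) and 20-tip (recovery panels) trees with
branch lengths 0.03–0.1, a transition-biased reversible model
(exchangeabilities 1,3,1,1,3,1; π = 0.3,0.2,0.2,0.3), elements of
150–300 bp, shifts λ ∈ {0.2, 5}, N = 100–200 permulations at α = 0.05.
The `toy24` fixture has 24 species with four foreground tips in three
independent lineages (a sister pair plus two singletons) and one 5×
accelerated 200-bp element among 20 neutral ones.  Panel sizes
(e.g. 500 neutral elements for the type-I check, 200 elements for the
adaptive/exhaustive comparison) were chosen to make binomial bands
informative while keeping the suite runnable on a laptop CPU.

## Numerical choices and edge cases

* Transition probabilities are clipped to [0, 1] and row-renormalized
  after the eigendecomposition reconstruction.
* Site likelihoods are floored at the smallest positive double before
  the log (relevant only for numerically impossible patterns).
* LRT statistics in (−10⁻⁸, 0) are clamped to 0 (roundoff); more
  negative values raise an internal error, since nested initialization
  makes them impossible.
* `pcorr` is never 0 (plus-one estimator); `scorr` at pcorr = 1 is 0
  regardless of λ̂.
* On very small trees the permulation configuration space is tiny
  (e.g. two valid cherries on a 4-tip tree), so a large fraction of
  null traits reproduce the observed foreground exactly and pcorr
  saturates near 1 even for strong parametric signals.  This is the
  correct behavior of a permutation test with few exchangeable
  configurations, not a defect; meaningful calibration needs trees
  with enough tips to support many matching foreground assignments.

## Known limitations

* Single-rate model: no gamma rate categories across sites.
* Binary traits only; continuous-trait permulation is out of scope.
* The LRT's χ²(1) reference is nominal; all downstream inference should
  use the calibrated pcorr/scorr, not the raw LRT p.
* MAF access is stream-scan (no index); genome-scale runs should supply
  sorted MAF blocks.
* Leave-one-out robustness quantifies "erased or flipped" as a sign
  change or p above a configurable cutoff; other notions (effect-size
  shrinkage) are not implemented.
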