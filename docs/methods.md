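# Methods

## Recruitment model

Center *i* (of *N*) recruits as a homogeneous Poisson process with rate
λᵢ ~ Gamma(α, β) (rate parametrization: E λᵢ = α/β, var λᵢ = α/β²,
patients/center/day), started at an activation time uᵢ ~ Uniform(a′, a″)
days. Recruitment is competitive: all centers enroll without quotas and the
trial stops at the *n*-th pooled enrollment. Centers are mapped to the *G*
regions in contiguous blocks of *N/G*; a configuration where *N* is not
divisible by *G* is rejected rather than guessed at.

Rather than generating *n* arrivals per center and discarding most of them,
the simulator uses the conditional-uniform property of the Poisson process:
it inverts the pooled cumulative intensity M(t) = Σᵢ λᵢ·max(t − uᵢ, 0) to
find a horizon expected to contain n + 4√n events, draws per-center Poisson
counts on each center's active window, places the times uniformly within the
window, pools, sorts and keeps the first *n*. If (rarely) fewer than *n*
events materialize, the horizon is extended and only the new time slice is
sampled, so no interval is ever double-counted. This is distributionally
identical to the direct construction; the test suite checks the completion
time against a literal generate-per-center-and-pool reference, the
negative-binomial marginal of per-center counts at a fixed time, and the
beta-binomial marginal of final center sizes under simultaneous activation.
Exact floating-point time ties (probability zero for continuous times) are
broken by ascending center index for reproducibility.

By default λᵢ and uᵢ are redrawn every replicate, which matches the mixed-
Poisson marginals above and the dispersion of recruitment-completion times
that the model implies (with a single shared rate draw the completion-time
IQR would collapse to the Poisson-only width). `redraw_rates_per_replicate =
False` pins a single rate vector for all replicates of an experiment.

## Randomization designs

A design is the conditional probability φ_{m+1} of assigning the next
patient to E. The four MTI procedures are implemented through their
allocation functions F(D) of the current imbalance D = n_E − n_C:

| procedure | φ | forced when |
|---|---|---|
| PBD(b) | ½(1 − D/(2b − (m mod 2b))) | end-of-block slots |
| BSD(b) | ½ if \|D\| < b, else 0/1 | \|D\| = b |
| EUD(b) | ½(1 − D/b) | \|D\| = b |
| BUD(b) | ½(1 − D/(2b − \|D\|)) | \|D\| = b |

The printed F(·) formulas are taken as the operational definitions (they are
Markov in D, which also yields the exact chain oracles); the urn narratives
are not re-derived. All four satisfy F(−D) = 1 − F(D) and keep |D| ≤ b at
every step, asserted as properties. Stratified variants run an independent
chain per center or per region; PBD's block position is the stratum's own
patient count, so final blocks may be left unfilled — that unfilled-block
imbalance is precisely what the comparison is about and is never "completed".
The first patient of every stratum has φ = ½ automatically (D = 0).

Dynamic balancing randomization checks, in order: center (force when
|Dᵢ| = b₁ — equality, as specified), region (force when |D̃_g| ≥ b₂), trial
(force when |D| ≥ b₃), else a fair coin. Because the thresholds are ≥ 1, a
triggering level has nonzero imbalance and the forced direction is
unambiguous; region/trial imbalances may exceed b₂/b₃ transiently since only
the center level is a hard invariant. Conditional probabilities are exact
rationals, so "deterministic" is detected as φ within 1e−12 of 0 or 1.

The sequential chains are vectorized across replicates (state arrays indexed
by replicate × stratum, one fancy-indexed update per patient), which is what
makes 10,000-replicate × 16-design runs take seconds rather than hours, and
is bit-compatible with allocating replicates one at a time.

## Measures

Loss and relative efficiency follow the fixed-effects linear-model forms
L₁ = D(n)²/n, L₂ = Σ_g D̃_g²/ñ_g, L₃ = Σᵢ Dᵢ²/nᵢ, RE = 1 − L/n; empty
strata contribute nothing (and must carry zero imbalance). P_skewed counts,
among centers with nᵢ ≥ 2, those with |Dᵢ|/nᵢ strictly above 1/3, averaged
over replicates; a replicate with no eligible center (impossible under the
study scenarios) is excluded with a warning. Imbalance survival curves are
reported at trial (|D(n)|), region (max_g |D̃_g(n)|) and center
(maxᵢ |Dᵢ(n)|) level.

PCG_c scores each patient against the pre-allocation imbalance *of that
patient's own center* (guess the underrepresented arm, random guess on a
tie); the realized 1/0.5/0 score averaged over patients and replicates is an
unbiased estimate of the expectation. PCG_d models an investigator who
guesses only when the next assignment in their center is certain: for
center-stratified procedures that is exactly when φ ∈ {0, 1}; for DBR only
the center-level forcings (|Dᵢ| = b₁) are recognizable from center-local
information, so region- and trial-triggered forcings score 0.5 — counting
all φ ∈ {0, 1} instead would conflate PCG_d with 0.5 + PD/2 (≈ 0.78 for
DBR(2,2,2)) and contradict the reference value 0.59, which the local-forcing
reading reproduces. For unstratified, region-stratified and CRD designs
PCG_d ≡ 0.5 by convention. PD is the fraction of φ values in {0, 1},
without regard to center, for every family.

## Experiment engine

A master seed spawns one substream for recruitment and one per design
(`numpy` `SeedSequence`), so all designs are allocated on the *identical*
pattern batch (checksum-verified) and reruns are byte-identical. The four
scenario presets are: base case (n = 500, N = 80, G = 5, activation window
[0, 122] days, α = 120, β = 5800 — mean rate 0.0207/center/day, calibrated
to finish ~500 patients near the 365-day target), realistic rate dispersion
(α = 1.2, β = 58), doubled centers (N = 160), and doubled thresholds (b = 4,
DBR (4,4,4)/(4,8,8)/(4,8,16)). Months are converted at the calibration's own
arithmetic: 12 months = 365 days, 4 months = 122 days.

## Problem sizes and tolerances

Reference comparisons use 10,000 replicates in `scripts/acceptance.py` and a
2,000-replicate profile in the test suite; stochastic assertions use 3 Monte
Carlo standard errors (bootstrap SEs for SD and median statistics) plus half
an ulp of the reference's printed precision, since published values are
quantized to 2–3 decimals. The exact Markov-chain oracles (imbalance pmf by
kernel propagation, exact PD, closed-form CRD SD|D(n)|) are computed
independently of the simulation path they validate.

## Known limitations and open points

* **Completion-time medians.** The stated base-case parameters give a mean
  rate α/β = 0.02069 while the calibration formula 500/((365 − 61)·80)
  gives 0.02056; the simulated completion-time distributions (S1 median
  ≈ 363 d, S2 IQR ≈ 341–389 d) sit ~2 days below the reference narrative,
  consistent with that gap. With 160 centers the simulated median is
  ≈ 212 d against a reference 215 d; the model implied by the stated
  parameters cannot produce 215 (analytically, median ≈ 61 + 500/(160·α/β)
  ≈ 212), so the package reports its simulated value.
* **Center-level imbalance tail.** For unstratified procedures the simulated
  Pr(maxᵢ |Dᵢ(n)| ≥ 6) is ≈ 0.90 (CRD ≈ 0.91). Under CRD this tail is fully
  determined by the center-size distribution; an exact binomial oracle
  conditioned on the simulated sizes reproduces 0.91, and the size histogram
  matches the reference's own recruitment summaries, so the package stands
  by ≈ 0.90 against the ≈ 0.96 quoted from a figure.
* The synthetic recruitment stream has no center closures/additions,
  no quota or balanced-recruitment policies, no seasonal rate variation and
  no dropout; passing tests certify the Poisson-gamma idealization, not
  operational realities of any particular trial.
* Inference (power, type I error, randomization tests), unequal allocation,
  >2 arms, minimization and Zelen-style rules are out of scope; exact chain
  oracles are not provided for stratified/DBR designs (their state spaces
  grow with the random center sizes), which are validated structurally and
  against published operating characteristics instead.
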