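# Methods

This note documents the statistical procedures implemented in `cosel`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the package's known limitations.

## Delphi consensus scoring

Each expert scores each candidate outcome with an integer 1–9; scores 1–3
are read as "unimportant", 4–6 "important but not critical", 7–9 "critical"
(band edges configurable). Two agreement coefficients are reported per
outcome: the *importance* coefficient (percent of votes in 7–9) and the
*selection* coefficient (percent in 4–9). Dispersion is summarised by the
coefficient of variation CV = SD/mean, with the SD using the sample
convention (denominator n−1) — the convention of standard statistical
packages in consensus reporting; the denominator is configurable
(`SelectionConfig.sd_ddof`).

The selection rule flags an outcome when

* its driving agreement coefficient is **strictly below** 80%, and
* its CV is **at or above** 0.3.

The strict/non-strict pairing is deliberate: it is the only combination
under which outcomes sitting exactly at 80% agreement with CV > 0.4 are
retained while outcomes at 73.33%/CV ≥ 0.37 are flagged, which is how the
reference consensus round resolved. The selection coefficient (4–9 bands)
drives the rule by default; both the driving coefficient and the CV polarity
are configurable, the latter because the methodological literature states
the rule in both directions and the flag-high-CV direction is the one
consistent with observed practice. Flagged outcomes in a user-supplied
override set (e.g. outcomes with independent evidence of responsiveness from
a meta-analysis) are retained with their justification recorded; other
flagged outcomes are excluded; everything else is selected. Every outcome
receives exactly one decision.

### Expert authority

The authority coefficient is Cr = (Ca + Cs)/2 with the conventional weight
tables: Ca sums, over four bases of judgement, the level frequencies
weighted by (0.3, 0.2, 0.1) for theoretical analysis, (0.5, 0.4, 0.3) for
practical experience and (0.1, 0.1, 0.1) for both literature and intuition,
divided by the panel size (the published formulation hard-codes a 15-expert
panel; the implementation generalises the denominator to n). Cs weights the
five familiarity levels by (1.0, 0.8, 0.6, 0.4, 0.2). Under these weights
Ca ∈ [0.6, 1.0], Cs ∈ [0.2, 1.0], and Cr > 0.7 is flagged as acceptable
reliability.

A note on the bundled reference panel: applying the Ca formula to the
bundled basis-frequency table gives 0.913, whereas the reference analysis
reports 0.92 and carries 0.92 forward into Cr = 0.875. The two cannot both
be exact; the package computes 0.913 from the frequencies and reproduces
0.875 when fed the reported coefficients, and takes no position on which of
the published numbers is the typo.

### Rounding

All internal computation is unrounded. At display/serialization boundaries,
percentages and CV round half-up to 2 decimals and coefficients to 2–3
decimals, matching the precision conventions of consensus tables (half-up,
not banker's rounding: 84.75% → 85%).

## AGREE II appraisal

The 23 items partition into six domains (3, 3, 8, 3, 4, 2 items). With
`obtained` the sum of all appraiser × item scores in a domain, the
standardized score is 100·(obtained − min)/(max − min), where min/max are
the all-1 and all-7 totals. Two ingest modes:

* **per-rater** — integer 1–7 scores per appraiser; rater consistency is
  computed as a two-way intraclass correlation (default ICC(2,1), two-way
  random effects, absolute agreement, single measures; ICC(3,1) selectable),
  delegated to `pingouin.intraclass_corr` with explicit degenerate-variance
  handling. The two-way random absolute-agreement default is the appropriate
  model when appraisers are interchangeable samples from a rater population,
  the usual situation in guideline appraisal.
* **aggregated** — only item means across appraisers are known (the typical
  published form). The domain total `n_appraisers · Σ(item means)` is
  snapped to the nearest integer before standardizing, because the true
  total is an integer and printed means carry rounding error (2.67 standing
  for 8/3); with ≤ 3 appraisers and ≤ 8 items that error is bounded well
  below 0.5, so the snap recovers the exact total. Aggregated means are
  accepted in [0, 7] rather than [1, 7] because published tables
  occasionally print means below the scale minimum. ICC is reported as
  unavailable in this mode rather than silently NaN.

The A/B/C recommendation rule is not part of the AGREE II instrument and is
unstated in the reference analysis; the default (A when every domain ≥ 60%,
C when fewer than 3 domains reach 30%, otherwise B) was chosen because it
reproduces all nine published grades of the bundled guideline set, and both
thresholds are configurable. One cell of the bundled table is internally
inconsistent (one document's Domain 1 prints 80% while its item means imply
91%); `cosel.datasets` keeps both the item means and the printed domain
scores so either can be used as input.

## Outcome pooling

Outcome names are matched exactly after whitespace-trimming and
case-folding; an optional user-supplied synonym map is applied first, and no
fuzzy matching is attempted (synonym resolution in practice is a manual,
judgement-laden step). Each trial contributes at most once per outcome. The
core-outcome frequency filter keeps outcomes reported in **strictly more
than** the threshold percentage of trials (default 6%; "more than"
interpreted as an open interval, a `strict=False` switch gives ≥).
Candidate merging unions source sets with the frequency-retained core set,
annotates provenance, orders deterministically by (domain, name), and
refuses conflicting domain assignments rather than guessing.

## Bayesian network meta-analysis

### Model

Arm-based random-effects consistency model. Trial i's baseline arm (its
reference-most treatment) has parameter μ_i; a non-baseline arm with
treatment k has expectation μ_i + δ, with δ ~ N(d_k − d_b, τ²) where b is
the trial's baseline treatment and d are basic parameters relative to the
network reference (d_ref ≡ 0). Continuous arms contribute N(ȳ | θ, sd²/n);
binary arms contribute Binomial(r | n, exp(θ)) — a log link, so contrasts
are log relative risks and proposals implying event probabilities ≥ 1 are
rejected outright. No continuity corrections enter the likelihood; the 0.5
correction is applied only in the closed-form pairwise path when a cell is
zero.

Priors: μ_i, d_k ~ N(0, 100²) on the model scale; τ ~ Uniform(0, U) with U
defaulting to 5× the median arm SD for continuous data and 2 for log-RR —
vague on the scale of the data. All priors are config-exposed.

Multi-arm trials are handled by the single-baseline parameterization with
*independent* deviations per non-baseline arm. This ignores the 0.5·τ²
covariance between deviations sharing a baseline; for networks dominated by
two-arm trials (the intended use) the approximation is exact, and for
multi-arm trials it slightly inflates the effective heterogeneity. This is
a declared simplification, not an oversight.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs. Baselines and deviations are
updated in vectorized blocks (they are conditionally independent across
trials), basic parameters and τ individually. Two moves update each basic
parameter: a plain random-walk step, and a joint translation that shifts d_k
together with every deviation whose mean involves d_k (prior residuals are
invariant under this shift, so acceptance is governed by the data
likelihood). The joint move is essential when τ is small: d_k and its
deviations are then ridge-coupled and per-parameter updates mix arbitrarily
slowly. Step sizes adapt toward a 44% acceptance rate during burn-in only,
so the retained chain is a valid Markov chain. Initial values come from the
observed arm summaries. Chains are seeded independently
(`seed + 1000·chain`) and runs are bit-reproducible.

Defaults: 3 chains, 10,000 iterations, 1,000 burn-in, no thinning.
Convergence is monitored with the classic Gelman–Rubin PSRF
(√[((n−1)/n·W + B/n)/W] over parallel chains, computed for each d_k and τ);
a fit whose PSRF leaves the configured band (default 1.00–1.05) is returned
flagged `converged=False`, never silently accepted or discarded. Tests and
examples use shorter chains (e.g. 2–3 chains × 1,500–6,000 iterations),
which these small networks mix well within; the defaults are deliberately
conservative for real use.

### Ranking

Each posterior draw ranks treatments by effect in the configured direction
(per-outcome "higher is better" flag, since outcome sets mix directions —
lung-function up, PaCO₂ down). SUCRA_t = (T − E[rank_t])/(T − 1), identical
to the mean cumulative rank probability over ranks 1..T−1; the
rank-probability matrix is doubly stochastic and mean SUCRA is exactly 0.5.
Exact ties within a draw (measure-zero for continuous posteriors, relevant
for degenerate fixtures) share their rank positions equally.

### Consistency checking

Full node-splitting across all loops is out of scope; the package implements
a declared Bucher-style first-order check and labels its output as such. The
direct estimate pools head-to-head trials (DerSimonian–Laird random effects
via `statsmodels`); the indirect estimate chains two legs through a common
comparator using only trials outside the direct set, with variances summed;
the difference is tested with a two-sided normal z-test. The package always
fits the consistency model and reports the check — it does not switch to an
inconsistency model on failure, it flags.

## Synthetic-data generators

* **Panels** — ratings are round(clip(N(μ_o, σ_o), 1, 9)) around latent
  per-outcome importance; judgement-basis and familiarity profiles are
  categorical draws. Default panel size 15. The truncated-rounded normal
  was chosen for transparency; it does not emulate rater-specific severity
  biases or correlated rating styles, so panel tests demonstrate arithmetic
  correctness, not robustness to real rater behaviour.
* **Appraisals** — item scores round(clip(1 + 6q_d + N(0, σ), 1, 7)) around
  latent domain quality q_d ∈ [0, 1], 3 appraisers by default.
* **Extraction records** — each of ~500 trials reports each outcome
  independently with its probability; real outcome reporting is correlated
  within trials (co-reported laboratory panels), which the independence
  model ignores; counts and frequencies are unaffected, co-occurrence
  structure would be.
* **Networks** — trial-level true contrasts d_a − d_b + N(0, τ); continuous
  arms report sample mean/SD of n normal draws (baselines jittered across
  trials); binary arms draw Binomial(n, risk) with the log-link-implied
  risk, clipped at 0.99 with a warning (rejection mode available).

All generators are deterministic under their seed and their output passes
the corresponding stage validators.

## Calibration experiments

Two properties of the synthesis stage are checked by simulation, at sizes
chosen to be informative:

* **Interval coverage** — 150 networks simulated from the model (3
  treatments, 6 trials per comparison, n = 400/arm, τ = 0.75) are fitted
  and coverage of the true basic parameters by the 95% credible intervals
  is pooled over 300 parameter instances, expected within ~±3 binomial
  standard errors of 0.95. The regime matters: when τ is far below the
  within-trial contrast SE it is unidentified, the vague heterogeneity
  prior dominates, and intervals legitimately overcover — nominal coverage
  is a property of identified regimes, so that is where it is tested.
* **Consistency-test size** — 400 consistent triangle networks (τ = 0,
  10 trials per comparison) are checked with the Bucher test; the
  non-rejection rate at the 5% level is expected near 95%. With very few
  trials per contrast the DerSimonian–Laird z-test is anticonservative (a
  documented small-sample property, reproducible here at 5 trials/leg), so
  the size check uses a moderate number of trials.

## Degenerate inputs and numerical choices

* Constant ratings: CV = 0, agreement 100% or 0% by band; division-by-zero
  in CV guarded although unreachable for valid 1–9 scores.
* ICC with no variance anywhere: explicit "degenerate" status, not NaN.
* PSRF with zero within-chain variance: 1.0 if the chains are identical,
  ∞ if they differ — both explicit.
* Disconnected networks, single-arm trials and duplicate (trial, treatment)
  pairs are rejected at network construction with specific messages.
* Multi-round Delphi is composed by the caller: rounds are independent
  evaluations and outcome carry-over between rounds is a pipeline step, not
  hidden state.

## Limitations

* The NMA stage is designed for the small-to-moderate networks of the COS
  workflow (tens of trials, a handful of treatments); the dense-matrix
  sampler is not tuned for hundreds of treatments.
* Multi-arm trial correlation is approximated as described above.
* The Bucher check covers first-order loops only.
* Outcome-name matching is exact by design; synonym resolution is the
  caller's responsibility.
* The recommendation-level rule is a reconstruction that reproduces the
  bundled reference grades; it is not a published standard and should be
  reported alongside results whenever used.
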