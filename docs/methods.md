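# Methods

This note documents the generative model, the estimators, the detector
protocol, and the numerical and design choices behind `funnelbias`, in the
spirit of a statistical software methods appendix.

## Generative model

Each simulated meta-analysis draws a pool of `n + m` independent studies:

- within-study standard error `s_i ~ Uniform(1, 4)`;
- study-specific true effect `mu_i ~ Normal(mu, tau^2)`;
- observed effect `y_i ~ Normal(mu_i, s_i^2)`;
- two-sided p-value `p_i = 2 * (1 - Phi(|y_i / s_i|))`.

Defaults encode the study conditions the harness is built to emulate:
`mu = 0`, `tau^2 ∈ {0, 1}`, published counts `n ∈ {15, 30, 50, 75}`,
suppressed fraction `m/n ∈ {0, 1/10, 1/5, 1/3}` with `m` rounded half-up
(a floor variant is available), two-sided `alpha = 0.05`, and 100
replicates per cell. With `tau^2 = 0` the marginal variance of `y` is
`E[s^2] = (1 + 4 + 16)/3 = 7`, which the test suite checks by simulation.

### Selection mechanisms

Suppression deletes the `m` "least favorable" studies from the pool:

- **p-value selection** ranks by the one-sided (upper-tail) p-value, so the
  most negative and least significant results are suppressed;
- **effect-size selection** ranks by the signed effect, suppressing the
  algebraically smallest.

Both defaults are *directional*. This is a deliberate design choice: under
`mu = 0`, sign-symmetric suppression (largest two-sided p, or smallest
|effect|) leaves the expectation of every standard asymmetry statistic —
Egger's intercept, Begg's signed-deviate correlation, trim-and-fill's
one-sided imputation — at its null value, so no asymmetry test could gain
power with study count, contrary to how these tests are known to behave
when publication favors one direction. The symmetric variants remain
available via `directional=False` and are unit-tested; only the directional
defaults are benchmarked. Selection is deterministic truncation of the
ranked list (ties broken on |effect|, then generation index), not
probabilistic thinning: with a fixed severity grid the truncation form is
the reproducible operationalization.

Ground truth for scoring is simply `severity > 0`. Severity-0 cells are
generated once per `(n, tau^2)` and shared across scenario labels, since
selection is a no-op there.

### Reproducibility

Every `(cell, replicate)` owns an independent RNG stream seeded by a
64-bit BLAKE2 hash of `(root seed, cell key, replicate)`. Any cell can be
regenerated in isolation, and scheduling order cannot affect results.
Non-convergent REML fits trigger regeneration of the whole draw (counted,
capped at 1000) so every delivered dataset carries a convergent fit.

## REML fitting

The random-effects model `y_i ~ N(mu, s_i^2 + tau^2)` is fitted by Fisher
scoring on the restricted log-likelihood

```
l_R(tau^2) = -1/2 [ sum log(s_i^2+tau^2) + log sum w_i + sum w_i (y_i - mu_hat)^2 ],
w_i = 1/(s_i^2+tau^2),  mu_hat = sum w_i y_i / sum w_i,
```

with score `-tr(P)/2 + y'P P y / 2` and expected information `tr(P^2)/2`
for the usual REML projection matrix `P`. Choices: initialization at the
DerSimonian–Laird moment estimate truncated at zero (standard practice,
fast); negative proposals truncated at zero; step-halving whenever a
proposal would decrease `l_R` (making the accepted likelihood sequence
monotone); convergence when `|delta tau^2| < 1e-8` within 100 iterations.
Reaching the cap is a reported state (`converged=False`), not an error,
because the simulation engine consumes it. The tolerance and cap are
package defaults chosen to make `tau^2` stable to reporting precision.
`se(mu_hat) = sqrt(1 / sum w_i)` at the final `tau^2`. The fit matches
`metafor::rma(method="REML")` on fixed inputs and a dense grid search of
the restricted likelihood in the tests.

## Classical detectors

- **Egger's test**: OLS of `z_i = y_i/s_i` on `1/s_i`; the statistic is the
  intercept t with `n-2` df, two-sided. Requires at least two distinct
  standard errors (otherwise the design is singular).
- **Begg's test**: fixed-effect mean with weights `1/s_i^2`; deviates
  standardized by `sqrt(s_i^2 - (sum 1/s_j^2)^{-1})`; Kendall's P and Q
  counted over all pairs against the variances; normal approximation with a
  continuity correction by default.
- **Trim-and-fill**: iterated estimation of the suppressed-study count
  `k0`. The funnel is centered at the fixed-effect estimate of the
  `k0`-trimmed data; deviates are ranked by magnitude; the dominant side is
  the one with the larger rank sum at the first centering (ties resolve to
  the positive side) and is held fixed across iterations to avoid
  oscillation. Estimators: `L0 = (4*T - n(n+1)) / (2n - 1)` from the
  dominant-side rank sum `T`, rounded half-up and clamped to `n - 2`; or
  `R0 = (outermost same-side run length) - 1`.

Binary calls: Egger and Begg flag at `p < alpha`. Trim-and-fill's default
call is the parameter-free rule `k0 > 0` under L0. This rule is *liberal*:
because the dominant side is data-chosen, its rank sum is the larger of two
halves of `n(n+1)/2`, so `L0 >= 0` almost surely and `round(L0) > 0` occurs
far more often than `alpha` under a symmetric funnel (measured null flag
rates around 0.75–0.87 on the default grid). Where a calibrated call is
wanted, `estimator="R0"` attaches the exact run-length test: under
symmetry the outermost run is geometric(1/2), giving `p = 2^-(R0+1)`
(identical to `metafor`'s `p.k0`), and flags at `p < alpha`. The benchmark
reports both columns so the type-I cost of the `k0 > 0` rule is visible
rather than hidden.

## Funnel plots and detector payloads

Funnel plots are rendered at exactly 600 x 600 px (6 in x 6 in at 100
dpi, Agg backend): effect on x, standard error on an inverted y-axis,
vertical reference line at the REML pooled estimate, optional 95%
pseudo-confidence wedge `mu_hat ± 1.96 s` (off by default), x-limits
symmetric about the pooled estimate with a 5% margin. Rendering is
byte-deterministic for fixed inputs, which the tests assert.

Detector payloads carry the base64 PNG and, in combined mode, the JSON
study table (`effect_size`, `standard_error` per published study) — never
the suppressed studies, the severity, or the label. The dataset reference
in the payload is an opaque hash so no field path leads back to the
scenario configuration. Detectors that consume only the numeric table can
skip rasterization (`include_image=False`); payload semantics when an image
is requested are unchanged.

## Detector protocol and scoring

A detector is anything with `query(bundle) -> str`. The prompt bundle
carries a contextual explanation of funnel plots, four decision criteria
(symmetry, precision distribution, small-study trends, missing-study gaps),
and — in combined mode — an instruction to cross-check the plot against the
data table; the requested output format is one word, Present or Absent.

Parsing is word-boundary matching of the two answer tokens,
negation-aware ("no publication bias" reads as Absent); texts with both or
neither signal are UNPARSEABLE. Stochastic detectors are queried five
times, independently and statelessly; a verdict is recorded only when all
five parsed answers are identical (all-unparseable gives UNPARSEABLE, any
other disagreement INCONSISTENT). Deterministic detectors are queried once.

Scoring: PRESENT/ABSENT map to the confusion matrix against the ground
truth; INCONSISTENT and UNPARSEABLE are counted as *incorrect for the true
label* (FN when bias is present, FP when absent), since a strict-agreement
rule treats non-unanimity as a failed identification. This convention
shapes every metric and is applied uniformly. Metrics with zero
denominators (e.g. sensitivity in a no-bias cell) are reported as missing,
never coerced to 0 or 1. Confidence intervals are percentile intervals
(linear-interpolation quantiles) across replicates.

The HTTP detector follows a chat-completions contract (one embedded base64
image per request, configurable temperature, bearer-token auth, three
transport attempts with exponential backoff) over stdlib `urllib` with an
injectable transport; the test suite exercises the client entirely through
injection, with no network.

## Benchmark aggregation and problem sizes

`benchmark_traditional` reports, per study count `n` and per method plus a
pooled row: the type-I error (rejection fraction over severity-0 cells) and
the power (rejection fraction pooled over all bias-present cells — both
scenarios, both `tau^2` values, all severities). Pooling across cells into
a single per-`n` figure is a declared aggregation choice. The acceptance
script runs this benchmark at `n ∈ {15, 30, 75}` with 100 replicates per
cell (1200 datasets, 3600 test decisions per `n`), which completes in
about a minute; the test suite uses the same sizes for the benchmark
checks, 1000 replicates per null cell for type-I checks, and the full
default grid (5600 datasets) for the oracle-detector upper-bound check.

## What the synthetic data does and does not emulate

The generator reproduces the severity-controlled suppression design:
normal effects, uniform standard errors, rank-based one-sided deletion.
Real publication processes differ in ways the harness deliberately does not
model: probabilistic and multi-factor selection, binary/log-odds outcome
scales, correlated study sizes and effects, time-lag bias, and endogenous
selection intensity. Passing benchmarks here therefore demonstrate correct
behavior *under the stated model*, not field performance; the case-study
path (user-supplied effect/SE tables) exists precisely because real data
carry no ground truth.

## Known limitations

- Evaluating actual hosted multimodal models requires credentials and
  network access; their reported accuracies are properties of proprietary
  systems and are out of scope. The harness ships mock, oracle, scripted,
  and statistical detectors so the full pipeline is testable offline.
- Trim-and-fill's `k0 > 0` call has no significance calibration (see
  above); comparisons built on it conflate power with a high baseline flag
  rate. The R0 exact test is the calibrated alternative.
- Knapp–Hartung adjustment and profile-likelihood intervals for `tau^2`
  are not implemented; the pooled-effect SE is the plain inverse-variance
  form.
- Peters' test, Copas selection models, PET-PEESE, and p-curve are not
  implemented.
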