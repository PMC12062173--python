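# Methods

This note documents the psychometric model, the algorithms, the defaults,
and the design decisions behind `mcat4pl`, in the spirit of the model
documentation shipped by packages like statsmodels or msprime.

## The measurement model

Responses are dichotomous (correct/incorrect). For item *j* and a child
with latent trait vector **θ** over D dimensions, the four-parameter
logistic (M4PL) model is

    P_j(θ) = χ_j + (γ_j − χ_j) · σ(a_j·θ + d_j),      σ(z) = 1/(1+e^−z)

* **a_j** — discrimination slopes; under the confirmatory structure only
  the item's content dimension (plus, for the bifactor block, one nuisance
  dimension) is nonzero.
* **d_j** — easiness intercept. The Reckase summaries are derived views:
  MDISC = ‖a_j‖ and MDIFF = −d_j/‖a_j‖.
* **χ_j ∈ [0,1)** — lower asymptote: the floor produced by guessing.
* **γ_j ∈ (0,1]** — upper asymptote: the ceiling produced by lapses,
  inattention and disengagement, which matter for preschool-age examinees;
  the curve is compressed into [χ_j, γ_j].

Setting χ=0, γ=1 recovers the M2PL, freeing χ only gives the M3PL; the
three families are nested. The logistic link is used without the
historical 1.7 scaling constant.

Item Fisher information is rank-one:

    I_j(θ) = [(γ_j−χ_j) p*(1−p*)]² / [P(1−P)] · a_j a_jᵀ,   p* = σ(a_j·θ+d_j)

and is defined as the zero matrix where P reaches 0 or 1, which keeps
adaptive selection total. Test information is prior precision plus the sum
of administered items' information.

## Calibration

`fit_mirt` maximizes the marginal likelihood by EM:

* **E-step.** The latent density is integrated on a fixed quadrature:
  tensor Gauss–Hermite for D ≤ 3 (21 points in 1-D, 15²/9³ above), and a
  seeded quasi-Monte-Carlo normal sample (2048 points) for D > 3, where
  tensor grids are infeasible.
* **M-step.** Each item's free parameters are refit against the expected
  correct/total counts per node by bounded L-BFGS with analytic gradients.
* **Asymptote stabilization.** χ and γ are estimated on the logit scale
  with weakly informative quadratic penalties centered at χ≈0.05 and
  γ≈0.95 (weight 1.0, configurable). 3/4PL asymptotes are notoriously
  ill-conditioned at moderate N; the penalties keep them identified
  without fixing them.
* **Multi-start.** `n_starts` random starts (seeded; the first start is
  deterministic from observed proportions) and the best marginal
  log-likelihood wins, so repeated runs with one seed are identical.
* The trait covariance is a fixed input (identity by default): the
  confirmatory correlation structure is supplied, not estimated. Parameter
  counting (`count_parameters`) nevertheless accepts `correlated_traits`
  so that published parameter totals that include free correlations can be
  reproduced.
* Items with zero observed variance (or fewer than `min_responses`
  respondents) carry no information about their parameters;
  `screen_items` flags them and `fit_mirt` refuses to run until they are
  removed.
* Missing responses simply contribute nothing to the likelihood
  (missing-at-random by design).

Parameter recovery under the true model (1 dimension, J=20, N=1000):
correlation with generating truth ≥ 0.95 for slopes and ≥ 0.99 for
intercepts in the shipped tests.

## Limited-information fit

`fit_indices` computes the M2 statistic on first- and second-order
margins: with s = J + J(J−1)/2 sample margins p and model margins π(ξ),

    M2 = N (p−π)ᵀ C₂ (p−π),
    C₂ = Ξ⁻¹ − Ξ⁻¹ Δ (ΔᵀΞ⁻¹Δ)⁻¹ ΔᵀΞ⁻¹,   df = s − q

where Ξ is the asymptotic covariance of the margins under the model
(entries are joint moments of up to four items, computed on the
calibration quadrature) and Δ = ∂π/∂ξ is obtained by central differences.
Derived indices:

* RMSEA = √max((M2−df)/(df·N), 0), with a 90% noncentrality-inversion CI;
* SRMSR = root mean square difference between observed and model-implied
  **product-moment** correlations of the binary responses (cheaper than
  tetrachoric and monotone-equivalent for ranking; swap-able by design);
* TLI/CFI against an independence null with free item margins (df₀ = s−J),
  fitted on the same margins.

The machinery is exact but O(s²) in memory and O(s²·Q) in time, i.e.
intended for banks of up to a few dozen items; the published
degrees-of-freedom accounting for large banks (e.g. J=177: df = 15,345 /
15,168 / 14,991 at q = 408 / 585 / 762) is closed-form via
`m2_degrees_of_freedom` and needs no fit. `compare_models` ranks fitted
families by SRMSR ascending by default (ties keep input order).

## Scoring

`map_estimate` maximizes log-likelihood + log MVN prior by L-BFGS with
analytic gradients (the 4PL log-likelihood is not globally concave, so a
quasi-Newton method with a damped-Newton polish is used rather than pure
Newton). Per-dimension SEM is the square root of the diagonal of the
inverse curvature at the mode, using **observed** information + prior
precision by default (expected information available via flag, and used
automatically if the observed curvature is indefinite at the mode).
Reliability is Rel = 1 − SEM², valid on the unit-variance latent scale;
T-scores are 50 + 10θ (the conventional T-metric; the source material
plots T-scores but never prints the constants). Nuisance dimensions are
estimated jointly but excluded from reporting and stopping.

## The adaptive engine

* **Starting items.** One designated easy item per age bucket (≤4, 5, ≥6);
  ages parse from "y;m" strings or integers.
* **Selection rules.** For each candidate, M = prior precision + acquired
  information + candidate information at the current MAP; criteria D
  (log-determinant), T (trace), A (−trace M⁻¹), E (smallest eigenvalue),
  W (wᵀMw, default weights uniform over the six content dimensions).
  Rank-one update identities make D/T/A/W O(D²) per candidate. The
  posterior-weighted variants (DP/TP/AP/WP/EP) average the same criterion
  over an equal-weight 2D+1 sigma-point grid at MAP ± the Cholesky columns
  of the current posterior covariance — a fixed, deterministic quadrature
  that is feasible at D=8 where tensor grids are not. Ties break to the
  lowest bank index.
* **Stopping.** Stage 1 (items 1–49): stop when all six content SEMs are
  below 0.387298334620742 (reliability 0.85). Stage 2 (from item 50):
  threshold 0.447213595499958 (reliability 0.80). From item 60 a
  stability criterion also applies: Σ over content dimensions of the
  squared SEM range over the last 10 items < 0.0005 (≈0.01 per dimension,
  i.e. the SEMs have stopped moving). Bank exhaustion always stops. The
  starting item counts as item 1 for the stage boundaries; whether the
  published boundaries are checked before or after positions 49/50/60 is
  ambiguous in the source, so this convention is documented rather than
  asserted.
* Stopping via a SEM threshold analytically guarantees the corresponding
  reliability floor (1 − threshold²) on every content dimension — the
  property the Monte-Carlo acceptance checks exercise end-to-end.

## Synthetic banks and simulation

No real item parameters or child data are available, so the generator
emulates the published pool geometry: 177 items over six correlated
content scales (sizes 38/19/12/29/45/34, echoing the published scale
spans), MDIFF stratified-uniform over [−2, 2], MDISC lognormal
(μ=1.1, σ=0.6 on the log scale, truncated to [0.5, 16]) so that most
items exceed 1.5 and a minority sits in 0.5–1.5, plus 15 "excellent"
items (MDISC 15–20, MDIFF in (−1, 1), spread round-robin over scales).
The excellent subset is not decorative: the published simulations report
sessions as short as 9 items reaching reliability 0.80 on all six
dimensions, which is only possible when single items carry several units
of Fisher information. χ is uniform on [0, 0.3], γ on [0.85, 1]. Content
traits follow a compound-symmetric correlation (0.5 by default); the
first scale's items additionally load on one of two orthogonal nuisance
dimensions ("numerical" / "iconic" writing awareness) with a
content-to-nuisance angle of 0.15–0.35 rad (the nuisance share of item
information is 2–12%; the true share is unknowable from published
material and is configurable). Three starting items are designated —
easy, well-discriminating, graded by age bucket.

What the generator does **not** emulate: real per-scale difficulty
distributions, content balancing, item wording effects, age-related
differential item functioning, and any dependence of χ/γ on item content.
Passing simulations therefore demonstrate the engine's behavior under the
published pool geometry, not field validity of any particular bank.

Monte-Carlo evaluation (`run_cat_simulation`) pre-draws each simulee's
full response vector from an independent child stream of the run seed, so
summaries are byte-identical for identical inputs and seed, and replays
one session per simulee. Summaries use nearest-rank percentiles (the
discrete convention of the published tables). The starting-item study is
an OLS regression of the summed squared SEM over the six dimensions on
dummy-coded starting items within age group plus a stop-rule indicator,
reported as b / SE / t / p / standardized β with the most beneficial
(most negative) starter listed first per age group; reference levels are
an explicit input because the published dummy coding is not stated.

## Problem sizes and tolerances

The shipped acceptance checks use the reference bank (177 items, 8
dimensions) with 200 simulees per stop rule — a desk-scale design chosen
so a full run completes in minutes on one core. MAP/grid-oracle
equivalence is checked to 0.02 per dimension against a 0.01-step grid
search; item information to 1e−5 against central finite differences;
EM recovery to correlation 0.9/0.95 at N=1000. The reliability-floor
checks exclude bank-exhausted sessions, which by construction cannot
certify a floor.

## Known limitations

* Trait correlations are inputs, not estimated; no standard errors for
  item parameters; no DIF testing; no exposure control or content
  balancing (none is described for the source system).
* The M2 machinery scales to a few dozen items, not hundreds.
* The stability stop rule can, in principle, trigger on a plateau far
  from convergence if the bank has no informative items left for a
  dimension — mirroring its published purpose of ending unproductive
  sessions.
* EAP/ML/WLE scoring and polytomous models are out of scope (MAP only).
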