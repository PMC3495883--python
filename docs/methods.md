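# Methods

## Problem setting

Respondent-driven sampling (RDS) reaches hidden populations — here,
internet-using men who have sex with men — by letting participants recruit
their own contacts with a limited number of invitations ("coupons").
Because recruitment travels along social ties, a person's inclusion
probability grows with their personal network size (degree); estimation
must undo that bias. In the web-based variant (webRDS), invitations are
electronic, which enables long chains at low cost but also invites
duplicate and ineligible submissions that must be screened out
statistically rather than in person.

The package implements the full analysis chain: a synthetic-data generator
(network, recruitment, submissions), validity cleaning with nested
inclusion levels, RDSII estimation, and Markov equilibrium diagnostics,
orchestrated by a deterministic pipeline.

## The RDSII estimator

For respondents i = 1..n with reported degrees d_i > 0, the estimated
population proportion of category A is

    p̂_A = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹,

the inverse-degree-weighted sample proportion, with the analogous weighted
mean x̂ = Σ x_i d_i⁻¹ / Σ d_i⁻¹ for numeric answers. The estimated mean
network size is the harmonic mean d̂ = n / Σ d_i⁻¹. Under
degree-proportional (size-biased) inclusion — the stationary random-walk
regime — p̂ is unbiased and d̂ recovers the population's arithmetic mean
degree; both facts are exercised directly in tests using the package's
random-walk sampler as the oracle.

Degree handling: a reported degree of zero is treated as missing, since a
recruited respondent has at least one in-scope contact by construction.
Missing degrees are imputed with d̂ computed from the non-missing reports
of the same analysis sample, and imputation always precedes estimation.
Refusals ("don't want to answer") on categorical analysis variables form
their own category (`no_answer`); for numeric means they are dropped
pairwise. No variance or confidence-interval machinery is provided — there
is no consensus RDS design-effect estimator, and the package deliberately
reports point estimates only.

## Cleaning and inclusion levels

Flags are computed from the record set alone: stated age below 18;
a phone / email / chat token previously registered (tokens are
canonicalised — trimmed, lowercased, phone numbers reduced to digits — and
the chronologically first bearer is never flagged, ties broken by record
id); a repeated IP token, same first-bearer rule; completion under
3 minutes; no education; more than 1,000 partners in six months. The
nested analysis samples are

* L0: non-seed records with valid age,
* L1: L0 minus repeated contact tokens (the *cleaned sample*),
* L2: L1 minus repeated IPs,
* L3: L2 minus fast / no-education / extreme-partner records.

Seeds are always excluded. Descendants of excluded records are retained;
for chain diagnostics they are re-attached to their nearest retained
ancestor (or promoted to pseudo-seeds) and waves recomputed. This repair
is purely diagnostic — RDSII uses no tree structure.

The sensitivity table recomputes the RDSII estimates per level and reports
each estimate's absolute difference from its L0 value, re-imputing degrees
within each level.

## Equilibrium diagnostics

For each categorical variable (numeric variables are binned first; default
bin edges live in the pipeline config), recruitment is modelled as a
first-order Markov chain whose transition matrix is the row-normalised
count matrix of recruiter-category → recruit-category events. The state
space is restricted to categories observed at least once as a recruiter;
categories appearing only as recruits are reported as dropped states (row
normalisation is undefined for them). The stationary distribution π solves
πP = π (least-squares with the normalisation row; residual checked against
1e-10, with irreducibility and aperiodicity verified on the positive-entry
digraph and violations reported with the offending states).

Waves-to-equilibrium is the smallest n such that every degenerate start
e_j satisfies |(e_j Pⁿ)_c − π_c| / π_c < tol for every category c, with
tol = 0.02 by default. The worst case over degenerate starts is the
default because the statistic is meant to certify seed-independence —
whatever single category the seeds had, n waves suffice; a specific
starting composition can be passed instead. For two-state chains the
statistic has the closed form driven by the second eigenvalue
λ = P₁₁ + P₂₂ − 1 (worst relative deviation |λ|ⁿ·max(π_A/π_B, π_B/π_A)),
used as an independent oracle in tests.

Empirical convergence is assessed by the running-composition curves
(estimates recomputed on the first m records, m = step, 2·step, …, n; the
final point equals the full-sample estimate exactly) and the last-k
comparison (maximum absolute difference between full-sample and last-k
estimates per variable; k = 200 by default). Chain statistics (per-chain
sizes, maximum waves, chains exceeding a wave threshold, cumulative
submissions per day) come straight from the parent map and timestamps.

## Synthetic-data generator

The generator emulates a webRDS study on an abstract attributed network:

* **Network.** Configuration-model-style stub matching on the drawn degree
  sequence (Poisson, zipf power-law, or regular), rejecting self-loops and
  multi-edges. Homophily on a trait with coefficient h ∈ [0,1] is imposed
  during matching: a cross-category pair is rejected with probability h.
  Matching is retried (up to 50 times) until all stubs pair; tiny residual
  deficits are accepted, and `true_degree` always equals the realised
  graph degree. Same-category edge fractions increase monotonically with
  h, which is tested Monte-Carlo.
* **Attributes.** Categorical traits from configured marginals; provinces
  from a categorical distribution with their own homophily coefficient;
  ages from a discrete distribution over 18–40 peaked at 22. Underage
  *stated* ages (16–17) enter only through the invalid-injection channel:
  the eligible population is adult, and underage submissions are misreports
  by ineligible respondents.
* **Recruitment.** Discrete waves; each participant invites a uniform
  random subset of at most `coupons_per_participant` (default 4) eligible
  neighbours; each invitee joins independently with
  `participation_probability`; without replacement nobody is sampled
  twice, competing same-wave invitations resolve first-recruiter-wins.
  Submission times increase strictly along chains (exponential
  inter-submission gaps). Reminder schedules and the 7-day recruitment
  window are not modelled; they play no analytical role.
* **Submissions.** Unique phone/email/chat and IP tokens, completion
  durations ≥ 3 minutes (log-normal around 9 minutes), education, income
  and partner counts from fixed distributions, and a reported 7-day
  network size drawn Poisson around 0.7 × true degree (the "internet-using
  contacts" question reports a fraction of all contacts), missing at a
  configurable rate. Invalid records — underage, copied contact token,
  copied IP, sub-3-minute completion — are injected into non-seed records
  at configured rates, with the injected ids returned as ground truth so
  the cleaning stage can be validated record-for-record.

**Default study conditions** (`configs/default.yaml`): 5,000 individuals,
Poisson(8) degrees; three provinces (0.45/0.37/0.18, i.e. 82% in the two
metropolitan areas) with province homophily 0.7 — which yields roughly a
third of recruitments crossing provinces, since the cross-category edge
share is approximately q(1−h)/(q(1−h)+1−q) with q = 1 − Σp² ≈ 0.63; three
mildly homophilous traits (a 95/5 partner-preference split and two
opinion/behaviour variables); 20 seeds, 4 coupons, participation 0.25.
With four coupons, participation 0.25 puts recruitment near criticality,
so chains grow to several hundred participants and then die out on their
own — the qualitative regime of a real webRDS study (local saturation
rather than exhaustion of the population). Injection rates (underage 0.03,
duplicate token 0.07, shared IP 0.08, fast 0.02; network size missing
0.08) give an invalid share near one in ten. A default run produces
roughly 400–800 submissions, invalid shares of 9–11%, cross-province
recruitment fractions near 0.35, and between-2-and-7 waves to equilibrium
across variables.

What the generator does **not** emulate: message forwarding and incentive
choice behaviour, within-person variation in truthful reporting, degree
misreporting beyond Poisson noise, temporal non-stationarity of
participation, and community structure beyond single-trait homophily.
Passing tests therefore demonstrate correctness of the estimators and
diagnostics under the stated sampling models, not robustness of webRDS to
every real-world violation.

## Determinism and numerics

All randomness descends from one master seed through named SHA-256-derived
per-stage substreams, so stages are individually reproducible and two runs
with the same configuration and seed produce hash-identical artifacts
(manifest of SHA-256 content hashes, checked in tests; figure files are
written without software metadata for byte stability). Ties in timestamps
are broken by record id everywhere an ordering matters. Stationary solves
use a least-squares formulation with an explicit residual guard at 1e-10;
waves-to-equilibrium iterates matrix powers with a hard iteration cap.
Degenerate inputs fail loudly: empty samples, all-missing degrees,
disconnected graphs for random walks (components reported), reducible or
periodic chains (states reported), and empty inclusion levels (level
named).

## Problem sizes used in tests

Unit and property tests run on populations of 500–2,000 nodes with a few
hundred recruits, 30-replicate stochastic checks, and 10⁵-step random
walks; the estimator-recovery benchmark uses 50 random-walk samples of 500
draws from a 2,000-node network. These sizes give comfortable Monte-Carlo
margins for every asserted effect while keeping the full suite under a
minute of compute.

## Known limitations

* The recruiter→recruit transition matrix treats all observed events as
  exchangeable (the "averaged" chain); no per-chain heterogeneity.
* Chain repair after exclusion re-parents across excluded nodes, which
  overstates tie homophily slightly for those repaired events.
* The IP-duplication share depends on the caller's denominator choice
  (submissions vs. non-seed submissions); the package reports counts and
  lets the caller choose.
* No variance estimation, by design.
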