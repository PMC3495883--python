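# webrds

Analysis toolkit for **web-based respondent-driven sampling (webRDS)**
surveys of hidden populations.

RDS reaches groups with no sampling frame — such as men who have sex with
men, people who inject drugs, or sex workers — by letting participants
recruit their own contacts with a small number of invitation coupons. In
webRDS the coupons are electronic messages, which makes long recruitment
chains cheap but also lets one person submit several surveys, or
ineligible people submit at all. Sound estimation therefore needs three
things this package provides:

1. **Cleaning** — flag underage submissions, repeated phone/email/chat
   tokens, repeated IPs, sub-3-minute completions and implausible answers,
   and build progressively stricter nested analysis samples (L0–L3) for
   sensitivity analysis;
2. **Estimation** — the RDSII estimator: with reported network sizes
   (degrees) d_i, the population proportion of category A is estimated by
   the inverse-degree-weighted share p̂_A = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹,
   which is unbiased when inclusion probability is proportional to degree;
   the mean network size is the harmonic mean d̂ = n / Σ d_i⁻¹, and missing
   degrees are imputed with d̂;
3. **Diagnostics** — model recruitment on each variable as a first-order
   Markov chain over recruiter→recruit categories, compute its stationary
   composition π (πP = π) and the number of waves until every starting
   composition is within 2% relative difference of π; plus
   running-composition curves, a full-sample vs last-200 comparison, and
   recruitment-chain statistics.

Because real webRDS datasets are rarely shareable, the package also ships
a first-class **synthetic-data generator**: attributed random networks
with degree models and attribute/province homophily, a coupon-based
recruitment simulator, and a submission fabricator that plants invalid
records with full ground-truth bookkeeping.

## Worked example

Estimate a proportion from three respondents with reported network sizes
2, 4 and 8:

```pycon
>>> from webrds import rdsii_proportion, impute_network_size, rdsii_mean_degree
>>> rdsii_proportion(["men_only", "men_only", "other"], [2, 4, 8]).proportions
{'men_only': 0.8571428571428571, 'other': 0.14285714285714285}
```

The low-degree respondents carry more weight than the raw 2/3 sample
share, because high-degree people are over-recruited. Missing network
sizes are imputed with the harmonic mean of the observed ones:

```pycon
>>> impute_network_size([1, 4, float("nan")])
array([1. , 4. , 1.6])
>>> rdsii_mean_degree([2, 3, 6])
3.0000000000000004
```

Run the whole pipeline on the packaged synthetic default (20 seeds, four
invitations each, voluntary participation, study-like invalid-injection
rates):

```bash
webrds all --seed 3 --outdir out
```

`out/report.md` from this run includes:

```
- invalid (underage or duplicated contact token): 115 = 10.2% of submissions
- excluded to form cleaned sample (seeds + invalid): 135 = 12%
- waves needed, median across variables: 2.0
- chains: 20, maximum wave 64
- cross-province recruitment fraction: 0.356
```

meaning: about one submission in ten was planted invalid and caught; the
cleaned sample drops seeds plus invalid records; on the averaged
recruitment Markov chains most variables forget the seed composition
within about two waves (the simulated chains ran far longer than that, so
equilibrium is plausible); and roughly a third of recruitments crossed
province boundaries. The directory also holds the estimates table
(sample proportion vs RDSII estimate per category), per-level sensitivity
table, equilibrium JSON, transition matrices, stabilisation curves and
figures, and a manifest of SHA-256 hashes — two runs with the same seed
are byte-identical.

Stages can be run individually (`webrds simulate|clean|estimate|diagnose|report`)
and accept `--config`, `--level L0..L3`, `--k` and `--tolerance`. Real
study data enter as a submissions CSV plus a recruiter-edge CSV with the
same schemas the simulator writes.

## Layout

```
src/webrds/
  synthetic_data.py   population, recruitment, random-walk and submission generators
  cleaning.py         validity flags, inclusion levels L0–L3, chain repair, sensitivity
  estimators.py       RDSII proportions/means, harmonic mean degree, imputation
  diagnostics.py      transition matrices, stationary/waves analysis, curves, chain stats
  cli_reporting.py    pipeline stages, manifest, report, click CLI
  forest.py, config.py, plots.py
configs/default.yaml  the packaged default study conditions
docs/methods.md       models, assumptions, defaults and their rationale
```
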