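# metafew

Meta-analysis of binary outcomes when only very few studies are available.

Standard random-effects meta-analysis works poorly when a systematic review
pools only 2–4 randomised trials — which is the typical case: the median
Cochrane meta-analysis contains 3 studies.  With so few studies the
between-study variance τ² cannot be estimated reliably, DerSimonian–Laird
intervals become anti-conservative, and Hartung–Knapp–Sidik–Jonkman
intervals can be enormously wide.  Beta-binomial likelihood models, which
pool the arm-level 2×2 tables directly and need no continuity correction
for zero-event studies, are a promising alternative.

`metafew` implements eleven pooled-effect estimators for two-arm binary
studies behind one scikit-learn-style interface, together with a simulation
engine and performance harness for comparing them under realistic few-study
conditions:

| name | model | CI |
|---|---|---|
| `bbst` | common-ρ beta-binomial (shared intraclass correlation ρ = 1/(α+β+1), fixed effect b_T) | t, df = 2K−2 or K−1 |
| `bbfr` | common-ρ beta-binomial + per-study random treatment effect γ_k ~ N(0, σ²) | t |
| `bbcb1` | common-β beta-binomial pooling arms across studies (OR only) | t |
| `bbcb2` | common-β beta-binomial conditioning on each study's event total (OR only) | t |
| `glfr` | logistic mixed model, fixed intercepts + random treatment effect (Laplace) | Wald |
| `glrri` | logistic mixed model, random intercepts + random treatment effect (Laplace) | Wald |
| `dsl` | DerSimonian–Laird inverse-variance random effects | normal |
| `hksj` | Hartung–Knapp–Sidik–Jonkman with Paule–Mandel τ² and the ad-hoc q* = max{1, q} rule | t, df = K−1 |
| `mh` | Mantel–Haenszel fixed effect (Robins–Breslow–Greenland SE) | normal |
| `peto` | Peto one-step odds ratio | normal |
| `coll` | collapsed single 2×2 table | normal |

All estimates are on the log OR (logit link) or log RR (log link) scale.

## Worked example

Three trials of a treatment against a binary adverse outcome
(`example.csv`):

```csv
study_id,y_t,n_t,y_c,n_c
ISIS-1,12,160,19,158
COP-2,4,48,9,52
MDPIT-3,7,95,13,97
```

```bash
metafew fit example.csv --methods bbst,bbcb1,glfr,hksj,dsl,mh
```

prints (columns trimmed):

```text
method,est,se,ci_lo,ci_hi,or,ci_lo_exp,ci_hi_exp
bbst,-0.629377,0.274255,-1.39083,0.132077,0.532924,0.248868,1.1412
bbcb1,-0.62937,0.274114,-1.39043,0.131693,0.532927,0.248967,1.14076
glfr,-0.62635,0.274406,-1.16417,-0.0885245,0.534539,0.31218,0.915281
hksj,-0.624609,0.274812,-1.80703,0.557811,0.535471,0.164141,1.74684
dsl,-0.624609,0.274812,-1.16323,-0.0859879,0.535471,0.312475,0.917605
mh,-0.626426,0.274388,-1.16422,-0.0886356,0.534499,0.312167,0.915179
```

Every method agrees the pooled odds ratio is about 0.53 (the treatment
roughly halves the odds of the outcome), but the intervals differ sharply:
the normal-approximation methods (GLFR, DSL, MH) exclude 1 and would call
the effect significant, the beta-binomial t intervals (df = 2K−2 = 4) do
not, and HKSJ — with only K−1 = 2 degrees of freedom — is far wider still.
With K = 3 studies that disagreement is exactly the methodological problem
this package exists to study.

The same estimators are available programmatically:

```python
from metafew import BetaBinomialCommonRho, MetaDataset

ds = MetaDataset.from_counts([[12, 160, 19, 158], [4, 48, 9, 52], [7, 95, 13, 97]])
fit = BetaBinomialCommonRho(measure="or", df_rule="2k-2").fit(ds)
fit.effect_, fit.se_, (fit.ci_low_, fit.ci_high_), fit.rho_
```

## Simulation engine

`metafew simulate` generates meta-analyses from distributions fitted to a
large corpus of Cochrane reviews: log-normal total study sizes (median
~102 participants), Beta(0.42, 1.43) control-arm risks (median 0.13, so
rare events are common), log-normal heterogeneity τ² and, under the
alternative, Fleishman-transformed skewed log odds ratios.  Scenario
configuration is a YAML/JSON file mirroring `ScenarioConfig`; results are
one CSV row per (replication, method), and `metafew summarize` computes
convergence counts, bias, coverage, CI length, and power, with an optional
Cochran-Q sensitivity subset (`--sensitivity`).

```bash
metafew simulate scenario.yaml --outdir out/
metafew summarize out/results.csv --hypothesis h0 --out summary.csv
```

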