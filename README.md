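# emovar

Do collective emotions drive protective behavior during a health
crisis, or the other way round? `emovar` is a Python package for
answering that question from two public time series: discrete emotions
(anger, anxiety, sadness) scored from short social-media texts with an
open word-count lexicon, and a 0–100 trends-style shopping index used
as a proxy for preventive behavior (e.g. hand-sanitizer purchases).
It is aimed at infodemiology and computational social-science
researchers who want the full chain — text scoring, index
construction, vector autoregression, Granger causality, impulse
responses — as tested, reusable, scriptable pieces.

## The model

Each document *t* gets a per-emotion **linguistic score**
p_m(t) = 100·|tokens of t matched by emotion m's lexicon|/|tokens of t|.
Scores are aggregated into a daily index of mean percent deviation
from the platform base rate p_B(m),

    index(d, m) = (100/|T_d|) · Σ_{t∈T_d} (p_m(t) − p_B(m)) / p_B(m),

averaged over consecutive 7-day blocks into weekly series, and aligned
with the weekly behavior index into a panel
y_w = [Behavior, Anger, Anxiety, Sadness]. The panel (standardized to
mean 0, variance 1 by default) is modelled as a VAR(p),

    y_w = c + A_1 y_{w−1} + … + A_p y_{w−p} + ε_w,

with p chosen by AIC/BIC on a common sample. The package then runs
companion-root stability diagnostics, directed Granger causality
block F-tests between each emotion and behavior, and orthogonalized
(Cholesky) impulse responses to one-standard-deviation shocks with
95% recursive-design residual-bootstrap bands.

A first-class synthetic-data module generates tweet-like corpora and a
coupled 0–100 behavior file from a *known* latent VAR, so every stage
of the pipeline is verifiable end to end without any downloads. See
`docs/methods.md` for the full methodological account.

## Worked example

Generate a synthetic study with a planted causal structure (anxiety
drives behavior; sadness is decoupled) and analyze it:

```sh
$ emovar simulate --scenario paper-like --weeks 120 --docs-per-day 100 \
      --seed 7 --out-dir demo/bundle
bundle -> demo/bundle (checksum 095677814572)

$ cat > demo/study.yaml <<EOF
documents: demo/bundle/documents.jsonl
lexicon: demo/bundle/lexicon.json
trends: demo/bundle/trends.csv
out_dir: demo/analysis
start_date: 2020-01-21
n_weeks: 120
p_max: 5
bootstrap: 500
seed: 42
EOF

$ emovar run --config demo/study.yaml
report -> demo/analysis/report.md (lag 1, stable)
```

The Granger section of `demo/analysis/report.md` reads:

| cause | effect | lag | F | p_value | decision |
|---|---|---|---|---|---|
| anger | behavior | 1 | 0.7471 | 0.3892 | accept |
| anxiety | behavior | 1 | 13.8686 | 0.0003 | reject |
| sadness | behavior | 1 | 0.0540 | 0.8167 | accept |
| behavior | anger | 1 | 0.1080 | 0.7430 | accept |
| behavior | anxiety | 1 | 0.2846 | 0.5948 | accept |
| behavior | sadness | 1 | 0.4458 | 0.5057 | accept |

The planted anxiety→behavior coupling is the one decisively rejected
null (F = 13.87, p = 0.0003); anger and sadness — decoupled or weakly
coupled in this scenario at this sample size — are not flagged. The
report also contains per-emotion descriptive statistics of the
84,000 scored documents, the correlation screen, the AIC/BIC lag
table, the stability diagnostic (max companion-root modulus 0.39),
and the IRF table with bootstrap bands (`irf.csv`); every intermediate
(scores, daily indices, panel, fitted model) is persisted alongside.

The same stages are available programmatically
(`emovar.score_document`, `daily_emotion_index`, `fit_var`,
`granger_matrix`, `bootstrap_irf_bands`, ...) and as individual
subcommands (`emovar score`, `panel`, `fit`, `granger`, `irf`), which
read and write the documented CSV/JSON formats so they can be mixed
with externally collected data.

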