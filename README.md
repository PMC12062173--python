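# mcat4pl

Multidimensional 4PL item response theory calibration, MAP scoring, and a
computerized adaptive testing (CAT) engine for early-literacy screening.

## Who this is for

Psychometricians and assessment developers building adaptive screeners for
young children, where six correlated early-literacy traits (concepts of
print, print awareness, word awareness, phonological awareness, alphabet
knowledge, early reading) must be measured in as few items as possible,
and where both guessing and disengagement distort responses.

## The model

The probability that child with trait vector **θ** answers item *j*
correctly follows the four-parameter logistic (M4PL) model

    P_j(θ) = χ_j + (γ_j − χ_j) · σ(a_j·θ + d_j)

with discrimination slopes a_j, easiness d_j, a guessing floor χ_j and a
disengagement ceiling γ_j (young children miss easy items through lapses
of attention, so γ_j < 1 matters). On top of this the package provides:

* **Calibration** — confirmatory EM marginal maximum likelihood for the
  nested M2PL/M3PL/M4PL families, with multi-start estimation, penalized
  asymptotes, and limited-information fit (M2, RMSEA + CI, SRMSR,
  TLI/CFI) for model comparison.
* **Scoring** — MAP trait estimates with per-dimension standard errors
  (SEM), reliability Rel = 1 − SEM², and T-scores (50 + 10θ).
* **Adaptive engine** — age-group starting items; optimal-design item
  selection (D/T/A/W/E rules and posterior-weighted variants, AP being
  the default); a staged stop rule: SEM < 0.3873 (reliability 0.85)
  through item 49, SEM < 0.4472 (reliability 0.80) from item 50, plus a
  SEM-stability criterion from item 60, on all six content dimensions.
* **Simulation** — Monte-Carlo CAT evaluation (item-count and reliability
  summaries, selection-rule comparison) and an OLS study for choosing
  age-appropriate starting items.
* **Synthetic banks** — a seeded generator reproducing the published pool
  geometry (177 items, difficulty −2..+2, predominantly high
  discrimination, bifactor nuisance dimensions), since no real item
  parameters or child data are published.

See `docs/methods.md` for formulas, defaults, and design decisions.

## Worked example

Generate a synthetic bank, run one adaptive session for a scripted
5-year-old respondent with known traits, and produce a screening report:

```bash
mcat4pl generate-bank --seed 1 --out bank.csv
mcat4pl run-session --bank bank.csv --age 5 --rule AP \
    --true-theta 0.5,0,-0.5,0.3,0,0,0,0 --seed 3 --out session.jsonl
mcat4pl report --session session.jsonl --child-id demo --out report.json
```

The session prints

```
39 items, stop reason stage1_sem; T-scores 47.1, 53.9, 45.8, 51.7, 49.7, 48.0, 48.5, 48.2
```

meaning the staged stop rule ended the test after 39 of 177 items because
every content dimension reached SEM < 0.3873 (reliability ≥ 0.85); the
first six T-scores are the content scales (population mean 50, SD 10),
the last two the nuisance dimensions, which are estimated but not
reported. The report then classifies each scale against the traffic-light
cut-offs (red below T=40, orange below T=45, otherwise green):

```
"concepts_of_print":  {"t_score": 47.05, "category": "green"}
"print_awareness":    {"t_score": 53.91, "category": "green"}
...
```

The same flows are available as library calls (`generate_bank`,
`CatSession` + `run_session`, `classify_traffic_light`), and
`mcat4pl calibrate` / `fit-indices` / `simulate` / `optimize-start` cover
calibration and the simulation studies. Every subcommand takes `--seed`
and is byte-deterministic given identical inputs.

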