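# Methods

## Model overview

`crcscreen` evaluates three colorectal-cancer (CRC) screening strategies for
a cohort aged 50–75 — no screening, sequential two-step screening (two-sample
FIT plus a risk questionnaire, with colonoscopy referral for positives), and
direct colonoscopy — with a decision tree acting once at baseline followed by
an annual-cycle Markov cohort model. The decision criterion is the
incremental cost-effectiveness ratio (ICER) in USD per quality-adjusted life
year (QALY), evaluated from a societal perspective.

### Decision tree (baseline)

The target population (804,180 people; CRC prevalence 0.99%) is split by the
chosen strategy:

- **No screening** — all prevalent cancers enter the model via the
  self-referral pathway at cycle 0 (the model has no sojourn/dwell model for
  asymptomatic disease, so undiagnosed prevalent cancers are taken to surface
  symptomatically at baseline).
- **Sequential** — everyone pays the primary-screen cost (5 USD). A fraction
  `p_high = 20.3%` is flagged high-risk; of these, a fraction *a* (the
  colonoscopy acceptance) completes colonoscopy at 195 USD. A prevalent
  cancer is flagged by the primary screen with probability
  `sens_primary = 0.83`; flagged cancers are detected iff the person
  completes colonoscopy, so the screen-detected fraction of prevalent CRC is
  `a x 0.83`. Undetected cancers self-refer at baseline.
- **Direct colonoscopy** — a fraction *a* of the entire population is
  colonoscoped; their prevalent cancers are all found.

Colonoscoped cancer-free participants enter a post-colonoscopy state with
reduced CRC incidence (0.0002/yr for five years, 0.00035/yr for years six to
ten, reverting to the general 0.002/yr afterwards).

### Markov engine

States: healthy-naive; post-colonoscopy (tunnel, years 1–10 since
colonoscopy); CRC by detection mode (screen/self) in a 10-year tunnel
indexed by years since diagnosis; cured; dead of CRC; dead of other causes.
Cycle length is one year, state membership is valued at cycle end, and costs
and QALYs are discounted at `(1+r)^-t` with `r = 5%` (baseline spending
undiscounted).

CRC mortality in tunnel year *k* is the conditional annual probability
derived from the printed cumulative death fractions at years 1/3/5/10
(2.4/7.8/13.1/23.1% screen-detected; 9.2/24.9/34.8/46.4% self-referred)
under a constant conditional hazard within each reporting segment; the
annualization reconstructs the printed anchors to 1e-12. Survival to tunnel
year 10 is cure: utility returns to 1 and no excess CRC mortality applies
afterwards. Competing risks are applied cause-specifically: CRC death first,
then background mortality on the survivors.

Background mortality comes from a bundled **synthetic life table** (Gompertz
hazard `qx = a*exp(0.09*age)`, calibrated so the uniform age-weighted
mortality over ages 50–75 equals the published 0.0063). The cohort's age
mix is held at its entry distribution and advanced in lockstep — survivor
re-weighting by age is ignored, which slightly overstates late-cycle
mortality. A flat 0.0063 rate is available by running without the table.

Costs: CRC treatment is charged once at diagnosis as a detection-mode
composite (6,286 USD screen-detected, 11,672 USD self-referred), which
already bundles hospitalization, adjuvant rounds, and productivity losses of
the patient and one caregiver at 37 USD per person-day. Utilities:
1 (healthy/cured), 0.85 (screen-detected CRC), 0.74 (self-referred CRC),
0 (dead). The stage-weighted derivation of each composite from per-stage
components is retained and tested: advanced-without-metastasis values use
the unweighted mean of stage II and III inputs, which reproduces the
printed screen-detected cure rate of 76.9% exactly; recomputed composite
costs land within 1% of the printed values (6,270.6 vs 6,286; 11,576.4 vs
11,672), a residual we attribute to currency-conversion rounding in the
sources.

### Horizon and accounting windows

The published table mixes two timescales: incident-case counts match a
10-year evaluation window, while per-capita effectiveness (~15.8 QALYs)
is only attainable over a cohort lifetime. The package therefore runs the
**lifetime** preset by default: economics (costs, QALYs) accrue until cohort
extinction (capped at 60 cycles), while the epidemiological tallies (new CRC
cases, cumulative CRC deaths) are collected over the programme's stated
10-year evaluation window. A strict `paper-10y` preset (10 cycles for
everything) is also provided. Screening is applied once at baseline; no
repeat rounds are modelled.

## Distribution fitting and sensitivity analysis

Printed parameter ranges are read as central 95% intervals, so
`sd = (high-low)/3.92`, and Beta/Gamma distributions are fitted by the
method of moments (Beta: `k = m(1-m)/var - 1`, `alpha = mk`; Gamma:
`shape = (m/sd)^2`, `scale = sd^2/m`). Fitted means equal the printed point
values to 1e-9. The printed range for the discount rate (0.3–0.8) is
inconsistent with its value (0.05); the guideline span 0–8% is used instead.

One-way (tornado) analysis re-runs a strategy pair with each parameter at
its bounds and reports the pairwise ICER spread, top five by default. PSA
samples every Beta/Gamma parameter independently (no correlation structure
is specified by the sources), re-runs all strategies per draw (default
2,000 draws), and summarises cost-effectiveness acceptability curves as the
per-WTP fraction of draws in which a strategy attains the strictly highest
net monetary benefit `wtp x QALY - cost`, with exact ties split equally.
The default WTP grid spans 0–3x per-capita GDP (17,324 USD) in GDP/20
steps. The acceptance threshold search bisects the direct-colonoscopy
acceptance rate on [0, 1] until cumulative CRC deaths match the
ideal-sequential target within 0.5 deaths (at most 40 iterations); deaths
are exactly linear in acceptance (the arm is a mixture of full uptake and
no screening), so the root is unique.

## Synthetic screening-cohort generator

No individual-level screening records are distributed, so
`crcscreen.screening` generates synthetic ones reproducing the programme's
printed structure: the joint distribution of questionnaire class x FIT
positives uses the published cell counts out of 175,550 screened; per-cell
colonoscopy acceptance (26.3/41.3/65.7% for high-score with 0/1/2 FIT
positives, 46.8/62.3% for low-score with 1/2), 2.7% CRC yield among
colonoscoped high-risk participants (decliners harbour cancer at the same
rate, tagged `undetected`), and a 65.5/34.5/0 stage mix for detected
cancers. High risk is the union of score >= 5 and >= 1 FIT positive.
The generator emulates marginal rates only: it has no within-person
correlation between questionnaire items, no age/sex structure linked to
cancer risk, and no behavioural model of acceptance. Tests that recover its
rates therefore validate the estimation pipeline and the printed-rate
calibration, not real-world screening behaviour.

## Known limitations and divergences from the published figures

- Under these inputs, both screening strategies are **cost-saving** relative
  to no screening (averted and earlier-treated cancers save more than the
  screening costs), so their ICERs are negative (dominant) rather than the
  published 19,335/27,379 USD per QALY, and the acceptability curves favour
  colonoscopy from a very low WTP upward. The published incremental cost of
  1,078 USD per capita at full colonoscopy uptake is several times the
  195-USD one-off colonoscopy price and cannot arise from a single baseline
  screen with treatment-cost offsets under any convention we examined.
- The no-screening cumulative CRC death count over the 10-year window is
  ~7,800 here versus the published 2,147; the published count is about half
  of what the published incidence (0.002/yr) and self-referred case fatality
  (46.4% at 10 years) jointly imply, before even counting prevalent cases.
  The ratio-based quantities (averted-death fractions, acceptance threshold)
  are far less sensitive to this level mismatch and do reproduce.
- Colonoscopy complications, adenoma natural history, repeat screening
  rounds and individual-level microsimulation are out of scope.
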