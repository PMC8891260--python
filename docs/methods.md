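# Methods

## Scope and model structure

`vaxtea` is a techno-economic model of vaccine drug-substance (DS)
manufacturing for three platform technologies: adenovirus-vectored (AVV)
vaccines produced in mammalian cell culture, and mRNA and self-amplifying
RNA (saRNA) vaccines produced by cell-free in-vitro transcription with
lipid-nanoparticle formulation. It deliberately replaces unit-operation
flowsheet simulation with a *lumped batch model*: one production line is
characterised by a batch cycle time, annual operating days, a working
volume and a net titre, and everything downstream of the bioreactor is
absorbed into the titre (which is defined net of purification recovery
losses) and into calibrated cost constants. This keeps every KPI an
explicit, auditable arithmetic chain while reproducing the published
behaviour of far more detailed process simulations at the design medians.

The eight KPIs per scenario are CapEx, OpEx, batches/yr, amount/batch,
amount/yr, doses/batch, doses/yr and cost/dose; specific productivity
(doses yr⁻¹ per litre of working volume) and time-to-target are carried
alongside.

## Uncertainty model

Each platform has six (AVV) or seven (RNA; the 5' cap analogue price does
not apply to AVV) independent uncertain factors. Factors with a credible
most-likely value are triangular with that value as mode; the batch
failure rate (0–15% AVV, 0–10% RNA) and the QC/QA cost share of labour
(30–80%) are uniform. Scenario designs map Sobol low-discrepancy points
through each factor's analytic inverse CDF, column by column, preserving
a fixed factor order. The unscrambled sequence skips its first (all-zero)
point; Owen scrambling with a recorded seed gives statistically
independent replicates of the design. All generator metadata (sequence,
n, skip, scramble, seed) is stored with the design and in the run
manifest, so any run is bit-reproducible.

The **baseline scenario** is each triangular factor at its mode and each
uniform factor at its midpoint (AVV: 2000 L, 2.5×10¹⁴ vp/L, 5×10¹⁰
vp/dose, 7.5% failure, 23 USD/h, QC 55%; mRNA: 30 L, 5 g/L, 30 µg; saRNA:
5 L, 5 g/L, 1 µg).

## Production model

Batch starts per year B = operating days / cycle time × parallel lines;
released batches are B(1−f). Failure discards whole lots (cGMP batch
rejection), so product and doses scale with released batches while
materials cost scales with starts. Batch counts and years are fractional
campaign averages — no integer rounding — matching the linear-
extrapolation stance of the capacity projections. Time-to-target excludes
QC lead times. Scenarios with zero output (f = 100%) carry `inf`
time/cost values and are flagged, never silently dropped.

## Cost model

- **CapEx**: power law in working volume, exponent 0.6 (six-tenths rule),
  per-platform reference points (167.6 M USD @ 2000 L AVV; 103.7 M @ 30 L
  mRNA; 28.6 M @ 5 L saRNA — the two RNA curves nearly coincide, as they
  should for near-identical facilities).
- **Fixed OpEx**: annualised CapEx (10-yr straight line + 4%/yr
  maintenance, folded into OpEx) + 2%/yr facility overhead + labour
  (crew × sampled basic rate × 8760 h coverage; crews of 60/20/15 for
  AVV/mRNA/saRNA) × (1 + sampled QC share).
- **Variable OpEx**: RNA materials are costed per gram of RNA started
  (cap analogue at 0.3 g per g RNA at its sampled price, plus a lumped
  10,280 USD/g for nucleotides, plasmid template, enzymes and the four
  LNP lipids); AVV materials at 587 USD per litre of culture per batch.
  Ionisable-lipid license fees are explicitly out of scope.

This structure reproduces the qualitative cost signatures: at baseline,
AVV OpEx is >50% fixed (facility + labour dominated) while mRNA OpEx is
>50% variable (materials dominated), which is why idle RNA surge capacity
is cheap to hold and idle AVV capacity is not.

## Fill-to-finish

Lines are specified by container rate, doses per container, OEE and
container cost: 400 containers/min at 60% OEE for vial lines (a 10-dose
vial line thus fills ≈1.26 B doses/yr), with continuous 525,600 min/yr
scheduling and OEE absorbing all downtime. The nameplate rate is
per *container*; the published figures are ambiguous between doses/min
and vials/min for the 10-dose line, so the unit is explicit in config.
Combined DS + fill trains run at min(DS rate, fill rate), ties to DS. At
baseline, AVV is DS-limited while one saRNA line swamps a 5-dose vial
line — the bottleneck shifts to fill-finish, which is also the dominant
saRNA cost component (vial consumables at 1.79 USD/container split over
5 doses).

## Sensitivity analysis

Pick-freeze estimation with blocks A and B drawn as disjoint column
halves of one 2d-dimensional Sobol stream and d column-substituted cross
blocks, N(d+2) model evaluations. Jansen (1999) estimators for both Sᵢ
and Sₜ (lowest variance among the common forms); percentile bootstrap
(1000 resamples, seeded, in memory-bounded blocks) for CIs and standard
errors. Constant outputs are flagged undefined rather than returning
spurious indices; negative point estimates are clipped to zero only in
display tables. On the Ishigami benchmark (a=7, b=0.1) at N=2¹³ the
estimates agree with the closed-form indices within three bootstrap
standard deviations in under a second.

The RS-HDMR surrogate expands each KPI as f₀ + Σᵢ fᵢ(xᵢ) (+ optional
pairwise terms) in orthonormal shifted-Legendre polynomials on the unit
cube, fitted by least squares with a ≥10×-coefficients sample-size guard
and a rank check. Component-function variances give surrogate-based Sᵢ;
quality is always reported as R² on held-out scenarios (1250 by
convention). Cubic per-factor bases (the default for index estimation)
cap held-out R² at ≈0.89 for doses/yr, because that KPI is reciprocal in
the dose amount over a 30-fold range; a 5th-order basis with pairwise
terms exceeds R² = 0.9 and is what the surrogate-quality check uses.

## Capacity projections

Linear extrapolation: lines needed = target / per-line doses/yr
(fractional; an integer-lines mode exists but is excluded from headline
figures), and scale, batches, CapEx and OpEx multiply exactly by the line
count. Economy of scale is deliberately suppressed here — the sampled
processes are already large, and supplier constraints counteract further
scale economies. Per-line scale is sampled from the uncertainty model
(the line count, not the line size, is solved for). Booster demand
arithmetic: (2.2 B vulnerable + 0.2 B frontline) × doses per person;
default targets 1 B, 2.4 B and 11.3 B doses/yr.

## Calibration

Four groups of constants are not first-principles quantities and were
fixed *once* against published median anchors, then frozen in
`data/platforms.yaml` (`scripts/calibrate.py` re-derives them):

1. **Batch cycle times** (AVV 14.67 d; mRNA 0.760 d; saRNA 0.642 d at
   330 operating days/yr): the median time-to-1B-doses and the median
   specific productivity each imply a batch rate; they agreed within ~1%
   per platform and the geometric mean was kept. The AVV cycle reflects
   its mammalian seed-train bottleneck; the sub-day RNA cycles reflect
   cell-free synthesis with parallelised LNP formulation.
2. **Reference CapEx** per platform, from median CapEx to supply 1e9
   doses/yr.
3. **RNA per-gram materials**, from the median mRNA OpEx at 1e9 doses/yr.
4. **Vial consumable cost and AVV per-litre materials**, from the saRNA
   and AVV baseline cost-per-dose anchors (0.39 and 0.54 USD/dose).

## What the synthetic designs do and do not show

The scenario generator *is* the study's uncertainty model: it reproduces
the stated ranges, shapes and independence of the input factors, and the
quasi-random designs used for all distribution summaries. It does not
emulate real-world features outside that model — correlated factors
(e.g. scale–titre co-movement), time-varying prices, learning curves,
campaign changeovers, or supply disruptions. Passing the distribution-
median checks therefore validates the model's functional form and
calibration, not any forecast about a particular facility.

## Known limitations

- The published record this model is anchored to is not fully
  self-consistent on the mRNA cost side: its design-median OpEx for 1e9
  doses/yr (~720 M USD/yr, reproduced here) and its baseline
  2.39 USD/dose figure cannot both hold in a linear-extrapolation cost
  model (this model's baseline mRNA cost is ≈0.75 USD/dose). The
  production-side anchors were preferred; the corresponding acceptance
  check is knowingly left failing rather than forcing both.
- For the same reason the AVV baseline cost anchor (0.54 USD/dose,
  reproduced) pins AVV materials at a level that puts the AVV
  1e9-doses/yr OpEx median near 340 M USD/yr, above the published
  ~112 M; all inter-platform orderings are unaffected.
- Required AVV *batch counts* at 1e9 doses/yr come out near 22/yr, below
  the published ~47/yr, which implies per-batch volumes smaller than the
  sampled scale distribution itself; the scale, CapEx and time anchors
  were preferred.
- Quantiles use linear interpolation between order statistics throughout;
  median/IQR are always computed on full samples, with 5%/95% trimming
  applied only to plotting exports.
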