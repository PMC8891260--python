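# vaxtea

Techno-economic assessment of pandemic vaccine manufacturing platforms
under uncertainty.

`vaxtea` models drug-substance (DS) production of the three genetic
vaccine platforms deployed against COVID-19 — adenovirus-vectored (AVV)
vaccines made in mammalian cell culture, and messenger RNA (mRNA) and
self-amplifying RNA (saRNA) vaccines made by cell-free in-vitro
transcription — and asks the questions that matter to manufacturers and
policymakers: how fast can one production line make a billion doses, what
does a dose cost, which uncertain process parameters drive those answers,
and what capital, scale and batch throughput would a multi-billion-dose
annual demand require.

## The model

Each platform is a lumped batch process. With working volume *V* [L], net
titre *T* (product per litre, net of downstream recovery), batch failure
rate *f*, dose amount *D*, and *B* batch starts per year (operating days /
batch cycle time), the physical KPI chain is

```
amount/batch = V·T          doses/yr = V·T·B·(1−f)/D
specific productivity = doses/yr / V          time to target = target/doses-per-yr
```

Costs follow a power law for capital investment, CapEx(V) = CapEx_ref ·
(V/V_ref)^0.6, with annualised CapEx (10-year straight line + 4%
maintenance) folded into fixed OpEx together with labour, the QC/QA charge
and facility overhead. Variable OpEx is materials and accrues over batch
*starts* — a failed cGMP batch still consumes its raw materials. Fill-to-
finish lines (5/10-dose vials, blow-fill-seal, 200-dose bags) add their
own throughput limit, container consumables and line costs.

Uncertainty in six (AVV) or seven (RNA) input factors — scale, failure
rate, titre, 5' cap analogue price (RNA only), labour rate, dose amount,
QC cost — is described by triangular/uniform distributions and propagated
through the model with Sobol quasi-random designs. Variance-based global
sensitivity analysis attributes each KPI's variance to the factors:
first-order (Sᵢ) and total-effect (Sₜ) Sobol indices via the Jansen
pick-freeze estimators with bootstrap confidence intervals, plus an
RS-HDMR polynomial metamodel (orthonormal shifted-Legendre bases) as a
validated fast surrogate.

## Worked example

Resources for one billion AVV doses per year, over a 10,000-scenario
quasi-random design:

```
$ vaxtea project --platform avv --n 10000 --seed 1 --out out/
avv @ 1e+09 doses/yr (medians): scale 6509 L, batches 22.27/yr, CapEx 355.2 M USD, OpEx 341.7 M USD/yr
```

Read: at the median uncertainty scenario, supplying 1 B doses/yr of AVV
drug substance needs about 6,500 L of bioreactor working volume (several
2,000 L-class lines) and roughly a third of a billion USD of capital —
the AVV platform is by far the most capital- and scale-intensive of the
three. The same command for `sarna` yields a median of ~1.4 L and ~5 M
USD: the tiny saRNA dose amount shrinks the whole facility by three
orders of magnitude.

Sensitivity analysis (`vaxtea gsa --platform avv ...`) shows AVV annual
dose output is driven by production scale (Sᵢ ≈ 0.55), then titre
(≈ 0.23), then dose amount (≈ 0.09), while for the RNA platforms the RNA
amount per dose dominates — and Sₜ ≈ Sᵢ throughout, i.e. factor
interactions are minor.

The full pipeline (design → KPIs → GSA → projections → summaries +
manifest) is `vaxtea report --platform mrna --n 10000 --seed 0 --out out/`.

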