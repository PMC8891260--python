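# Platform configuration: uncertain input factors, lumped batch-scheduling
# constants, cost-model constants and fill-to-finish line specifications.
#
# Factor rows mirror the study's uncertainty model: triangular factors carry
# their most-likely value as `mode`; failure rate and QC cost are uniform.
# Titres are net of downstream recovery losses, so no separate recovery
# factor exists.  Factor order is fixed — sensitivity indices are reported
# per factor position.
#
# Calibration constants (batch cycle times, reference CapEx, material unit
# costs) are lumped stand-ins for flowsheet-level detail; they were fixed
# once so that baseline and design-median outputs land on published
# industrial anchors, and are not meant to be edited independently of that
# calibration.

shared:
  operating_days: 330        # days/yr of cGMP production
  staffed_hours: 8760        # annual staffed coverage hours per crew member
  annualisation_years: 10    # straight-line CapEx depreciation
  maintenance_frac: 0.04     # annual maintenance, fraction of CapEx
  overhead_frac: 0.02        # facility overhead, fraction of CapEx per year
  capex_exponent: 0.6        # six-tenths power-law scaling of CapEx

platforms:
  avv:
    amount_units: viral particles
    dose_unit_scale: 1.0           # dose sampled in vp, amounts tracked in vp
    batch_cycle_days: 14.67         # mammalian seed train + production + downstream
    parallel_lines: 1
    crew_per_line: 60
    capex_ref_musd: 167.6          # one line at the reference scale below
    capex_ref_scale_l: 2000
    materials:
      kind: per_litre_batch
      usd_per_litre_batch: 587.0   # media, consumables, resins per L culture per batch
    factors:
      - {name: scale, units: L, dist: triangular, low: 1000, mode: 2000, high: 20000}
      - {name: failure_pct, units: "%", dist: uniform, low: 0, high: 15}
      - {name: titre, units: vp/L, dist: triangular, low: 1.0e+14, mode: 2.5e+14, high: 7.0e+14}
      - {name: labour_rate, units: USD/h, dist: triangular, low: 5, mode: 23, high: 30}
      - {name: dose_amount, units: vp/dose, dist: triangular, low: 2.2e+10, mode: 5.0e+10, high: 6.5e+10}
      - {name: qc_pct, units: "% of labour", dist: uniform, low: 30, high: 80}

  mrna:
    amount_units: g
    dose_unit_scale: 1.0e-06       # dose sampled in µg, amounts tracked in g
    batch_cycle_days: 0.760         # cell-free IVT with parallelised LNP formulation
    parallel_lines: 1
    crew_per_line: 20
    capex_ref_musd: 103.7
    capex_ref_scale_l: 30
    materials:
      kind: per_gram
      other_usd_per_g: 10280.0     # nucleotides, plasmid, enzymes, LNP lipids per g RNA
      cap_usage_g_per_g: 0.3       # co-transcriptional capping stoichiometry
    factors:
      - {name: scale, units: L, dist: triangular, low: 2, mode: 30, high: 200}
      - {name: failure_pct, units: "%", dist: uniform, low: 0, high: 10}
      - {name: titre, units: g/L, dist: triangular, low: 3, mode: 5, high: 7}
      - {name: cap_price, units: USD/g, dist: triangular, low: 2500, mode: 3000, high: 10000}
      - {name: labour_rate, units: USD/h, dist: triangular, low: 5, mode: 23, high: 30}
      - {name: dose_amount, units: µg/dose, dist: triangular, low: 5, mode: 30, high: 150}
      - {name: qc_pct, units: "% of labour", dist: uniform, low: 30, high: 80}

  sarna:
    amount_units: g
    dose_unit_scale: 1.0e-06
    batch_cycle_days: 0.642
    parallel_lines: 1
    crew_per_line: 15
    capex_ref_musd: 28.6
    capex_ref_scale_l: 5
    materials:
      kind: per_gram
      other_usd_per_g: 10280.0
      cap_usage_g_per_g: 0.3
    factors:
      - {name: scale, units: L, dist: triangular, low: 0.5, mode: 5, high: 50}
      - {name: failure_pct, units: "%", dist: uniform, low: 0, high: 10}
      - {name: titre, units: g/L, dist: triangular, low: 3, mode: 5, high: 7}
      - {name: cap_price, units: USD/g, dist: triangular, low: 2500, mode: 3000, high: 10000}
      - {name: labour_rate, units: USD/h, dist: triangular, low: 5, mode: 23, high: 30}
      - {name: dose_amount, units: µg/dose, dist: triangular, low: 0.1, mode: 1, high: 10}
      - {name: qc_pct, units: "% of labour", dist: uniform, low: 30, high: 80}

fill_finish:
  vial10:
    technology: multi-dose vial
    doses_per_container: 10
    containers_per_minute: 400
    oee: 0.6
    operating_minutes: 525600
    cost_per_container: 1.79
    capex_musd: 15.0
    operating_musd_per_year: 1.0
  vial5:
    technology: multi-dose vial
    doses_per_container: 5
    containers_per_minute: 400
    oee: 0.6
    operating_minutes: 525600
    cost_per_container: 1.79
    capex_musd: 15.0
    operating_musd_per_year: 1.0
  bfs1:
    technology: blow-fill-seal single-dose
    doses_per_container: 1
    containers_per_minute: 700
    oee: 0.6
    operating_minutes: 525600
    cost_per_container: 0.30
    capex_musd: 12.0
    operating_musd_per_year: 0.8
  bag200:
    technology: 200-dose bag
    doses_per_container: 200
    containers_per_minute: 6
    oee: 0.6
    operating_minutes: 525600
    cost_per_container: 150.0
    capex_musd: 20.0
    operating_musd_per_year: 1.2
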