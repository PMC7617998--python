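# Demo configuration for `modyburden run-all`.
# Scaled-down two-cohort study (600 panel cases vs 4,000 genome controls)
# over the default six-gene set; completes in seconds on one CPU.
n_case: 600
n_control: 4000
seed: 1
case_mode: panel
control_mode: wgs
grid: full            # primary | full (adds MAF tiers, MAC=1, domain and NMD scopes)
freq_source: reference  # reference (AC_*/AN_* INFO fields) | control cohort
pedigrees:
  n_families: 3
  penetrance: 0.9
  phenocopy_rate: 0.02
credibility:
  prevalence: 2.48e-4   # MODY: 248 cases per million
  penetrance: 0.5
  max_allelic_contribution: 1.0
  max_genetic_contribution: 1.0
power:
  mafs: [5.0e-5, 1.0e-4, 2.0e-4]
  odds_ratios: [5.0, 9.8, 14.5, 21.0]
  n_reps: 2000
  alpha: 0.05
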