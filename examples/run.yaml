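# Full desk-scale study: pharmacovigilance screen + drug-target MR +
# mediation + SMR/HEIDI, all from synthetic presets.
seed: 7
outdir: mrpv_run
pv:
  scenario: headline        # 200k reports, suicide-SMQ OR 1.65 in weight-loss stratum
  n_reports: 200000
  targets: [glp1_ra]
  level: SMQ
  scope: narrow
  stratum: {indication: weight_loss}
  controls:
    venlafaxine: {suicide_self_harm: true}
    sitagliptin: {suicide_self_harm: false}
genetics:
  scenario: independent     # 22 strong cis instruments
  theta: -0.14618           # ln(0.864): protective effect on the outcome
  outcome_name: suicide
mediation:
  enabled: true
  proportion: 0.18
smr:
  enabled: true
  mode: causal
thresholds:
  p_max: 5.0e-8
  eaf_min: 0.01
  r2_max: 0.01
  f_min: 10
  min_cases: 3
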