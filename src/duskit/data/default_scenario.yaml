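# Default scenario configuration.  Every "paper-gap" parameter choice of the
# package lives here so the defaults are auditable in one file.
scenario: aerobic          # pilot | aerobic | anaerobic | knockout_panel | polysome
seed: 1
n_trnas: 20
baseline_occupancy: 0.90   # assumed wild-type occupancy at every annotated D site
replicates: 3              # biological replicates per condition (knockout_panel preset uses 5)
paraquat_mM: [0.0, 0.1, 0.3]
strains: [WT]
aerobic: true
sensitivity:               # activity retained under aerobic paraquat, per enzyme
  DusA: 1.00
  DusB: 0.60
  DusC: 0.40
aas_params:
  molecules_per_trna: 2000
  alk_cleavage_prob: 0.10        # P(scission | site modified)
  background_break_rate: 0.001   # residual ligatable hydrolysis breaks per bond
  terminal_ligatable_rate: 0.10  # residual mature 5'-P escaping dephosphorylation
  read_len: 50
  min_fragment_len: 15
lcms_params:
  scale: 1000.0
  noise_cv: 0.05
  noise_floor_frac: 0.003
f3_shift: 1.0              # polysome scenario: F3 occupancies relative to F0
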