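# Glucose minimal medium for the iJO1366 E. coli reconstruction.
# Positive uptake magnitudes; unlisted exchanges are closed for uptake.
# Mirrors the BiGG snapshot defaults shipped with the reconstruction:
# glucose capped at 10 mmol/gDW/h, cobalamin trace-limited, minerals and
# gases effectively unbounded.  Oxygen availability is governed by the
# aerobic flag.
name: glucose-minimal-iJO1366
aerobic: true
oxygen_exchange: EX_o2_e
exchanges:
  EX_glc__D_e: {uptake: 10, secretion: unbounded}
  EX_o2_e: {uptake: 1000, secretion: unbounded}
  EX_nh4_e: {uptake: 1000, secretion: unbounded}
  EX_pi_e: {uptake: 1000, secretion: unbounded}
  EX_so4_e: {uptake: 1000, secretion: unbounded}
  EX_h2o_e: {uptake: 1000, secretion: unbounded}
  EX_h_e: {uptake: 1000, secretion: unbounded}
  EX_co2_e: {uptake: 1000, secretion: unbounded}
  EX_k_e: {uptake: 1000, secretion: unbounded}
  EX_na1_e: {uptake: 1000, secretion: unbounded}
  EX_cl_e: {uptake: 1000, secretion: unbounded}
  EX_ca2_e: {uptake: 1000, secretion: unbounded}
  EX_mg2_e: {uptake: 1000, secretion: unbounded}
  EX_fe2_e: {uptake: 1000, secretion: unbounded}
  EX_fe3_e: {uptake: 1000, secretion: unbounded}
  EX_cu2_e: {uptake: 1000, secretion: unbounded}
  EX_mn2_e: {uptake: 1000, secretion: unbounded}
  EX_zn2_e: {uptake: 1000, secretion: unbounded}
  EX_mobd_e: {uptake: 1000, secretion: unbounded}
  EX_ni2_e: {uptake: 1000, secretion: unbounded}
  EX_cobalt2_e: {uptake: 1000, secretion: unbounded}
  EX_sel_e: {uptake: 1000, secretion: unbounded}
  EX_slnt_e: {uptake: 1000, secretion: unbounded}
  EX_tungs_e: {uptake: 1000, secretion: unbounded}
  EX_cbl1_e: {uptake: 0.01, secretion: unbounded}
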