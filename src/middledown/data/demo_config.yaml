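# Demo run: GluC histone H3 1-50 tails, five-component mixture under
# heavy-methyl (13CD3) labeling.  Includes an isobaric K9me2/K14me2 pair
# (co-isolated and FIRR-split), a hybrid heavy-methyl mark and a doubly
# modified form.  Noise-free so the pipeline recovers the ground truth
# exactly.  One label channel per experiment, as in practice: heavy-KR
# and heavy-methyl labeling are separate workflows.
tail:
  name: H3_1_50
  residues: ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALRE
  first_position: 1
  cleavage_context: GluC after E50, 0 missed cleavages
modifiable_sites: [4, 8, 9, 14, 18, 23, 26, 27, 36]
mod_rules:
  K: [me1, me2, me3, ac]
  R: [me1, me2]
label_scheme:
  sequence_channel_enabled: false
  methyl_channel_enabled: true
search:
  precursor_tol: 2.1
  fragment_tol_search: 0.01
  fragment_tol_filter_ppm: 30.0
  isobaric_window: 0.05
  max_mods: 9
  max_candidates: 200000
simulate:
  seed: 7
  base_intensity: 1000.0
  charge: 8
  noise: {intensity_cv: 0.0, dropout: 0.0, mass_jitter_ppm: 0.0}
  components:
    - ["", light, 0.20]
    - [K9me2, light, 0.30]
    - [K14me2, light, 0.20]
    - [K27me3:1, light, 0.18]
    - [K14acK27me2:2, light, 0.12]
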