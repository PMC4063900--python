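# Demo pipeline: synthetic before/after spectra of amyloid-beta 1-40 dimers.
#
# Window "dim8" reproduces the appearance, after the cross-linking reaction,
# of a covalent 8+ dimer at a longer drift time (7.17 ms) than the
# non-covalent 8+ dimer (6.28 ms), with the -2 Da di-tyrosine mass shift.
# Window "dim5" shows the other signature: no new drift feature, only a
# population shift of the 5+ dimer toward its compact conformer, quantified
# by the shared-center Gaussian decomposition.

sequence: default          # human A-beta 1-40
convention: physical
seed: 7
mz_step: 0.02              # Th
drift_step: 0.05           # ms
mz_sigma: 0.02             # Th
noise_sd: 0.005            # fraction of the window maximum
tolerance: 1.0             # Da, species-assignment tolerance
match_tolerance: 0.5       # Da, bond-count tolerance on the mass shift
n_max: 4
z_max: 12

calibration:
  demo: {c: 53.1, x: 0.652, t_min: 6.0, t_max: 17.0}

windows:
  - name: dim8
    mz_range: [1078.0, 1090.0]
    drift_range: [4.5, 10.0]
    species:
      before:
        - {n: 2, k: 0, z: 8, drift: [[6.28, 0.25, 1.0]], intensity: 1.0}
      after:
        - {n: 2, k: 0, z: 8, drift: [[6.28, 0.25, 1.0]], intensity: 0.55}
        - {n: 2, k: 1, z: 8, drift: [[7.17, 0.25, 1.0]], intensity: 0.8}
    analyses:
      - {conditions: [before, after], drift_gate: [5.7, 6.8]}
      - {conditions: [after], drift_gate: [6.85, 7.9]}
    decompose: false

  - name: dim5
    mz_range: [1729.0, 1737.0]
    drift_range: [5.0, 13.0]
    species:
      before:
        - {n: 2, k: 0, z: 5, drift: [[7.39, 0.35, 0.35], [10.40, 0.45, 1.0]], intensity: 1.0}
      after:
        - {n: 2, k: 1, z: 5, drift: [[7.39, 0.35, 1.0], [10.40, 0.45, 0.45]], intensity: 1.0}
    analyses:
      - {conditions: [before, after], drift_gate: [6.6, 8.2]}
    decompose: {n_components: 2}
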