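targets:
- name: steroid_A
  parent_mz: 289.2
  fragment_mz: 97.0
- name: steroid_B
  parent_mz: 305.2
  fragment_mz: 109.0
- name: steroid_C
  parent_mz: 331.2
  fragment_mz: 97.0
- name: steroid_D
  parent_mz: 347.2
  fragment_mz: 121.0
- name: steroid_E
  parent_mz: 363.2
  fragment_mz: 309.0
- name: steroid_F
  parent_mz: 409.3
  fragment_mz: 267.0
parameters:
- name: gradient_time
  minimum: 4.0
  maximum: 16.0
  step: 3.0
  unit: min
- name: spray_voltage
  minimum: 3.0
  maximum: 5.0
  step: 0.5
  unit: kV
- name: source_temp
  minimum: 350.0
  maximum: 550.0
  step: 50.0
  unit: degC
ga:
  archive_capacity: 100
  initial_runs: 20
  runs_per_generation: 2
  max_runs: 200
  crossover_prob: 0.9
  mutation_prob: null
  grid_divisions: 8
  seed: 0
  memoize: false
detection:
  mz_tolerance: 0.5
  smoothing_width: 5
  snr_threshold: 3.0
  min_points_across_peak: 5
  boundary_fraction: 0.05
objectives:
- analysis_time
- n_detected
- total_area
peak_algorithm: simple
output_dir: campaign_output
instrument:
  kind: simulated
  model:
    analytes:
    - name: steroid_A
      parent_mz: 289.2
      fragment_mz: 97.0
      base_rt: 1.1
      base_height: 90000.0
    - name: steroid_B
      parent_mz: 305.2
      fragment_mz: 109.0
      base_rt: 1.55
      base_height: 75000.0
    - name: steroid_C
      parent_mz: 331.2
      fragment_mz: 97.0
      base_rt: 2.05
      base_height: 110000.0
    - name: steroid_D
      parent_mz: 347.2
      fragment_mz: 121.0
      base_rt: 2.6
      base_height: 60000.0
    - name: steroid_E
      parent_mz: 363.2
      fragment_mz: 309.0
      base_rt: 3.2
      base_height: 85000.0
    - name: steroid_F
      parent_mz: 409.3
      fragment_mz: 267.0
      base_rt: 3.9
      base_height: 50000.0
    rt_parameter: gradient_time
    rt_reference: 10.0
    sensitivity_curves:
    - analyte: steroid_A
      parameter: spray_voltage
      optimum: 3.0
      width: 0.5
    - analyte: steroid_B
      parameter: spray_voltage
      optimum: 3.5
      width: 0.5
    - analyte: steroid_C
      parameter: spray_voltage
      optimum: 4.0
      width: 0.5
    - analyte: steroid_D
      parameter: spray_voltage
      optimum: 4.5
      width: 0.5
    - analyte: steroid_E
      parameter: spray_voltage
      optimum: 5.0
      width: 0.5
    - analyte: steroid_F
      parameter: spray_voltage
      optimum: 5.5
      width: 0.5
    - analyte: steroid_A
      parameter: source_temp
      optimum: 350.0
      width: 120.0
    - analyte: steroid_B
      parameter: source_temp
      optimum: 350.0
      width: 120.0
    - analyte: steroid_C
      parameter: source_temp
      optimum: 450.0
      width: 120.0
    - analyte: steroid_D
      parameter: source_temp
      optimum: 450.0
      width: 120.0
    - analyte: steroid_E
      parameter: source_temp
      optimum: 550.0
      width: 120.0
    - analyte: steroid_F
      parameter: source_temp
      optimum: 550.0
      width: 120.0
    peak_sigma: 0.05
    noise_sd: 0.0
    sampling_interval: 0.01
    run_length_factor: 1.2
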