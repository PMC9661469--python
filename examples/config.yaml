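parameters:
  R_c: 5.0
  R_k: 155.0
  D_f: 9600.0
  D_b: 600.0
  P: 6.0
  f_u: 0.25
  V_bind: 10.0
  K_bind: 1.0
  k_unbind: 0.06
  V_up: 2.0
  K_up: 2.0
  k_eff: 0.0
  k_out: 1.0
  k_el: 0.02
  V_ratio: 0.02
  phi_i: 0.4
grid:
  n_cells: 200
scenario:
  mode: carrier_rapid
  dose: 3926.9908169872415
  f_seq: 0.6
output:
  times_min:
  - 0.0
  - 1.0
  - 2.0
  - 3.0
  - 4.0
  - 5.0
  - 6.0
  - 7.0
  - 8.0
  - 9.0
  - 10.0
  - 11.0
  - 12.0
  - 13.0
  - 14.0
  - 15.0
  - 16.0
  - 17.0
  - 18.0
  - 19.0
  - 20.0
  - 21.0
  - 22.0
  - 23.0
  - 24.0
  - 25.0
  - 26.0
  - 27.0
  - 28.0
  - 29.0
  - 30.0
  - 31.0
  - 32.0
  - 33.0
  - 34.0
  - 35.0
  - 36.0
  - 37.0
  - 38.0
  - 39.0
  - 40.0
  - 41.0
  - 42.0
  - 43.0
  - 44.0
  - 45.0
  - 46.0
  - 47.0
  - 48.0
  - 49.0
  - 50.0
  - 51.0
  - 52.0
  - 53.0
  - 54.0
  - 55.0
  - 56.0
  - 57.0
  - 58.0
  - 59.0
  - 60.0
  - 61.0
  - 62.0
  - 63.0
  - 64.0
  - 65.0
  - 66.0
  - 67.0
  - 68.0
  - 69.0
  - 70.0
  - 71.0
  - 72.0
  - 73.0
  - 74.0
  - 75.0
  - 76.0
  - 77.0
  - 78.0
  - 79.0
  - 80.0
  - 81.0
  - 82.0
  - 83.0
  - 84.0
  - 85.0
  - 86.0
  - 87.0
  - 88.0
  - 89.0
  - 90.0
  - 91.0
  - 92.0
  - 93.0
  - 94.0
  - 95.0
  - 96.0
  - 97.0
  - 98.0
  - 99.0
  - 100.0
  csv_path: simulation.csv
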