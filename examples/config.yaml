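# Desk-scale end-to-end run: vary carrying capacity and contact inhibition,
# transfer a Morris screening through the cell-cycle surrogate.
parameters:
  K_A: [500, 2400]
  T_con: [1, 7]
design:
  type: grid
  levels: 3
abm:
  n_replicates: 6
sm_candidates: [cellcycle]
gsa:
  method: moat
  mode: both          # direct ABM screening and the surrogate transfer
  metric: final       # total cell count at day 3
  n_mc: 100
  options: {r: 10, levels: 4}
seed: 11
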