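"""Calibration benchmark: false positive rate versus confounding strength.

Replicates the null experiment on a reduced scale: for each confounding
strength gamma, simulate many null datasets and count rejections at
alpha = 0.05. A calibrated test stays at 0.05 across the axis.
"""

import mrtwin as mt

grid = mt.ExperimentGrid(
    n_replicates=100,
    gammas=(0.0, 0.4, 0.8),
    methods=("mrtwin_trio", "ivw"),
    b_twins=100,
    base_config=mt.PopSimConfig(
        n_external=2000, n_families=200, m_snps=50, m_causal=25
    ),
    seed=5,
)
table = mt.run_fpr_experiment(grid)
print(table[["method", "gamma", "rejection_rate", "ci_low", "ci_high"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# mrtwin_trio stays near the nominal 0.05 at every gamma; IVW's false
# positive rate climbs with the confounding strength.
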