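"""Pick the upper-quantile threshold from at-risk vs healthy separation.

Scans q = 0.75..0.99: the group difference in mean per-sample UQ score
(effect size) grows with q because methylation gains in at-risk tissue are
outliers, but so does the bootstrap dispersion of the estimate. The chosen
threshold maximizes effect minus one dispersion unit.
"""

import stemtoc as st

cfg = st.SimStageConfig(seed=3)
for stage in cfg.stages:
    stage.n_samples = 60
beta, sheet, _ = st.simulate_stage_dataset(cfg)
groups = sheet.column("group")

curve = st.choose_uq_threshold(
    beta,
    beta.cpg_ids,
    at_risk_ids=groups.index[groups == "at_risk"].tolist(),
    healthy_ids=groups.index[groups == "normal"].tolist(),
    n_boot=200,
    seed=3,
)

print("q      effect   bootstrap-SE")
for q, e, d in zip(curve.quantile_grid[::4], curve.effect_size[::4], curve.dispersion[::4]):
    print(f"{q:.2f}   {e:+.4f}   {d:.4f}")
print(f"\nchosen threshold: q = {curve.chosen_q:.2f}")
print("-> effect size rises monotonically with q (stochastic outlier gains); "
      "the penalty keeps the choice away from the noisy extreme quantiles.")
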