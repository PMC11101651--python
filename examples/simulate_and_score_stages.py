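"""Staged carcinogenesis model: why an upper quantile beats the mean.

Simulates 20 CpGs across four disease stages (normal, at-risk,
preneoplastic, cancer; 200 samples each). Methylation gains hit a small,
sample-specific CpG subset, so the per-sample mean dilutes the signal while
the 95% upper quantile (taken nearest-rank-upper, i.e. the maximum over 20
CpGs) tracks the most advanced subclone.
"""

import stemtoc as st

cfg = st.SimStageConfig(seed=1)
for stage in cfg.stages:
    stage.n_samples = 200
beta, sheet, truth = st.simulate_stage_dataset(cfg)
groups = sheet.column("group")

uq_clock = st.build_clock(beta.cpg_ids, name="uq95")
mean_clock = st.build_clock(beta.cpg_ids, method="mean", name="mean")
uq = st.score_upper_quantile(beta, uq_clock, mode="nearest_upper").set_index("sample_id")
mean = st.score_mean(beta, mean_clock).set_index("sample_id")

print("mean UQ score per stage (should rise strictly):")
print(uq["score"].groupby(groups).mean().reindex(
    ["normal", "at_risk", "preneoplastic", "cancer"]).round(3).to_string())

sel = groups.isin(["normal", "at_risk"])
labels = (groups[sel] == "at_risk").to_numpy()
auc_uq = st.auc(uq.loc[groups[sel].index, "score"], labels)
auc_mean = st.auc(mean.loc[groups[sel].index, "score"], labels)
print(f"\nnormal vs at-risk AUC  upper-quantile: {auc_uq:.3f}   mean: {auc_mean:.3f}")
print("-> the UQ score separates healthy from at-risk tissue better than the "
      "mean because the altered CpG subset differs between subjects.")
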