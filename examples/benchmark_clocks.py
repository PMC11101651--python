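"""Benchmark several clock scoring schemes against each other.

Scores an age-drifting synthetic cohort with an upper-quantile clock, a
mean clock and a hypomethylation-style (1 - mean) clock over decoy CpGs,
then compares their age correlations and derives the division-rate
summaries (TNSC = intrinsic rate x age; RIR = median(score/age) x 10).
"""

import numpy as np
import pandas as pd

import stemtoc as st

beta, sheet, truth = st.simulate_cohort(
    n_samples=200, n_cpgs=500, n_planted=50, seed=11, name="colon"
)
ages = sheet.column("age").to_numpy()
planted = truth["planted"]
decoys = [c for c in beta.cpg_ids if c not in set(planted)][:50]

clocks = {
    "uq95": st.score_upper_quantile(beta, st.build_clock(planted, name="uq95")),
    "mean": st.score_mean(beta, st.build_clock(planted, method="mean", name="mean")),
    "hypo": st.score_one_minus_mean(
        beta, st.build_clock(decoys, method="one_minus_mean", name="hypo")),
}

print("clock   PCC(age)      p          RIR")
rows = {}
for name, table in clocks.items():
    scores = table["score"].to_numpy()
    res = st.correlate(ages, scores)
    rir = st.compute_rir(scores, ages)
    rows[name] = res.pcc
    print(f"{name:6s} {res.pcc:+.3f}   {res.p:10.2e}   {rir:.3f}")

tnsc = st.compute_tnsc({"colon": 10.0},
                       st.SampleSheet(sheet.data.assign(tissue="colon")))
print(f"\nTNSC for the oldest sample: {tnsc.max():.0f} divisions "
      f"(intrinsic rate 10/yr x age {ages.max():.0f})")

# paired comparison across three bootstrap "datasets" of the cohort
rng = np.random.default_rng(11)
cols = {}
for d in range(5):
    idx = rng.choice(len(ages), size=len(ages), replace=True)
    cols[f"d{d}"] = {
        name: st.correlate(ages[idx], table["score"].to_numpy()[idx]).pcc
        for name, table in clocks.items()
    }
mat = pd.DataFrame(cols)
res = st.compare_clocks(mat)
print("\none-tailed paired signed-rank p (row clock beats column clock):")
print(res.p_values.round(4).to_string())
print("-> clocks built on the truly mitotic CpGs track age; the decoy-based "
      "hypo clock does not.")
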