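# stemtoc

Mitotic-age analysis of DNA-methylation (DNAm) data: construction of a
stochastic epigenetic mitotic clock, upper-quantile scoring of relative
mitotic age, generative models of methylation drift, and a benchmarking
suite for comparing mitotic clocks.

## The problem

The cumulative number of stem-cell divisions a tissue has undergone — its
*mitotic age* — is a major determinant of cancer risk, and DNAm is a
practical molecular substrate for estimating it: certain promoter CpGs that
are unmethylated in the fetal ground state gain methylation with every cell
division. Two obstacles make this hard in bulk tissue. First, cell-type
heterogeneity and mere chronological aging both masquerade as mitotic
signal, so clock CpGs must be selected to respond to division count
specifically. Second, methylation gains in normal tissue at cancer risk are
*stochastic*: they appear at a small, subject-specific subset of the clock
CpGs (subclonal expansions), so averaging over the CpG set dilutes the
signal.

This package addresses both. Clock CpGs are selected by a three-stage
filter:

1. promoter CpGs (within 200 bp upstream of a TSS) with beta < 0.2 in every
   fetal/ground-state sample;
2. CpGs gaining DNAm with population doublings (OLS slope > 0, BH FDR
   q < 0.05) in **every** cultured cell line, but *not* gaining DNAm
   (unadjusted P < 0.05) with days in culture under mitomycin-C arrest or
   serum deprivation — decoupling division count from passage of time;
3. CpGs whose DNAm rises with age in vivo across several whole-blood
   cohorts after adjusting for 12 immune cell-type fractions, combined by
   the directional Stouffer method
   (z_i = sign(b_i) Φ⁻¹(1 − p_i/2), z = Σz_i/√k; keep z > 0, P < 0.05).

A sample's **relative mitotic age** is then the 95% upper quantile (UQ) of
its beta values over the selected CpGs — an order statistic that captures
the most advanced subclone where the mean does not. Comparator scoring
schemes (mean, 1 − mean for hypomethylation clocks, weighted linear) and
the evaluation statistics used to compare clocks (Pearson/Spearman age
correlation, AUC, one-tailed Wilcoxon rank-sum, paired signed-rank across
datasets, TNSC = intrinsic division rate × age, RIR = median(score/age) × 10)
are included.

## Worked example

`examples/simulate_and_score_stages.py` simulates the staged carcinogenesis
model — 20 CpGs whose baseline betas come from Beta(10, 90), with 1–3
(at-risk), 5–10 (preneoplastic) or 11–17 (cancer) randomly chosen CpGs per
sample redrawn from Beta(3, 7), Beta(5, 5) or Beta(8, 2) — and scores each
sample with the 95% UQ and with the mean:

```
mean UQ score per stage (should rise strictly):
group
normal           0.163
at_risk          0.370
preneoplastic    0.704
cancer           0.956

normal vs at-risk AUC  upper-quantile: 0.953   mean: 0.895
```

The UQ score rises strictly with disease stage and separates normal from
at-risk tissue better than the mean (AUC 0.95 vs 0.89), because the altered
CpG subset differs between subjects. The other examples cover the selection
pipeline on synthetic cell-line + cohort data (`select_mitotic_cpgs.py`:
recovery 0.94, false-discovery proportion 0.00 at default thresholds),
threshold selection (`choose_uq_threshold.py`), clock benchmarking
(`benchmark_clocks.py`) and matrix hygiene (`clean_and_impute.py`).

A thin CLI wraps the same functions:

```bash
stemtoc simulate stage --seed 1 --out sim/
stemtoc score --beta sim/beta.tsv --clock clock.json --out scores.tsv
stemtoc select --config pipeline.yaml --out selected/
stemtoc benchmark --scores scores.tsv --sheet sim/samples.tsv --out report/
```

Every command writes a `provenance.json` (version, parameters, seed, input
checksums); identical seeds give byte-identical outputs.

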