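# lipidmr

Mendelian-randomization (MR) analysis of blood-lipid risk factors for
coronary artery disease (CAD) from GWAS summary statistics.

MR uses genetic variants as instrumental variables: a SNP robustly
associated with an exposure (here LDL-cholesterol, HDL-cholesterol or
triglycerides, each in per-SD units) but influencing the outcome (CAD log
odds) only through that exposure identifies the causal effect even in the
presence of ordinary confounding.  The catch is *which* SNPs make valid
instruments, and what to do about pleiotropy — SNPs associated with two or
more of the lipid fractions, which can make a non-causal lipid look
causal.  `lipidmr` implements a complete pipeline for this problem:

* **Instrument selection** from merged lipid/CAD summary tables by three
  successive filters: the minimum exposure p-value
  (`P_vj ≤ P_v`, default 5e-08), sample-size proportions relative to the
  per-table maxima (`P_cj > P_c`, `P_dj > P_d` — keeping SNPs genotyped in
  nearly the full meta-analysis samples), and a minimum genomic spacing
  (adjacent interval length, AIL); plus a threshold-grid convergence scan
  that shows how the causal estimates move with the number of SNPs
  selected.
* **Allele harmonization** of all effect estimates to the CAD reference
  allele (the β table every estimator consumes), with palindromic SNPs
  flagged rather than silently resolved.
* **Pleiotropy dissection** of an instrument set into *unique*
  (single-exposure, a.k.a. restricted) and *shared* (≥ 2 exposures) SNPs,
  with full seven-region Venn accounting.
* **Estimators**: inverse-variance-weighted (IVW), MR-Egger (slope +
  directional-pleiotropy intercept), simple and weighted medians
  (bootstrap SEs), and multivariable MR (MVMR) — the weighted no-intercept
  regression of CAD log odds on all three exposures' effects jointly,
  reported as β, SE, p and odds ratio per 1 SD with 95% CI.
* **Null-embedding simulation**: a selected instrument set is embedded,
  one exposure at a time, into a simulated null GWAS background built from
  the mother data's moments, breaking all cross-exposure co-association;
  rerunning selection over a `P_c`–`P_d` grid yields a false discovery
  rate for the selection and pleiotropy-free MVMR estimates, averaged over
  replicates.
* **Synthetic data**: a generator for full mother datasets with known
  causal architecture (planted effects θ, configurable pleiotropy), so the
  entire pipeline runs and is tested with no downloads.

## Worked example

```python
from lipidmr import (SynthConfig, Thresholds, apply_thresholds,
                     build_beta_table, generate_mother_data, mvmr,
                     partition_table)

table, truth = generate_mother_data(SynthConfig(m=20_000), seed=42)
selected = apply_thresholds(table, Thresholds(p_v=5e-08), reference=table)
beta_table = build_beta_table(selected)
part = partition_table(beta_table, 5e-08)
print(len(selected), len(part.shared), len(part.unique))
print(mvmr(beta_table).to_frame()[["exposure", "beta", "se", "p", "or"]])
```

prints

```
338 83 255
exposure    beta     se     p      or
     ldl  0.3729 0.0106 0.000  1.4519
     hdl -0.2967 0.0092 0.000  0.7432
      tg -0.0005 0.0089 0.959  0.9995
```

The generator planted θ = (+0.4, −0.3, 0.0): MVMR recovers LDL as a risk
factor (OR ≈ 1.45 per 1 SD), HDL as protective (OR ≈ 0.74) and TG as
null.  `examples/` contains one narrative script per capability —
end-to-end pipeline, pleiotropy dissection (how shared SNPs fake a TG
effect), the null-embedding FDR simulation, the single-variable estimator
suite, and the threshold convergence scan — each printing its numbers
with a line on what they mean.  A thin CLI mirrors the stages:

```bash
lipidmr synth --m 20000 --seed 1 --out mother.tsv
lipidmr select --pv 5e-08 --pc 0.979 --pd 0.979 --in mother.tsv --out selected.tsv
lipidmr harmonize --in selected.tsv --out beta_table.tsv
lipidmr split --in beta_table.tsv --out-prefix part_
lipidmr mr --in beta_table.tsv --methods mvmr,ivw --out results.tsv
```

## Published instrument tables

The two real instrument sets analysed in the source study (338 SNPs
selected from metabochip lipid + CAD meta-analyses; 363 SNPs from the
joint-GWAS tables) are distributed as supplementary data with that study
and are not bundled here.  To run the corresponding acceptance checks,
convert them to the merged-table TSV layout (`snp_id`, `chrom`, `pos`,
then `beta_/se_/p_/n_/a1_/a2_{ldl,hdl,tg,cad}`) and place them at
`data/external/dataset_A.tsv` and `data/external/dataset_B.tsv`.
Arbitrary consortium tables are read with `read_trait_table` using the
shipped `"lipid"`/`"cad"` column dialects or an explicit mapping, and
merged with `merge_by_snpid`.
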