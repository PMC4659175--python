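# methsnp

**Do the CpG sites your methylation array calls "differentially methylated"
actually differ in methylation — or in genotype?**

Infinium-style BeadChip arrays (e.g. the HumanMethylation450 platform) infer
the methylation level of a CpG dinucleotide from hybridization and
single-base extension of 50-mer probes on bisulfite-converted DNA, reporting
per-sample beta values

&nbsp;&nbsp;&nbsp;&nbsp;β = signal_Meth / (signal_Meth + signal_Unmeth),&nbsp;&nbsp;&nbsp;&nbsp;M = log₂[β / (1 − β)]  (β clamped to [0.001, 0.999]).

A genomic SNP inside the interrogated CpG breaks the assay's chemistry in
position- and probe-type-specific ways: a C>T in the first CpG position is
indistinguishable from a converted unmethylated cytosine (type II probes
read it as "unmethylated"); any SNP in the second position mismatches the
probe's 3' end and blocks extension, collapsing both channel signals to
background — which *inflates* β, because the ratio of two background-level
signals sits mid-range. When the SNP's allele frequencies differ between the
compared groups — as they routinely do between human populations — these
artifacts masquerade as group differences in methylation.

`methsnp` is aimed at researchers running comparative methylation studies
(population, case/control, ancestry-stratified) who need to understand,
detect and simulate these artifacts. It provides:

* **`methsnp.chemistry`** — a mechanistic simulator of Infinium I/II probe
  chemistry: bisulfite conversion, probe design (including co-methylation of
  under-a-probe CpGs for type I, degenerate bases for type II),
  mismatch-dependent hybridization efficiency, channel-resolved signals —
  plus a hand-coded qualitative predicted-readout table that serves as the
  simulator's independent oracle.
* **`methsnp.cohort`** — a synthetic two-population cohort generator (HWE
  genotypes, per-allele methylation, lognormal signal noise, negative
  controls) with canonical scenario factories for the trimodal, bimodal,
  flattened-high and cloud beta patterns.
* **`methsnp.pipeline`** — the analysis chain: β/M computation, detection-p
  filtering, per-probe equal-variance Student's t-tests on M values with
  Benjamini–Hochberg FDR, effect-size categories (pop-diff: q < 0.05 and
  |M_av_diff| > 1), a global-methylation test and a 500-bp neighbor-probe
  scan.
* **`methsnp.pattern`** — a Gaussian-mixture classifier of per-probe beta
  distributions (trimodal / bimodal / flattened_high / cloud /
  clean_unimodal) with low-total-intensity flagging and genotype
  concordance scoring.
* **`methsnp.popgen`** — Hudson's two-population Fst and allele-frequency
  differentiation (MAF_diff).
* **`methsnp` CLI** — `simulate`, `analyze`, `classify`, `fst`, `report`,
  `neighbors` subcommands over TSV matrices and YAML configs.

## Worked example

Simulate the study design (18 + 18 samples) with one SNP-confounded locus —
a type II probe over a CpG whose first position carries a C>T SNP at
alternate-allele frequency 0.2 (EUR) vs 0.7 (EAS), CpG allele fully
methylated, **no methylation difference between populations** — and one
clean locus methylated at 0.3 in both populations:

```python
from methsnp.cohort import CohortConfig, scenario_trimodal, scenario_clean, simulate_cohort
from methsnp.pipeline import differential_methylation
from methsnp.pattern import classify_beta_pattern

cfg = CohortConfig(
    n_per_pop=18,
    loci=(scenario_trimodal(locus_id="cg_snp"),
          scenario_clean(locus_id="cg_clean", meth_by_pop={"EUR": 0.3, "EAS": 0.3})),
    seed=42,
)
res = simulate_cohort(cfg)
diff = differential_methylation(res.m_values, res.truth.sample_populations, beta=res.beta)
print(diff.round(3).to_string())
```

```
          m_av_EUR  m_av_EAS  beta_av_EUR  beta_av_EAS  m_av_diff      t     p      q  category
probe_id
cg_snp       2.384    -2.091        0.712        0.308      4.474  3.957  0.00  0.001  pop_diff
cg_clean    -1.110    -1.257        0.318        0.297      0.147  1.641  0.11  0.110        ns
```

The SNP-only locus is called **pop_diff** (q = 0.001, |M_av_diff| = 4.5 —
an apparent 40-percentage-point beta difference) although its methylation
truth is identical in both populations: the group means only track the
allele-frequency difference. The clean locus is correctly non-significant.
Inspecting *individual* beta values exposes the artifact:

```python
beta = res.beta.loc["cg_snp"].to_numpy()
totals = (res.signal_meth.loc["cg_snp"] + res.signal_unmeth.loc["cg_snp"]).to_numpy()
call = classify_beta_pattern(beta, totals, genotypes=res.truth.genotypes.loc["cg_snp"].to_numpy())
print(call.label, [round(m, 3) for m in call.cluster_means], call.genotype_concordance)
```

```
trimodal [0.027, 0.492, 0.974] 1.0
```

Three beta bands at ≈ 0, ½ and 1 whose membership matches the SNP genotype
perfectly (concordance 1.0) — the signature of a genomic polymorphism, not
of differential methylation. The `report` CLI subcommand combines the two
analyses into per-probe verdicts (`snp_confounded`, `suspect_genomic`,
`methylation_candidate`, ...).

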