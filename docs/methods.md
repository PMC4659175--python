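# Methods

## The chemistry model

One interrogated CpG is described by its top-strand context sequence (odd
length, default 101 nt, the CpG's C at the center), an optional SNP in the
first (C) or second (G) position of the dinucleotide, the offsets of any
additional CpGs under the probe footprint ("under-a-probe" CpGs), and the
methylation level of the CpG allele. Only the top strand is modelled; probes
are built against the reference allele over the footprint running from the
CpG downstream (type I: starting at the C, 3'-terminal base pairing the C;
type II: starting at the G, 3'-terminal base pairing the G, single-base
extension reading the C position).

Bisulfite conversion turns every cytosine outside a methylated CpG into T.
Type I M/U probes are reverse complements of the fully methylated /
unmethylated converted footprint — they differ at the 3' terminus and at
every base pairing an under-a-probe C, encoding the platform's
co-methylation assumption. The type II probe is built on the unmethylated
footprint with a degenerate purine R at under-a-probe C positions; R pairs
both the preserved C and the converted T at no penalty.

**Hybridization/extension efficiency** of a probe on a converted
single-chromosome template is a product over mismatches. A 3'-terminal
mismatch leaves residual efficiency `eps_terminal = 0.01` (extension
essentially blocked). An internal mismatch `d` bases from the 3' end
contributes `min(1, 0.02 · d²)`: destabilization is strongest at the
extension end and fades quadratically with distance, reaching no penalty at
`d ≥ 8`. The qualitative constraint this family must satisfy is fixed by
the predicted-readout table (below): a mismatch at the penultimate base
(second CpG position, `d = 1` → 0.02) or at under-a-probe CpGs within a few
bases of the 3' end must suppress the channel signal below the high/low
dichotomy threshold, while distal mismatches may be tolerated. A linear
family shallow enough to leave penultimate mismatches above ~0.25 would
violate that dichotomy, which is why the near-terminal penalties are steep;
both parameters are exposed in `ChemistryParams`.

**Signals.** Each of the two allele copies contributes `scale × efficiency`
to the channel selected by the chemistry — for type I, the M probe feeds the
methylated channel and the U probe the unmethylated one; for type II the
incorporated ddNTP decides (C/G → methylated "green", A/T → unmethylated
"red", reflecting that A and T labels are indistinguishable, as are C and
G). A fractional methylation level `m` mixes the methylated- and
unmethylated-template contributions linearly (`m·S_meth + (1−m)·S_unmeth`
per copy), i.e. a cell-population average; we deliberately did not model
per-copy Bernoulli methylation states, which would discretize beta into
spurious bands instead of the observed continuous spread. Per-channel
background `b` is added once, then each channel is multiplied by independent
lognormal noise `exp(N(0, sdlog²))`.

Defaults: `scale = 1000`, `background = 50`, `sdlog = 0.15` (arbitrary
units; the real platform reports normalized intensities on an arbitrary
scale, and these values put the background at 5 % of a full single-copy
signal with ~15 % multiplicative noise, giving beta spreads comparable to
the archetypal published per-probe distributions). `probe_len = 50` as on
the platform.

**The predicted-readout oracle.** `expected_readout` hand-codes the
qualitative (methylated, unmethylated) channel levels for every combination
of probe type × SNP position × substituting base × allele × methylation
state × under-probe context, independent of the simulator:

| probe | SNP | allele | readout |
|---|---|---|---|
| I or II | — | CpG, methylated | meth high, unmeth low |
| I or II | — | CpG, unmethylated | meth low, unmeth high |
| II | pos 1 C>T or C>A | alt | mimics unmethylated (A/T labels identical) |
| II | pos 1 C>G | alt | mimics methylated (C/G labels identical) |
| II | pos 2 any | alt | both low (3'-terminal mismatch, no extension) |
| I | pos 1 C>T | alt, under-probe CpGs unmethylated/absent | mimics unmethylated (U probe matches) |
| I | pos 1 C>T | alt, under-probe CpGs methylated | both low (U probe mismatched near 3' end) — the flattened case |
| I | pos 1 C>A or C>G | alt | both low (both probes terminally mismatched) |
| I | pos 2 any | alt | both low (converted TpN mismatches both probes at/near the terminus) |

An exhaustive test dichotomizes the noise-free, background-free homozygote
simulator output at `scale/2` and requires equality with this table for all
104 combinations.

## The cohort generator

Two populations (default "EUR"/"EAS", n = 18 each, matching the study
design the package emulates: two panels of unrelated male B-lymphocyte cell
lines) are simulated at a list of loci. Genotypes are drawn per population
under Hardy–Weinberg equilibrium (`Binomial(2, freq_alt)`), independently
across loci — linkage, inbreeding and batch effects are not modelled (the
emulated study detected no batch effect). Methylation truth is per locus
and population; optional between-sample variability draws each sample's
level from a Beta distribution with the population mean and a configurable
SD (this inter-individual heterogeneity is what produces cloud-like beta
patterns). Negative-control intensities (background-only beads) provide the
mean/SD for the detection-p model. Everything is driven by one
`numpy.random.Generator` seeded from the config, so equal seeds give
bit-identical matrices.

Canonical scenarios (defaults chosen as a realistic strongly differentiated
common SNP, MAF_diff = 0.5):

* **trimodal** — type II, pos-1 C>T, CpG allele methylated, freq_alt
  0.2/0.7: beta bands at ≈ 0.02 / 0.5 / 0.98 indexed by genotype.
* **bimodal** — type I, pos-2 G>A, methylated, freq_alt 0.1/0.6:
  heterozygotes are indistinguishable from CpG homozygotes (the only
  readable signal is from the M probe); alt homozygotes collapse to
  near-background totals with beta inflated to ≈ 0.35.
* **flattened_high** — type I, pos-1 C>T with three methylated
  under-a-probe CpGs at offsets +2/+4/+6: alt homozygotes lose both probes
  (M terminally, U at the under-probe CpGs near the 3' end), totals drop to
  near background and beta inflates to ≈ 0.45–0.55, so all values cluster
  mid-to-high. Three under-probe CpGs close to the terminus mirror the
  archetypal published example of this pattern.
* **cloud** — clean locus, mean methylation 0.5 with between-sample
  SD 0.2.

## The analysis pipeline

Beta uses offset 0 by default (the printed formula; the platform's
conventional +100 offset is available as an option). M clamps beta to
[0.001, 0.999], bounding |M| by log₂ 999 ≈ 9.96. The detection p-value of a
measurement is the upper-tail probability of its total intensity under a
normal model of negative-control totals; a probe fails when p > 0.01 in at
least one sample (the platform's own detection-p definition is not public;
this one-sided normal model is this package's choice). Per-probe testing is
a two-sided equal-variance Student's t on M values — "Student's t-test"
taken literally; Welch is available behind `equal_var=False` — followed by
Benjamini–Hochberg step-up (the canonical FDR procedure), which is verified
in the tests against an independent brute-force implementation.
Categories: `pop_diff` (q < 0.05 and |M_av_diff| > 1, roughly a 20-point
beta difference), `weak_diff` (q < 0.05 and |M_av_diff| between a
configurable floor — 0.3 in the reference configuration — and 1), else
`ns`. Zero-variance probes with equal means get p = 1 by convention, with a
logged count; missing beta values are excluded from per-sample global means
and their count logged. The global test compares per-sample mean beta
between groups with the same t-test. `neighbor_probes` returns probes on
the same chromosome within an inclusive window (default 500 bp).

## The pattern classifier

Per probe, 1–3-component Gaussian mixtures are fitted to the beta vector
(scikit-learn, 10 seeded restarts) and the component count chosen by BIC
with ties broken toward fewer components. Adjacent components are merged
when their means are closer than `min_sep = 0.15` **or** when Ashman's
D = |μ₁ − μ₂|·√(2/(σ₁² + σ₂²)) < 3.5 — two broad, heavily overlapping
Gaussians routinely tile one wide mode and must not count as bimodality.
The calibration of both thresholds (and of `cloud_sd = 0.12`,
`low_intensity_frac = 0.25`, `inflated_beta_min = 0.4`) is validated by the
seeded round-trip suite, not taken from any reference data: in the
canonical scenarios real modes have D ≥ 10 while spurious splits of the
cloud scenario have D ≈ 2.5.

Label logic, in order:

1. **flattened_high** — samples flagged for abnormally low total intensity
   (< 0.25 × cohort median) exist, their mean beta is *inflated*
   (> 0.4), and the unflagged samples' mean is high (> 0.6). Low intensity
   with inflated beta is the discriminating signature of blocked probes, so
   this check precedes modality: the flattened pattern does present two
   numeric clusters (inflated ≈ 0.5 vs high ≈ 0.95) and would otherwise be
   indistinguishable from true bimodality. Genuinely bimodal cohorts are
   unaffected because their low-intensity homozygotes have *low* beta.
2. **trimodal** / **bimodal** — three / two surviving clusters.
3. **cloud** — one cluster with SD > 0.12.
4. **clean_unimodal** — otherwise.

Genotype concordance maps clusters one-to-one onto genotype classes by the
assignment maximizing agreement (≤ 3 clusters, exhaustive search) and
reports the matched fraction; it is undefined (None) for a single cluster.
Classification refuses cohorts of fewer than 10 samples as unstable.

## Population genetics

Hudson's two-population Fst estimator,
`[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂) + p₂(1−p₁)]`,
is the default: it is unbiased-by-construction for two populations, stable
at small equal sample sizes, and needs only frequencies. Negative raw
estimates are truncated to 0 for summaries (the raw value is retained);
when both populations are fixed for the same allele the denominator
vanishes and Fst is defined as 0. A Weir–Cockerham variant (heterozygosity
at its HWE expectation) is available for sensitivity analysis. MAF_diff is
the absolute difference of *alternate*-allele frequencies, not folded MAF,
avoiding folding ambiguity near 0.5.

## What the simulations do and do not show

The generator reproduces the mechanistic consequences of CpG-site SNPs on
an idealized assay: band structure, heterozygote behavior, signal collapse
and beta inflation, and the resulting false positives in two-group testing
at realistic sample sizes. It does not emulate dye bias, probe-affinity
variation between loci, within-array spatial effects, normalization (a
pass-through; SWAN-style normalization is out of scope), under-a-probe
SNPs/indels outside the interrogated CpG, repeat/multi-mapping probes, or
strand-resolved probe design from a real manifest. Passing round-trip tests
therefore demonstrates internal consistency of chemistry, generator and
classifier under the stated noise model — not classifier performance on
real arrays, where the inflated-beta and modality thresholds may need
re-calibration against genotyped samples.

## Numerical choices and degenerate inputs

Problem sizes in the validation suite: 100 seeded replicates per scenario
at n = 200/population for pattern round-trips (large n makes the intended
pattern unambiguous); 200 cohorts at the study's n = 18/18 for the
confounding rate; 10,000 clean probes for type-I calibration; n = 100 for
methylation-level recovery (tolerance ±0.03, which also absorbs the small
background-induced compression of extreme beta values, ≈ 0.024 at
beta = 1). Lognormal noise makes M = log₂(meth/unmeth) exactly normal for
clean loci, so the t-test calibration check is exact rather than
asymptotic. GMM fits use `reg_covar = 1e-5` to keep near-degenerate
single-value clusters well-conditioned. Beta with zero total signal and
zero offset is NaN and treated as missing throughout.
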