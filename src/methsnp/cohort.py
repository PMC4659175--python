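"""Synthetic two-population cohort generator with known genotype/methylation truth.

Emulates the study design the package targets: two populations of male
B-lymphocyte lines (defaults EUR and EAS, n = 18 each) assayed at loci with
and without CpG-dinucleotide SNPs whose allele frequencies differ strongly
between the populations.  Genotypes are drawn under Hardy-Weinberg
equilibrium independently per population; signals come from the chemistry
model with lognormal noise and additive background; negative-control
intensities provide the background model for detection filtering.

Canonical scenario factories reproduce the archetypal beta-distribution
patterns: trimodal (type II probe, C>T in the first CpG position, methylated
CpG allele), bimodal (type I, G>A in the second position), flattened-high
(type I, C>T in the first position with methylated under-a-probe CpGs) and a
clean partially methylated locus with between-sample variability (cloud).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    ChemistryParams,
    InfiniumType,
    LocusSpec,
    SNPSpec,
    allele_channel_units,
)
from .pipeline import compute_beta, compute_m

__all__ = [
    "CohortLocus",
    "CohortConfig",
    "CohortTruth",
    "CohortResult",
    "sample_genotypes",
    "simulate_cohort",
    "make_context",
    "scenario_trimodal",
    "scenario_bimodal",
    "scenario_flattened",
    "scenario_cloud",
    "scenario_clean",
    "CANONICAL_SCENARIOS",
]


def make_context(
    under_probe_cpg_offsets: Sequence[int] = (), length: int = 101
) -> str:
    """Deterministic top-strand context with CpGs only where requested.

    The filler alphabet contains no G, so the only CG dinucleotides are the
    interrogated one at the center and those placed at the given offsets.
    """
    if length % 2 != 1:
        raise ValueError("length must be odd")
    filler = "ACTTA"
    seq = [filler[i % len(filler)] for i in range(length)]
    c = length // 2
    for off in (0, *under_probe_cpg_offsets):
        if not 0 <= c + off < length - 1:
            raise ValueError(f"offset {off} outside the context")
        seq[c + off] = "C"
        seq[c + off + 1] = "G"
    return "".join(seq)


@dataclass(frozen=True)
class CohortLocus:
    """One simulated locus: probe type, genomic spec, per-population truth.

    ``meth_by_pop`` overrides the locus-wide CpG-allele methylation level per
    population (to simulate true population differences).
    ``meth_between_sd`` adds between-sample variability: each sample's level
    is drawn from a Beta distribution with the population mean and this SD
    (non-uniform methylation across individuals, the source of cloud-like
    patterns).
    """

    spec: LocusSpec
    infinium_type: InfiniumType = "II"
    meth_by_pop: Optional[Mapping[str, float]] = None
    meth_between_sd: float = 0.0

    def meth_level(self, population: str) -> float:
        if self.meth_by_pop is not None:
            return float(self.meth_by_pop[population])
        return self.spec.meth_cpg_allele


@dataclass(frozen=True)
class CohortConfig:
    populations: tuple[str, str] = ("EUR", "EAS")
    n_per_pop: int = 18
    loci: tuple[CohortLocus, ...] = ()
    params: ChemistryParams = field(default_factory=ChemistryParams)
    seed: int = 0
    n_negative_controls: int = 200

    def __post_init__(self) -> None:
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        if len(self.populations) != 2:
            raise ValueError("exactly two populations are supported")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort (for testing and validation)."""

    genotypes: pd.DataFrame  # loci x samples, copies of the non-CpG allele (0/1/2)
    meth_levels: pd.DataFrame  # loci x populations, CpG-allele methylation mean
    sample_populations: pd.Series  # sample id -> population label
    seed: int


@dataclass(frozen=True)
class CohortResult:
    signal_meth: pd.DataFrame
    signal_unmeth: pd.DataFrame
    beta: pd.DataFrame
    m_values: pd.DataFrame
    truth: CohortTruth
    background_mean: float  # of negative-control total intensity
    background_sd: float
    config: CohortConfig


def sample_genotypes(freq_alt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw HWE genotypes as copies of the alternate allele (binomial(2, f))."""
    if not 0.0 <= freq_alt <= 1.0:
        raise ValueError(f"freq_alt = {freq_alt} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.binomial(2, freq_alt, size=n)


def _beta_draw(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Beta-distributed methylation levels with the given mean and SD."""
    if sd <= 0:
        return np.full(size, mean)
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    var = min(sd**2, mean * (1 - mean) * 0.98)
    nu = mean * (1 - mean) / var - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu, size=size)


def simulate_cohort(config: CohortConfig) -> CohortResult:
    """Simulate signal, beta and M matrices plus ground truth.

    Deterministic given ``config.seed``; matrices are loci x (2 * n_per_pop)
    with samples ordered population-by-population.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    pops = config.populations
    n = config.n_per_pop
    sample_ids = [f"{pop}_{i + 1:02d}" for pop in pops for i in range(n)]
    pop_of = pd.Series(
        [pop for pop in pops for _ in range(n)], index=sample_ids, name="population"
    )
    locus_ids = [loc.spec.locus_id for loc in config.loci]
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus ids in config")

    n_samples = 2 * n
    sig_m = np.empty((len(config.loci), n_samples))
    sig_u = np.empty_like(sig_m)
    geno = np.zeros((len(config.loci), n_samples), dtype=int)
    meth_truth = np.zeros((len(config.loci), 2))

    for li, loc in enumerate(config.loci):
        try:
            units = allele_channel_units(loc.spec, loc.infinium_type, params)
        except ValueError as exc:
            raise ValueError(f"locus {loc.spec.locus_id!r}: {exc}") from exc
        cm1, cu1 = units[("cpg", True)]
        cm0, cu0 = units[("cpg", False)]
        if loc.spec.snp is not None:
            am1, au1 = units[("alt", True)]
            am0, au0 = units[("alt", False)]
        else:
            am1 = au1 = am0 = au0 = 0.0

        for pi, pop in enumerate(pops):
            sl = slice(pi * n, (pi + 1) * n)
            mean_meth = loc.meth_level(pop)
            meth_truth[li, pi] = mean_meth
            if loc.spec.snp is not None:
                f = loc.spec.snp.freq_alt.get(pop)
                if f is None:
                    raise ValueError(
                        f"locus {loc.spec.locus_id!r}: no alt frequency for population {pop!r}"
                    )
                g = sample_genotypes(f, n, rng)
            else:
                g = np.zeros(n, dtype=int)
            geno[li, sl] = g
            m_s = _beta_draw(mean_meth, loc.meth_between_sd, n, rng)
            n_cpg = 2 - g
            # fractional mixing of methylated/unmethylated template contributions
            sig_m[li, sl] = params.scale * (
                n_cpg * (m_s * cm1 + (1 - m_s) * cm0) + g * (m_s * am1 + (1 - m_s) * am0)
            )
            sig_u[li, sl] = params.scale * (
                n_cpg * (m_s * cu1 + (1 - m_s) * cu0) + g * (m_s * au1 + (1 - m_s) * au0)
            )

    sig_m += params.background
    sig_u += params.background
    if params.sdlog > 0:
        sig_m *= rng.lognormal(0.0, params.sdlog, size=sig_m.shape)
        sig_u *= rng.lognormal(0.0, params.sdlog, size=sig_u.shape)

    # negative controls: background-only beads in both channels
    ctrl = params.background * np.ones((config.n_negative_controls, 2))
    if params.sdlog > 0:
        ctrl = ctrl * rng.lognormal(0.0, params.sdlog, size=ctrl.shape)
    ctrl_total = ctrl.sum(axis=1)

    beta = compute_beta(sig_m, sig_u)
    mvals = compute_m(beta)
    idx = pd.Index(locus_ids, name="probe_id")
    cols = pd.Index(sample_ids, name="sample_id")
    truth = CohortTruth(
        genotypes=pd.DataFrame(geno, index=idx, columns=cols),
        meth_levels=pd.DataFrame(meth_truth, index=idx, columns=list(pops)),
        sample_populations=pop_of,
        seed=config.seed,
    )
    return CohortResult(
        signal_meth=pd.DataFrame(sig_m, index=idx, columns=cols),
        signal_unmeth=pd.DataFrame(sig_u, index=idx, columns=cols),
        beta=pd.DataFrame(beta, index=idx, columns=cols),
        m_values=pd.DataFrame(mvals, index=idx, columns=cols),
        truth=truth,
        background_mean=float(ctrl_total.mean()),
        background_sd=float(ctrl_total.std(ddof=1)),
        config=config,
    )


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------


def _snp(pos: int, alt: str, freq_alt: Mapping[str, float]) -> SNPSpec:
    return SNPSpec(cpg_position=pos, alt_base=alt, freq_alt=dict(freq_alt))


def scenario_trimodal(
    freq_alt: Mapping[str, float] | None = None,
    meth: float = 1.0,
    locus_id: str = "tri_snp1_typeII",
) -> CohortLocus:
    """Type II probe, C>T in the first CpG position, methylated CpG allele.

    Genotype classes separate into three beta bands (high CpG/CpG,
    intermediate heterozygote, low alt/alt)."""
    freq_alt = freq_alt or {"EUR": 0.2, "EAS": 0.7}
    spec = LocusSpec(
        locus_id=locus_id,
        context_seq=make_context(),
        snp=_snp(1, "T", freq_alt),
        meth_cpg_allele=meth,
    )
    return CohortLocus(spec=spec, infinium_type="II")


def scenario_bimodal(
    freq_alt: Mapping[str, float] | None = None,
    meth: float = 1.0,
    locus_id: str = "bi_snp2_typeI",
) -> CohortLocus:
    """Type I probe, G>A in the second CpG position, methylated CpG allele.

    Both probes mismatch the converted TpA template at/near their 3' ends, so
    heterozygotes read like CpG homozygotes (one high band) while alt
    homozygotes collapse to low-intensity, beta-inflated low values."""
    freq_alt = freq_alt or {"EUR": 0.1, "EAS": 0.6}
    spec = LocusSpec(
        locus_id=locus_id,
        context_seq=make_context(),
        snp=_snp(2, "A", freq_alt),
        meth_cpg_allele=meth,
    )
    return CohortLocus(spec=spec, infinium_type="I")


def scenario_flattened(
    freq_alt: Mapping[str, float] | None = None,
    meth: float = 1.0,
    locus_id: str = "flat_snp1_typeI",
) -> CohortLocus:
    """Type I probe, C>T in the first position, methylated under-a-probe CpGs.

    The M probe is terminally mismatched on the alt allele and the U probe is
    mismatched at three under-a-probe CpGs close to its 3' end, so alt
    homozygotes yield near-background signals in both channels and inflated
    beta values clustering in the upper range."""
    freq_alt = freq_alt or {"EUR": 0.1, "EAS": 0.6}
    spec = LocusSpec(
        locus_id=locus_id,
        context_seq=make_context(under_probe_cpg_offsets=(2, 4, 6)),
        snp=_snp(1, "T", freq_alt),
        under_probe_cpg_offsets=(2, 4, 6),
        meth_cpg_allele=meth,
        comethylation=True,
    )
    return CohortLocus(spec=spec, infinium_type="I")


def scenario_cloud(
    meth: float = 0.5,
    between_sd: float = 0.2,
    locus_id: str = "cloud_clean",
) -> CohortLocus:
    """Clean locus (no SNP) with non-uniform methylation across samples."""
    spec = LocusSpec(locus_id=locus_id, context_seq=make_context(), meth_cpg_allele=meth)
    return CohortLocus(spec=spec, infinium_type="II", meth_between_sd=between_sd)


def scenario_clean(
    meth: float = 0.5,
    locus_id: str = "clean",
    infinium_type: InfiniumType = "II",
    meth_by_pop: Optional[Mapping[str, float]] = None,
) -> CohortLocus:
    """Clean locus with a fixed methylation level (optionally per population)."""
    spec = LocusSpec(locus_id=locus_id, context_seq=make_context(), meth_cpg_allele=meth)
    return CohortLocus(spec=spec, infinium_type=infinium_type, meth_by_pop=meth_by_pop)


CANONICAL_SCENARIOS = {
    "trimodal": scenario_trimodal,
    "bimodal": scenario_bimodal,
    "flattened_high": scenario_flattened,
    "cloud": scenario_cloud,
}
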