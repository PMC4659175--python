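"""Classification of per-probe beta-value distributions across samples.

SNPs in the interrogated CpG leave recognizable footprints in the
distribution of individual beta values across a cohort: tri-modal bands
tracking the three genotype classes (type II probes, SNP in the first CpG
position, methylated CpG allele), bi-modal bands when heterozygotes are
indistinguishable from CpG homozygotes (SNP in the second position), and a
flattened high-beta pattern when blocked probes collapse both channel
signals to background, inflating beta in the affected samples.  True
methylation differences with inter-individual variability instead produce a
wide unimodal "cloud".

The classifier fits 1-3 component univariate Gaussian mixtures on beta,
selects the component count by BIC (ties broken toward fewer components),
merges components whose means are closer than ``min_sep``, and combines the
resulting modality with a low-total-intensity flag to assign a pattern
label.  Abnormally low total intensity with *inflated* beta is the
discriminating signature of the flattened pattern, so that check takes
precedence over modality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "PatternParams",
    "PatternCall",
    "classify_beta_pattern",
    "low_intensity_flag",
    "genotype_concordance",
]

PATTERN_LABELS = ("trimodal", "bimodal", "flattened_high", "cloud", "clean_unimodal")


@dataclass(frozen=True)
class PatternParams:
    """Calibration thresholds for pattern classification.

    ``min_sep``: minimum separation between adjacent cluster means for them
    to count as distinct modes.  ``min_ashman_d``: minimum Ashman's D
    (mean gap scaled by component widths) for adjacent components to count
    as distinct — heavily overlapping components fitted to one wide mode are
    merged.  ``cloud_sd``: within-cluster SD above which
    a unimodal distribution is called a cloud.  ``low_intensity_frac``:
    fraction of the cohort-median total intensity below which a sample is
    flagged.  ``inflated_beta_min``: mean beta of flagged samples above
    which their signal collapse is read as beta inflation (flattened
    pattern) rather than genuine unmethylation.
    """

    min_sep: float = 0.15
    min_ashman_d: float = 3.5
    cloud_sd: float = 0.12
    low_intensity_frac: float = 0.25
    inflated_beta_min: float = 0.4
    flattened_high_mean: float = 0.6
    max_components: int = 3
    n_init: int = 10
    random_state: int = 0


@dataclass(frozen=True)
class PatternCall:
    label: str
    n_clusters: int
    cluster_means: tuple[float, ...]  # ascending
    assignments: np.ndarray  # per-sample cluster index into cluster_means
    low_intensity_samples: tuple[int, ...]  # positional sample indices
    genotype_concordance: Optional[float] = None


def low_intensity_flag(
    total_intensity: Sequence[float], frac: float = 0.25
) -> np.ndarray:
    """Positional indices of samples with abnormally low total intensity.

    A sample is flagged when its meth+unmeth total falls below ``frac``
    times the cohort median total.  All-zero cohorts flag every sample.
    """
    totals = np.asarray(total_intensity, dtype=float)
    if totals.size < 3:
        raise ValueError("need >= 3 samples to assess low intensity")
    med = np.median(totals)
    if med <= 0:
        import warnings

        warnings.warn("all-zero total intensities; every sample flagged")
        return np.arange(totals.size)
    return np.nonzero(totals < frac * med)[0]


def _fit_mixture(beta: np.ndarray, params: PatternParams) -> GaussianMixture:
    x = beta.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, params.max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            n_init=params.n_init,
            random_state=params.random_state,
            covariance_type="full",
            reg_covar=1e-5,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:  # strict improvement: ties favor smaller k
            best, best_bic = gm, bic
    return best


def _merged_clusters(
    beta: np.ndarray, gm: GaussianMixture, params: PatternParams
) -> tuple[np.ndarray, list[float]]:
    """Assignments after merging components that do not form distinct modes.

    Adjacent components (by mean) are merged when their means are closer
    than ``min_sep`` or when Ashman's D = |mu1 - mu2| * sqrt(2 / (s1^2 +
    s2^2)) falls below ``min_ashman_d`` (their densities overlap too much to
    be separate modes; a single wide mode is routinely fitted by two broad
    overlapping Gaussians).  Merged groups are moment-matched before being
    compared with the next component.
    """
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    raw = gm.predict(beta.reshape(-1, 1))
    rank_of = {comp: r for r, comp in enumerate(order)}
    ranks = np.array([rank_of[c] for c in raw])

    group = np.zeros(len(means), dtype=int)
    cur_w, cur_mu, cur_var = weights[0], means[0], sds[0] ** 2
    for r in range(1, len(means)):
        gap = means[r] - cur_mu
        d = gap * np.sqrt(2.0 / max(cur_var + sds[r] ** 2, 1e-12))
        if gap < params.min_sep or d < params.min_ashman_d:
            group[r] = group[r - 1]
            w = cur_w + weights[r]
            mu = (cur_w * cur_mu + weights[r] * means[r]) / w
            cur_var = (
                cur_w * (cur_var + cur_mu**2) + weights[r] * (sds[r] ** 2 + means[r] ** 2)
            ) / w - mu**2
            cur_w, cur_mu = w, mu
        else:
            group[r] = group[r - 1] + 1
            cur_w, cur_mu, cur_var = weights[r], means[r], sds[r] ** 2
    assignments = group[ranks]
    cluster_means = [float(beta[assignments == g].mean()) for g in range(group[-1] + 1)]
    return assignments, cluster_means


def classify_beta_pattern(
    beta: Sequence[float],
    total_intensity: Optional[Sequence[float]] = None,
    params: PatternParams = PatternParams(),
    genotypes: Optional[Sequence[int]] = None,
) -> PatternCall:
    """Label the distribution of one probe's beta values across samples.

    Labels: ``flattened_high`` when low-intensity samples are present, their
    mean beta is inflated (> ``inflated_beta_min``) and the remaining
    samples' mean is high; otherwise ``trimodal``/``bimodal`` by the number
    of well-separated mixture components; otherwise ``cloud`` when the
    single cluster is wide (SD > ``cloud_sd``), else ``clean_unimodal``.
    When genotypes are supplied the call carries the genotype concordance of
    the clustering.  Requires at least 10 samples.
    """
    b = np.asarray(beta, dtype=float)
    if b.size < 10:
        raise ValueError("classification is unstable below 10 samples; refusing")
    if np.any((b < 0) | (b > 1)) or np.isnan(b).any():
        raise ValueError("beta values must lie in [0, 1]")

    gm = _fit_mixture(b, params)
    assignments, cluster_means = _merged_clusters(b, gm, params)
    k_eff = len(cluster_means)

    flagged: tuple[int, ...] = ()
    label = None
    if total_intensity is not None:
        flagged = tuple(
            int(i) for i in low_intensity_flag(total_intensity, params.low_intensity_frac)
        )
        if flagged:
            mask = np.zeros(b.size, dtype=bool)
            mask[list(flagged)] = True
            if (
                b[mask].mean() > params.inflated_beta_min
                and (not mask.all())
                and b[~mask].mean() > params.flattened_high_mean
            ):
                label = "flattened_high"
    if label is None:
        if k_eff >= 3:
            label = "trimodal"
        elif k_eff == 2:
            label = "bimodal"
        elif float(b.std(ddof=0)) > params.cloud_sd:
            label = "cloud"
        else:
            label = "clean_unimodal"

    concordance = None
    if genotypes is not None and k_eff >= 2:
        concordance = genotype_concordance(assignments, genotypes)
    return PatternCall(
        label=label,
        n_clusters=k_eff,
        cluster_means=tuple(cluster_means),
        assignments=assignments,
        low_intensity_samples=flagged,
        genotype_concordance=concordance,
    )


def genotype_concordance(
    assignments: Sequence[int] | PatternCall, genotypes: Sequence[int]
) -> Optional[float]:
    """Fraction of samples whose cluster matches their genotype class.

    Clusters are mapped one-to-one onto genotype classes by the assignment
    that maximizes agreement (at most 3 clusters, so exhaustive search over
    injective mappings).  Returns None for a single cluster (undefined).
    """
    if isinstance(assignments, PatternCall):
        assignments = assignments.assignments
    a = np.asarray(assignments)
    g = np.asarray(genotypes)
    if a.shape != g.shape:
        raise ValueError("assignments and genotypes must have equal length")
    clusters = np.unique(a)
    classes = np.unique(g)
    if len(clusters) < 2:
        return None
    best = 0
    small, big, small_is_cluster = (
        (clusters, classes, True) if len(clusters) <= len(classes) else (classes, clusters, False)
    )
    for perm in itertools.permutations(big, len(small)):
        if small_is_cluster:
            matched = sum(int(((a == c) & (g == t)).sum()) for c, t in zip(small, perm))
        else:
            matched = sum(int(((g == c) & (a == t)).sum()) for c, t in zip(small, perm))
        best = max(best, matched)
    return best / a.size
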