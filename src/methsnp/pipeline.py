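"""Differential-methylation analysis chain for two-group array data.

Implements the standard readout statistics — beta = signal_Meth /
(signal_Meth + signal_Unmeth), M = log2(beta / (1 - beta)) with beta clamped
to [0.001, 0.999] — followed by per-probe detection filtering against a
negative-control background model, two-sample Student's t-tests on M values
with Benjamini-Hochberg FDR control, category assignment by effect-size
thresholds on the between-group mean-M difference, a global (per-sample mean
beta) comparison, and a positional neighbor-probe scan.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "M_CLAMP",
    "compute_beta",
    "compute_m",
    "detection_filter",
    "differential_methylation",
    "global_methylation_test",
    "neighbor_probes",
]

M_CLAMP = (0.001, 0.999)


def compute_beta(signal_meth, signal_unmeth, offset: float = 0.0):
    """Beta value: signal_Meth / (signal_Meth + signal_Unmeth + offset).

    Vectorized over arrays.  With ``offset`` 0 and both signals 0 the value
    is undefined and returned as NaN (reported missing).  Negative signals
    are rejected.
    """
    sm = np.asarray(signal_meth, dtype=float)
    su = np.asarray(signal_unmeth, dtype=float)
    if np.any(sm < 0) or np.any(su < 0):
        raise ValueError("signals must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    denom = sm + su + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, sm / np.where(denom > 0, denom, 1.0), np.nan)
    n_missing = int(np.isnan(beta).sum())
    if n_missing:
        logger.info("compute_beta: %d undefined value(s) (zero total signal)", n_missing)
    if sm.ndim == 0:
        return float(beta)
    return beta


def compute_m(beta, clamp: tuple[float, float] = M_CLAMP):
    """M value: log2(beta / (1 - beta)) after clamping beta to ``clamp``.

    The clamp bounds |M| by log2(999) ~ 9.9643; NaN propagates.
    """
    b = np.clip(np.asarray(beta, dtype=float), clamp[0], clamp[1])
    m = np.log2(b / (1.0 - b))
    if np.ndim(beta) == 0:
        return float(m)
    return m


def detection_filter(
    signal_meth: pd.DataFrame,
    signal_unmeth: pd.DataFrame,
    background_mean: float,
    background_sd: float,
    alpha: float = 0.01,
) -> pd.Index:
    """Probes failing detection in at least one sample.

    The detection p-value of a measurement is the upper-tail probability of
    its total intensity (meth + unmeth) under a normal background model
    estimated from negative controls; a probe fails when p > alpha for any
    sample.
    """
    if background_sd <= 0:
        raise ValueError("background model requires a positive sd")
    total = signal_meth.to_numpy() + signal_unmeth.to_numpy()
    pvals = stats.norm.sf(total, loc=background_mean, scale=background_sd)
    failed = (pvals > alpha).any(axis=1)
    failed_idx = signal_meth.index[failed]
    logger.info(
        "detection filter: %d of %d probes failed (alpha=%g)",
        len(failed_idx),
        len(signal_meth),
        alpha,
    )
    return failed_idx


def _two_sample_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test; zero-variance identical groups get p = 1."""
    res = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(t) & np.isclose(x.mean(axis=1), y.mean(axis=1))
    if degenerate.any():
        logger.info(
            "t-test: %d probe(s) with zero variance and equal means; p set to 1",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    return t, p


def differential_methylation(
    m_values: pd.DataFrame,
    populations: Sequence[str] | pd.Series,
    beta: pd.DataFrame | None = None,
    q_max: float = 0.05,
    m_diff_strong: float = 1.0,
    m_diff_weak: float = 0.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-probe two-group comparison on M values.

    Returns a DataFrame with per-group mean M (and mean beta when ``beta`` is
    given), ``m_av_diff`` (group-1 minus group-2 mean M), the Student's t
    statistic (equal-variance by default; Welch with ``equal_var=False``),
    raw p, Benjamini-Hochberg q, and a category:

    * ``pop_diff``  — q < q_max and |m_av_diff| > m_diff_strong
    * ``weak_diff`` — q < q_max and m_diff_weak < |m_av_diff| <= m_diff_strong
    * ``ns``        — otherwise
    """
    pops = pd.Series(np.asarray(populations), index=m_values.columns)
    labels = pd.unique(pops)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 population labels, got {list(labels)}")
    g1 = m_values.loc[:, (pops == labels[0]).to_numpy()].to_numpy()
    g2 = m_values.loc[:, (pops == labels[1]).to_numpy()].to_numpy()
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise ValueError("missing M values; filter or impute before testing")

    mean1, mean2 = g1.mean(axis=1), g2.mean(axis=1)
    t, p = _two_sample_t(g1, g2, equal_var)
    q = multipletests(p, method="fdr_bh")[1]
    m_av_diff = mean1 - mean2

    out = pd.DataFrame(index=m_values.index)
    out[f"m_av_{labels[0]}"] = mean1
    out[f"m_av_{labels[1]}"] = mean2
    if beta is not None:
        b1 = beta.loc[:, (pops == labels[0]).to_numpy()].mean(axis=1)
        b2 = beta.loc[:, (pops == labels[1]).to_numpy()].mean(axis=1)
        out[f"beta_av_{labels[0]}"] = b1
        out[f"beta_av_{labels[1]}"] = b2
    out["m_av_diff"] = m_av_diff
    out["t"] = t
    out["p"] = p
    out["q"] = q
    abs_diff = np.abs(m_av_diff)
    category = np.where(
        (q < q_max) & (abs_diff > m_diff_strong),
        "pop_diff",
        np.where((q < q_max) & (abs_diff > m_diff_weak), "weak_diff", "ns"),
    )
    out["category"] = category
    logger.info(
        "differential methylation: %d probes, %d q<%g, %d pop_diff, %d weak_diff",
        len(out),
        int((q < q_max).sum()),
        q_max,
        int((category == "pop_diff").sum()),
        int((category == "weak_diff").sum()),
    )
    return out


def global_methylation_test(
    beta: pd.DataFrame, populations: Sequence[str] | pd.Series, equal_var: bool = True
) -> tuple[pd.Series, float, float]:
    """Global methylation comparison.

    Each sample's global methylation is its mean beta over all probes
    (probes with missing beta excluded per sample, with a logged count);
    groups are compared with a two-sample Student's t-test.
    """
    pops = pd.Series(np.asarray(populations), index=beta.columns)
    labels = pd.unique(pops)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 population labels, got {list(labels)}")
    n_missing = int(beta.isna().to_numpy().sum())
    if n_missing:
        logger.info("global methylation: %d missing beta value(s) excluded", n_missing)
    sample_means = beta.mean(axis=0, skipna=True)
    x = sample_means[(pops == labels[0]).to_numpy()]
    y = sample_means[(pops == labels[1]).to_numpy()]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if np.isnan(t) and np.isclose(x.mean(), y.mean()):
        logger.info("global test: zero variance with equal means; p set to 1")
        t, p = 0.0, 1.0
    return sample_means, float(t), float(p)


def neighbor_probes(
    manifest: pd.DataFrame, probe_id: str, window: int = 500
) -> list[str]:
    """Probes on the same chromosome within ``window`` bp (inclusive) of a query.

    ``manifest`` must carry ``chromosome`` and 1-based ``position`` columns
    indexed by probe id; the query probe itself is excluded.
    """
    if probe_id not in manifest.index:
        raise KeyError(f"unknown probe id {probe_id!r}")
    row = manifest.loc[probe_id]
    same = manifest[
        (manifest["chromosome"] == row["chromosome"])
        & ((manifest["position"] - row["position"]).abs() <= window)
    ]
    return [p for p in same.index if p != probe_id]
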