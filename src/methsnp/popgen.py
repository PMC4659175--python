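"""Population-genetic annotation of CpG-site SNPs: allele-frequency
differentiation (MAF_diff) and the two-population fixation index Fst.

Hudson's estimator is the default: it is well behaved for exactly two
populations with small, equal sample sizes and requires only allele
frequencies and sample sizes.  A Weir-Cockerham variant (assuming HWE
heterozygosity) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["FstEntry", "FstResult", "fst_two_pop", "fst_summary", "maf_diff"]


@dataclass(frozen=True)
class FstEntry:
    """Per-SNP Fst: raw estimate and its [0, 1]-truncated value."""

    raw: float
    fst: float  # truncated to [0, 1]


@dataclass(frozen=True)
class FstResult:
    entries: tuple[FstEntry, ...]
    mean: float
    sd: float


def _validate(p1: float, p2: float, n1: int, n2: int) -> None:
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency {p} outside [0, 1]")
    for n in (n1, n2):
        if n < 2:
            raise ValueError("sample sizes must be >= 2")


def fst_two_pop(
    p1: float, p2: float, n1: int, n2: int, estimator: str = "hudson"
) -> FstEntry:
    """Two-population Fst from alternate-allele frequencies and sample sizes.

    Hudson's estimator:

        numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        denominator = p1(1-p2) + p2(1-p1)

    The raw ratio may be slightly negative by sampling correction; the
    ``fst`` field truncates it to [0, 1].  When both populations are fixed
    for the same allele the denominator is 0 and Fst is defined as 0.
    """
    _validate(p1, p2, n1, n2)
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "weir_cockerham":
        num, den = _weir_cockerham(p1, p2, n1, n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if den == 0:
        logger.info("Fst denominator 0 (both populations fixed); defining Fst = 0")
        return FstEntry(raw=0.0, fst=0.0)
    raw = num / den
    return FstEntry(raw=raw, fst=float(min(1.0, max(0.0, raw))))


def _weir_cockerham(p1: float, p2: float, n1: int, n2: int) -> tuple[float, float]:
    """Weir & Cockerham (1984) theta components for two populations.

    Observed heterozygosities are taken at their HWE expectations (only
    allele frequencies are available here).
    """
    r = 2
    n = np.array([n1, n2], dtype=float)
    p = np.array([p1, p2], dtype=float)
    h = 2 * p * (1 - p)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def fst_summary(entries: Iterable[FstEntry]) -> FstResult:
    """Mean and SD (of the truncated values) over a SNP set."""
    entries = tuple(entries)
    if not entries:
        raise ValueError("empty SNP set")
    vals = np.array([e.fst for e in entries])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return FstResult(entries=entries, mean=float(vals.mean()), sd=sd)


def maf_diff(p1: float, p2: float) -> float:
    """Absolute alternate-allele frequency difference between two populations.

    Computed on the shared alternate-allele scale (not folded minor-allele
    frequency) to avoid folding ambiguity near p = 0.5.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency {p} outside [0, 1]")
    return abs(p1 - p2)
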