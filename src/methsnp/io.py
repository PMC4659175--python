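"""TSV/YAML interchange, run configuration, and per-probe report verdicts.

All matrices travel as TSV with probes as rows and samples as columns; the
first column is ``probe_id`` and missing values are written as ``NA``.
Output files carry comment headers embedding the seed and a configuration
hash so re-runs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "config_hash",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "report_verdict",
    "build_report",
    "VERDICTS",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds and bookkeeping, serialized into output headers."""

    q_max: float = 0.05
    m_diff_popdiff: float = 1.0
    m_diff_weak: float = 0.3
    detection_alpha: float = 0.01
    neighbor_window: int = 500
    beta_offset: float = 0.0
    equal_var: bool = True
    seed: int = 0
    chemistry: Mapping[str, float] = field(default_factory=dict)
    pattern: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q_max", "m_diff_popdiff", "m_diff_weak", "detection_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.neighbor_window <= 0:
            raise ValueError("neighbor_window must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed: Optional[int], cfg_hash: Optional[str]) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config_sha256={cfg_hash}")
    return "".join(line + "\n" for line in lines)


def write_matrix(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index_label="probe_id", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix, validating shape and ids."""
    path = Path(path)
    with open(path) as fh:
        raw = fh.readlines()
    rows = [(i + 1, line.rstrip("\n")) for i, line in enumerate(raw)
            if line.strip() and not line.startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = rows[0][1].split("\t")
    ncol = len(header)
    ids = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ValueError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        ids.append(fields[0])
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate probe id(s): {list(dupes)}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    df.index.name = "probe_id"
    return df


MANIFEST_COLUMNS = [
    "infinium_type",
    "chromosome",
    "position",
    "snp_in_cpg",
    "snp_position",
    "alt_base",
]


def write_manifest(
    manifest: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        manifest.to_csv(fh, sep="\t", index_label="probe_id", na_rep="NA")


def read_manifest(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    m.index.name = "probe_id"
    if m.index.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids in manifest")
    if "position" in m.columns and (m["position"] < 1).any():
        raise ValueError(f"{path}: positions must be >= 1")
    if "infinium_type" in m.columns:
        bad = set(m["infinium_type"].dropna()) - {"I", "II"}
        if bad:
            raise ValueError(f"{path}: invalid infinium_type values {sorted(bad)}")
    if "snp_in_cpg" in m.columns:
        m["snp_in_cpg"] = m["snp_in_cpg"].astype(bool)
    return m


# ---------------------------------------------------------------------------
# Report verdicts
# ---------------------------------------------------------------------------

# (pattern label, snp annotated) -> verdict for probes that are differential
# (category pop_diff or weak_diff).  Multimodal/flattened patterns with an
# annotated SNP are genomic artifacts; without annotation they still warrant
# genotyping.  Cloud/unimodal patterns are methylation-difference candidates,
# flagged for inspection when a SNP could overlap the signal.
_MULTIMODAL = ("trimodal", "bimodal", "flattened_high")
VERDICTS = {
    **{(lab, True): "snp_confounded" for lab in _MULTIMODAL},
    **{(lab, False): "suspect_genomic" for lab in _MULTIMODAL},
    ("cloud", True): "candidate_inspect",
    ("cloud", False): "methylation_candidate",
    ("clean_unimodal", True): "methylation_candidate",
    ("clean_unimodal", False): "methylation_candidate",
}


def report_verdict(category: str, pattern_label: str, snp_in_cpg: bool) -> str:
    """Pure table-driven verdict for one probe."""
    if category == "ns":
        return "not_differential"
    if category not in ("pop_diff", "weak_diff"):
        raise ValueError(f"unknown category {category!r}")
    try:
        return VERDICTS[(pattern_label, bool(snp_in_cpg))]
    except KeyError:
        raise ValueError(f"unknown pattern label {pattern_label!r}") from None


def build_report(
    diff: pd.DataFrame,
    patterns: pd.DataFrame,
    manifest: Optional[pd.DataFrame] = None,
    fst: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join differential results, pattern calls and annotation into verdicts."""
    out = diff.join(patterns[["label"]], how="left")
    if manifest is not None and "snp_in_cpg" in manifest.columns:
        out = out.join(manifest[["snp_in_cpg"]], how="left")
    else:
        out["snp_in_cpg"] = False
    out["snp_in_cpg"] = out["snp_in_cpg"].fillna(False).astype(bool)
    if fst is not None:
        out = out.join(fst, how="left")
    out["verdict"] = [
        report_verdict(c, lab, s) if isinstance(lab, str) else "unclassified"
        for c, lab, s in zip(out["category"], out["label"], out["snp_in_cpg"])
    ]
    return out
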