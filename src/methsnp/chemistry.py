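"""Mechanistic model of Infinium I/II probe chemistry at CpG sites with genomic SNPs.

The Infinium methylation assay infers the methylation state of a single CpG
dinucleotide from hybridization and single-base extension of 50-mer probes on
bisulfite-converted DNA (BCD).  Bisulfite treatment converts every cytosine
that is not part of a methylated CpG to uracil (read as T), so the converted
sequence of an unmethylated CpG is TpG while a methylated CpG stays CpG.

Two probe designs coexist on the array:

* **Infinium I** uses a pair of probes per CpG.  The M probe is complementary
  to the fully methylated converted template and the U probe to the fully
  unmethylated one; they differ at the 3'-terminal base (pairing the
  interrogated C, preserved vs converted) and at every base pairing the C of
  an additional CpG covered by the probe body ("under-a-probe" CpGs), because
  the design assumes those CpGs are co-methylated with the interrogated one.
  The methylation readout is which of the two probes extends.
* **Infinium II** uses a single probe whose 3'-most base pairs the G (second
  position) of the interrogated CpG; under-a-probe CpG positions carry a
  degenerate base (R) so the probe tolerates either methylation state there.
  Single-base extension incorporates a labelled ddNTP complementary to the
  first CpG position: C or G incorporation is read in the methylated (green)
  channel, A or T in the unmethylated (red) channel.

A SNP in the interrogated CpG perturbs this machinery in position- and
type-specific ways (wrong ddNTP channel, 3'-terminal mismatch blocking
extension, under-a-probe mismatches destabilizing the U probe).  This module
models the whole chain quantitatively — conversion, probe design, mismatch-
dependent hybridization efficiency, channel-resolved signal — and separately
hand-codes the qualitative per-allele readout table (`expected_readout`) as an
independent oracle for the simulator.

Only the genomic top strand is modelled; positions are 1-based in user-facing
descriptions ("first position" = the C, "second" = the G of the CpG) and
0-based internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ChemistryParams",
    "SNPSpec",
    "LocusSpec",
    "ProbeDesign",
    "AlleleTemplate",
    "ExpectedReadout",
    "SignalPair",
    "bisulfite_convert",
    "design_probes",
    "hybridization_efficiency",
    "expected_readout",
    "simulate_locus_signals",
    "allele_channel_units",
    "dichotomize_signals",
    "reverse_complement",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")

InfiniumType = Literal["I", "II"]
AlleleLabel = Literal["cpg", "alt"]
Level = Literal["high", "low"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (degenerate R <-> Y)."""
    table = str.maketrans("ACGTRY", "TGCAYR")
    return seq.translate(table)[::-1]


def bisulfite_convert(seq: str, methylated_c_positions: Sequence[int] | set[int] = ()) -> str:
    """Bisulfite-convert a top-strand sequence.

    Every C outside the protected set becomes T; a C at a methylated position
    is preserved.  All other bases are untouched.

    Parameters
    ----------
    seq : str
        Genomic top-strand sequence (ACGT only).
    methylated_c_positions : set of int
        0-based indices of methylated cytosines (protected from conversion).

    Raises
    ------
    ValueError
        On non-ACGT characters, out-of-range indices, or a protected index
        that does not hold a C.
    """
    bad = set(seq) - _BASES
    if bad:
        raise ValueError(f"non-ACGT character(s) in sequence: {sorted(bad)!r}")
    protected = set(methylated_c_positions)
    for i in protected:
        if not 0 <= i < len(seq):
            raise ValueError(f"methylated position {i} out of range for length {len(seq)}")
        if seq[i] != "C":
            raise ValueError(f"methylated position {i} holds {seq[i]!r}, expected 'C'")
    return "".join(
        "T" if (b == "C" and i not in protected) else b for i, b in enumerate(seq)
    )


@dataclass(frozen=True)
class ChemistryParams:
    """Signal-model parameters.

    Attributes
    ----------
    probe_len : int
        Probe length in bases (50 on the real platform).
    scale : float
        Fluorescence contributed by one fully efficient extended allele copy,
        in arbitrary units.
    background : float
        Additive per-channel background, same units.
    sdlog : float
        Log-sd of the multiplicative lognormal channel noise.
    eps_terminal : float
        Residual extension efficiency with a 3'-terminal mismatch
        (essentially blocked).
    internal_coef : float
        Internal-mismatch penalty is ``min(1, internal_coef * d**2)`` for a
        mismatch ``d`` bases from the 3' end (d >= 1): destabilization fades
        with distance from the extension end, and near-terminal mismatches
        block extension almost as strongly as a terminal one.
    """

    probe_len: int = 50
    scale: float = 1000.0
    background: float = 50.0
    sdlog: float = 0.15
    eps_terminal: float = 0.01
    internal_coef: float = 0.02

    def mismatch_penalty(self, dist_from_3prime: int) -> float:
        if dist_from_3prime < 0:
            raise ValueError("distance from 3' end must be >= 0")
        if dist_from_3prime == 0:
            return self.eps_terminal
        return min(1.0, self.internal_coef * dist_from_3prime**2)


@dataclass(frozen=True)
class SNPSpec:
    """A SNP in the interrogated CpG dinucleotide.

    ``cpg_position`` 1 is the C, 2 is the G.  ``freq_alt`` maps a population
    label to the frequency of the alternate (non-CpG) allele.
    """

    cpg_position: int
    alt_base: str
    freq_alt: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cpg_position not in (1, 2):
            raise ValueError("cpg_position must be 1 (the C) or 2 (the G)")
        ref = "C" if self.cpg_position == 1 else "G"
        if self.alt_base not in _BASES:
            raise ValueError(f"alt_base must be one of A/C/G/T, got {self.alt_base!r}")
        if self.alt_base == ref:
            raise ValueError(f"alt_base equals the reference base {ref!r}")
        for pop, f in self.freq_alt.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"freq_alt[{pop!r}] = {f} outside [0, 1]")

    @property
    def ref_base(self) -> str:
        return "C" if self.cpg_position == 1 else "G"


@dataclass(frozen=True)
class LocusSpec:
    """Genomic context of one interrogated CpG.

    ``context_seq`` is the top strand, odd length, with the interrogated C at
    the center index.  ``under_probe_cpg_offsets`` are signed offsets
    (relative to the interrogated C) of the C of each additional CpG falling
    under the probe footprint.  ``meth_cpg_allele`` is the methylation level
    of the CpG allele; with ``comethylation`` (the platform's design
    assumption) under-a-probe CpGs share that state.
    """

    locus_id: str
    context_seq: str
    snp: Optional[SNPSpec] = None
    under_probe_cpg_offsets: tuple[int, ...] = ()
    meth_cpg_allele: float = 1.0
    comethylation: bool = True

    def __post_init__(self) -> None:
        seq = self.context_seq
        if len(seq) % 2 != 1:
            raise ValueError("context_seq must have odd length")
        bad = set(seq) - _BASES
        if bad:
            raise ValueError(f"non-ACGT character(s) in context_seq: {sorted(bad)!r}")
        c = self.center
        if seq[c : c + 2] != "CG":
            raise ValueError("context_seq center must hold the interrogated 'CG'")
        for off in self.under_probe_cpg_offsets:
            if off in (0, 1):
                raise ValueError("under-probe offsets must not point at the interrogated CpG")
            pos = c + off
            if not 0 <= pos < len(seq) - 1 or seq[pos : pos + 2] != "CG":
                raise ValueError(f"under-probe offset {off} does not point at a 'CG'")
        if not 0.0 <= self.meth_cpg_allele <= 1.0:
            raise ValueError("meth_cpg_allele must be in [0, 1]")
        object.__setattr__(
            self, "under_probe_cpg_offsets", tuple(sorted(self.under_probe_cpg_offsets))
        )

    @property
    def center(self) -> int:
        return len(self.context_seq) // 2

    def genomic_allele_seq(self, allele: AlleleLabel) -> str:
        """Top-strand genomic sequence of one chromosome carrying `allele`."""
        if allele == "cpg":
            return self.context_seq
        if self.snp is None:
            raise ValueError(f"locus {self.locus_id} has no SNP; allele 'alt' is invalid")
        pos = self.center + (self.snp.cpg_position - 1)
        seq = self.context_seq
        return seq[:pos] + self.snp.alt_base + seq[pos + 1 :]

    def converted_template(
        self, allele: AlleleLabel, methylated: bool, under_probe_methylated: bool | None = None
    ) -> "AlleleTemplate":
        """Bisulfite-converted top strand for one chromosome.

        ``methylated`` applies to the interrogated CpG (CpG allele only) and,
        under co-methylation, to the under-a-probe CpGs; the latter can be
        overridden with ``under_probe_methylated``.  A CpG disrupted by the
        SNP is never methylable.
        """
        seq = self.genomic_allele_seq(allele)
        c = self.center
        if under_probe_methylated is None:
            under_probe_methylated = methylated if self.comethylation else False
        protected: set[int] = set()
        if allele == "cpg" and methylated:
            protected.add(c)
        if under_probe_methylated:
            for off in self.under_probe_cpg_offsets:
                # still a CpG on this chromosome (the SNP only touches the center)
                if seq[c + off : c + off + 2] == "CG":
                    protected.add(c + off)
        return AlleleTemplate(
            allele_label=allele,
            converted_seq=bisulfite_convert(seq, protected),
            methylated=bool(methylated and allele == "cpg"),
        )


@dataclass(frozen=True)
class AlleleTemplate:
    """A bisulfite-converted single-chromosome strand the probes hybridize to."""

    allele_label: AlleleLabel
    converted_seq: str
    methylated: bool


@dataclass(frozen=True)
class ProbeDesign:
    """Probe sequence(s) for one locus.

    Probes are written 5'->3'; the 3'-terminal base is the last character.
    ``extension_offset`` is the offset, relative to the interrogated C, of
    the template base read by single-base extension: -1 for type I (the base
    upstream of the CpG — the methylation call comes from *which* probe
    extends, governed by the 3'-terminal base pairing the C itself) and 0 for
    type II (the incorporated ddNTP reads the first CpG position).
    """

    probe_id: str
    infinium_type: InfiniumType
    probe_len: int = 50
    seq_m: Optional[str] = None
    seq_u: Optional[str] = None
    seq_deg: Optional[str] = None
    extension_offset: int = 0

    def __post_init__(self) -> None:
        if self.infinium_type == "I":
            if not (self.seq_m and self.seq_u):
                raise ValueError("type I design requires seq_m and seq_u")
            if len(self.seq_m) != self.probe_len or len(self.seq_u) != self.probe_len:
                raise ValueError("type I probe sequences must have length probe_len")
        elif self.infinium_type == "II":
            if not self.seq_deg:
                raise ValueError("type II design requires seq_deg")
            if len(self.seq_deg) != self.probe_len:
                raise ValueError("type II probe sequence must have length probe_len")
        else:
            raise ValueError("infinium_type must be 'I' or 'II'")


@dataclass(frozen=True)
class ExpectedReadout:
    """Qualitative channel levels; 'low' means background only (no extension)."""

    signal_meth_level: Level
    signal_unmeth_level: Level


@dataclass(frozen=True)
class SignalPair:
    """Per-probe fluorescence intensities in the two channels."""

    meth: float
    unmeth: float

    @property
    def total(self) -> float:
        return self.meth + self.unmeth


def _footprint_start(locus: LocusSpec, infinium_type: InfiniumType) -> int:
    # Type I covers [C .. downstream], 3' terminus at the C; type II covers
    # [G .. downstream], 3' terminus at the G.
    return locus.center if infinium_type == "I" else locus.center + 1


def design_probes(
    locus: LocusSpec, infinium_type: InfiniumType, params: ChemistryParams = ChemistryParams()
) -> ProbeDesign:
    """Build probe sequence(s) against the reference (CpG) allele.

    Type I: M probe is the reverse complement of the fully methylated
    converted footprint, U probe of the fully unmethylated one.  Type II: the
    probe is built on the unmethylated converted footprint with a degenerate
    R at every base pairing an under-a-probe CpG C (R pairs the converted T
    as well as the preserved C).
    """
    start = _footprint_start(locus, infinium_type)
    end = start + params.probe_len
    if end > len(locus.context_seq):
        raise ValueError(
            f"context_seq too short for a {params.probe_len}-mer {infinium_type} probe"
        )
    c = locus.center
    if infinium_type == "I":
        meth_tmpl = locus.converted_template("cpg", True, under_probe_methylated=True)
        unmeth_tmpl = locus.converted_template("cpg", False, under_probe_methylated=False)
        return ProbeDesign(
            probe_id=locus.locus_id,
            infinium_type="I",
            probe_len=params.probe_len,
            seq_m=reverse_complement(meth_tmpl.converted_seq[start:end]),
            seq_u=reverse_complement(unmeth_tmpl.converted_seq[start:end]),
            extension_offset=-1,
        )
    tmpl = locus.converted_template("cpg", False, under_probe_methylated=False)
    probe = list(reverse_complement(tmpl.converted_seq[start:end]))
    for off in locus.under_probe_cpg_offsets:
        d = c + off - start  # distance of the under-probe C from the probe 3' end
        if 0 <= d < params.probe_len:
            probe[params.probe_len - 1 - d] = "R"
    return ProbeDesign(
        probe_id=locus.locus_id,
        infinium_type="II",
        probe_len=params.probe_len,
        seq_deg="".join(probe),
        extension_offset=0,
    )


def _pairs(probe_base: str, template_base: str) -> bool:
    if probe_base == "R":  # degenerate purine: pairs template C (as G) or T (as A)
        return template_base in ("C", "T")
    return _COMPLEMENT[probe_base] == template_base


def hybridization_efficiency(
    probe_seq: str, template_seq: str, params: ChemistryParams = ChemistryParams()
) -> float:
    """Extension efficiency of a probe on a template segment.

    ``template_seq`` is the covered template region 5'->3'; its first base
    pairs the probe's 3'-terminal base (antiparallel duplex), so a template
    index *d* is also the mismatch's distance from the 3' end.  Mismatch
    penalties multiply; a perfect duplex returns 1.0.
    """
    if len(probe_seq) != len(template_seq):
        raise ValueError("probe and template segment must have equal length")
    n = len(probe_seq)
    eff = 1.0
    for d in range(n):
        if not _pairs(probe_seq[n - 1 - d], template_seq[d]):
            eff *= params.mismatch_penalty(d)
    return eff


# ---------------------------------------------------------------------------
# Qualitative readout oracle (hand-coded, independent of the simulator)
# ---------------------------------------------------------------------------

_HIGH_LOW = ExpectedReadout("high", "low")
_LOW_HIGH = ExpectedReadout("low", "high")
_LOW_LOW = ExpectedReadout("low", "low")


def expected_readout(
    infinium_type: InfiniumType,
    snp: Optional[SNPSpec],
    allele: AlleleLabel,
    cpg_methylated: bool,
    comethylated_context: bool = False,
) -> ExpectedReadout:
    """Predicted qualitative channel readout for one allele copy.

    This is a direct transcription of the predicted-readout rules, coded as a
    lookup so it can serve as an oracle for the signal simulator:

    * CpG allele: methylated -> (high, low); unmethylated -> (low, high).
    * Type II, SNP in position 1: the probe body still matches, extension
      reads the substituted base.  C>T and C>A template red (A/T labels are
      not distinguishable) -> mimics unmethylated; C>G templates green ->
      mimics methylated.
    * Type II, any SNP in position 2: 3'-terminal mismatch, no extension ->
      both channels low.
    * Type I, SNP pos 1 C>T: the converted alt template equals the
      unmethylated template, so the U probe matches -> mimics unmethylated —
      unless the under-a-probe CpGs are methylated (``comethylated_context``),
      which mismatches the U probe body near its 3' end too -> both low (the
      flattened case).  The M probe is always terminally mismatched.
    * Type I, SNP pos 1 C>A or C>G: both probes 3'-terminally mismatched ->
      both low.
    * Type I, any SNP pos 2: the converted alt template is TpN, doubly/near-
      terminally mismatching both probes -> both low.

    ``comethylated_context`` is only meaningful for type I and means
    "methylated under-a-probe CpGs are present".
    """
    if allele == "cpg" or snp is None:
        return _HIGH_LOW if cpg_methylated else _LOW_HIGH
    if infinium_type == "II":
        if snp.cpg_position == 1:
            return _HIGH_LOW if snp.alt_base == "G" else _LOW_HIGH
        return _LOW_LOW
    # type I, alt allele
    if snp.cpg_position == 1:
        if snp.alt_base == "T" and not comethylated_context:
            return _LOW_HIGH
        return _LOW_LOW
    return _LOW_LOW


# ---------------------------------------------------------------------------
# Quantitative signal simulation
# ---------------------------------------------------------------------------


def _channel_contribution(
    locus: LocusSpec,
    design: ProbeDesign,
    template: AlleleTemplate,
    params: ChemistryParams,
) -> tuple[float, float]:
    """(meth, unmeth) signal, units of ``scale``, for one allele copy on one template."""
    start = _footprint_start(locus, design.infinium_type)
    segment = template.converted_seq[start : start + params.probe_len]
    if design.infinium_type == "I":
        return (
            hybridization_efficiency(design.seq_m, segment, params),
            hybridization_efficiency(design.seq_u, segment, params),
        )
    eff = hybridization_efficiency(design.seq_deg, segment, params)
    ext_base = template.converted_seq[locus.center]  # base read by extension
    incorporated = _COMPLEMENT[ext_base]
    if incorporated in ("C", "G"):  # green label
        return eff, 0.0
    return 0.0, eff  # A/T: red label


def allele_channel_units(
    locus: LocusSpec,
    infinium_type: InfiniumType,
    params: ChemistryParams = ChemistryParams(),
) -> dict[tuple[AlleleLabel, bool], tuple[float, float]]:
    """Per-copy (meth, unmeth) signal units for each (allele, methylation-state).

    For the alt allele the state refers to the under-a-probe CpGs (under
    co-methylation); the interrogated site itself is not methylable there.
    Used by both `simulate_locus_signals` and the vectorized cohort
    simulator, so the two paths agree by construction.
    """
    design = design_probes(locus, infinium_type, params)
    alleles: list[AlleleLabel] = ["cpg"] + (["alt"] if locus.snp is not None else [])
    units: dict[tuple[AlleleLabel, bool], tuple[float, float]] = {}
    for allele in alleles:
        for state in (True, False):
            tmpl = locus.converted_template(allele, state)
            units[(allele, state)] = _channel_contribution(locus, design, tmpl, params)
    return units


def simulate_locus_signals(
    locus: LocusSpec,
    genotype: Sequence[AlleleLabel],
    per_allele_meth: Sequence[float | bool],
    infinium_type: InfiniumType,
    params: ChemistryParams = ChemistryParams(),
    rng: Optional[np.random.Generator] = None,
) -> SignalPair:
    """Simulate the two channel intensities for one sample at one locus.

    Each of the two allele copies contributes ``scale * efficiency`` to the
    channel selected by the extension chemistry; a fractional methylation
    level mixes the methylated- and unmethylated-template contributions
    (cell-population average).  Per-channel background is added once, then
    multiplicative lognormal noise is applied when an ``rng`` is given.
    """
    if len(genotype) != 2 or len(per_allele_meth) != 2:
        raise ValueError("genotype and per_allele_meth must each have two entries")
    for a in genotype:
        if a not in ("cpg", "alt"):
            raise ValueError(f"invalid allele label {a!r}")
        if a == "alt" and locus.snp is None:
            raise ValueError(f"locus {locus.locus_id} has no SNP; genotype {genotype!r} invalid")
    units = allele_channel_units(locus, infinium_type, params)
    meth = unmeth = 0.0
    for allele, m in zip(genotype, per_allele_meth):
        m = float(m)
        if not 0.0 <= m <= 1.0:
            raise ValueError("per-allele methylation level must be in [0, 1]")
        um, uu = units[(allele, True)]
        vm, vu = units[(allele, False)]
        meth += params.scale * (m * um + (1.0 - m) * vm)
        unmeth += params.scale * (m * uu + (1.0 - m) * vu)
    meth += params.background
    unmeth += params.background
    if rng is not None and params.sdlog > 0:
        meth *= rng.lognormal(0.0, params.sdlog)
        unmeth *= rng.lognormal(0.0, params.sdlog)
    return SignalPair(meth=meth, unmeth=unmeth)


def dichotomize_signals(pair: SignalPair, params: ChemistryParams = ChemistryParams()) -> ExpectedReadout:
    """Dichotomize a noise-free signal pair at scale/2 into high/low levels."""
    thr = params.scale / 2.0
    return ExpectedReadout(
        "high" if pair.meth >= thr else "low",
        "high" if pair.unmeth >= thr else "low",
    )
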