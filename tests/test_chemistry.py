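"""Bisulfite conversion, probe design, hybridization and readout chemistry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsnp.chemistry import (
    ChemistryParams,
    ExpectedReadout,
    LocusSpec,
    SNPSpec,
    bisulfite_convert,
    design_probes,
    dichotomize_signals,
    expected_readout,
    hybridization_efficiency,
    reverse_complement,
    simulate_locus_signals,
)
from methsnp.cohort import make_context

from conftest import locus_with_snp


class TestBisulfiteConvert:
    @pytest.mark.parametrize(
        "seq,meth,expected",
        [
            ("ACGT", {1}, "ACGT"),  # methylated C preserved
            ("ACGT", set(), "ATGT"),  # unmethylated C converted
            ("CCGC", {1}, "TCGT"),  # rule applied position by position
        ],
    )
    def test_examples(self, seq, meth, expected):
        assert bisulfite_convert(seq, meth) == expected

    @pytest.mark.parametrize(
        "seq,meth,err",
        [
            ("ACNT", set(), "non-ACGT"),
            ("ACGT", {9}, "out of range"),
            ("ACGT", {0}, "expected 'C'"),
        ],
    )
    def test_rejects_invalid(self, seq, meth, err):
        with pytest.raises(ValueError, match=err):
            bisulfite_convert(seq, meth)

    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=80),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_length_preserving(self, seq, data):
        c_positions = [i for i, b in enumerate(seq) if b == "C"]
        meth = set(data.draw(st.lists(st.sampled_from(c_positions), unique=True))) if c_positions else set()
        out = bisulfite_convert(seq, meth)
        assert len(out) == len(seq)
        # non-C bases unchanged, methylated Cs preserved, others converted
        for i, (a, b) in enumerate(zip(seq, out)):
            if a != "C":
                assert b == a
            else:
                assert b == ("C" if i in meth else "T")
        assert bisulfite_convert(out, meth & {i for i, b in enumerate(out) if b == "C"}) == out


class TestDesignProbes:
    def test_type_i_no_under_probe_differ_only_at_terminus(self, plain_locus):
        d = design_probes(plain_locus, "I")
        diffs = [i for i, (a, b) in enumerate(zip(d.seq_m, d.seq_u)) if a != b]
        assert diffs == [len(d.seq_m) - 1]
        assert d.seq_m[-1] == "G" and d.seq_u[-1] == "A"

    def test_type_i_two_under_probe_cpgs_differ_at_three_positions(self):
        locus = locus_with_snp(1, "T", under_probe=True)  # offsets (2, 4)
        d = design_probes(locus, "I")
        diffs = [i for i, (a, b) in enumerate(zip(d.seq_m, d.seq_u)) if a != b]
        assert len(diffs) == 3  # terminus + one per under-probe CpG

    def test_type_ii_degenerate_positions(self):
        locus = locus_with_snp(1, "T", under_probe=True)
        d = design_probes(locus, "II")
        assert d.seq_deg.count("R") == 2
        assert d.seq_deg[-1] == "C"  # complementary to the CpG's G

    def test_context_too_short_rejected(self):
        locus = LocusSpec("short", make_context(length=31))
        with pytest.raises(ValueError, match="too short"):
            design_probes(locus, "I")

    def test_center_must_be_cg(self):
        with pytest.raises(ValueError, match="CG"):
            LocusSpec("bad", "A" * 101)


class TestHybridizationEfficiency:
    def test_perfect_match(self):
        probe = "ACGT" * 5
        assert hybridization_efficiency(probe, reverse_complement(probe)) == 1.0

    def test_terminal_mismatch(self):
        params = ChemistryParams()
        probe = "A" * 20
        tmpl = list("T" * 20)
        tmpl[0] = "G"  # pairs the probe's 3'-terminal base
        assert hybridization_efficiency(probe, "".join(tmpl), params) == pytest.approx(
            params.eps_terminal
        )

    def test_multiplicativity(self):
        params = ChemistryParams()
        probe = "A" * 20
        single = {}
        for d in (3, 11):
            tmpl = list("T" * 20)
            tmpl[d] = "G"
            single[d] = hybridization_efficiency(probe, "".join(tmpl), params)
        tmpl = list("T" * 20)
        tmpl[3] = tmpl[11] = "G"
        both = hybridization_efficiency(probe, "".join(tmpl), params)
        assert both == pytest.approx(single[3] * single[11])

    def test_penalty_monotone_in_distance(self):
        params = ChemistryParams()
        pens = [params.mismatch_penalty(d) for d in range(0, 12)]
        assert all(b >= a for a, b in zip(pens, pens[1:]))
        assert pens[-1] == 1.0

    def test_degenerate_r_matches_both_states(self):
        probe = "R" + "A" * 19
        for last in ("C", "T"):  # methylated / converted under-probe C
            tmpl = "T" * 19 + last
            assert hybridization_efficiency(probe, tmpl) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            hybridization_efficiency("ACGT", "ACG")


class TestExpectedReadout:
    """Spot checks of the hand-coded predicted-readout table."""

    def test_type_ii_pos1_ct_alt_mimics_unmethylated(self):
        snp = SNPSpec(1, "T")
        assert expected_readout("II", snp, "alt", True) == ExpectedReadout("low", "high")

    def test_type_i_pos2_ga_alt_both_low(self):
        snp = SNPSpec(2, "A")
        assert expected_readout("I", snp, "alt", True) == ExpectedReadout("low", "low")

    def test_type_i_pos1_ct_methylated_under_probe_both_low(self):
        snp = SNPSpec(1, "T")
        assert expected_readout("I", snp, "alt", True, comethylated_context=True) == (
            ExpectedReadout("low", "low")
        )

    def test_type_i_pos1_ct_without_under_probe_mimics_unmethylated(self):
        snp = SNPSpec(1, "T")
        assert expected_readout("I", snp, "alt", True, comethylated_context=False) == (
            ExpectedReadout("low", "high")
        )

    def test_canonical_methylated(self):
        assert expected_readout("II", None, "cpg", True) == ExpectedReadout("high", "low")
        assert expected_readout("I", None, "cpg", False) == ExpectedReadout("low", "high")

    def test_type_ii_pos1_cg_mimics_methylated(self):
        snp = SNPSpec(1, "G")
        assert expected_readout("II", snp, "alt", False) == ExpectedReadout("high", "low")


def _all_table_rows():
    """Every (probe type, SNP, allele, methylation, under-probe context) combination."""
    snps = [None] + [SNPSpec(1, a) for a in "TAG"] + [SNPSpec(2, a) for a in "ATC"]
    for itype in ("I", "II"):
        for snp in snps:
            for allele in (["cpg", "alt"] if snp else ["cpg"]):
                for meth in (True, False):
                    for under in (False, True):
                        yield itype, snp, allele, meth, under


@pytest.mark.parametrize("itype,snp,allele,meth,under", list(_all_table_rows()))
def test_oracle_equivalence(itype, snp, allele, meth, under, noise_free_params):
    """Dichotomized noise-free homozygote signals match the readout table exactly."""
    offsets = (2, 4) if under else ()
    locus = LocusSpec("L", make_context(offsets), snp=snp, under_probe_cpg_offsets=offsets)
    expected = expected_readout(itype, snp, allele, meth, comethylated_context=under and meth)
    pair = simulate_locus_signals(locus, (allele, allele), (meth, meth), itype, noise_free_params)
    assert dichotomize_signals(pair, noise_free_params) == expected


class TestSimulateLocusSignals:
    def test_methylated_homozygote_type_ii(self, plain_locus, noise_free_params):
        pair = simulate_locus_signals(plain_locus, ("cpg", "cpg"), (1, 1), "II", noise_free_params)
        assert pair.meth == pytest.approx(2 * noise_free_params.scale)
        assert pair.unmeth == pytest.approx(0.0)

    def test_heterozygote_equal_channels(self, noise_free_params):
        locus = locus_with_snp(1, "T")
        pair = simulate_locus_signals(locus, ("cpg", "alt"), (1, 1), "II", noise_free_params)
        assert pair.meth == pytest.approx(noise_free_params.scale)
        assert pair.unmeth == pytest.approx(noise_free_params.scale)

    def test_pos2_alt_homozygote_near_background(self):
        params = ChemistryParams(sdlog=0.0)  # background on, noise off
        locus = locus_with_snp(2, "A")
        pair = simulate_locus_signals(locus, ("alt", "alt"), (1, 1), "I", params)
        assert pair.meth < params.scale / 4
        assert pair.unmeth < params.scale / 4
        assert pair.meth >= params.background

    def test_invalid_genotype_rejected(self, plain_locus, noise_free_params):
        with pytest.raises(ValueError, match="no SNP"):
            simulate_locus_signals(plain_locus, ("cpg", "alt"), (1, 1), "II", noise_free_params)

    def test_channel_swap_on_methylation_flip(self, plain_locus, noise_free_params):
        hi = simulate_locus_signals(plain_locus, ("cpg", "cpg"), (1, 1), "II", noise_free_params)
        lo = simulate_locus_signals(plain_locus, ("cpg", "cpg"), (0, 0), "II", noise_free_params)
        assert hi.meth == pytest.approx(lo.unmeth)
        assert hi.unmeth == pytest.approx(lo.meth)

    def test_beta_inflation_monotone_in_background(self):
        """Non-extending genotype: beta strictly increases with background/scale."""
        from methsnp.pipeline import compute_beta

        locus = locus_with_snp(2, "A")
        betas = []
        for b in np.linspace(0.0, 400.0, 9):
            params = ChemistryParams(background=b, sdlog=0.0)
            pair = simulate_locus_signals(locus, ("alt", "alt"), (1, 1), "I", params)
            betas.append(compute_beta(pair.meth, pair.unmeth))
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))

    def test_fractional_methylation_mixes_channels(self, plain_locus, noise_free_params):
        pair = simulate_locus_signals(plain_locus, ("cpg", "cpg"), (0.25, 0.25), "II", noise_free_params)
        total = pair.meth + pair.unmeth
        assert pair.meth / total == pytest.approx(0.25)
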