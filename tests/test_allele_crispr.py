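"""Polymorphic PAM detection and allele-specific guide design."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gemini_loh import allele_crispr as ac
from gemini_loh.formats_io import ValidationError

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def oracle_pam_placements(seq):
    """Exhaustive trinucleotide scan for NGG/NAG on both strands."""
    hits = set()
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri[1:] in ("GG", "AG"):
            hits.add((i, "+"))
        if revcomp(tri)[1:] in ("GG", "AG"):
            hits.add((i, "-"))
    return hits


def oracle_snv_specific(window, off, ref, alt):
    """Independent specificity decision by full enumeration on both alleles."""
    assert window[off] == ref
    alt_seq = window[:off] + alt + window[off + 1 :]
    overlapping = {
        (i, s)
        for i in range(max(0, off - 2), min(len(window) - 3, off) + 1)
        for s in "+-"
    }
    ref_pams = oracle_pam_placements(window) & overlapping
    alt_pams = oracle_pam_placements(alt_seq) & overlapping
    ref_only, alt_only = ref_pams - alt_pams, alt_pams - ref_pams
    if ref_only and alt_only:
        return False, None
    if ref_only:
        return True, "ref"
    if alt_only:
        return True, "alt"
    return False, None


def snv_context(window, off, alt, vid="v"):
    return ac.AlleleContext(vid, window, off, window[off], alt)


class TestEnumeratePams:
    def test_plus_strand_hit(self):
        assert (1, "+", "AGG") in ac.enumerate_pams("AAGGA")

    def test_no_hits(self):
        assert ac.enumerate_pams("TTTTT") == []

    def test_minus_strand_reported_in_plus_coordinates(self):
        # revcomp("CCA") = "TGG", a PAM on the minus strand
        assert ac.enumerate_pams("CCA") == [(0, "-", "TGG")]

    def test_too_short(self):
        assert ac.enumerate_pams("AG") == []

    def test_agrees_with_oracle_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=15))
            got = {(i, s) for i, s, _ in ac.enumerate_pams(seq)}
            assert got == oracle_pam_placements(seq)


class TestAlleleSpecificPam:
    def test_alt_creates_pam(self):
        # ref: ...A C G... (no PAM), alt: ...A G G... (PAM) at one placement
        window = "T" * 10 + "A" + "C" + "G" + "T" * 10
        ctx = ac.AlleleContext("v", window, 11, "C", "G")
        specific, sensitive, placements = ac.allele_specific_pam(ctx)
        assert specific and sensitive == "alt"
        assert (10, "+") in placements

    def test_n_position_change_not_specific(self):
        # both CGG and TGG are PAMs: the N position is unconstrained
        # (C->T avoids creating a side NAG the way an A allele would)
        window = "T" * 10 + "C" + "G" + "G" + "T" * 10
        ctx = ac.AlleleContext("v", window, 10, "C", "T")
        specific, _, _ = ac.allele_specific_pam(ctx)
        assert not specific

    def test_ngg_to_nag_not_specific(self):
        # NAG is in the motif set, so NGG<->NAG keeps a PAM on both alleles
        window = "T" * 10 + "C" + "G" + "G" + "T" * 10
        ctx = ac.AlleleContext("v", window, 11, "G", "A")
        specific, _, _ = ac.allele_specific_pam(ctx)
        assert not specific

    def test_insertion_creating_pam(self):
        window = "AT" * 15 + "A" + "TA" * 15
        ctx = ac.AlleleContext("v", window, 30, "A", "ATGG")
        specific, sensitive, placements = ac.allele_specific_pam(ctx)
        assert specific and sensitive == "alt" and placements

    def test_indel_with_pams_on_both_alleles_not_specific(self):
        window = "G" * 30 + "A" + "G" * 30  # PAMs everywhere on both alleles
        ctx = ac.AlleleContext("v", window, 30, "A", "ATGG")
        specific, _, _ = ac.allele_specific_pam(ctx)
        assert not specific

    def test_offset_out_of_window_raises(self):
        with pytest.raises(ValidationError):
            ac.AlleleContext("v", "ACGT", 4, "A", "G")

    def test_matches_oracle_on_random_snvs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            window = "".join(rng.choice(list("ACGT"), size=9))
            off = 4
            alt = str(rng.choice([b for b in "ACGT" if b != window[off]]))
            ctx = snv_context(window, off, alt)
            got_specific, got_sens, _ = ac.allele_specific_pam(ctx)
            want_specific, want_sens = oracle_snv_specific(window, off, window[off], alt)
            assert (got_specific, got_sens) == (want_specific, want_sens)

    @given(st.integers(0, 4**9 - 1))
    def test_strand_symmetry(self, code):
        bases = "ACGT"
        window = "".join(bases[(code >> (2 * k)) & 3] for k in range(9))
        off = 4
        alt = bases[(code + 1) % 4]
        if alt == window[off]:
            alt = bases[(code + 2) % 4]
            if alt == window[off]:
                return
        fwd = ac.allele_specific_pam(snv_context(window, off, alt))
        rev = ac.allele_specific_pam(
            ac.AlleleContext(
                "v", revcomp(window), len(window) - 1 - off,
                revcomp(window[off]), revcomp(alt),
            )
        )
        assert fwd[0] == rev[0]
        assert fwd[1] == rev[1]


class TestGuideDesign:
    def make_specific_context(self):
        flank5 = "ACGTACGTACGTACGTACGT"  # 20 nt protospacer source
        window = "T" * 5 + flank5 + "A" + "C" + "G" + "T" * 10
        return ac.AlleleContext("v", window, 26, "C", "G")

    def test_protospacer_is_20nt_upstream_of_pam(self):
        ctx = self.make_specific_context()
        specific, sensitive, placements = ac.allele_specific_pam(ctx)
        assert specific and sensitive == "alt"
        # the alt G completes both an NAG (one base left) and the seeded
        # NGG; design against the canonical NGG placement at position 25
        assert (25, "+") in placements
        guide = ac.design_as_guide(ctx, (25, "+"), sensitive)
        assert guide.protospacer == "ACGTACGTACGTACGTACGT"
        assert guide.pam_sensitive == "AGG"
        assert guide.pam_resistant == "ACG"

    def test_guide_rescans_to_its_site_and_mismatches_resistant_only_in_pam(self):
        rng = np.random.default_rng(23)
        n_checked = 0
        for _ in range(200):
            window = "".join(rng.choice(list("ACGT"), size=61))
            alt = str(rng.choice([b for b in "ACGT" if b != window[30]]))
            ctx = snv_context(window, 30, alt)
            specific, sensitive, placements = ac.allele_specific_pam(ctx)
            if not specific:
                continue
            n_checked += 1
            guide = ac.design_as_guide(ctx, placements[0], sensitive)
            sens_seq = ctx.ref_sequence if sensitive == "ref" else ctx.alt_sequence
            res_seq = ctx.alt_sequence if sensitive == "ref" else ctx.ref_sequence
            if guide.strand == "-":
                sens_seq, res_seq = revcomp(sens_seq), revcomp(res_seq)
            site = guide.protospacer + guide.pam_sensitive
            assert site in sens_seq  # perfect match on the sensitive allele
            start = sens_seq.index(site)
            res_local = res_seq[start : start + 23] if len(res_seq) == len(sens_seq) else None
            if res_local is not None:
                assert res_local[:20] == guide.protospacer  # mismatch only in PAM
                assert res_local[20:] == guide.pam_resistant
        assert n_checked >= 10

    def test_insufficient_flank_raises(self):
        window = "T" * 3 + "A" + "C" + "G" + "T" * 24
        ctx = ac.AlleleContext("v", window, 4, "C", "G")
        specific, sensitive, placements = ac.allele_specific_pam(ctx)
        assert specific
        plus = [p for p in placements if p[1] == "+"]
        with pytest.raises(ValidationError, match="window"):
            ac.design_as_guide(ctx, plus[0], sensitive)


class TestPamFraction:
    def make_contexts(self, flags):
        out = []
        for i, flag in enumerate(flags):
            if flag:
                window = "T" * 30 + "C" + "G" + "T" * 29
                out.append(ac.AlleleContext(f"v{i}", window, 30, "C", "G"))
            else:
                # A->G in a poly-T background touches no PAM on either strand
                window = "T" * 30 + "A" + "T" * 30
                out.append(ac.AlleleContext(f"v{i}", window, 30, "A", "G"))
        return out

    def test_simple_fraction(self):
        contexts = self.make_contexts([True, False, False, False])
        n_spec, n_total, frac = ac.pam_fraction(contexts)
        assert (n_spec, n_total) == (1, 4)
        assert frac == pytest.approx(0.25)

    def test_orf_restriction_excludes_utr(self):
        contexts = self.make_contexts([True, True])
        classes = {"v0": "missense_variant", "v1": "3_prime_UTR_variant"}
        n_spec, n_total, _ = ac.pam_fraction(
            contexts, consequence_by_id=classes, orf_classes_only=True
        )
        assert (n_spec, n_total) == (1, 1)

    def test_all_utr_gives_missing_fraction(self):
        contexts = self.make_contexts([True])
        classes = {"v0": "5_prime_UTR_variant"}
        n_spec, n_total, frac = ac.pam_fraction(
            contexts, consequence_by_id=classes, orf_classes_only=True
        )
        assert n_total == 0 and np.isnan(frac)
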