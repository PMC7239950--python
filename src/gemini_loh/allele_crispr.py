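"""Allele-specific CRISPR PAM discovery and guide design.

A heterozygous variant is a candidate for allele-specific Cas9 knockout
when one allele completes a S. pyogenes PAM (canonical NGG, or the
weaker non-canonical NAG) and the other allele does not.  The
allele-specific guide is the 20 nucleotides immediately 5' of the
polymorphic PAM on the PAM-bearing ("sensitive") allele; cells carrying
the PAM-less ("resistant") allele are not cut.

Because NAG is part of the motif set, a substitution that converts NGG
to NAG leaves a functional PAM on both alleles and is *not*
allele-specific, and a substitution in the unconstrained N position
never is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import ORF_CLASSES, ValidationError

log = logging.getLogger(__name__)

DEFAULT_MOTIFS = frozenset({"NGG", "NAG"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default variant-anchored window: 30-nt flanks either side of the variant
DEFAULT_WINDOW = 61


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_motif(tri: str, motifs: Iterable[str]) -> bool:
    if len(tri) != 3:
        return False
    for motif in motifs:
        if all(m == "N" or m == b for m, b in zip(motif, tri)):
            return True
    return False


@dataclass(frozen=True)
class AlleleContext:
    """A variant anchored in its local sequence window (ref-allele sequence)."""

    variant_id: str
    window: str
    variant_offset: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        window = self.window.upper()
        object.__setattr__(self, "window", window)
        if set(window) - set("ACGT"):
            raise ValidationError(f"{self.variant_id}: window not over ACGT")
        if not (
            0 <= self.variant_offset
            and self.variant_offset + len(self.ref_allele) <= len(window)
        ):
            raise ValidationError(f"{self.variant_id}: variant_offset out of window")
        if window[self.variant_offset : self.variant_offset + len(self.ref_allele)] != (
            self.ref_allele.upper()
        ):
            raise ValidationError(
                f"{self.variant_id}: window does not carry the ref allele at offset"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def ref_sequence(self) -> str:
        return self.window

    @property
    def alt_sequence(self) -> str:
        i = self.variant_offset
        return self.window[:i] + self.alt_allele.upper() + self.window[i + len(self.ref_allele):]


@dataclass(frozen=True)
class GuideDesign:
    """A 20-nt allele-specific protospacer and its polymorphic PAM."""

    variant_id: str
    protospacer: str
    strand: str
    pam_position: int
    pam_sensitive: str
    pam_resistant: str
    sensitive_allele: str  # "ref" | "alt"

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValidationError("protospacer must be exactly 20 nt")
        if not _matches_motif(self.pam_sensitive, DEFAULT_MOTIFS):
            raise ValidationError(f"sensitive PAM {self.pam_sensitive} not NGG/NAG")
        if _matches_motif(self.pam_resistant, DEFAULT_MOTIFS):
            raise ValidationError(f"resistant PAM {self.pam_resistant} is a PAM")


def enumerate_pams(
    sequence: str,
    motifs: Iterable[str] = DEFAULT_MOTIFS,
    strands: str = "both",
) -> list[tuple[int, str, str]]:
    """Exhaustively list PAM placements as (position, strand, trinucleotide).

    Positions are plus-strand 0-based starts of the trinucleotide window;
    a minus-strand placement at position i means the reverse complement
    of ``sequence[i:i+3]`` matches a motif.
    """
    sequence = sequence.upper()
    out = []
    for i in range(len(sequence) - 2):
        tri = sequence[i : i + 3]
        if strands in ("both", "+") and _matches_motif(tri, motifs):
            out.append((i, "+", tri))
        if strands in ("both", "-"):
            rc = reverse_complement(tri)
            if _matches_motif(rc, motifs):
                out.append((i, "-", rc))
    return out


def _placements_overlapping(seq_len: int, start: int, end: int) -> list[int]:
    """Trinucleotide window starts overlapping the interval [start, end)."""
    lo = max(0, start - 2)
    hi = min(seq_len - 3, end - 1)
    return list(range(lo, hi + 1))


def allele_specific_pam(
    context: AlleleContext, motifs: Iterable[str] = DEFAULT_MOTIFS
) -> tuple[bool, Optional[str], list[tuple[int, str]]]:
    """Decide whether a variant creates a PAM in exactly one allele.

    For SNVs, every trinucleotide placement (position, strand) overlapping
    the variant base is compared between the two allele sequences; the
    variant is allele-specific iff some placement is a PAM in exactly one
    allele, and all such placements favour the same allele.  (When both
    alleles gain PAMs at *different* placements the variant is reported
    not-specific but logged, since each placement alone may still
    discriminate.)

    For indels the two allele sequences differ in length, so placements
    cannot be compared one-to-one; instead the variant is allele-specific
    iff exactly one allele sequence contains at least one PAM overlapping
    the edited interval +/- 2 nt.

    Returns ``(is_specific, sensitive_allele, placements)`` where
    placements are the discriminating (position, strand) pairs on the
    sensitive allele's sequence.
    """
    motifs = frozenset(motifs)
    ref_seq = context.ref_sequence
    alt_seq = context.alt_sequence
    off = context.variant_offset

    if context.is_snv:
        ref_only: list[tuple[int, str]] = []
        alt_only: list[tuple[int, str]] = []
        for pos in _placements_overlapping(len(ref_seq), off, off + 1):
            for strand in ("+", "-"):
                ref_tri = ref_seq[pos : pos + 3]
                alt_tri = alt_seq[pos : pos + 3]
                if strand == "-":
                    ref_tri = reverse_complement(ref_tri)
                    alt_tri = reverse_complement(alt_tri)
                ref_pam = _matches_motif(ref_tri, motifs)
                alt_pam = _matches_motif(alt_tri, motifs)
                if ref_pam and not alt_pam:
                    ref_only.append((pos, strand))
                elif alt_pam and not ref_pam:
                    alt_only.append((pos, strand))
        if ref_only and alt_only:
            log.info(
                "%s: both alleles create PAMs at different placements; "
                "reported not allele-specific",
                context.variant_id,
            )
            return False, None, []
        if ref_only:
            return True, "ref", ref_only
        if alt_only:
            return True, "alt", alt_only
        return False, None, []

    # indel: presence/absence of any PAM overlapping the edited interval +/- 2 nt
    def overlapping_pams(seq: str, allele: str) -> list[tuple[int, str]]:
        lo = off - 2
        hi = off + len(allele) + 2
        found = []
        for pos in range(max(0, lo - 2), min(len(seq) - 3, hi - 1) + 1):
            if pos + 3 <= lo or pos >= hi:
                continue
            for strand in ("+", "-"):
                tri = seq[pos : pos + 3]
                if strand == "-":
                    tri = reverse_complement(tri)
                if _matches_motif(tri, motifs):
                    found.append((pos, strand))
        return found

    ref_hits = overlapping_pams(ref_seq, context.ref_allele)
    alt_hits = overlapping_pams(alt_seq, context.alt_allele)
    if bool(ref_hits) == bool(alt_hits):
        return False, None, []
    if ref_hits:
        return True, "ref", ref_hits
    return True, "alt", alt_hits


def design_as_guide(
    context: AlleleContext,
    placement: tuple[int, str],
    sensitive_allele: str,
) -> GuideDesign:
    """Design the allele-specific guide for a discriminating PAM placement.

    The protospacer is the 20 nt immediately 5' of the PAM on the
    sensitive allele's sequence (on the PAM's strand).  Raises when fewer
    than 20 nt of flank are available inside the window.
    """
    pos, strand = placement
    sens_seq = context.ref_sequence if sensitive_allele == "ref" else context.alt_sequence
    res_seq = context.alt_sequence if sensitive_allele == "ref" else context.ref_sequence
    if strand == "+":
        if pos < 20:
            raise ValidationError(
                f"{context.variant_id}: only {pos} nt 5' of the PAM in the window; "
                "provide a wider window"
            )
        protospacer = sens_seq[pos - 20 : pos]
        pam_s = sens_seq[pos : pos + 3]
        pam_r = res_seq[pos : pos + 3]
    else:
        if pos + 23 > len(sens_seq):
            raise ValidationError(
                f"{context.variant_id}: insufficient 5' flank on the minus strand; "
                "provide a wider window"
            )
        protospacer = reverse_complement(sens_seq[pos + 3 : pos + 23])
        pam_s = reverse_complement(sens_seq[pos : pos + 3])
        pam_r = reverse_complement(res_seq[pos : pos + 3])
    return GuideDesign(
        variant_id=context.variant_id,
        protospacer=protospacer,
        strand=strand,
        pam_position=pos,
        pam_sensitive=pam_s,
        pam_resistant=pam_r,
        sensitive_allele=sensitive_allele,
    )


def pam_fraction(
    contexts: Sequence[AlleleContext],
    consequence_by_id: Optional[Mapping[str, str]] = None,
    orf_classes_only: bool = False,
    motifs: Iterable[str] = DEFAULT_MOTIFS,
) -> tuple[int, int, float]:
    """Fraction of variants whose alleles differ in PAM content.

    With ``orf_classes_only`` the denominator is restricted to variants
    whose consequence class lies in an open reading frame (UTR classes
    excluded); ``consequence_by_id`` supplies the classes.  Returns
    ``(n_specific, n_total, fraction)``; fraction is NaN when n_total = 0.
    """
    n_specific = 0
    n_total = 0
    for ctx in contexts:
        if orf_classes_only:
            if consequence_by_id is None:
                raise ValidationError(
                    "orf_classes_only requires consequence_by_id"
                )
            cls = consequence_by_id.get(ctx.variant_id)
            if cls not in ORF_CLASSES:
                continue
        n_total += 1
        specific, _, _ = allele_specific_pam(ctx, motifs)
        if specific:
            n_specific += 1
    fraction = n_specific / n_total if n_total else float("nan")
    return n_specific, n_total, fraction
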