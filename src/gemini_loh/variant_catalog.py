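"""Common-variant catalog: filtering, heterozygosity, protein consequences.

The catalog keeps PASSing variants with folded minor allele frequency
at or above a threshold (default 0.01) in the closed set of targetable
consequence classes.  Heterozygosity is the Hardy-Weinberg expectation
2pq at the variant's MAF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .formats_io import CONSEQUENCE_CLASSES, ORF_CLASSES, ValidationError, VariantRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*")


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level consequence of a coding variant."""

    kind: str  # missense | inframe_insertion | inframe_deletion | other
    ref_residues: str
    alt_residues: str
    residue_position: int

    def __post_init__(self):
        for residues in (self.ref_residues, self.alt_residues):
            if set(residues) - AMINO_ACIDS:
                raise ValidationError(f"unknown residue in {residues!r}")
        if self.kind == "missense" and not (
            len(self.ref_residues) == 1 and len(self.alt_residues) == 1
        ):
            raise ValidationError("missense requires single residues on both sides")

    @property
    def short_form(self) -> str:
        """HGVS-like short form, e.g. D5A."""
        return f"{self.ref_residues}{self.residue_position}{self.alt_residues}"


def filter_common_variants(
    variants: Iterable[VariantRecord],
    maf_min: float = 0.01,
    classes: frozenset[str] = CONSEQUENCE_CLASSES,
) -> list[VariantRecord]:
    """Keep PASSing variants with MAF >= maf_min (inclusive) in ``classes``.

    Input order is preserved; the operation is idempotent.
    """
    return [
        v
        for v in variants
        if v.filter_status == "PASS"
        and v.global_af >= maf_min
        and v.consequence_class in classes
    ]


def heterozygosity(maf: float) -> float:
    """Hardy-Weinberg heterozygote fraction 2pq for minor allele frequency p."""
    if not 0.0 <= maf <= 0.5:
        raise ValidationError(
            f"MAF {maf} outside [0, 0.5]; fold the allele frequency first"
        )
    return 2.0 * maf * (1.0 - maf)


def per_gene_variant_summary(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-gene variant count and median MAF over an (already filtered) catalog.

    Genes absent from ``variants`` simply do not appear; the median of an
    even-length list is the midpoint mean (numpy convention).
    """
    if not variants:
        return pd.DataFrame(columns=["gene_symbol", "n_variants", "median_maf"])
    df = pd.DataFrame(
        {
            "gene_symbol": [v.gene_symbol for v in variants],
            "maf": [v.global_af for v in variants],
        }
    )
    out = (
        df.groupby("gene_symbol")["maf"]
        .agg(n_variants="size", median_maf="median")
        .reset_index()
    )
    return out


def cohort_median_maf(variants: Sequence[VariantRecord]) -> float:
    """Median MAF across all catalog variants (NaN on empty input)."""
    if not variants:
        return float("nan")
    return float(np.median([v.global_af for v in variants]))


def compare_maf_distributions(
    essential_mafs: Sequence[float], nonessential_mafs: Sequence[float]
) -> tuple[float, float]:
    """One-sided Welch t-test of essential < non-essential MAF.

    Returns ``(t, p)``; a small p supports the hypothesis that variants in
    essential genes are rarer than those in non-essential genes.
    """
    a = np.asarray(essential_mafs, dtype=float)
    b = np.asarray(nonessential_mafs, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValidationError("zero-variance inputs")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(t), float(p)


def six_frame_translate(context: str) -> list[str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns three forward frames followed by three reverse-complement
    frames; stops are rendered ``*`` and trailing partial codons dropped.
    """
    context = context.upper()
    if set(context) - set("ACGT"):
        raise ValidationError("sequence contains non-ACGT characters")
    if len(context) < 3:
        raise ValidationError("sequence shorter than one codon")
    frames = []
    for template in (Seq(context), Seq(context).reverse_complement()):
        for offset in range(3):
            sub = template[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    return frames


def classify_protein_change(
    ref_residues: str, alt_residues: str, position: int
) -> ProteinChange:
    """Classify a protein change by residue-length comparison."""
    if ref_residues == alt_residues:
        raise ValidationError(
            f"{ref_residues}->{alt_residues}: identical residues are not protein-altering"
        )
    if len(ref_residues) == 1 and len(alt_residues) == 1:
        kind = "missense"
    elif len(alt_residues) > len(ref_residues):
        kind = "inframe_insertion"
    elif len(alt_residues) < len(ref_residues):
        kind = "inframe_deletion"
    else:
        kind = "other"
    return ProteinChange(kind, ref_residues, alt_residues, position)
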