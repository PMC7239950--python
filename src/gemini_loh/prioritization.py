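"""Target compendium assembly and scoring.

Each compendium row pairs a common germline variant with a
final-essential gene and carries everything needed to judge it as an
allele-specific target: Hardy-Weinberg heterozygosity, tumor LOH rates,
a theoretical yearly patient reach, whether the variant sits in a
polymorphic PAM, RNAi dependency strength, and a 0-7 druggability
composite.

The patient reach is Pi = kappa * chi * lambda * 0.5, with kappa the
number of new US cancer cases per year (default 1,735,350), chi the
heterozygosity 2pq at the variant's MAF, lambda the pan-cancer LOH rate
of the gene, and 0.5 the chance that the allele lost in the tumor is the
one that makes the retained allele targetable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import ValidationError, VariantRecord
from .variant_catalog import ProteinChange, heterozygosity

log = logging.getLogger(__name__)

KAPPA_US_CASES_PER_YEAR = 1_735_350
DEMETER2_CUT = -0.5
LIGAND_DRUGGABILITY_PERCENTILE_CUT = 90.0
VISUAL_POCKET_CUT = 3

NEGATIVE_RESIDUES = frozenset("DE")
#: histidine counted positively charged (conventional physiological-pH classes)
POSITIVE_RESIDUES = frozenset("KRH")
CHARGED_RESIDUES = NEGATIVE_RESIDUES | POSITIVE_RESIDUES


@dataclass(frozen=True)
class DruggabilityAnnotation:
    """Per-variant druggability evidence (canSAR-style plus manual scores)."""

    has_ligand_bound_structure: bool
    structure_druggable_or_tractable: bool
    ligand_druggability_percentile: float
    has_ec_number: bool
    visual_pocket_score: int
    charge_altering: bool
    introduces_cysteine: bool

    def __post_init__(self):
        if self.visual_pocket_score not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"visual pocket score {self.visual_pocket_score} not in 0..4"
            )
        if not 0.0 <= self.ligand_druggability_percentile <= 100.0:
            raise ValidationError("ligand druggability percentile outside [0, 100]")


def patients_per_year(
    kappa: float, chi: float, lam: float
) -> int:
    """Theoretical new US patients per year: round(kappa * chi * lam * 0.5)."""
    if kappa < 0 or lam < 0 or lam > 1:
        raise ValidationError("kappa must be >= 0 and lambda in [0, 1]")
    if not 0.0 <= chi <= 0.5:
        raise ValidationError(f"heterozygosity {chi} outside [0, 0.5]")
    return int(math.floor(kappa * chi * lam * 0.5 + 0.5))


def classify_dependency(
    demeter2_scores: Sequence[float], cut: float = DEMETER2_CUT
) -> tuple[float, bool]:
    """Median RNAi (DEMETER2) score over non-missing lines and strength call.

    A gene is a moderately strong dependency when its median score is
    <= -0.5 (boundary inclusive).  Returns (NaN, False) with no data.
    """
    scores = np.asarray(list(demeter2_scores), dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        return float("nan"), False
    median = float(np.median(scores))
    return median, median <= cut


def enrichment_test(
    k_subset: int, n_subset: int, k_background: int, n_background: int
) -> float:
    """Exact one-sided binomial proportion test, alternative 'greater'.

    Tests whether k_subset/n_subset exceeds the background proportion
    k_background/n_background.
    """
    for k, n in ((k_subset, n_subset), (k_background, n_background)):
        if k < 0 or n <= 0 or k > n:
            raise ValidationError(f"invalid counts k={k}, n={n}")
    p0 = k_background / n_background
    return float(stats.binomtest(k_subset, n_subset, p0, alternative="greater").pvalue)


def _charge_class(residue: str) -> str:
    if residue not in set("ACDEFGHIKLMNPQRSTVWY*"):
        raise ValidationError(f"unknown residue {residue!r}")
    if residue in NEGATIVE_RESIDUES:
        return "negative"
    if residue in POSITIVE_RESIDUES:
        return "positive"
    return "neutral"


def charge_change(change: ProteinChange) -> bool:
    """Does the variant alter the number or sign of residue charges?

    Missense: true iff the ref and alt residues fall in different charge
    classes.  Insertions/deletions: true iff any inserted or deleted
    residue is charged.
    """
    if change.kind == "missense":
        return _charge_class(change.ref_residues) != _charge_class(change.alt_residues)
    if change.kind == "inframe_insertion":
        inserted = change.alt_residues[len(change.ref_residues):]
        return any(r in CHARGED_RESIDUES for r in inserted)
    if change.kind == "inframe_deletion":
        deleted = change.ref_residues[len(change.alt_residues):]
        return any(r in CHARGED_RESIDUES for r in deleted)
    return any(
        _charge_class(r) != "neutral"
        for r in set(change.ref_residues) ^ set(change.alt_residues)
    )


def introduces_cysteine(change: ProteinChange) -> bool:
    """True iff exactly one allele carries a cysteine at the affected residues."""
    ref_has = "C" in change.ref_residues
    alt_has = "C" in change.alt_residues
    return alt_has != ref_has


def composite_score(annotation: DruggabilityAnnotation) -> int:
    """0-7 druggability composite: one point per satisfied criterion."""
    criteria = (
        annotation.has_ligand_bound_structure,
        annotation.structure_druggable_or_tractable,
        annotation.ligand_druggability_percentile >= LIGAND_DRUGGABILITY_PERCENTILE_CUT,
        annotation.has_ec_number,
        annotation.visual_pocket_score >= VISUAL_POCKET_CUT,
        annotation.charge_altering,
        annotation.introduces_cysteine,
    )
    return sum(bool(c) for c in criteria)


def yates_chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Chi-square with Yates continuity correction for a 2x2 table.

    The correction term |O - E| - 0.5 is floored at 0.  Any zero marginal
    raises, since expecteds are then undefined or degenerate.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValidationError("expected a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(stat), float(p)


def assemble_compendium(
    essential_genes: set[str],
    catalog: Sequence[VariantRecord],
    loh_rates_pan: Mapping[str, float],
    pam_specific_ids: set[str],
    demeter2: Optional[pd.DataFrame] = None,
    annotations: Optional[Mapping[str, DruggabilityAnnotation]] = None,
    kappa: float = KAPPA_US_CASES_PER_YEAR,
    demeter2_cut: float = DEMETER2_CUT,
) -> pd.DataFrame:
    """Join the catalog against the essential-gene set into the compendium.

    One row per (common variant, final-essential gene) pair, ordered by
    gene then position.  LOH rates annotate rows (0 when the gene was
    never observed with LOH) but never filter them.  ``demeter2`` is a
    gene x cell-line score matrix; ``annotations`` maps variant_id to
    druggability evidence (rows without one get a missing composite).
    """
    rows = []
    for v in catalog:
        if v.gene_symbol not in essential_genes:
            continue
        if v.gene_symbol not in loh_rates_pan:
            log.warning(
                "%s: gene %s has no LOH characterization; row emitted without "
                "LOH annotation", v.variant_id, v.gene_symbol,
            )
            lam = float("nan")
        else:
            lam = float(loh_rates_pan[v.gene_symbol])
        chi = heterozygosity(v.global_af)
        pi = patients_per_year(kappa, chi, lam) if not math.isnan(lam) else np.nan
        if demeter2 is not None and v.gene_symbol in demeter2.index:
            d2_median, strong = classify_dependency(
                demeter2.loc[v.gene_symbol].to_numpy(), demeter2_cut
            )
        else:
            d2_median, strong = float("nan"), False
        ann = annotations.get(v.variant_id) if annotations else None
        rows.append(
            {
                "gene_symbol": v.gene_symbol,
                "variant_id": v.variant_id,
                "chromosome": v.chromosome,
                "position": v.position,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "consequence_class": v.consequence_class,
                "maf": v.global_af,
                "heterozygosity": chi,
                "loh_rate_pan": lam,
                "patients_per_year": pi,
                "pam_allele_specific": v.variant_id in pam_specific_ids,
                "demeter2_median": d2_median,
                "strong_dependency": strong,
                "composite_score": composite_score(ann) if ann else np.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol", "variant_id", "chromosome", "position", "ref_allele",
            "alt_allele", "consequence_class", "maf", "heterozygosity",
            "loh_rate_pan", "patients_per_year", "pam_allele_specific",
            "demeter2_median", "strong_dependency", "composite_score",
        ],
    )
    return df.sort_values(["gene_symbol", "position"], ignore_index=True)
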