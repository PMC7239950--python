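"""Essential-gene nomination and filter cascade.

Candidate essential genes are nominated from three loss-of-function
screens of haploid cell lines (two CRISPR screens whose FDR q-values are
taken as input, plus a gene-trap screen scored here with an exact
one-sided binomial test against equal sense/antisense insertion
probability and Benjamini-Hochberg correction).  Candidates are then
filtered on cell-line copy-number/expression evidence of tolerated loss,
on mean CRISPR-knockout (CERES) dependency, rescued when cell-line data
are missing, and finally purged of Tier-1 tumor suppressor genes and of
genes without tumor copy-number characterization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ValidationError

log = logging.getLogger(__name__)

FDR_CUT = 0.10
CERES_CUT = -0.4
HOMDEL_LOG2_CUT = -5.0
LOW_RPKM = 0.5
LOW_RPKM_WITH_HOMDEL = 1.0


@dataclass
class EssentialityEvidence:
    """Per-gene screen and cell-line evidence.

    ``crispr_q_values`` maps screen id -> FDR q-value for the two CRISPR
    haploid screens; the gene-trap screen contributes raw orientation
    counts scored by :func:`gene_trap_fdr`.  Cell-line vectors may be
    ``None`` (data not available for the gene).
    """

    gene_symbol: str
    crispr_q_values: dict[str, float] = field(default_factory=dict)
    gene_trap_sense: int = 0
    gene_trap_antisense: int = 0
    ccle_log2_cn: Optional[np.ndarray] = None
    ccle_rpkm: Optional[np.ndarray] = None
    ceres_scores: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.gene_trap_sense < 0 or self.gene_trap_antisense < 0:
            raise ValidationError(f"{self.gene_symbol}: negative gene-trap count")
        for q in self.crispr_q_values.values():
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"{self.gene_symbol}: q-value {q} outside [0,1]")

    @property
    def mean_ceres(self) -> float:
        """Mean CERES over non-missing cell lines (NaN when absent)."""
        if self.ceres_scores is None:
            return float("nan")
        scores = np.asarray(self.ceres_scores, dtype=float)
        scores = scores[~np.isnan(scores)]
        return float(scores.mean()) if scores.size else float("nan")

    @property
    def ccle_missing(self) -> bool:
        return self.ccle_log2_cn is None or self.ccle_rpkm is None


@dataclass
class EssentialCall:
    gene_symbol: str
    candidate: bool
    n_screens_passed: int
    ccle_excluded: bool
    ccle_reason: str
    ceres_excluded: bool
    rescued: bool
    tsg_excluded: bool
    in_cn_calls: bool
    final_essential: bool


def gene_trap_fdr(counts: Sequence[tuple[int, int]]) -> list[float]:
    """BH q-values for sense-insertion depletion in a gene-trap screen.

    For each gene with n = sense + antisense >= 1 insertions, the p-value
    is the one-sided lower-tail exact binomial P(X <= sense | n, 0.5);
    q-values are Benjamini-Hochberg across all tested genes.  Genes with
    n = 0 get q = NaN and do not enter the correction.
    """
    pvals = []
    tested = []
    for i, (sense, antisense) in enumerate(counts):
        if sense < 0 or antisense < 0:
            raise ValidationError(f"negative gene-trap count at index {i}")
        n = sense + antisense
        if n == 0:
            pvals.append(float("nan"))
        else:
            pvals.append(float(stats.binom.cdf(sense, n, 0.5)))
            tested.append(i)
    qvals = [float("nan")] * len(counts)
    if tested:
        _, q, _, _ = multipletests([pvals[i] for i in tested], method="fdr_bh")
        for i, qi in zip(tested, q):
            qvals[i] = float(qi)
    return qvals


def nominate_candidates(
    screen_qvalues: Sequence[dict[str, float]], fdr: float = FDR_CUT
) -> list[tuple[bool, int]]:
    """Candidate call per gene from the three screen q-values.

    A gene is a candidate essential gene when q < fdr (strict) in at
    least one screen; NaN q-values never pass.
    """
    if not 0.0 < fdr < 1.0:
        raise ValidationError(f"FDR threshold {fdr} outside (0, 1)")
    out = []
    for qmap in screen_qvalues:
        n_passed = sum(
            1 for q in qmap.values() if not math.isnan(q) and q < fdr
        )
        out.append((n_passed >= 1, n_passed))
    return out


def ccle_filter(evidence: EssentialityEvidence) -> tuple[bool, str]:
    """Exclude genes whose loss is tolerated in cell lines.

    Criteria (any one excludes): homozygous deletion (log2 CN < -5) in
    more than 2 lines; very low expression (< 0.5 RPKM) in more than 5
    lines; or homozygous deletion in at least 1 line that also has low
    expression (< 1.0 RPKM) in that same line.  When cell-line data are
    absent the filter is inapplicable: ``(False, "missing_data")``.
    """
    if evidence.ccle_missing:
        return False, "missing_data"
    cn = np.asarray(evidence.ccle_log2_cn, dtype=float)
    rpkm = np.asarray(evidence.ccle_rpkm, dtype=float)
    homdel = cn < HOMDEL_LOG2_CUT
    if np.nansum(homdel) > 2:
        return True, "homozygous_deletion"
    if np.nansum(rpkm < LOW_RPKM) > 5:
        return True, "low_expression"
    if cn.shape == rpkm.shape and np.any(homdel & (rpkm < LOW_RPKM_WITH_HOMDEL)):
        return True, "homdel_with_low_expression"
    return False, ""


def ceres_filter(evidence: EssentialityEvidence, ceres_cut: float = CERES_CUT) -> bool:
    """Exclude genes with mean CERES score > -0.4 (a mean of exactly -0.4 is retained).

    Genes with no CERES data at all cannot demonstrate dependency and are
    excluded here; missing-data cases are the province of the rescue rule.
    """
    mean = evidence.mean_ceres
    if math.isnan(mean):
        return True
    return mean > ceres_cut


def rescue_rule(
    evidence: EssentialityEvidence, n_screens_passed: int, ceres_cut: float = CERES_CUT
) -> bool:
    """Rescue a gene lacking cell-line copy-number/expression data.

    Applies only when CCLE data are missing; the gene is rescued when it
    scored essential in at least two of the three haploid screens and its
    mean CERES score is strictly below -0.4.
    """
    if not evidence.ccle_missing:
        return False
    mean = evidence.mean_ceres
    return n_screens_passed >= 2 and not math.isnan(mean) and mean < ceres_cut


def run_cascade(
    evidence: Sequence[EssentialityEvidence],
    tsg_list: set[str] = frozenset(),
    genes_with_cn_calls: Optional[set[str]] = None,
    fdr: float = FDR_CUT,
    ceres_cut: float = CERES_CUT,
) -> list[EssentialCall]:
    """Run the full essential-gene filter cascade.

    final_essential = candidate and (not ccle_excluded or rescued)
    and (not ceres_excluded or rescued) and not tsg_excluded
    and gene in genes_with_cn_calls.  ``genes_with_cn_calls=None`` means
    every gene has tumor copy-number characterization.
    """
    trap_q = gene_trap_fdr(
        [(e.gene_trap_sense, e.gene_trap_antisense) for e in evidence]
    )
    screen_q = [
        {**e.crispr_q_values, "gene_trap": q} for e, q in zip(evidence, trap_q)
    ]
    nominations = nominate_candidates(screen_q, fdr=fdr)

    calls = []
    for e, (candidate, n_passed) in zip(evidence, nominations):
        ccle_excluded, reason = ccle_filter(e)
        ceres_excluded = ceres_filter(e, ceres_cut)
        rescued = candidate and rescue_rule(e, n_passed, ceres_cut)
        tsg_excluded = e.gene_symbol in tsg_list
        in_cn = genes_with_cn_calls is None or e.gene_symbol in genes_with_cn_calls
        final = (
            candidate
            and (not ccle_excluded or rescued)
            and (not ceres_excluded or rescued)
            and not tsg_excluded
            and in_cn
        )
        calls.append(
            EssentialCall(
                gene_symbol=e.gene_symbol,
                candidate=candidate,
                n_screens_passed=n_passed,
                ccle_excluded=ccle_excluded,
                ccle_reason=reason,
                ceres_excluded=ceres_excluded,
                rescued=rescued,
                tsg_excluded=tsg_excluded,
                in_cn_calls=in_cn,
                final_essential=final,
            )
        )
    _log_stage_counts(calls)
    return calls


def _log_stage_counts(calls: Sequence[EssentialCall]) -> None:
    n_cand = sum(c.candidate for c in calls)
    n_post_ccle = sum(c.candidate and (not c.ccle_excluded or c.rescued) for c in calls)
    n_post_ceres = sum(
        c.candidate
        and (not c.ccle_excluded or c.rescued)
        and (not c.ceres_excluded or c.rescued)
        for c in calls
    )
    n_rescued = sum(c.rescued for c in calls)
    n_final = sum(c.final_essential for c in calls)
    log.info(
        "essentiality cascade: %d genes -> %d candidates -> %d post-CCLE -> "
        "%d post-CERES (%d rescued) -> %d final essential",
        len(calls), n_cand, n_post_ccle, n_post_ceres, n_rescued, n_final,
    )


def stage_counts(calls: Sequence[EssentialCall]) -> dict[str, int]:
    """Per-stage accounting of the cascade, for logs and summary tables."""
    return {
        "n_genes": len(calls),
        "n_candidates": sum(c.candidate for c in calls),
        "n_all_three_screens": sum(c.n_screens_passed == 3 for c in calls),
        "n_ccle_excluded": sum(c.candidate and c.ccle_excluded for c in calls),
        "n_ceres_excluded": sum(c.candidate and c.ceres_excluded for c in calls),
        "n_rescued": sum(c.rescued for c in calls),
        "n_tsg_excluded": sum(c.candidate and c.tsg_excluded for c in calls),
        "n_final_essential": sum(c.final_essential for c in calls),
    }
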