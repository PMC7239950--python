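"""Loss-of-heterozygosity calling from allelic copy-number segments.

A tumor locus has undergone LOH when the absolute copy number of one
allele is zero (minor_cn = 0) on an autosome.  LOH events are split by
total copy number into copy-loss (gene-level log2 relative <= -0.1) and
copy-neutral (> -0.1).  Per-sample segments are transformed into
per-gene calls by assigning each gene the overlapping segment with
maximal overlap, ties broken by leftmost segment start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import AllelicSegment, GeneModel, ValidationError

log = logging.getLogger(__name__)

LOG2_LOSS_CUT = -0.1

LOH_NONE = "none"
LOH_COPY_LOSS = "copy_loss"
LOH_COPY_NEUTRAL = "copy_neutral"


@dataclass(frozen=True)
class GeneLohCall:
    sample_id: str
    tumor_type: str
    gene_symbol: str
    minor_cn: int
    log2_relative: float
    loh_class: str


def classify_loh(
    minor_cn: int, log2_relative: float, is_autosome: bool, log2_cut: float = LOG2_LOSS_CUT
) -> str:
    """Classify one gene call as none / copy_loss / copy_neutral LOH."""
    if minor_cn < 0:
        raise ValidationError(f"negative minor_cn {minor_cn}")
    if not is_autosome or minor_cn >= 1:
        return LOH_NONE
    return LOH_COPY_LOSS if log2_relative <= log2_cut else LOH_COPY_NEUTRAL


def segments_to_gene_calls(
    segments: Sequence[AllelicSegment],
    genes: Sequence[GeneModel],
    log2_cut: float = LOG2_LOSS_CUT,
) -> list[GeneLohCall]:
    """Transform per-sample segments into per-gene LOH calls.

    Each (sample, gene) pair is assigned the overlapping segment with the
    largest overlap; ties go to the segment with the leftmost start.  Genes
    with no overlapping segment in a sample get no call (they are excluded
    from all denominators downstream).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    # group segments per (sample, chromosome), preserving sample metadata
    seg_df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "tumor_type": [s.tumor_type for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "minor_cn": [s.minor_cn for s in segments],
            "log2_relative": [s.log2_relative for s in segments],
        }
    )
    calls: list[GeneLohCall] = []
    if seg_df.empty:
        return calls
    for (sample_id, tumor_type, chrom), grp in seg_df.groupby(
        ["sample_id", "tumor_type", "chromosome"], sort=True
    ):
        gene_list = by_chrom.get(chrom)
        if not gene_list:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        minors = grp["minor_cn"].to_numpy()
        log2s = grp["log2_relative"].to_numpy()
        for gene in gene_list:
            overlap = np.minimum(ends, gene.end) - np.maximum(starts, gene.start)
            hit = overlap > 0
            if not hit.any():
                continue
            best = overlap[hit].max()
            tied = np.flatnonzero(hit & (overlap == best))
            if tied.size > 1:
                values = {(int(minors[i]), float(log2s[i])) for i in tied}
                if len(values) > 1:
                    log.warning(
                        "%s %s: tied max-overlap segments with contradictory values; "
                        "using leftmost",
                        sample_id,
                        gene.gene_symbol,
                    )
                idx = tied[np.argmin(starts[tied])]
            else:
                idx = tied[0]
            minor = int(minors[idx])
            log2 = float(log2s[idx])
            calls.append(
                GeneLohCall(
                    sample_id=str(sample_id),
                    tumor_type=str(tumor_type),
                    gene_symbol=gene.gene_symbol,
                    minor_cn=minor,
                    log2_relative=log2,
                    loh_class=classify_loh(minor, log2, gene.is_autosome, log2_cut),
                )
            )
    return calls


def calls_to_frame(calls: Iterable[GeneLohCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "tumor_type": [c.tumor_type for c in calls],
            "gene_symbol": [c.gene_symbol for c in calls],
            "minor_cn": [c.minor_cn for c in calls],
            "log2_relative": [c.log2_relative for c in calls],
            "loh_class": [c.loh_class for c in calls],
        }
    )


def sample_loh_fraction(calls: Sequence[GeneLohCall]) -> float:
    """Fraction of callable genes with LOH in one sample (NaN if no calls)."""
    if not calls:
        return float("nan")
    n_loh = sum(c.loh_class != LOH_NONE for c in calls)
    return n_loh / len(calls)


def sample_essential_loh_count(
    calls: Sequence[GeneLohCall], essential_set: set[str]
) -> int:
    """Number of essential genes with LOH in one sample."""
    return sum(
        c.loh_class != LOH_NONE and c.gene_symbol in essential_set for c in calls
    )


def cohort_gene_loh_rate(
    calls: Sequence[GeneLohCall], by: str = "pan_cancer"
) -> pd.DataFrame:
    """Per-gene LOH rate table, pan-cancer or stratified by tumor type.

    Columns: gene_symbol, stratum, n_called, n_loh, n_copy_neutral, rate,
    copy_neutral_share (share of LOH events that are copy-neutral; NaN when
    a gene has no LOH events in the stratum).
    """
    if by not in ("pan_cancer", "tumor_type"):
        raise ValidationError(f"unknown stratum {by!r}")
    df = calls_to_frame(calls)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "gene_symbol", "stratum", "n_called", "n_loh",
                "n_copy_neutral", "rate", "copy_neutral_share",
            ]
        )
    df["stratum"] = "pan_cancer" if by == "pan_cancer" else df["tumor_type"]
    df["is_loh"] = df["loh_class"] != LOH_NONE
    df["is_cn"] = df["loh_class"] == LOH_COPY_NEUTRAL
    out = (
        df.groupby(["gene_symbol", "stratum"])
        .agg(n_called=("is_loh", "size"), n_loh=("is_loh", "sum"), n_copy_neutral=("is_cn", "sum"))
        .reset_index()
    )
    out["rate"] = out["n_loh"] / out["n_called"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["copy_neutral_share"] = np.where(
            out["n_loh"] > 0, out["n_copy_neutral"] / out["n_loh"], np.nan
        )
    return out.sort_values(["gene_symbol", "stratum"], ignore_index=True)


def loh_rate_lookup(rate_table: pd.DataFrame) -> Mapping[str, float]:
    """Map gene_symbol -> pan-cancer LOH rate from a rate table."""
    pan = rate_table[rate_table["stratum"] == "pan_cancer"]
    return dict(zip(pan["gene_symbol"], pan["rate"]))


def compare_loh_rates(
    essential_rates: Sequence[float], nonessential_rates: Sequence[float]
) -> tuple[float, float]:
    """One-sided Welch t-test of essential < non-essential per-gene LOH rates."""
    from .variant_catalog import compare_maf_distributions

    return compare_maf_distributions(essential_rates, nonessential_rates)
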