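"""Synthetic cohort generator with the statistical structure the analysis assumes.

Emulates the four external data sources the pipeline consumes — a
population variant catalog with controllable PAM-overlapping contexts,
per-tumor allelic copy-number segments with planted per-type LOH rates
and a planted copy-neutral share, loss-of-function screen evidence with
planted essential genes, and druggability annotation tables — so that
every downstream stage is testable without downloads, and so that the
planted parameters are recoverable by the analysis modules.

All generators are deterministic under ``SimulationConfig.seed``; each
uses an independent substream so the outputs of one generator do not
shift when another is reconfigured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import formats_io
from .allele_crispr import AlleleContext, allele_specific_pam
from .essentiality import EssentialityEvidence
from .formats_io import AllelicSegment, GeneModel, ValidationError, VariantRecord
from .prioritization import DruggabilityAnnotation
from .variant_catalog import ProteinChange

_AUTOSOME_COUNT = 22
_GENE_LENGTH = 3_000
_GENE_SPACING = 10_000
_WINDOW = 61
_OFFSET = 30  # variant position inside the context window

#: weights over consequence classes, missense-heavy like an exome catalog
_CLASS_WEIGHTS = {
    "missense_variant": 0.30,
    "synonymous_variant": 0.22,
    "3_prime_UTR_variant": 0.10,
    "5_prime_UTR_variant": 0.08,
    "splice_region_variant": 0.08,
    "inframe_deletion": 0.04,
    "inframe_insertion": 0.04,
    "frameshift_variant": 0.04,
    "stop_gained": 0.03,
    "splice_acceptor_variant": 0.02,
    "splice_donor_variant": 0.02,
    "initiator_codon_variant": 0.01,
    "stop_lost": 0.01,
    "stop_retained_variant": 0.01,
}

_SNV_CLASSES = frozenset(_CLASS_WEIGHTS) - {
    "inframe_deletion", "inframe_insertion", "frameshift_variant"
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    The defaults are the study conditions the analysis is validated
    under: four tumor types at 500 samples each with planted LOH rates
    spanning the observed per-type range (0.45 down to 0.01), a 0.28
    copy-neutral share among LOH events, common-variant MAFs on
    [0.01, 0.5], a 0.23 fraction of variants sitting in polymorphic PAM
    sites, and 1000 genes of which 100 are planted essential with a 0.8
    mean dependency-score shift.
    """

    seed: int = 0
    n_genes: int = 1000
    n_essential: int = 100
    n_samples_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"ACC": 500, "LUAD": 500, "PAAD": 500, "THCA": 500}
    )
    loh_rate_per_type: Mapping[str, float] = field(
        default_factory=lambda: {"ACC": 0.45, "LUAD": 0.21, "PAAD": 0.09, "THCA": 0.01}
    )
    copy_neutral_fraction: float = 0.28
    maf_low: float = 0.01
    maf_high: float = 0.5
    pam_overlap_fraction: float = 0.23
    n_cell_lines: int = 25
    essential_effect: float = 0.8
    mean_variants_per_gene: float = 3.0
    decoy_low_maf_fraction: float = 0.1
    decoy_nonpass_fraction: float = 0.1
    ccle_trigger_fraction: float = 0.05
    missing_ccle_fraction: float = 0.02
    druggability_prevalence: float = 0.2
    tsg_genes: tuple[str, ...] = ()

    def __post_init__(self):
        fractions = {
            "copy_neutral_fraction": self.copy_neutral_fraction,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "pam_overlap_fraction": self.pam_overlap_fraction,
            "decoy_low_maf_fraction": self.decoy_low_maf_fraction,
            "decoy_nonpass_fraction": self.decoy_nonpass_fraction,
            "ccle_trigger_fraction": self.ccle_trigger_fraction,
            "missing_ccle_fraction": self.missing_ccle_fraction,
            "druggability_prevalence": self.druggability_prevalence,
            **{f"loh_rate[{t}]": r for t, r in self.loh_rate_per_type.items()},
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} = {value} outside [0, 1]")
        if self.maf_low >= self.maf_high:
            raise ValidationError("maf_low must be < maf_high")
        if self.n_essential > self.n_genes:
            raise ValidationError("n_essential > n_genes")
        if self.n_genes <= 0 or self.n_cell_lines <= 0:
            raise ValidationError("counts must be positive")
        for t, n in self.n_samples_per_type.items():
            if n <= 0:
                raise ValidationError(f"n_samples_per_type[{t}] must be positive")
        if set(self.n_samples_per_type) != set(self.loh_rate_per_type):
            raise ValidationError("sample and LOH-rate tumor-type keys differ")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stream])


def gene_layout(config: SimulationConfig) -> list[GeneModel]:
    """Lay out non-overlapping genes round-robin over the 22 autosomes."""
    genes = []
    for i in range(config.n_genes):
        chrom = str(i % _AUTOSOME_COUNT + 1)
        row = i // _AUTOSOME_COUNT
        start = _GENE_SPACING + row * _GENE_SPACING
        genes.append(GeneModel(f"G{i + 1:04d}", chrom, start, start + _GENE_LENGTH))
    return genes


def planted_essential_genes(config: SimulationConfig) -> set[str]:
    """The deterministic planted-essential subset for this config."""
    rng = config.rng(0)
    idx = rng.choice(config.n_genes, size=config.n_essential, replace=False)
    return {f"G{i + 1:04d}" for i in idx}


# ---------------------------------------------------------------------------
# variants and contexts
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_window(rng: np.random.Generator) -> list[str]:
    return list(rng.choice(_BASES, size=_WINDOW))


def _fallback_specific(rng: np.random.Generator) -> tuple[str, str, str]:
    """All-A window where only the alt allele completes a PAM (alt-sensitive)."""
    window = ["A"] * _WINDOW
    window[_OFFSET] = "C"
    window[_OFFSET + 1] = "G"
    return "".join(window), "C", "G"


def _fallback_nonspecific(rng: np.random.Generator) -> tuple[str, str, str]:
    window = ["A"] * _WINDOW
    window[_OFFSET] = "C"
    return "".join(window), "C", "T"


def _draw_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    if consequence == "inframe_insertion":
        ref = str(rng.choice(_BASES))
        ins = "".join(rng.choice(_BASES, size=3))
        return ref, ref + ins
    if consequence in ("inframe_deletion", "frameshift_variant"):
        n_del = 3 if consequence == "inframe_deletion" else 2
        ref = "".join(rng.choice(_BASES, size=1 + n_del))
        return ref, ref[0]
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def _context_for(
    rng: np.random.Generator,
    variant_id: str,
    ref: str,
    alt: str,
    want_specific: bool,
    max_tries: int = 200,
) -> tuple[str, str, str]:
    """Draw a window so allele-specific PAM status matches ``want_specific``.

    Rejection-sampled from random sequence; for the PAM-overlapping case
    the draw is seeded with an alt-completed NGG at the variant site.
    Returns (window, ref, alt) — alleles may be re-drawn for SNVs to
    realise the wanted status.
    """
    snv = len(ref) == 1 and len(alt) == 1
    if want_specific and not snv:
        # random flanks almost always carry PAMs shared by both alleles, so
        # a discriminating indel needs a PAM-free (A/T) background with the
        # PAM supplied by the inserted/deleted bases themselves
        window = list(rng.choice(["A", "T"], size=_WINDOW))
        if len(alt) > len(ref):
            ref, alt = "A", "ATGG"
        else:
            ref, alt = "ATGG", "A"
        window[_OFFSET : _OFFSET + len(ref)] = list(ref)
        return "".join(window), ref, alt
    for _ in range(max_tries):
        window = _random_window(rng)
        if want_specific and snv:
            # seed an alt-completed NGG: alt G at the middle PAM position
            ref = str(rng.choice(["C", "T"]))
            alt = "G"
            window[_OFFSET + 1] = "G"
        window[_OFFSET : _OFFSET + len(ref)] = list(ref)
        seq = "".join(window)
        ctx = AlleleContext(variant_id, seq, _OFFSET, ref, alt)
        specific, _, _ = allele_specific_pam(ctx)
        if specific == want_specific:
            return seq, ref, alt
    if not snv:
        raise ValidationError(
            f"{variant_id}: could not draw an indel context with "
            f"specific={want_specific}"
        )
    return (_fallback_specific if want_specific else _fallback_nonspecific)(rng)


def simulate_variants(
    config: SimulationConfig, genes: Optional[Sequence[GeneModel]] = None
) -> tuple[list[VariantRecord], dict[str, str]]:
    """Simulate a population variant catalog and 61-nt context sequences.

    Each variant carries a planted allele-specific-PAM status: a fraction
    ``pam_overlap_fraction`` of variants is placed so that exactly one
    allele completes a PAM in its context, the rest so that neither or
    both do.  A configurable fraction of decoys fails the common-variant
    filter by sub-threshold MAF or non-PASS status.
    """
    if genes is None:
        genes = gene_layout(config)
    rng = config.rng(1)
    variants: list[VariantRecord] = []
    contexts: dict[str, str] = {}
    classes = list(_CLASS_WEIGHTS)
    weights = np.array([_CLASS_WEIGHTS[c] for c in classes])
    weights = weights / weights.sum()
    counter = 0
    for gene in genes:
        n_var = int(rng.poisson(config.mean_variants_per_gene))
        positions = rng.choice(
            np.arange(gene.start + _OFFSET, gene.end - _OFFSET),
            size=min(n_var, _GENE_LENGTH - 2 * _OFFSET),
            replace=False,
        )
        for pos in sorted(int(p) for p in positions):
            counter += 1
            vid = f"rs{counter:07d}"
            consequence = str(rng.choice(classes, p=weights))
            ref, alt = _draw_alleles(rng, consequence)
            want_specific = bool(rng.random() < config.pam_overlap_fraction)
            window, ref, alt = _context_for(rng, vid, ref, alt, want_specific)
            maf = float(rng.uniform(config.maf_low, config.maf_high))
            status = "PASS"
            if rng.random() < config.decoy_low_maf_fraction:
                maf = float(rng.uniform(0.0005, 0.0095))
            if rng.random() < config.decoy_nonpass_fraction:
                status = "low_qual"
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    gene_symbol=gene.gene_symbol,
                    chromosome=gene.chromosome,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    consequence_class=consequence,
                    global_af=maf,
                    filter_status=status,
                )
            )
            contexts[vid] = window
    return variants, contexts


# ---------------------------------------------------------------------------
# allelic segments
# ---------------------------------------------------------------------------


def simulate_allelic_segments(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> list[AllelicSegment]:
    """Simulate per-sample allelic segments with planted per-type LOH rates.

    Per sample, each gene's covering segment has minor_cn = 0 with the
    tumor type's planted probability; among LOH events a planted fraction
    is copy-neutral (major_cn 2, log2 relative > -0.1) and the rest
    copy-loss (major_cn 1, log2 relative <= -0.1).  Neutral flanking
    segments are emitted between genes so overlap assignment is
    exercised.
    """
    if not genes:
        raise ValidationError("genes must be non-empty")
    rng = config.rng(2)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)

    segments: list[AllelicSegment] = []
    for tumor_type in sorted(config.n_samples_per_type):
        n_samples = config.n_samples_per_type[tumor_type]
        rate = config.loh_rate_per_type[tumor_type]
        for i in range(n_samples):
            sample_id = f"{tumor_type}_{i:04d}"
            for chrom in sorted(by_chrom, key=lambda c: int(c) if c.isdigit() else 99):
                chrom_genes = by_chrom[chrom]
                cursor = 0
                for gene in chrom_genes:
                    if gene.start > cursor:
                        segments.append(
                            AllelicSegment(
                                sample_id, tumor_type, chrom, cursor, gene.start,
                                major_cn=1, minor_cn=1,
                                log2_relative=float(rng.normal(0.0, 0.01)),
                            )
                        )
                    is_loh = rng.random() < rate
                    if is_loh:
                        if rng.random() < config.copy_neutral_fraction:
                            major, minor = 2, 0
                            log2 = float(rng.uniform(-0.05, 0.15))
                        else:
                            major, minor = 1, 0
                            log2 = float(rng.uniform(-1.0, -0.15))
                    else:
                        major, minor = 1, 1
                        log2 = float(rng.normal(0.0, 0.02))
                    segments.append(
                        AllelicSegment(
                            sample_id, tumor_type, chrom, gene.start, gene.end,
                            major_cn=major, minor_cn=minor, log2_relative=log2,
                        )
                    )
                    cursor = gene.end
                segments.append(
                    AllelicSegment(
                        sample_id, tumor_type, chrom, cursor, cursor + 5_000,
                        major_cn=1, minor_cn=1,
                        log2_relative=float(rng.normal(0.0, 0.01)),
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def simulate_screens(
    config: SimulationConfig,
) -> tuple[list[EssentialityEvidence], pd.DataFrame, set[str]]:
    """Simulate screen evidence with planted essential genes.

    Returns per-gene evidence, a DEMETER2-style gene x cell-line score
    matrix, and the planted ground-truth essential set.  With
    ``essential_effect`` = 0 planted and null genes are statistically
    indistinguishable.
    """
    rng = config.rng(3)
    effect = config.essential_effect
    essential = planted_essential_genes(config)
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    cell_lines = [f"CL{j + 1:03d}" for j in range(config.n_cell_lines)]

    null_genes = [g for g in gene_names if g not in essential]
    n_trigger = int(round(config.ccle_trigger_fraction * len(null_genes)))
    trigger_rules = {
        g: ("homdel", "lowexpr", "homdel_lowexpr")[k % 3]
        for k, g in enumerate(null_genes[:n_trigger])
    }
    missing_mask = rng.random(config.n_genes) < config.missing_ccle_fraction

    # essential q-values concentrate near 0 as the effect grows;
    # Beta(1, 1 + 50*effect) reduces to Uniform(0,1) at effect = 0
    beta_b = 1.0 + 50.0 * effect
    p_sense_ess = 0.5 * float(np.exp(-1.5 * effect))

    evidence = []
    demeter_rows = np.empty((config.n_genes, config.n_cell_lines))
    for i, gene in enumerate(gene_names):
        is_ess = gene in essential
        if is_ess:
            q1, q2 = rng.beta(1.0, beta_b, size=2)
            p_sense = p_sense_ess
            ceres = rng.normal(-effect, 0.15, size=config.n_cell_lines)
            demeter = rng.normal(-effect, 0.2, size=config.n_cell_lines)
        else:
            q1, q2 = rng.uniform(0.0, 1.0, size=2)
            p_sense = 0.5
            ceres = rng.normal(0.0, 0.15, size=config.n_cell_lines)
            demeter = rng.normal(0.0, 0.2, size=config.n_cell_lines)
        n_insertions = max(1, int(rng.poisson(100)))
        sense = int(rng.binomial(n_insertions, p_sense))

        cn = rng.normal(0.0, 0.5, size=config.n_cell_lines)
        rpkm = np.exp(rng.normal(2.0, 1.0, size=config.n_cell_lines))
        rule = trigger_rules.get(gene)
        if rule == "homdel":
            cn[:3] = -6.0
            rpkm[:3] = np.maximum(rpkm[:3], 2.0)
        elif rule == "lowexpr":
            rpkm[:6] = 0.1
        elif rule == "homdel_lowexpr":
            cn[0] = -6.0
            rpkm[0] = 0.8

        ccle_cn = None if missing_mask[i] else cn
        ccle_rpkm = None if missing_mask[i] else rpkm
        evidence.append(
            EssentialityEvidence(
                gene_symbol=gene,
                crispr_q_values={"crispr_kbm7": float(q1), "crispr_stem": float(q2)},
                gene_trap_sense=sense,
                gene_trap_antisense=n_insertions - sense,
                ccle_log2_cn=ccle_cn,
                ccle_rpkm=ccle_rpkm,
                ceres_scores=ceres,
            )
        )
        demeter_rows[i] = demeter
    demeter2 = pd.DataFrame(demeter_rows, index=gene_names, columns=cell_lines)
    demeter2.index.name = "gene_symbol"
    return evidence, demeter2, essential


# ---------------------------------------------------------------------------
# druggability annotations
# ---------------------------------------------------------------------------

PROTEIN_ALTERING_CLASSES = frozenset(
    {"missense_variant", "inframe_insertion", "inframe_deletion"}
)

#: residue substitutions realising each (charge_altering, introduces_cysteine) pair
_SUBSTITUTIONS = {
    (True, True): ("R", "C"),
    (True, False): ("D", "A"),
    (False, True): ("S", "C"),
    (False, False): ("L", "V"),
}


def simulate_annotations(
    config: SimulationConfig, variants: Sequence[VariantRecord]
) -> dict[str, tuple[DruggabilityAnnotation, ProteinChange]]:
    """Simulate druggability annotations for protein-altering variants.

    The seven composite criteria are drawn independently with prevalence
    ``druggability_prevalence``; the charge and cysteine flags are
    realised through an actual residue substitution so the annotation is
    consistent with the protein change it describes.
    """
    rng = config.rng(4)
    prev = config.druggability_prevalence
    out = {}
    for v in variants:
        if v.consequence_class not in PROTEIN_ALTERING_CLASSES:
            continue
        flags = rng.random(7) < prev
        want_charge, want_cys = bool(flags[5]), bool(flags[6])
        position = int(rng.integers(2, 500))
        if v.consequence_class == "missense_variant":
            ref_res, alt_res = _SUBSTITUTIONS[(want_charge, want_cys)]
        else:
            # inserted/deleted residues realise the wanted flags:
            # a charged residue (R) and/or a cysteine; G is inert filler
            extra = ("R" if want_charge else "") + ("C" if want_cys else "") or "G"
            if v.consequence_class == "inframe_insertion":
                ref_res, alt_res = "A", "A" + extra
            else:
                ref_res, alt_res = "A" + extra, "A"
        change = ProteinChange(
            kind={
                "missense_variant": "missense",
                "inframe_insertion": "inframe_insertion",
                "inframe_deletion": "inframe_deletion",
            }[v.consequence_class],
            ref_residues=ref_res,
            alt_residues=alt_res,
            residue_position=position,
        )
        percentile = (
            float(rng.uniform(90.0, 100.0)) if flags[2] else float(rng.uniform(0.0, 89.9))
        )
        visual = int(rng.integers(3, 5)) if flags[4] else int(rng.integers(0, 3))
        annotation = DruggabilityAnnotation(
            has_ligand_bound_structure=bool(flags[0]),
            structure_druggable_or_tractable=bool(flags[1]),
            ligand_druggability_percentile=percentile,
            has_ec_number=bool(flags[3]),
            visual_pocket_score=visual,
            charge_altering=want_charge,
            introduces_cysteine=want_cys,
        )
        out[v.variant_id] = (annotation, change)
    return out


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------


def write_cohort(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write a complete miniature cohort in the formats the readers accept.

    Emits genes.bed, variants.vcf, contexts.fasta, segments.tsv,
    crispr_q.tsv, gene_trap.tsv, ccle_log2_cn.csv, ccle_rpkm.csv,
    ceres.csv, demeter2.csv, annotations.tsv, tsg.tsv, and truth.json
    (the planted ground truth, for verification only — the pipeline never
    reads it).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = gene_layout(config)
    variants, contexts = simulate_variants(config, genes)
    segments = simulate_allelic_segments(config, genes)
    evidence, demeter2, essential = simulate_screens(config)
    annotations = simulate_annotations(config, variants)

    paths = {name: outdir / fname for name, fname in {
        "genes": "genes.bed",
        "variants": "variants.vcf",
        "contexts": "contexts.fasta",
        "segments": "segments.tsv",
        "crispr_q": "crispr_q.tsv",
        "gene_trap": "gene_trap.tsv",
        "ccle_log2_cn": "ccle_log2_cn.csv",
        "ccle_rpkm": "ccle_rpkm.csv",
        "ceres": "ceres.csv",
        "demeter2": "demeter2.csv",
        "annotations": "annotations.tsv",
        "tsg": "tsg.tsv",
        "truth": "truth.json",
    }.items()}

    formats_io.write_gene_bed(genes, paths["genes"])
    formats_io.write_variants_vcf(variants, paths["variants"])
    formats_io.write_fasta_contexts(contexts, paths["contexts"])
    formats_io.write_allelic_segments(segments, paths["segments"])

    screen_ids = sorted(evidence[0].crispr_q_values) if evidence else []
    pd.DataFrame(
        {
            "gene_symbol": [e.gene_symbol for e in evidence],
            **{
                sid: [e.crispr_q_values[sid] for e in evidence] for sid in screen_ids
            },
        }
    ).to_csv(paths["crispr_q"], sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_symbol": [e.gene_symbol for e in evidence],
            "sense": [e.gene_trap_sense for e in evidence],
            "antisense": [e.gene_trap_antisense for e in evidence],
        }
    ).to_csv(paths["gene_trap"], sep="\t", index=False)

    cell_lines = list(demeter2.columns)
    def _matrix(attr):
        rows, index = [], []
        for e in evidence:
            vec = getattr(e, attr)
            if vec is not None:
                rows.append(np.asarray(vec))
                index.append(e.gene_symbol)
        df = pd.DataFrame(rows, index=index, columns=cell_lines)
        df.index.name = "gene_symbol"
        return df

    formats_io.write_matrix(_matrix("ccle_log2_cn"), paths["ccle_log2_cn"])
    formats_io.write_matrix(_matrix("ccle_rpkm"), paths["ccle_rpkm"])
    formats_io.write_matrix(_matrix("ceres_scores"), paths["ceres"])
    formats_io.write_matrix(demeter2, paths["demeter2"])

    ann_rows = []
    for vid in sorted(annotations):
        ann, change = annotations[vid]
        ann_rows.append(
            {
                "variant_id": vid,
                "protein_change": change.short_form,
                "change_kind": change.kind,
                "has_ligand_bound_structure": int(ann.has_ligand_bound_structure),
                "structure_druggable_or_tractable": int(
                    ann.structure_druggable_or_tractable
                ),
                "ligand_druggability_percentile": ann.ligand_druggability_percentile,
                "has_ec_number": int(ann.has_ec_number),
                "visual_pocket_score": ann.visual_pocket_score,
                "charge_altering": int(ann.charge_altering),
                "introduces_cysteine": int(ann.introduces_cysteine),
            }
        )
    pd.DataFrame(
        ann_rows,
        columns=[
            "variant_id", "protein_change", "change_kind",
            "has_ligand_bound_structure", "structure_druggable_or_tractable",
            "ligand_druggability_percentile", "has_ec_number",
            "visual_pocket_score", "charge_altering", "introduces_cysteine",
        ],
    ).to_csv(paths["annotations"], sep="\t", index=False)

    pd.DataFrame({"gene_symbol": list(config.tsg_genes)}).to_csv(
        paths["tsg"], sep="\t", index=False
    )

    truth = {
        "essential_genes": sorted(essential),
        "loh_rate_per_type": dict(config.loh_rate_per_type),
        "copy_neutral_fraction": config.copy_neutral_fraction,
        "pam_overlap_fraction": config.pam_overlap_fraction,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
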