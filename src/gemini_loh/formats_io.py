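"""Readers and writers for the external formats the pipeline touches.

A single coordinate convention is enforced at the I/O boundary: all
intervals and positions are 0-based, half-open in memory.  VCF positions
(1-based) and ABSOLUTE-style segment tables (1-based, inclusive ends) are
converted on read and converted back on write, so interval lengths are
preserved.  Chromosome labels are normalised by stripping a leading
``chr``.  Alternate-allele frequencies are folded to minor allele
frequencies (AF > 0.5 becomes 1 - AF) at read time, so every downstream
computation sees a MAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: The closed set of consequence classes considered potentially targetable.
CONSEQUENCE_CLASSES = frozenset(
    {
        "3_prime_UTR_variant",
        "5_prime_UTR_variant",
        "frameshift_variant",
        "inframe_deletion",
        "inframe_insertion",
        "initiator_codon_variant",
        "missense_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "stop_gained",
        "stop_lost",
        "stop_retained_variant",
        "synonymous_variant",
    }
)

#: Classes retained for open-reading-frame analyses (PAM discovery):
#: everything except the two UTR classes.
ORF_CLASSES = frozenset(
    CONSEQUENCE_CLASSES - {"3_prime_UTR_variant", "5_prime_UTR_variant"}
)

VARIANT_TSV_COLUMNS = [
    "variant_id",
    "gene_symbol",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "consequence_class",
    "global_af",
    "filter_status",
]

SEGMENT_TSV_COLUMNS = [
    "sample",
    "tumor_type",
    "chromosome",
    "start",
    "end",
    "major_cn",
    "minor_cn",
    "log2_relative",
]

COMPENDIUM_COLUMNS = [
    "gene_symbol",
    "variant_id",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "consequence_class",
    "maf",
    "heterozygosity",
    "loh_rate_pan",
    "patients_per_year",
    "pam_allele_specific",
    "demeter2_median",
    "strong_dependency",
    "composite_score",
]


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class ValidationError(ValueError):
    """A well-formed record violates a domain invariant."""


def normalize_chromosome(label: str) -> str:
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise ValidationError("empty chromosome label")
    return label


def is_autosome(chromosome: str) -> bool:
    return normalize_chromosome(chromosome) in AUTOSOMES


def fold_maf(af: float) -> float:
    """Fold an alternate-allele frequency to a minor allele frequency."""
    if not 0.0 <= af <= 1.0:
        raise ValidationError(f"allele frequency {af} outside [0, 1]")
    return af if af <= 0.5 else 1.0 - af


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    is_autosome: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_symbol}: start {self.start} >= end {self.end}"
            )
        auto = self.chromosome in AUTOSOMES
        if self.is_autosome is None:
            object.__setattr__(self, "is_autosome", auto)
        elif self.is_autosome != auto:
            raise ValidationError(
                f"{self.gene_symbol}: is_autosome={self.is_autosome} inconsistent "
                f"with chromosome {self.chromosome}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One germline variant; ``global_af`` is the folded minor allele frequency."""

    variant_id: str
    gene_symbol: str
    chromosome: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    consequence_class: str
    global_af: float
    filter_status: str = "PASS"

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.variant_id}: ref equals alt")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - NUCLEOTIDES:
                raise ValidationError(
                    f"{self.variant_id}: allele {allele!r} not over ACGT"
                )
        if not 0.0 <= self.global_af <= 1.0:
            raise ValidationError(f"{self.variant_id}: AF outside [0, 1]")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"{self.variant_id}: unknown consequence class "
                f"{self.consequence_class!r}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class AllelicSegment:
    """Per-sample allelic copy-number interval (0-based half-open)."""

    sample_id: str
    tumor_type: str
    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    log2_relative: float

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start >= self.end:
            raise ValidationError(
                f"{self.sample_id} {self.chromosome}:{self.start}-{self.end}: "
                "start >= end"
            )
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ValidationError(
                f"{self.sample_id} {self.chromosome}:{self.start}-{self.end}: "
                "negative copy number"
            )
        if self.minor_cn > self.major_cn:
            raise ValidationError(
                f"{self.sample_id} {self.chromosome}:{self.start}-{self.end}: "
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn}"
            )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")


def read_variants(path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a variant table, returning records with folded MAF and 0-based positions.

    Malformed rows are skipped and logged with their line number; a missing
    mandatory column raises :class:`FormatError`.
    """
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, VARIANT_TSV_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                VariantRecord(
                    variant_id=row.variant_id,
                    gene_symbol=row.gene_symbol,
                    chromosome=row.chromosome,
                    position=int(row.position) - 1,  # 1-based on disk
                    ref_allele=str(row.ref_allele).upper(),
                    alt_allele=str(row.alt_allele).upper(),
                    consequence_class=row.consequence_class,
                    global_af=fold_maf(float(row.global_af)),
                    filter_status=row.filter_status,
                )
            )
        except (ValidationError, ValueError) as exc:
            log.warning("%s line %d: skipping malformed row (%s)", path, i, exc)
    return records


def _read_variants_vcf(path) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            status = "PASS" if (not filters or filters == ["PASS"]) else filters[0]
            afs = rec.info.get("AF")
            csq = rec.info.get("CSQ")
            gene = rec.info.get("GENE", rec.id or "")
            if afs is None or csq is None:
                log.warning(
                    "%s %s:%d: skipping record without AF/CSQ", path, rec.chrom, rec.pos
                )
                continue
            if not isinstance(afs, tuple):
                afs = (afs,)
            if isinstance(csq, tuple):
                csq = csq[0]
            csq = str(csq).split("|")[0]
            for alt, af in zip(rec.alts or (), afs):
                try:
                    records.append(
                        VariantRecord(
                            variant_id=rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}",
                            gene_symbol=str(gene),
                            chromosome=rec.chrom,
                            position=rec.pos - 1,
                            ref_allele=str(rec.ref).upper(),
                            alt_allele=str(alt).upper(),
                            consequence_class=csq,
                            global_af=fold_maf(float(af)),
                            filter_status=status,
                        )
                    )
                except (ValidationError, ValueError) as exc:
                    log.warning(
                        "%s %s:%d: skipping record (%s)", path, rec.chrom, rec.pos, exc
                    )
    return records


def write_variants_tsv(variants: Iterable[VariantRecord], path) -> None:
    """Write variants as TSV with 1-based positions (inverse of the reader)."""
    rows = [
        {
            "variant_id": v.variant_id,
            "gene_symbol": v.gene_symbol,
            "chromosome": v.chromosome,
            "position": v.position + 1,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
            "consequence_class": v.consequence_class,
            "global_af": v.global_af,
            "filter_status": v.filter_status,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: Sequence[VariantRecord], path) -> None:
    """Write a minimal VCF 4.2 with AF, CSQ and GENE INFO fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta(
        "INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                       ("Description", "Allele frequency")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CSQ"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Consequence class")]
    )
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Gene symbol")]
    )
    header.filters.add("nonpass", None, None, "Failed upstream filters")
    for chrom in sorted({v.chromosome for v in variants}, key=_chrom_key):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (_chrom_key(v.chromosome), v.position)):
            rec = out.new_record(
                contig=v.chromosome,
                start=v.position,
                stop=v.position + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
                id=v.variant_id,
            )
            rec.info["AF"] = v.global_af
            rec.info["CSQ"] = v.consequence_class
            rec.info["GENE"] = v.gene_symbol
            rec.filter.add("PASS" if v.filter_status == "PASS" else "nonpass")
            out.write(rec)


def _chrom_key(label: str):
    label = normalize_chromosome(label)
    return (0, int(label)) if label.isdigit() else (1, label)


# ---------------------------------------------------------------------------
# allelic segments
# ---------------------------------------------------------------------------


def read_allelic_segments(path) -> list[AllelicSegment]:
    """Read an ABSOLUTE-style allelic segment table (1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SEGMENT_TSV_COLUMNS, path)
    segments = []
    for row in df.itertuples(index=False):
        major, minor = row.major_cn, row.minor_cn
        if float(major) != int(major) or float(minor) != int(minor):
            raise ValidationError(
                f"{row.sample} {row.chromosome}:{row.start}-{row.end}: "
                "non-integer copy number"
            )
        segments.append(
            AllelicSegment(
                sample_id=str(row.sample),
                tumor_type=str(row.tumor_type),
                chromosome=str(row.chromosome),
                start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(row.end),
                major_cn=int(major),
                minor_cn=int(minor),
                log2_relative=float(row.log2_relative),
            )
        )
    return segments


def write_allelic_segments(segments: Iterable[AllelicSegment], path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "tumor_type": s.tumor_type,
            "chromosome": s.chromosome,
            "start": s.start + 1,
            "end": s.end,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
            "log2_relative": s.log2_relative,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes, contexts, matrices, compendium
# ---------------------------------------------------------------------------


def read_gene_bed(path) -> list[GeneModel]:
    """Read a BED4 gene file (already 0-based half-open)."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path} line {i}: expected 4 BED columns")
            chrom, start, end, name = parts[:4]
            genes.append(GeneModel(name, chrom, int(start), int(end)))
    symbols = [g.gene_symbol for g in genes]
    dupes = sorted({s for s in symbols if symbols.count(s) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicated gene symbols: {', '.join(dupes)}")
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_symbol}\n")


def read_fasta_contexts(path) -> dict[str, str]:
    """Read FASTA context sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_contexts(contexts: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contexts.items()]
    SeqIO.write(records, str(path), "fasta")


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x cell-line CSV matrix; empty cells stay missing (NaN)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path)


def write_compendium(compendium: pd.DataFrame, path) -> None:
    """Write the target compendium as TSV in the fixed documented column order."""
    extra = [c for c in compendium.columns if c not in COMPENDIUM_COLUMNS]
    ordered = [c for c in COMPENDIUM_COLUMNS if c in compendium.columns] + extra
    compendium[ordered].to_csv(path, sep="\t", index=False)


def read_compendium(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
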