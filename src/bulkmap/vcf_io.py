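"""Read and write the two-bulk SNP table as VCF, plus TSV/BED emitters.

The on-disk interchange format is a standard VCF 4.2 with two sample
columns (low bulk, high bulk) carrying ``GT:AD:DP:GQ``.  Per-bulk depth
used downstream is always the sum of that sample's allelic depths (AD),
which keeps the depth filter self-consistent with the allele-frequency
numerator and denominator; DP is written alongside for interoperability.

The alternate allele is, by convention, the CB4856-specific allele.  The
simulator writes VCFs polarised this way; real-mode input must already be
polarised the same way (this module does not auto-detect parental origin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import pysam

from .genome import GenomeMap

logger = logging.getLogger(__name__)


@dataclass
class SnpRecord:
    """One biallelic SNP with per-bulk read counts, AD-sum depth, and GQ."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str  # the CB4856-specific allele
    ref_count_low: int
    alt_count_low: int
    depth_low: int
    gq_low: int
    ref_count_high: int
    alt_count_high: int
    depth_high: int
    gq_high: int


def scan_bulk_vcf(
    path: str, low_sample: str, high_sample: str
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Parse a two-bulk VCF; returns (records, skip-counters).

    Counter keys: ``not_biallelic_snp`` (multiallelic or indel),
    ``malformed_ad`` (missing/invalid AD in either sample), ``kept``.
    Records missing GQ in a sample get GQ = 0 there (worst case, so the
    quality filter removes them) and are counted under ``missing_gq``.
    """
    counts = {"kept": 0, "not_biallelic_snp": 0, "malformed_ad": 0, "missing_gq": 0}
    records: list[SnpRecord] = []
    with pysam.VariantFile(path) as vcf:
        for name in (low_sample, high_sample):
            if name not in vcf.header.samples:
                raise ValueError(f"sample {name!r} not in VCF header")
        contig_rank = {c: i for i, c in enumerate(vcf.header.contigs)}
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                counts["not_biallelic_snp"] += 1
                continue
            fields = {}
            ok = True
            for name in (low_sample, high_sample):
                sample = rec.samples[name]
                ad = sample.get("AD")
                if ad is None or len(ad) != 2 or any(a is None for a in ad):
                    logger.warning(
                        "skipping %s:%d — malformed AD for sample %s",
                        rec.chrom, rec.pos, name,
                    )
                    counts["malformed_ad"] += 1
                    ok = False
                    break
                gq = sample.get("GQ")
                if gq is None:
                    counts["missing_gq"] += 1
                    gq = 0
                fields[name] = (int(ad[0]), int(ad[1]), int(gq))
            if not ok:
                continue
            rl, al, gl = fields[low_sample]
            rh, ah, gh = fields[high_sample]
            records.append(
                SnpRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    ref_count_low=rl,
                    alt_count_low=al,
                    depth_low=rl + al,
                    gq_low=gl,
                    ref_count_high=rh,
                    alt_count_high=ah,
                    depth_high=rh + ah,
                    gq_high=gh,
                )
            )
            counts["kept"] += 1
    records.sort(key=lambda r: (contig_rank.get(r.chrom, len(contig_rank)), r.pos))
    return records, counts


def read_bulk_vcf(path: str, low_sample: str, high_sample: str) -> list[SnpRecord]:
    """Parse a two-bulk VCF into sorted biallelic SnpRecords (see scan_bulk_vcf)."""
    records, counts = scan_bulk_vcf(path, low_sample, high_sample)
    skipped = counts["not_biallelic_snp"] + counts["malformed_ad"]
    if skipped:
        logger.info("read_bulk_vcf: kept %d records, skipped %d", len(records), skipped)
    return records


def _genotype(ref_count: int, alt_count: int) -> tuple[int | None, int | None]:
    # pooled samples are not diploid; emit hom calls only when the pool is
    # pure at the observed reads, otherwise missing
    if ref_count > 0 and alt_count == 0:
        return (0, 0)
    if alt_count > 0 and ref_count == 0:
        return (1, 1)
    return (None, None)


def write_bulk_vcf(
    records: list[SnpRecord],
    path: str,
    low_sample: str,
    high_sample: str,
    gmap: GenomeMap | None = None,
) -> None:
    """Write SnpRecords as VCF 4.2 with FORMAT GT:AD:DP:GQ and two samples.

    ``records`` must be sorted by (chrom, pos); contig headers come from
    ``gmap`` when given, otherwise from the records themselves.
    """
    header = pysam.VariantHeader()
    if gmap is not None:
        for name, plen, _ in gmap.chromosomes:
            header.contigs.add(name, length=plen)
        contig_rank = {name: i for i, name in enumerate(gmap.names)}
    else:
        seen: list[str] = []
        for r in records:
            if r.chrom not in seen:
                seen.append(r.chrom)
        max_pos = {c: max(r.pos for r in records if r.chrom == c) for c in seen}
        for name in seen:
            header.contigs.add(name, length=max_pos[name])
        contig_rank = {name: i for i, name in enumerate(seen)}
    prev = None
    for r in records:
        if r.chrom not in contig_rank:
            raise ValueError(f"record chromosome {r.chrom!r} not in genome map")
        key = (contig_rank[r.chrom], r.pos)
        if prev is not None and key < prev:
            raise ValueError("records must be sorted by (chrom, pos)")
        prev = key
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth (sum of AD)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(low_sample)
    header.add_sample(high_sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref_allele, r.alt_allele),
            )
            low = rec.samples[low_sample]
            low["GT"] = _genotype(r.ref_count_low, r.alt_count_low)
            low["AD"] = (r.ref_count_low, r.alt_count_low)
            low["DP"] = r.depth_low
            low["GQ"] = r.gq_low
            high = rec.samples[high_sample]
            high["GT"] = _genotype(r.ref_count_high, r.alt_count_high)
            high["AD"] = (r.ref_count_high, r.alt_count_high)
            high["DP"] = r.depth_high
            high["GQ"] = r.gq_high
            out.write(rec)


def write_qtl_bed(intervals, path: str) -> None:
    """Write QTL intervals as BED6 (0-based half-open).

    Interval coordinates are 1-based half-open window spans, so BED start/end
    are both shifted down by one.  Name is ``chrom:sign``; the score column
    is min(1000, round(100·|peak log-odds|)).
    """
    with open(path, "w") as fh:
        for iv in intervals:
            sign = "+" if iv.sign > 0 else "-"
            score = min(1000, int(round(100 * abs(iv.peak_log_odds))))
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end - 1}\t"
                f"{iv.chrom}:{sign}\t{score}\t{sign}\n"
            )


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth, path: str) -> None:
    pd.DataFrame(
        [{"chrom": q.chrom, "pos": q.pos, "effect": q.effect} for q in truth]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str):
    from .rilsim import QtlEffect

    df = pd.read_csv(path, sep="\t")
    return [
        QtlEffect(str(r.chrom), int(r.pos), float(r.effect))
        for r in df.itertuples(index=False)
    ]
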