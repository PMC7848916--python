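"""Variant-site containers, VCF I/O, hard filtering and allele frequency.

A variant site carries the per-sample allele depths (AD), total depth (DP)
and the caller's site annotations QD (variant confidence / depth), FS
(Fisher strand-bias, phred) and MQ (RMS mapping quality).  Hard filtering
uses the strict inequalities DP > 40, QD > 2, FS < 60, MQ > 40 by default.
The per-site alternate allele frequency is the read fraction of the most
abundant non-reference allele, with sum(AD) as the denominator.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .references import SUBGENOMES, subgenome_of

log = logging.getLogger(__name__)


@dataclass
class VariantSite:
    """One (possibly multi-allelic) variant site for one sample.

    ``ad`` lists read counts for the reference allele first, then each
    alternate allele in VCF order.  ``genotype`` is the called GT as a
    tuple of allele indices (``(0, 1)`` for 0/1), or None if uncalled.
    Annotations missing from the record are stored as None.
    """

    subgenome: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    ad: tuple[int, ...]
    dp: int | None
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    genotype: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if not self.alts:
            raise ValueError("a variant site needs at least one alternate allele")
        if len(self.ad) != 1 + len(self.alts):
            raise ValueError("AD must have one entry per allele (ref first)")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_hom_alt(self) -> bool:
        gt = self.genotype
        return gt is not None and len(gt) > 0 and all(a == gt[0] for a in gt) and gt[0] > 0

    @property
    def is_hom_ref(self) -> bool:
        gt = self.genotype
        return gt is not None and len(gt) > 0 and all(a == 0 for a in gt)

    @property
    def is_het(self) -> bool:
        gt = self.genotype
        return gt is not None and len(set(gt)) > 1


def alt_allele_frequency(site: VariantSite) -> float:
    """Read fraction of the most abundant alternate allele.

    max over alternates of AD_alt / sum(AD); ties between alternates are
    broken toward the lowest allele index.  Raises if sum(AD) == 0.
    """
    total = sum(site.ad)
    if total <= 0:
        raise ValueError(f"undefined allele frequency at {site.chrom}:{site.pos}: sum(AD) == 0")
    return max(site.ad[1:]) / total


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cut-offs; all comparisons are strict.

    A site is kept iff DP > min_depth, QD > min_qd, FS < max_fs and
    MQ > min_mq.  Defaults are the standard short-variant hard filters
    used for this analysis.
    """

    min_depth: float = 40.0
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_qd", "max_fs", "min_mq"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def passes(self, site: VariantSite, permissive_missing: bool = False) -> bool:
        checks = (
            (site.dp, lambda v: v > self.min_depth),
            (site.qd, lambda v: v > self.min_qd),
            (site.fs, lambda v: v < self.max_fs),
            (site.mq, lambda v: v > self.min_mq),
        )
        for value, ok in checks:
            if value is None:
                if not permissive_missing:
                    return False  # fail closed on missing annotations
                continue
            if not ok(value):
                return False
        return True


def filter_variants(
    sites: Iterable[VariantSite],
    thresholds: FilterThresholds | None = None,
    permissive_missing: bool = False,
) -> list[VariantSite]:
    """Keep sites passing all hard-filter thresholds (order preserved).

    Missing annotations remove a site unless ``permissive_missing``.
    """
    thresholds = thresholds or FilterThresholds()
    sites = list(sites)
    kept = [s for s in sites if thresholds.passes(s, permissive_missing)]
    log.info("filter_variants: kept %d of %d sites (removed %d)",
             len(kept), len(sites), len(sites) - len(kept))
    return kept


def _info_float(rec: pysam.VariantRecord, key: str) -> float | None:
    try:
        value = rec.info.get(key)
    except (KeyError, ValueError):  # key absent from the header
        return None
    if value is None:
        return None
    if isinstance(value, tuple):
        value = value[0]
    return float(value)


def read_vcf(path, sample: str | None = None) -> list[VariantSite]:
    """Read VariantSites for one sample from a VCF.

    The subgenome is derived from the contig-name prefix (``Sc_...`` /
    ``Se_...``); records on other contigs are skipped with a warning, as
    are records lacking AD or any alternate allele.
    """
    path = Path(path)
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ValueError(f"{path}: specify a sample, file has {samples}")
            sample = samples[0]
        elif sample not in samples:
            raise ValueError(f"{path}: sample {sample!r} not in {samples}")
        for rec in vcf:
            sub = subgenome_of(rec.chrom)
            if sub is None:
                log.warning("%s: skipping record on unknown contig %r at pos %d",
                            path.name, rec.chrom, rec.pos)
                continue
            if not rec.alts:
                continue
            call = rec.samples[sample]
            ad = call.get("AD")
            if ad is None or any(a is None for a in ad):
                log.warning("%s: record %s:%d lacks AD; skipped", path.name, rec.chrom, rec.pos)
                continue
            gt = call.get("GT")
            genotype = tuple(a for a in gt if a is not None) if gt else None
            dp = call.get("DP")
            sites.append(
                VariantSite(
                    subgenome=sub,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    ad=tuple(int(a) for a in ad),
                    dp=int(dp) if dp is not None else None,
                    qd=_info_float(rec, "QD"),
                    fs=_info_float(rec, "FS"),
                    mq=_info_float(rec, "MQ"),
                    genotype=genotype or None,
                )
            )
    return sites


def _vcf_header(sample: str, contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Combined depth across samples")
    header.info.add("QD", 1, "Float", "Variant confidence divided by depth")
    header.info.add("FS", 1, "Float", "Phred-scaled Fisher strand bias")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alts)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample)
    return header


def write_vcf(
    sites: Sequence[VariantSite],
    path,
    sample: str,
    contig_lengths: dict[str, int],
) -> None:
    """Write VariantSites as an uncompressed single-sample VCF v4.2."""
    header = _vcf_header(sample, contig_lengths)
    order = {name: i for i, name in enumerate(contig_lengths)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (order.get(s.chrom, 1 << 30), s.pos)):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alts),
            )
            if site.dp is not None:
                rec.info["DP"] = site.dp
            for key, value in (("QD", site.qd), ("FS", site.fs), ("MQ", site.mq)):
                if value is not None:
                    rec.info[key] = value
            call = rec.samples[sample]
            if site.genotype is not None:
                call["GT"] = site.genotype
            call["AD"] = list(site.ad)
            if site.dp is not None:
                call["DP"] = site.dp
            out.write(rec)


def split_by_chromosome(sites: Iterable[VariantSite]) -> dict[str, list[VariantSite]]:
    """Group sites by contig, preserving input order within each."""
    out: dict[str, list[VariantSite]] = {}
    for site in sites:
        out.setdefault(site.chrom, []).append(site)
    return out
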