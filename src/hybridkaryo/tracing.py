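"""Parental-origin tracing via private homozygous SNPs.

A SNP homozygous in exactly one parent and absent from the other is a
clean marker: every read carrying the marker allele in the hybrid came
from the owning parent's haplotypes.  Pooling both parents' private
markers, the per-site parental allele frequency (reads carrying the
parental allele / all reads) estimates the fraction of the chromosome's
copies inherited from that parent — e.g. 0.33 for one of three copies,
0.66 for two of three.  Chromosome-wide medians of these frequencies,
combined with the chromosome's copy number, yield integer per-parent
contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .references import subgenome_of
from .variants import VariantSite

log = logging.getLogger(__name__)

#: a chromosome-wide median farther than this from the nearest k/c ratio
#: demotes the contribution call to low confidence
MEDIAN_DEVIATION_TOL = 0.15


@dataclass(frozen=True)
class PrivateMarker:
    """A SNP homozygous in one parent, reference-only in the other."""

    subgenome: str
    chrom: str
    pos: int
    owner: str  # parent homozygous for the alternate
    parental_allele: str  # alternate base carried by every owner haplotype
    other_allele: str  # base carried by the other parent (the reference)


def private_homozygous_snps(
    parent_a_sites: list[VariantSite],
    parent_b_sites: list[VariantSite],
    name_a: str,
    name_b: str,
) -> list[PrivateMarker]:
    """Markers where one parent is homozygous-alternate and the other is not.

    A position qualifies if it is GT 1/1 (homozygous for the first
    alternate) in one parent and homozygous-reference or absent in the
    other.  Heterozygous sites in either parent and shared
    homozygous-alternate sites are excluded.  Only SNPs are used.
    """
    by_pos_a = {(s.chrom, s.pos): s for s in parent_a_sites}
    by_pos_b = {(s.chrom, s.pos): s for s in parent_b_sites}

    markers: list[PrivateMarker] = []
    for (owner_name, own, other) in (
        (name_a, by_pos_a, by_pos_b),
        (name_b, by_pos_b, by_pos_a),
    ):
        for key, site in own.items():
            if not site.is_snp or not site.is_hom_alt:
                continue
            counterpart = other.get(key)
            if counterpart is not None and not counterpart.is_hom_ref:
                continue  # het or hom-alt in the other parent: not private
            allele_index = site.genotype[0]
            markers.append(
                PrivateMarker(
                    subgenome=site.subgenome,
                    chrom=site.chrom,
                    pos=site.pos,
                    owner=owner_name,
                    parental_allele=site.alts[allele_index - 1],
                    other_allele=site.ref,
                )
            )
    markers.sort(key=lambda m: (m.chrom, m.pos))
    log.info("private_homozygous_snps: %d markers (%s + %s)", len(markers), name_a, name_b)
    return markers


def parental_allele_frequency(
    markers: list[PrivateMarker],
    hybrid_sites: list[VariantSite],
    track: pd.DataFrame | None = None,
    min_depth: float = 1.0,
) -> pd.DataFrame:
    """Per-site parental allele frequencies at marker positions.

    For every marker position with a hybrid variant record, the owning
    parent's frequency is AD(marker allele)/sum(AD) and the other
    parent's frequency is AD(other allele)/sum(AD) — the two parents'
    haplotypes carry complementary alleles at a private marker, so one
    site informs both.  A covered marker position (bin depth >= min_depth)
    with no hybrid record is evidence of non-inheritance and contributes
    frequency 0 for the owning parent; uncovered positions are dropped.

    Returns a DataFrame with columns subgenome, chrom, pos, parent, freq.
    """
    hybrid_by_pos = {(s.chrom, s.pos): s for s in hybrid_sites}
    rows: list[dict] = []
    bin_cache: dict[str, pd.DataFrame] = {}

    def covered(chrom: str, pos: int) -> bool:
        if track is None:
            return False
        if chrom not in bin_cache:
            sel = track[track["chrom"] == chrom]
            bin_cache[chrom] = sel
        sel = bin_cache[chrom]
        hit = sel[(sel["start"] < pos) & (pos <= sel["end"])]
        return bool((hit["depth"] >= min_depth).any()) if not hit.empty else False

    for m in markers:
        site = hybrid_by_pos.get((m.chrom, m.pos))
        if site is None:
            if covered(m.chrom, m.pos):
                rows.append(
                    {"subgenome": m.subgenome, "chrom": m.chrom, "pos": m.pos,
                     "parent": m.owner, "freq": 0.0}
                )
            continue
        total = sum(site.ad)
        if total == 0:
            continue
        alleles = (site.ref, *site.alts)
        for parent, base in ((m.owner, m.parental_allele), (None, m.other_allele)):
            try:
                idx = alleles.index(base)
            except ValueError:
                count = 0
            else:
                count = site.ad[idx]
            rows.append(
                {"subgenome": m.subgenome, "chrom": m.chrom, "pos": m.pos,
                 "parent": parent, "freq": count / total}
            )
    df = pd.DataFrame(rows, columns=["subgenome", "chrom", "pos", "parent", "freq"])
    return df


def _fill_other_parent(df: pd.DataFrame, name_a: str, name_b: str) -> pd.DataFrame:
    other = {name_a: name_b, name_b: name_a}
    out = df.copy()
    mask = out["parent"].isna()
    # the "other parent" row of each marker belongs to whichever parent
    # does not own it; ownership is the non-null row at the same position
    owners = df.dropna(subset=["parent"]).set_index(["chrom", "pos"])["parent"]
    owner_for = out.loc[mask, ["chrom", "pos"]].apply(tuple, axis=1).map(owners)
    out.loc[mask, "parent"] = owner_for.map(other)
    return out.dropna(subset=["parent"])


def chromosome_median_frequency(
    frequencies: pd.DataFrame,
    min_sites: int = 20,
) -> pd.DataFrame:
    """Chromosome-wide median parental allele frequency per parent.

    Rows with fewer than ``min_sites`` informative sites are flagged
    ``undetermined``.  Returns columns subgenome, chrom, parent,
    median_af, n_sites, status.
    """
    if frequencies.empty:
        return pd.DataFrame(
            columns=["subgenome", "chrom", "parent", "median_af", "n_sites", "status"]
        )
    grouped = (
        frequencies.groupby(["subgenome", "chrom", "parent"], sort=True)["freq"]
        .agg(median_af="median", n_sites="count")
        .reset_index()
    )
    grouped["status"] = np.where(grouped["n_sites"] >= min_sites, "determined", "undetermined")
    return grouped


@dataclass
class ParentalContribution:
    """Integer copies of one chromosome contributed by each of two parents."""

    subgenome: str
    chrom: str
    copies: int  # chromosome copy number used
    contributions: dict[str, int]  # parent -> contributed copies
    medians: dict[str, float]  # parent -> median parental AF (NaN if unknown)
    n_sites: dict[str, int]
    status: str  # "determined" | "undetermined"
    confidence: str  # "high" | "low"


def assign_contributions(
    medians: dict[str, float],
    n_sites: dict[str, int],
    copies: int,
    chrom: str,
    name_a: str,
    name_b: str,
) -> ParentalContribution:
    """Integer split of ``copies`` between two parents from their medians.

    With both medians m_A, m_B known, k_A minimizes
    |k_A - m_A c| + |(c - k_A) - m_B c| (joint consistency, guaranteeing
    k_A + k_B = c); ties go to the parent with more informative sites.
    With one median known, k = round(m c) clipped to [0, c].  A median
    deviating more than 0.15 from the nearest k/c demotes confidence.
    """
    if copies < 0:
        raise ValueError("copy number must be >= 0")
    m_a = medians.get(name_a, np.nan)
    m_b = medians.get(name_b, np.nan)
    have_a = np.isfinite(m_a)
    have_b = np.isfinite(m_b)

    sub = subgenome_of(chrom) or ""
    if copies == 0:
        if (have_a and m_a > 0) or (have_b and m_b > 0):
            log.warning("%s: nonzero parental medians on a deleted chromosome", chrom)
        return ParentalContribution(
            subgenome=sub, chrom=chrom, copies=0,
            contributions={name_a: 0, name_b: 0},
            medians={name_a: m_a, name_b: m_b}, n_sites=dict(n_sites),
            status="determined", confidence="high",
        )
    if not have_a and not have_b:
        return ParentalContribution(
            subgenome=sub, chrom=chrom, copies=copies,
            contributions={name_a: 0, name_b: 0},
            medians={name_a: m_a, name_b: m_b}, n_sites=dict(n_sites),
            status="undetermined", confidence="low",
        )

    if have_a and have_b:
        costs = [
            abs(k - m_a * copies) + abs((copies - k) - m_b * copies)
            for k in range(copies + 1)
        ]
        best = min(costs)
        tied = [k for k, cost in enumerate(costs) if abs(cost - best) < 1e-9]
        if len(tied) == 1:
            k_a = tied[0]
        elif n_sites.get(name_a, 0) >= n_sites.get(name_b, 0):
            k_a = min(tied, key=lambda k: abs(k - m_a * copies))
        else:
            k_a = min(tied, key=lambda k: abs((copies - k) - m_b * copies))
    elif have_a:
        k_a = int(np.clip(np.round(m_a * copies), 0, copies))
    else:
        k_a = copies - int(np.clip(np.round(m_b * copies), 0, copies))
        k_a = int(np.clip(k_a, 0, copies))

    deviation = 0.0
    if have_a:
        deviation = max(deviation, abs(m_a - k_a / copies))
    if have_b:
        deviation = max(deviation, abs(m_b - (copies - k_a) / copies))
    return ParentalContribution(
        subgenome=sub, chrom=chrom, copies=copies,
        contributions={name_a: int(k_a), name_b: int(copies - k_a)},
        medians={name_a: m_a, name_b: m_b}, n_sites=dict(n_sites),
        status="determined",
        confidence="high" if deviation <= MEDIAN_DEVIATION_TOL else "low",
    )


def trace_parental_origin(
    parent_a_sites: list[VariantSite],
    parent_b_sites: list[VariantSite],
    name_a: str,
    name_b: str,
    hybrid_sites: list[VariantSite],
    copy_numbers: dict[str, int],
    track: pd.DataFrame | None = None,
    min_sites: int = 20,
    min_depth: float = 1.0,
) -> list[ParentalContribution]:
    """Full tracing pipeline: markers -> frequencies -> medians -> copies."""
    markers = private_homozygous_snps(parent_a_sites, parent_b_sites, name_a, name_b)
    freqs = parental_allele_frequency(markers, hybrid_sites, track, min_depth)
    freqs = _fill_other_parent(freqs, name_a, name_b)
    medians = chromosome_median_frequency(freqs, min_sites)

    out: list[ParentalContribution] = []
    for chrom, copies in copy_numbers.items():
        rows = medians[medians["chrom"] == chrom]
        med = {r.parent: (r.median_af if r.status == "determined" else np.nan)
               for r in rows.itertuples()}
        n = {r.parent: int(r.n_sites) for r in rows.itertuples()}
        out.append(
            assign_contributions(med, n, copies, chrom, name_a, name_b)
        )
    return out


def contributions_frame(contribs: list[ParentalContribution]) -> pd.DataFrame:
    rows = []
    for c in contribs:
        for parent, k in c.contributions.items():
            rows.append(
                {
                    "subgenome": c.subgenome,
                    "chrom": c.chrom,
                    "parent": parent,
                    "median_af": round(float(c.medians.get(parent, np.nan)), 4),
                    "n_sites": c.n_sites.get(parent, 0),
                    "copies": k,
                    "chrom_copies": c.copies,
                    "status": c.status,
                    "confidence": c.confidence,
                }
            )
    return pd.DataFrame(rows)
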