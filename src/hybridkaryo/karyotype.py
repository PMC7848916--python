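"""Per-chromosome copy-number inference from allele frequency and depth.

Two complementary signals identify the copy number of a region:

* the modal alternate allele frequency of heterozygous variants — 0.5 for
  two alleles, 0.33/0.66 for three, 0.25/0.5/0.75 for four, and ~1 for
  homozygous or single-copy regions — which counts distinct alleles but
  cannot separate e.g. haploid from homozygous-diploid;
* the binned read depth, proportional to copy number, which resolves that
  ambiguity once the per-copy depth unit u is known.

The per-copy unit u is estimated genome-wide by a quantization grid
search (bin depths should sit near integer multiples of u), depth then
fixes each chromosome's integer copy number, and the allele-frequency
peak profile is kept as an agreement check.  Whole-genome modal copies
per subgenome give the karyotype ratio (e.g. "3:1"), ploidy, and the
duplication/deletion lists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .references import subgenome_of
from .variants import VariantSite, alt_allele_frequency

#: canonical allele-frequency peak sets, ordered by parsimony (checked in
#: this order; ties in matching distance go to the earlier, smaller set)
CANONICAL_PEAK_SETS: tuple[tuple[float, ...], ...] = (
    (1.0,),
    (0.5,),
    (1 / 3, 2 / 3),
    (0.25, 0.5, 0.75),
)

#: copy numbers consistent with each canonical set; None = any copy number
#: (an all-homozygous profile fits every c, so it never contradicts depth)
PEAK_SET_COPIES: dict[tuple[float, ...], frozenset[int] | None] = {
    (1.0,): None,
    (0.5,): frozenset({2, 4}),
    (1 / 3, 2 / 3): frozenset({3, 6}),
    (0.25, 0.5, 0.75): frozenset({4}),
}

MAX_COPIES = 8
QUANT_SIGMA = 0.15
PEAK_MATCH_TOL = 0.05
HIST_BIN_WIDTH = 0.02
PEAK_MIN_MASS = 0.10


#: near-tie margin for the quantization score; candidate units scoring
#: within this of the best are considered equivalent and the largest wins
UNIT_TIE_TOL = 0.01


def quantization_score(depths, unit: float, sigma: float = QUANT_SIGMA) -> float:
    """Mean over nonzero bins of exp(-(d/u - round(d/u))^2 / 2 sigma^2),
    with round(d/u) clipped to [1, 8]: how well depths sit on multiples of u."""
    d = np.asarray(depths, dtype=float)
    d = d[d > 0]
    m = np.clip(np.round(d / unit), 1, MAX_COPIES)
    return float(np.mean(np.exp(-((d / unit - m) ** 2) / (2 * sigma**2))))


def estimate_per_copy_depth(depths, n_grid: int = 2000) -> float:
    """Estimate the depth contributed by one chromosome copy.

    Grid search over candidate units u in [max_depth/8, max_depth],
    scoring each by the quantization score (bin depths should lie near
    integer multiples of u, integers restricted to 1..8).  Integer
    divisors of the true unit tie the score, so near-ties are broken
    toward the larger u — fewer copies.  The winning local maximum is
    refined on a finer local grid.
    """
    d = np.asarray(depths, dtype=float)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("per-copy depth undefined: no bins with depth > 0")

    dmax = float(d.max())
    if d.size < 2 or np.allclose(d, dmax):
        return dmax  # single depth level: copy-1 interpretation

    grid = np.linspace(dmax / MAX_COPIES, dmax, n_grid)
    scores = np.array([quantization_score(d, u) for u in grid])
    best = scores.max()

    # local maxima of the score curve (plateau-tolerant at the ends)
    is_max = np.ones_like(scores, dtype=bool)
    is_max[1:] &= scores[1:] >= scores[:-1]
    is_max[:-1] &= scores[:-1] >= scores[1:]
    candidates = np.flatnonzero(is_max & (scores >= best - UNIT_TIE_TOL))
    i = int(candidates.max())  # largest near-optimal unit

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    fine = np.linspace(lo, hi, 128)
    fine_scores = np.array([quantization_score(d, u) for u in fine])
    fbest = fine_scores.max()
    return float(fine[fine_scores >= fbest - 1e-12].max())


def scaled_depth(depths, robust_quantile: float = 0.995) -> np.ndarray:
    """Depths scaled to [0, 1] by a robust maximum (for display only)."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("empty depth track")
    robust_max = np.quantile(d, robust_quantile)
    if robust_max <= 0:
        return np.zeros_like(d)
    return np.clip(d / robust_max, 0.0, 1.0)


@dataclass
class AFPeakProfile:
    """Allele-frequency modality of one region.

    ``peaks`` are detected histogram maxima (mass-weighted positions);
    ``canonical`` is the matched canonical set or None when nothing
    matches or the region has too few sites.
    """

    region: str
    peaks: tuple[float, ...]
    canonical: tuple[float, ...] | None
    n_sites: int

    @property
    def copy_candidates(self) -> frozenset[int] | None:
        if self.canonical is None:
            return None
        return PEAK_SET_COPIES[self.canonical]


def af_peak_profile(
    sites: list[VariantSite],
    region: str = "",
    min_sites: int = 20,
) -> AFPeakProfile:
    """Detect modal allele-frequency peaks and match them to a canonical set.

    Histogram of per-site most-abundant-alternate frequencies over (0, 1]
    with bin width 0.02, smoothed by a 3-bin moving average; local maxima
    carrying >= 10% of the region's sites become peaks.  The canonical set
    {1}, {1/2}, {1/3, 2/3} or {1/4, 1/2, 3/4} that matches every detected
    peak within +-0.05 with the smallest total distance is reported.
    """
    usable = [s for s in sites if s.is_snp and sum(s.ad) > 0]
    n = len(usable)
    if n < min_sites:
        return AFPeakProfile(region=region, peaks=(), canonical=None, n_sites=n)

    freqs = np.array([alt_allele_frequency(s) for s in usable])
    freqs = freqs[freqs > 0]
    edges = np.arange(0.0, 1.0 + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
    counts, _ = np.histogram(freqs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")

    peaks: list[float] = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -1.0
        right = smooth[i + 1] if i < len(smooth) - 1 else -1.0
        if smooth[i] <= 0 or smooth[i] < left or smooth[i] < right:
            continue
        lo, hi = max(i - 1, 0), min(i + 2, len(counts))
        mass = counts[lo:hi].sum()
        if mass < PEAK_MIN_MASS * n:
            continue
        centroid = float(np.average(centers[lo:hi], weights=np.maximum(counts[lo:hi], 1e-9)))
        if not peaks or abs(centroid - peaks[-1]) > HIST_BIN_WIDTH / 2:
            peaks.append(round(centroid, 4))

    canonical: tuple[float, ...] | None = None
    best_cost = np.inf
    for cand in CANONICAL_PEAK_SETS:
        cost = 0.0
        ok = bool(peaks)
        for p in peaks:
            dist = min(abs(p - c) for c in cand)
            if dist > PEAK_MATCH_TOL:
                ok = False
                break
            cost += dist
        if ok and cost < best_cost - 1e-12:
            best_cost = cost
            canonical = cand
    return AFPeakProfile(region=region, peaks=tuple(peaks), canonical=canonical, n_sites=n)


@dataclass
class CopyNumberCall:
    """Inferred integer copy number of one chromosome with its evidence."""

    subgenome: str
    chrom: str
    copies: int
    modal_depth: float
    unit: float  # estimated per-copy depth u
    profile: AFPeakProfile | None
    agreement: bool
    confidence: str  # "high" | "low"


def modal_bin_depth(depths, unit: float) -> float:
    """Depth of the modal copy state: median depth among bins whose
    quantized copy (round(d/u), clipped to [0, 8]) is the most common."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("no depth bins")
    copies = np.clip(np.round(d / unit), 0, MAX_COPIES).astype(int)
    modal_c = np.bincount(copies).argmax()  # ties -> smaller copy
    return float(np.median(d[copies == modal_c]))


def infer_copy_number(
    profile: AFPeakProfile | None,
    modal_depth: float,
    unit: float,
    chrom: str,
) -> CopyNumberCall:
    """Final copy call: depth decides, the AF profile corroborates.

    c = round(modal_depth / u) clipped to [0, 8].  The AF profile's copy
    candidates set the agreement flag; a disagreement demotes confidence
    to low but never overrides the depth call.
    """
    if unit <= 0:
        raise ValueError("per-copy depth unit must be > 0")
    c = int(np.clip(np.round(modal_depth / unit), 0, MAX_COPIES))
    candidates = profile.copy_candidates if profile is not None else None
    if profile is None or profile.canonical is None or candidates is None:
        agreement = True  # no usable AF signal cannot contradict depth
    else:
        agreement = c in candidates
    return CopyNumberCall(
        subgenome=subgenome_of(chrom), chrom=chrom, copies=c,
        modal_depth=modal_depth, unit=unit, profile=profile,
        agreement=agreement, confidence="high" if agreement else "low",
    )


@dataclass
class KaryotypeResult:
    """Whole-genome karyotype: per-chromosome calls and modal summary."""

    calls: list[CopyNumberCall]
    modal: dict[str, int]  # subgenome -> modal copy number
    ratio: str  # "Sc:Se", e.g. "3:1"
    ploidy: int  # modal Sc + modal Se
    duplications: dict[str, list[str]] = field(default_factory=dict)
    deletions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ploidy_string(self) -> str:
        return f"{self.ploidy}N"

    def call_for(self, chrom: str) -> CopyNumberCall:
        for call in self.calls:
            if call.chrom == chrom:
                return call
        raise KeyError(chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subgenome": c.subgenome,
                    "chrom": c.chrom,
                    "copies": c.copies,
                    "modal_depth": round(c.modal_depth, 3),
                    "unit": round(c.unit, 3),
                    "peaks": ",".join(f"{p:.3f}" for p in (c.profile.peaks if c.profile else ())),
                    "agreement": c.agreement,
                    "confidence": c.confidence,
                }
                for c in self.calls
            ]
        )


def call_karyotype(calls: list[CopyNumberCall]) -> KaryotypeResult:
    """Summarize per-chromosome calls into karyotype ratio and ploidy.

    The modal copy per subgenome (ties toward the smaller value) defines
    the ratio string and ploidy (= modal Sc + modal Se); chromosomes above
    the subgenome modal are duplications, below it deletions (copy 0 = full
    deletion).
    """
    seen = Counter(c.chrom for c in calls)
    dup = [chrom for chrom, k in seen.items() if k > 1]
    if dup:
        raise ValueError(f"multiple calls for chromosomes {dup}")

    modal: dict[str, int] = {}
    for sub in ("Sc", "Se"):
        copies = [c.copies for c in calls if c.subgenome == sub]
        modal[sub] = int(np.bincount(copies).argmax()) if copies else 0

    duplications: dict[str, list[str]] = {"Sc": [], "Se": []}
    deletions: dict[str, list[str]] = {"Sc": [], "Se": []}
    for c in calls:
        if c.copies > modal[c.subgenome]:
            duplications[c.subgenome].append(c.chrom)
        elif c.copies < modal[c.subgenome]:
            deletions[c.subgenome].append(c.chrom)

    return KaryotypeResult(
        calls=list(calls),
        modal=modal,
        ratio=f"{modal['Sc']}:{modal['Se']}",
        ploidy=modal["Sc"] + modal["Se"],
        duplications=duplications,
        deletions=deletions,
    )
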