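"""Subgenome content metrics: covered proportions, mapping ratio, mitotype.

Competitive mapping to a chimeric reference splits reads between the two
subgenomes; the fraction of each subgenome's positions that received
coverage, and the Se/Sc ratio of those fractions, summarize which
subgenomes a strain carries.  Mitochondria are uniparentally inherited,
so the mitotype is called from the coverage dominance of one
mitochondrial contig over the other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth import mitochondrial, nuclear
from .references import SUBGENOMES

log = logging.getLogger(__name__)

MITOTYPES = ("Sc", "Se", "ambiguous")


def covered_proportion(
    track: pd.DataFrame, subgenome: str, min_depth: float = 1.0
) -> tuple[float, float]:
    """Fraction (and Mb) of a subgenome's positions in bins with depth >= cutoff.

    Length-weighted over the nuclear bins of the subgenome; mitochondrial
    contigs are excluded.  Returns ``(proportion, covered_mb)``.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    bins = nuclear(track)
    bins = bins[bins["subgenome"] == subgenome]
    if bins.empty:
        raise ValueError(f"depth track has no bins for subgenome {subgenome!r}")
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    covered = widths[(bins["depth"] >= min_depth).to_numpy()].sum()
    return float(covered / widths.sum()), float(covered / 1e6)


def mapping_ratio(prop_se: float, prop_sc: float) -> float:
    """Se/Sc covered-proportion ratio; inf for pure-Se, error if no signal."""
    for p in (prop_se, prop_sc):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if prop_sc == 0.0:
        if prop_se == 0.0:
            raise ValueError("no coverage signal on either subgenome")
        return math.inf
    return prop_se / prop_sc


def call_mitotype(
    cov_sc_mito: float, cov_se_mito: float, fold_threshold: float = 5.0
) -> str:
    """Mitotype from mitochondrial coverage dominance.

    ``Sc`` if the Sc mitochondrion is covered >= fold_threshold times more
    deeply than the Se one, ``Se`` for the converse, else ``ambiguous``.
    """
    if cov_sc_mito < 0 or cov_se_mito < 0:
        raise ValueError("coverages must be >= 0")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if cov_sc_mito == 0 and cov_se_mito == 0:
        log.warning("both mitochondrial contigs uncovered; mitotype ambiguous")
        return "ambiguous"
    if cov_sc_mito >= fold_threshold * cov_se_mito:
        return "Sc"
    if cov_se_mito >= fold_threshold * cov_sc_mito:
        return "Se"
    return "ambiguous"


@dataclass
class SubgenomeSummary:
    """Covered proportions, mapping ratio and mitotype for one strain."""

    sample: str
    prop: dict[str, float]  # subgenome -> covered proportion
    covered_mb: dict[str, float]  # subgenome -> covered length (Mb)
    ratio: float  # Se / Sc (may be inf)
    mito_coverage: dict[str, float]  # subgenome -> mito mean depth
    mitotype: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample,
                    "prop_Sc": self.prop["Sc"],
                    "prop_Se": self.prop["Se"],
                    "ratio": self.ratio,
                    "covered_Sc_mb": self.covered_mb["Sc"],
                    "covered_Se_mb": self.covered_mb["Se"],
                    "mito_cov_Sc": self.mito_coverage["Sc"],
                    "mito_cov_Se": self.mito_coverage["Se"],
                    "mitotype": self.mitotype,
                }
            ]
        )


def mito_coverages(track: pd.DataFrame) -> dict[str, float]:
    """Length-weighted mean depth of each subgenome's mitochondrial contig."""
    bins = mitochondrial(track)
    out: dict[str, float] = {}
    for sub in SUBGENOMES:
        sel = bins[bins["subgenome"] == sub]
        if sel.empty:
            out[sub] = 0.0
            continue
        widths = (sel["end"] - sel["start"]).to_numpy(dtype=float)
        out[sub] = float(np.average(sel["depth"], weights=widths))
    return out


def summarize_subgenomes(
    track: pd.DataFrame,
    sample: str,
    min_depth: float = 1.0,
    mito_fold_threshold: float = 5.0,
) -> SubgenomeSummary:
    """Full subgenome summary (proportions, ratio, mitotype) from one track."""
    prop: dict[str, float] = {}
    mb: dict[str, float] = {}
    for sub in SUBGENOMES:
        prop[sub], mb[sub] = covered_proportion(track, sub, min_depth)
    try:
        ratio = mapping_ratio(prop["Se"], prop["Sc"])
    except ValueError:
        ratio = math.nan
    mito = mito_coverages(track)
    mitotype = call_mitotype(mito["Sc"], mito["Se"], mito_fold_threshold)
    return SubgenomeSummary(
        sample=sample, prop=prop, covered_mb=mb, ratio=ratio,
        mito_coverage=mito, mitotype=mitotype,
    )
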