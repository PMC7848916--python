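"""Model/results interface for hybrid-genome characterization.

``HybridGenomeModel`` bundles a strain's observed data — filtered variant
sites and a binned depth track, optionally the two parents' variant sites
— and ``fit()`` runs the full inference: per-copy depth estimation, per
chromosome allele-frequency profiling and copy-number calling, karyotype
and ploidy summary, subgenome coverage metrics and mitotype, and (with
parents) per-chromosome parental contributions.  The returned
``HybridGenomeResults`` exposes the estimates, evidence tables and a
``summary()`` text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import depth as depthio
from .depth import nuclear
from .karyotype import (
    AFPeakProfile,
    CopyNumberCall,
    KaryotypeResult,
    af_peak_profile,
    call_karyotype,
    estimate_per_copy_depth,
    infer_copy_number,
    modal_bin_depth,
    scaled_depth,
)
from .metrics import SubgenomeSummary, summarize_subgenomes
from .tracing import (
    ParentalContribution,
    contributions_frame,
    trace_parental_origin,
)
from .variants import (
    FilterThresholds,
    VariantSite,
    filter_variants,
    read_vcf,
    split_by_chromosome,
)


class HybridGenomeModel:
    """Hybrid-genome characterization model for one strain.

    Parameters
    ----------
    sites : hybrid variant sites (will be hard-filtered at fit time unless
        ``prefiltered=True``).
    track : binned depth DataFrame (chrom/start/end/depth), mitochondrial
        contigs included.
    sample : strain name.
    parents : optional mapping of exactly two parent names to their variant
        sites; enables parental-origin tracing.
    """

    def __init__(
        self,
        sites: list[VariantSite],
        track: pd.DataFrame,
        sample: str = "strain",
        parents: dict[str, list[VariantSite]] | None = None,
        prefiltered: bool = False,
    ) -> None:
        if parents is not None and len(parents) != 2:
            raise ValueError("parental tracing needs exactly two parents")
        self.sites = list(sites)
        self.track = depthio.as_track(track)
        self.sample = sample
        self.parents = parents
        self.prefiltered = prefiltered

    @classmethod
    def from_files(
        cls,
        vcf_path,
        bedgraph_path,
        sample: str | None = None,
        parent_vcfs: dict[str, str] | None = None,
    ) -> "HybridGenomeModel":
        """Build the model from a hybrid VCF, a bedGraph track and
        optionally two parent VCFs ({name: path})."""
        sites = read_vcf(vcf_path, sample)
        track = depthio.read_bedgraph(bedgraph_path)
        parents = None
        if parent_vcfs:
            parents = {name: read_vcf(path, name) for name, path in parent_vcfs.items()}
        return cls(sites, track, sample=sample or "strain", parents=parents)

    def fit(
        self,
        thresholds: FilterThresholds | None = None,
        permissive_missing: bool = False,
        min_sites: int = 20,
        covered_min_depth: float = 1.0,
        mito_fold_threshold: float = 5.0,
    ) -> "HybridGenomeResults":
        """Run the full inference and return the results object."""
        thresholds = thresholds or FilterThresholds()
        if self.prefiltered:
            filtered = list(self.sites)
        else:
            filtered = filter_variants(self.sites, thresholds, permissive_missing)
        snps = [s for s in filtered if s.is_snp]
        by_chrom = split_by_chromosome(snps)

        summary = summarize_subgenomes(
            self.track, self.sample, covered_min_depth, mito_fold_threshold
        )

        nuc = nuclear(self.track)
        unit = estimate_per_copy_depth(nuc["depth"].to_numpy())

        calls: list[CopyNumberCall] = []
        profiles: dict[str, AFPeakProfile] = {}
        chroms = list(dict.fromkeys(nuc["chrom"]))
        for chrom in chroms:
            depths = nuc.loc[nuc["chrom"] == chrom, "depth"].to_numpy()
            profile = af_peak_profile(by_chrom.get(chrom, []), region=chrom, min_sites=min_sites)
            profiles[chrom] = profile
            modal = modal_bin_depth(depths, unit)
            calls.append(infer_copy_number(profile, modal, unit, chrom))

        karyotype = call_karyotype(calls)

        contributions: list[ParentalContribution] | None = None
        if self.parents is not None:
            (name_a, sites_a), (name_b, sites_b) = self.parents.items()
            copy_numbers = {c.chrom: c.copies for c in calls}
            contributions = trace_parental_origin(
                sites_a, sites_b, name_a, name_b,
                hybrid_sites=snps, copy_numbers=copy_numbers,
                track=self.track, min_sites=min_sites,
                min_depth=covered_min_depth,
            )

        return HybridGenomeResults(
            model=self,
            thresholds=thresholds,
            n_sites_raw=len(self.sites),
            n_sites_filtered=len(filtered),
            subgenomes=summary,
            unit=unit,
            karyotype=karyotype,
            profiles=profiles,
            contributions=contributions,
        )


@dataclass
class HybridGenomeResults:
    """Fitted estimates for one strain."""

    model: HybridGenomeModel
    thresholds: FilterThresholds
    n_sites_raw: int
    n_sites_filtered: int
    subgenomes: SubgenomeSummary
    unit: float  # estimated per-copy depth
    karyotype: KaryotypeResult
    profiles: dict[str, AFPeakProfile]
    contributions: list[ParentalContribution] | None = None

    @property
    def sample(self) -> str:
        return self.model.sample

    @property
    def ploidy(self) -> str:
        return self.karyotype.ploidy_string

    @property
    def mitotype(self) -> str:
        return self.subgenomes.mitotype

    def copy_numbers(self) -> dict[str, int]:
        return {c.chrom: c.copies for c in self.karyotype.calls}

    def calls_frame(self) -> pd.DataFrame:
        df = self.karyotype.to_frame()
        df.insert(0, "sample", self.sample)
        return df

    def contributions_frame(self) -> pd.DataFrame:
        if self.contributions is None:
            raise ValueError("model was fitted without parents")
        df = contributions_frame(self.contributions)
        df.insert(0, "sample", self.sample)
        return df

    def scaled_depth_track(self) -> pd.DataFrame:
        """Depth track with a display column scaled to [0, 1]."""
        track = nuclear(self.model.track).copy()
        track["scaled"] = scaled_depth(track["depth"].to_numpy())
        return track

    def summary(self) -> str:
        """Human-readable multi-section summary of the fitted strain."""
        k = self.karyotype
        s = self.subgenomes
        lines = [
            f"Hybrid genome characterization: {self.sample}",
            "=" * 54,
            f"variant sites            {self.n_sites_filtered} kept of "
            f"{self.n_sites_raw} (DP>{self.thresholds.min_depth:g}, "
            f"QD>{self.thresholds.min_qd:g}, FS<{self.thresholds.max_fs:g}, "
            f"MQ>{self.thresholds.min_mq:g})",
            f"per-copy depth (u)       {self.unit:.2f} reads",
            f"karyotype (Sc:Se)        {k.ratio}   ploidy {k.ploidy_string}",
            f"mitotype                 {s.mitotype}  "
            f"(mito depth Sc {s.mito_coverage['Sc']:.1f}, Se {s.mito_coverage['Se']:.1f})",
            f"covered proportion       Sc {s.prop['Sc']:.3f}  Se {s.prop['Se']:.3f}  "
            f"(Se/Sc ratio {s.ratio:.3f})" if np.isfinite(s.ratio) else
            f"covered proportion       Sc {s.prop['Sc']:.3f}  Se {s.prop['Se']:.3f}  "
            f"(Se/Sc ratio inf)",
            f"covered length (Mb)      Sc {s.covered_mb['Sc']:.2f}  Se {s.covered_mb['Se']:.2f}",
        ]
        for sub in ("Sc", "Se"):
            dup = ", ".join(k.duplications[sub]) or "-"
            dele = ", ".join(k.deletions[sub]) or "-"
            lines.append(f"{sub} duplications          {dup}")
            lines.append(f"{sub} deletions             {dele}")
        lines.append("-" * 54)
        lines.append(f"{'chrom':<12}{'copies':>7}{'depth':>9}{'peaks':>22}  conf")
        for c in k.calls:
            peaks = ",".join(f"{p:.2f}" for p in (c.profile.peaks if c.profile else ())) or "-"
            lines.append(
                f"{c.chrom:<12}{c.copies:>7}{c.modal_depth:>9.1f}{peaks:>22}  {c.confidence}"
            )
        if self.contributions is not None:
            lines.append("-" * 54)
            lines.append("parental contributions (copies per chromosome):")
            for contrib in self.contributions:
                parts = ", ".join(f"{p}: {n}" for p, n in contrib.contributions.items())
                lines.append(f"  {contrib.chrom:<12}{parts}  [{contrib.status}]")
        return "\n".join(lines)
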