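"""Strain reports and the end-to-end pipeline driver.

``StrainReport`` collects the headline genomic facts for one strain —
ploidy, Sc:Se karyotype ratio, mitotype, covered lengths, chromosome
duplications and deletions, parental contributions — together with full
provenance (config hash, seed, thresholds, version).  ``run_pipeline``
executes a configured run end-to-end: optional simulation, filtering,
subgenome metrics, karyotype inference, parental tracing, and report
writing, including a truth-vs-inferred comparison in simulation mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import depth as depthio
from .karyotype import KaryotypeResult
from .metrics import SubgenomeSummary
from .model import HybridGenomeModel, HybridGenomeResults
from .references import build_references, chrom_name, subgenome_of
from .simulate import (
    KaryotypeSpec,
    ParentSpec,
    group3_cross_karyotype,
    group3_parent_specs,
    mate,
    random_karyotype,
    simulate_observed,
    simulate_parents,
)
from .tracing import ParentalContribution
from .variants import FilterThresholds

log = logging.getLogger(__name__)

_ROMAN_ORDER = {
    numeral: i
    for i, numeral in enumerate(
        "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX".split()
    )
}


def _chrom_sort_key(chrom: str) -> tuple:
    sub = subgenome_of(chrom) or "~"
    tail = chrom.split("chr", 1)[-1]
    if sub == "Sc":
        return (0, _ROMAN_ORDER.get(tail, 99))
    try:
        return (1, int(tail))
    except ValueError:
        return (2, 0)


@dataclass
class StrainReport:
    """Table-style genomic summary for one strain, with provenance."""

    sample: str
    ploidy: str
    karyotype_ratio: str
    mitotype: str
    covered_length_mb: dict[str, float]
    mapping_ratio: float
    duplications: dict[str, list[str]]
    deletions: dict[str, list[str]]
    parental_contributions: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sample": self.sample,
            "ploidy": self.ploidy,
            "karyotype_ratio": self.karyotype_ratio,
            "mitotype": self.mitotype,
            "covered_length_mb": {k: round(v, 3) for k, v in self.covered_length_mb.items()},
            "mapping_ratio": None if not np.isfinite(self.mapping_ratio)
            else round(float(self.mapping_ratio), 4),
            "duplications": self.duplications,
            "deletions": self.deletions,
            "parental_contributions": (
                None if self.parental_contributions is None
                else self.parental_contributions.to_dict(orient="records")
            ),
            "provenance": self.provenance,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample,
                    "ploidy": self.ploidy,
                    "karyotype_Sc_Se": self.karyotype_ratio,
                    "mitotype": self.mitotype,
                    "covered_Sc_mb": round(self.covered_length_mb["Sc"], 3),
                    "covered_Se_mb": round(self.covered_length_mb["Se"], 3),
                    "dup_Sc": ",".join(self.duplications["Sc"]) or "-",
                    "dup_Se": ",".join(self.duplications["Se"]) or "-",
                    "del_Sc": ",".join(self.deletions["Sc"]) or "-",
                    "del_Se": ",".join(self.deletions["Se"]) or "-",
                }
            ]
        )


def build_strain_report(
    summary: SubgenomeSummary,
    karyotype: KaryotypeResult,
    contributions: list[ParentalContribution] | None = None,
    sample: str | None = None,
    provenance: dict | None = None,
) -> StrainReport:
    """Assemble the per-strain report from the three analysis outputs."""
    if sample is not None and summary.sample != sample:
        raise ValueError(f"sample mismatch: summary is for {summary.sample!r}, not {sample!r}")
    contrib_df = None
    if contributions is not None:
        from .tracing import contributions_frame

        contrib_df = contributions_frame(contributions)
        contrib_df = contrib_df.sort_values(
            by="chrom", key=lambda s: s.map(_chrom_sort_key)
        ).reset_index(drop=True)

    dup = {s: sorted(v, key=_chrom_sort_key) for s, v in karyotype.duplications.items()}
    dele = {s: sorted(v, key=_chrom_sort_key) for s, v in karyotype.deletions.items()}
    return StrainReport(
        sample=summary.sample,
        ploidy=karyotype.ploidy_string,
        karyotype_ratio=karyotype.ratio,
        mitotype=summary.mitotype,
        covered_length_mb=dict(summary.covered_mb),
        mapping_ratio=summary.ratio,
        duplications=dup,
        deletions=dele,
        parental_contributions=contrib_df,
        provenance=provenance or {},
    )


def report_from_results(results: HybridGenomeResults, provenance: dict | None = None) -> StrainReport:
    return build_strain_report(
        results.subgenomes,
        results.karyotype,
        results.contributions,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# pipeline driver

_SCENARIOS = ("group3_like", "group2_like", "random")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _thresholds_from(config: dict) -> FilterThresholds:
    f = config.get("filters", {})
    return FilterThresholds(
        min_depth=f.get("min_dp", 40.0),
        min_qd=f.get("min_qd", 2.0),
        max_fs=f.get("max_fs", 60.0),
        min_mq=f.get("min_mq", 40.0),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def _simulate_scenario(config: dict, outdir: Path) -> dict:
    """Generate a simulated data set and return paths + truth."""
    sim = config["simulate"]
    seed = config.get("seed")
    if seed is None:
        raise ValueError("simulation mode requires an explicit seed")
    scenario = sim.get("scenario", "group3_like")
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {_SCENARIOS}")

    refs = build_references(
        n_chroms_per_subgenome=sim.get("n_chroms", 8),
        chrom_length=sim.get("chrom_length", 50_000),
        divergence=sim.get("divergence", 0.05),
        seed=seed,
    )
    specs = group3_parent_specs(
        het_density=sim.get("het_density", 1.0),
        private_density=sim.get("private_density", 2.0),
    )
    parents = simulate_parents(specs, refs, seed)
    if scenario == "group3_like":
        kspec = group3_cross_karyotype(refs)
    elif scenario == "group2_like":
        haplotypes = {}
        for chrom in refs.chromosomes:
            sub = subgenome_of(chrom)
            if sub == "Sc":
                haplotypes[chrom] = [("ale_parent", 0), ("ale_parent", 1)]
            else:
                haplotypes[chrom] = [("lager_segregant", 0), ("lager_segregant", 0)]
        kspec = KaryotypeSpec(haplotypes=haplotypes, mitotype="Se")
    else:
        kspec = random_karyotype(refs, parents, seed)

    truth = mate(parents, kspec, seed)
    obs = simulate_observed(
        truth,
        refs,
        per_copy_depth=sim.get("per_copy_depth", 50.0),
        mito_depth_multiplier=sim.get("mito_depth_multiplier", 20.0),
        bin_width=sim.get("bin_width", 10_000),
        error_rate=sim.get("error_rate", 0.002),
        seed=seed,
    )

    sample = config.get("sample", "simulated_hybrid")
    outdir.mkdir(parents=True, exist_ok=True)
    refs.write_fasta(outdir / "reference.fa")
    vcf = outdir / f"{sample}.vcf"
    bedgraph = outdir / f"{sample}.depth.bedgraph"
    obs.write(vcf, bedgraph, sample=sample, refs=refs)
    parent_vcfs = {}
    for name, parent in parents.items():
        path = outdir / f"{name}.vcf"
        parent.write_vcf(path, refs)
        parent_vcfs[name] = str(path)
    truth.to_json(outdir / "truth.json")

    return {
        "hybrid_vcf": str(vcf),
        "depth_bedgraph": str(bedgraph),
        "parent_vcfs": parent_vcfs,
        "truth": truth,
        "sample": sample,
    }


def _truth_comparison(results: HybridGenomeResults, truth) -> pd.DataFrame:
    rows = []
    inferred = results.copy_numbers()
    contrib_by_chrom = {}
    if results.contributions is not None:
        contrib_by_chrom = {c.chrom: c.contributions for c in results.contributions}
    for chrom, true_copies in truth.copy_numbers().items():
        called = inferred.get(chrom)
        row = {
            "chrom": chrom,
            "true_copies": true_copies,
            "called_copies": called,
            "copies_match": called == true_copies,
        }
        if chrom in contrib_by_chrom:
            true_contrib = truth.contributions[chrom]
            called_contrib = contrib_by_chrom[chrom]
            row["contrib_match"] = all(
                called_contrib.get(p, 0) == k for p, k in true_contrib.items()
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(by="chrom", key=lambda s: s.map(_chrom_sort_key)).reset_index(drop=True)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> StrainReport:
    """Execute a configured run end-to-end and write all artifacts.

    In simulation mode (config has a ``simulate`` section) the synthetic
    data set is generated first and a truth-vs-inferred comparison table
    is written alongside the report.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if "simulate" in config:
        sim_out = _simulate_scenario(config, outdir / "simulated")
        hybrid_vcf = sim_out["hybrid_vcf"]
        bedgraph = sim_out["depth_bedgraph"]
        parent_vcfs = sim_out["parent_vcfs"]
        sample = sim_out["sample"]
        truth = sim_out["truth"]
    else:
        inputs = config.get("inputs", {})
        for key in ("hybrid_vcf", "depth_bedgraph"):
            if key not in inputs:
                raise ValueError(f"analysis mode config lacks inputs.{key}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"inputs.{key}: {inputs[key]} does not exist")
        hybrid_vcf = inputs["hybrid_vcf"]
        bedgraph = inputs["depth_bedgraph"]
        parent_vcfs = inputs.get("parent_vcfs")
        sample = config.get("sample", "strain")

    thresholds = _thresholds_from(config)
    model = HybridGenomeModel.from_files(
        hybrid_vcf, bedgraph, sample=sample, parent_vcfs=parent_vcfs
    )
    results = model.fit(
        thresholds=thresholds,
        min_sites=config.get("min_sites", 20),
        covered_min_depth=config.get("covered_min_depth", 1.0),
        mito_fold_threshold=config.get("mito_fold_threshold", 5.0),
    )

    provenance = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "thresholds": dataclasses.asdict(thresholds),
    }
    report = report_from_results(results, provenance=provenance)

    results.subgenomes.to_frame().to_csv(outdir / "subgenome_summary.tsv", sep="\t", index=False)
    results.calls_frame().to_csv(outdir / "copy_number_calls.tsv", sep="\t", index=False)
    if results.contributions is not None:
        results.contributions_frame().to_csv(
            outdir / "parental_contributions.tsv", sep="\t", index=False
        )
    report.to_row().to_csv(outdir / "strain_report.tsv", sep="\t", index=False)
    report.to_json(outdir / "strain_report.json")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")

    if truth is not None:
        comparison = _truth_comparison(results, truth)
        comparison.to_csv(outdir / "truth_comparison.tsv", sep="\t", index=False)
        match_rate = float(comparison["copies_match"].mean())
        log.info("truth comparison: %.1f%% of chromosome copy calls match", 100 * match_rate)
        with open(outdir / "truth_match_rate.json", "w") as fh:
            json.dump({"copy_call_match_rate": match_rate}, fh)

    log.info("pipeline complete for %s: %s %s, mitotype %s",
             sample, report.karyotype_ratio, report.ploidy, report.mitotype)
    return report
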