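"""Simulation of allopolyploid hybrid genomes with known ground truth.

The simulator works at the variant/pileup level: read alignment and
variant calling are upstream of this package, so allele depths and binned
depths are drawn directly from the sampling distributions the analysis
assumes — Poisson total depth per site, multinomial (here binomial) allele
depths with a small symmetric base-error leakage, and near-Gaussian bin
means whose spread shrinks with bin width.

The pieces compose like the wet-lab protocol they emulate: build a
chimeric two-subgenome reference, simulate diploid/allodiploid parents
carrying heterozygous and private homozygous SNPs, mate chosen parental
haplotypes into a hybrid with an arbitrary per-chromosome karyotype, then
generate the noisy observables (hybrid VCF + bedGraph depth track).
Identical seeds and parameters give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import depth as depthio
from .references import ReferencePair, SUBGENOMES, mito_name, subgenome_of
from .variants import VariantSite, write_vcf

#: approximate read length used to scale bin-mean noise: a bin of width w
#: aggregates ~w/READ_SCALE independent read placements.
READ_SCALE = 150.0

DEFAULT_ERROR_RATE = 0.002

HapLabel = tuple[str, int]  # (parent name, haplotype index within subgenome)


# ---------------------------------------------------------------------------
# parents

@dataclass(frozen=True)
class ParentSpec:
    """Composition of one simulated parent strain.

    copies : chromosome copies per subgenome, e.g. ``{"Sc": 2}`` for a
        diploid ale strain or ``{"Sc": 1, "Se": 1}`` for an allodiploid
        lager segregant.
    het_density : heterozygous sites per kb within each subgenome that has
        at least two copies.
    private_density : homozygous SNPs per kb private to this parent.
    mitotype : subgenome of the parent's mitochondria.
    """

    name: str
    copies: dict[str, int]
    het_density: float = 1.0
    private_density: float = 1.0
    mitotype: str = "Sc"

    def __post_init__(self) -> None:
        total = sum(self.copies.values())
        if total < 1:
            raise ValueError("parent must carry at least one chromosome set")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError("copy numbers must be >= 0")
        if self.het_density < 0 or self.private_density < 0:
            raise ValueError("densities must be >= 0")
        if self.mitotype not in SUBGENOMES:
            raise ValueError(f"mitotype must be one of {SUBGENOMES}")
        if any(g not in SUBGENOMES for g in self.copies):
            raise ValueError(f"unknown subgenome in copies: {self.copies}")

    def n_haplotypes(self, subgenome: str) -> int:
        return self.copies.get(subgenome, 0)


@dataclass
class ParentVariant:
    """A planted SNP in one parent: which haplotypes carry the alternate."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    carriers: frozenset[int]  # haplotype indices carrying the alternate
    private: bool  # homozygous and private to this parent


@dataclass
class ParentGenome:
    """Simulated parent: spec, planted variants, and observed VCF sites."""

    spec: ParentSpec
    variants: dict[tuple[str, int], ParentVariant]
    sites: list[VariantSite] = field(repr=False, default_factory=list)

    @property
    def name(self) -> str:
        return self.spec.name

    def haplotype_table(self) -> pd.DataFrame:
        """One row per planted variant: position, alleles, carrying haplotypes."""
        rows = [
            {
                "parent": self.name,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "carrier_haplotypes": ",".join(f"h{i}" for i in sorted(v.carriers)),
                "private": v.private,
            }
            for v in sorted(self.variants.values(), key=lambda v: (v.chrom, v.pos))
        ]
        return pd.DataFrame(rows)

    def write_vcf(self, path, refs: ReferencePair) -> None:
        write_vcf(self.sites, path, sample=self.name, contig_lengths=refs.all_lengths)


class PositionRegistry:
    """Coordinates variant positions across parents simulated in one run.

    Registering every planted position here guarantees that a private
    homozygous SNP of one parent is absent from every other parent.
    """

    def __init__(self) -> None:
        self._used: set[tuple[str, int]] = set()

    def claim(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Return the subset of ``positions`` not yet taken, and take them."""
        free = np.array([p for p in positions if (chrom, int(p)) not in self._used], dtype=int)
        self._used.update((chrom, int(p)) for p in free)
        return free


_MAX_POSITION_RETRIES = 8


def _draw_positions(
    rng: np.random.Generator,
    length: int,
    n: int,
    forbidden: set[int],
    registry: PositionRegistry,
    chrom: str,
) -> np.ndarray:
    """Draw ``n`` distinct 1-based positions avoiding forbidden/claimed ones."""
    chosen: list[int] = []
    for _ in range(_MAX_POSITION_RETRIES):
        need = n - len(chosen)
        if need == 0:
            break
        cand = rng.integers(1, length + 1, size=2 * need + 8)
        cand = np.unique(cand)
        cand = cand[[int(p) not in forbidden and int(p) not in chosen for p in cand]]
        cand = registry.claim(chrom, cand)
        rng.shuffle(cand)
        chosen.extend(int(p) for p in cand[:need])
    if len(chosen) < n:
        raise RuntimeError(
            f"could not place {n} variants on {chrom} (length {length}): "
            "density too high for the available positions"
        )
    return np.sort(np.array(chosen, dtype=int))


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[int(rng.integers(0, 3))]


def _passing_info(rng: np.random.Generator) -> tuple[float, float, float]:
    """(QD, FS, MQ) drawn from comfortably passing ranges."""
    qd = float(rng.uniform(15.0, 35.0))
    fs = float(rng.uniform(0.0, 5.0))
    mq = float(rng.uniform(50.0, 60.0))
    return round(qd, 2), round(fs, 2), round(mq, 2)


def _observed_ad(
    rng: np.random.Generator, mean_depth: float, alt_fraction: float, error_rate: float
) -> tuple[int, int, int]:
    """(DP, ref reads, alt reads) with Poisson depth and binomial alt count."""
    dp = int(rng.poisson(mean_depth))
    p = alt_fraction * (1.0 - error_rate) + (1.0 - alt_fraction) * error_rate
    n_alt = int(rng.binomial(dp, p)) if dp > 0 else 0
    return dp, dp - n_alt, n_alt


def simulate_parent(
    spec: ParentSpec,
    refs: ReferencePair,
    seed: int,
    registry: PositionRegistry | None = None,
    depth_per_copy: float = 50.0,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> ParentGenome:
    """Simulate one parent: plant SNPs and generate its observed VCF sites.

    Heterozygous sites (GT 0/1) are planted at ``het_density`` per kb on
    subgenomes with >= 2 copies; private homozygous SNPs (GT 1/1 on every
    haplotype) at ``private_density`` per kb on subgenomes with >= 1 copy.
    Pass one shared ``registry`` for all parents of a run so that private
    sites are never reused across parents.  Positions colliding with the
    recorded inter-subgenome divergence are excluded (competitive mapping
    would absorb them into the reference).
    """
    registry = registry if registry is not None else PositionRegistry()
    rng = np.random.default_rng(np.random.SeedSequence([seed, _stable_hash(spec.name)]))
    variants: dict[tuple[str, int], ParentVariant] = {}
    sites: list[VariantSite] = []

    for chrom, length in refs.chromosomes.items():
        sub = subgenome_of(chrom)
        n_hap = spec.n_haplotypes(sub)
        if n_hap == 0:
            continue
        forbidden = {int(p) + 1 for p in refs.divergent_positions.get(chrom, ())}
        seq = refs.sequences[chrom]

        n_het = int(rng.poisson(spec.het_density * length / 1000.0)) if n_hap >= 2 else 0
        n_priv = int(rng.poisson(spec.private_density * length / 1000.0))
        het_pos = _draw_positions(rng, length, n_het, forbidden, registry, chrom)
        priv_pos = _draw_positions(rng, length, n_priv, forbidden, registry, chrom)

        for pos_arr, private in ((het_pos, False), (priv_pos, True)):
            for pos in pos_arr:
                ref_base = chr(seq[pos - 1])
                alt = _alt_base(rng, ref_base)
                if private:
                    carriers = frozenset(range(n_hap))
                else:
                    n_carry = int(rng.integers(1, n_hap))  # proper subset
                    carriers = frozenset(
                        int(i) for i in rng.choice(n_hap, size=n_carry, replace=False)
                    )
                variants[(chrom, int(pos))] = ParentVariant(
                    chrom=chrom, pos=int(pos), ref=ref_base, alt=alt,
                    carriers=carriers, private=private,
                )

        for pos in np.sort(np.concatenate([het_pos, priv_pos])):
            v = variants[(chrom, int(pos))]
            frac = len(v.carriers) / n_hap
            dp, n_ref, n_alt = _observed_ad(rng, depth_per_copy * n_hap, frac, error_rate)
            if dp == 0:
                dp, n_ref, n_alt = 1, (0 if frac == 1.0 else 1), (1 if frac == 1.0 else 0)
            qd, fs, mq = _passing_info(rng)
            gt = tuple(1 if i in v.carriers else 0 for i in range(n_hap))
            sites.append(
                VariantSite(
                    subgenome=sub, chrom=chrom, pos=v.pos, ref=v.ref, alts=(v.alt,),
                    ad=(n_ref, n_alt), dp=dp, qd=qd, fs=fs, mq=mq, genotype=gt,
                )
            )

    return ParentGenome(spec=spec, variants=variants, sites=sites)


def simulate_parents(
    specs: list[ParentSpec],
    refs: ReferencePair,
    seed: int,
    depth_per_copy: float = 50.0,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> dict[str, ParentGenome]:
    """Simulate a set of parents sharing one position registry."""
    registry = PositionRegistry()
    return {
        spec.name: simulate_parent(
            spec, refs, seed, registry=registry,
            depth_per_copy=depth_per_copy, error_rate=error_rate,
        )
        for spec in specs
    }


def _stable_hash(text: str) -> int:
    # deterministic across processes (hash() is salted)
    h = 2166136261
    for byte in text.encode():
        h = ((h ^ byte) * 16777619) % (1 << 31)
    return h


# ---------------------------------------------------------------------------
# mating

@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype: which parental haplotypes each chromosome got.

    haplotypes : chromosome name -> ordered list of (parent, hap index);
        the list length IS the copy number (empty list = deletion).
    mitotype : subgenome of the inherited mitochondria.
    """

    haplotypes: dict[str, list[HapLabel]]
    mitotype: str

    def __post_init__(self) -> None:
        if self.mitotype not in SUBGENOMES:
            raise ValueError(f"mitotype must be one of {SUBGENOMES}")
        if all(len(h) == 0 for h in self.haplotypes.values()):
            raise ValueError("at least one chromosome must have copy number >= 1")

    def copy_number(self, chrom: str) -> int:
        return len(self.haplotypes[chrom])


@dataclass
class TruthSite:
    """True state of one variant position in the hybrid."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_copies: int  # how many inherited haplotypes carry the alternate
    total_copies: int  # chromosome copy number (ref copies = total - alt)
    source_parent: str
    private: bool


@dataclass
class TruthSet:
    """Everything the inference should recover, for one simulated hybrid."""

    karyotype: KaryotypeSpec
    sites: dict[str, list[TruthSite]]  # per chromosome, position-sorted
    contributions: dict[str, dict[str, int]]  # chrom -> parent -> haplotypes
    mitotype: str
    seed: int
    refs: ReferencePair = field(repr=False, default=None)

    def copy_numbers(self) -> dict[str, int]:
        return {c: self.karyotype.copy_number(c) for c in self.karyotype.haplotypes}

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "mitotype": self.mitotype,
            "copy_numbers": self.copy_numbers(),
            "contributions": self.contributions,
            "haplotypes": {
                c: [f"{p}:h{i}" for p, i in labels]
                for c, labels in self.karyotype.haplotypes.items()
            },
            "sites": {
                c: [
                    {
                        "pos": s.pos, "ref": s.ref, "alt": s.alt,
                        "alt_copies": s.alt_copies, "total_copies": s.total_copies,
                        "parent": s.source_parent, "private": s.private,
                    }
                    for s in sites
                ]
                for c, sites in self.sites.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def mate(
    parents: dict[str, ParentGenome],
    karyotype: KaryotypeSpec,
    seed: int,
) -> TruthSet:
    """Combine parental haplotypes per the karyotype into a hybrid truth set.

    Per-site alternate copy counts are the number of inherited haplotypes
    carrying the alternate; parental contribution per chromosome is the
    number of haplotypes taken from each parent.
    """
    refs = None
    for chrom, labels in karyotype.haplotypes.items():
        for parent_name, hap in labels:
            if parent_name not in parents:
                raise KeyError(f"karyotype references unknown parent {parent_name!r}")
            parent = parents[parent_name]
            n_hap = parent.spec.n_haplotypes(subgenome_of(chrom))
            if not 0 <= hap < n_hap:
                raise KeyError(
                    f"karyotype references haplotype h{hap} of {parent_name} on "
                    f"{chrom}, which has {n_hap} haplotype(s)"
                )

    sites: dict[str, list[TruthSite]] = {}
    contributions: dict[str, dict[str, int]] = {}
    for chrom, labels in karyotype.haplotypes.items():
        contrib: dict[str, int] = {name: 0 for name in parents}
        for parent_name, _ in labels:
            contrib[parent_name] += 1
        contributions[chrom] = contrib

        total = len(labels)
        if total == 0:  # deleted chromosome: no sites
            sites[chrom] = []
            continue
        positions: dict[int, TruthSite] = {}
        for parent_name, parent in parents.items():
            for (vchrom, pos), v in parent.variants.items():
                if vchrom != chrom:
                    continue
                alt_copies = sum(
                    1 for (pn, hap) in labels if pn == parent_name and hap in v.carriers
                )
                positions[pos] = TruthSite(
                    chrom=chrom, pos=pos, ref=v.ref, alt=v.alt,
                    alt_copies=alt_copies, total_copies=total,
                    source_parent=parent_name, private=v.private,
                )
        sites[chrom] = [positions[p] for p in sorted(positions)]

    return TruthSet(
        karyotype=karyotype, sites=sites, contributions=contributions,
        mitotype=karyotype.mitotype, seed=seed,
    )


# ---------------------------------------------------------------------------
# observation

@dataclass
class SimulatedObservation:
    """Noisy observables for one simulated hybrid."""

    sites: list[VariantSite]
    track: pd.DataFrame  # depth bins incl. mitochondrial contigs
    mito_coverage: dict[str, float]  # subgenome -> mean mito depth

    def write(self, vcf_path, bedgraph_path, sample: str, refs: ReferencePair) -> None:
        write_vcf(self.sites, vcf_path, sample=sample, contig_lengths=refs.all_lengths)
        depthio.write_bedgraph(self.track, bedgraph_path)


def _bin_depths(
    rng: np.random.Generator, length: int, bin_width: int, mean: float
) -> pd.DataFrame:
    starts = np.arange(0, length, bin_width)
    ends = np.minimum(starts + bin_width, length)
    widths = ends - starts
    sd = np.sqrt(max(mean, 1e-6)) / np.sqrt(widths / READ_SCALE)
    vals = np.maximum(rng.normal(mean, sd), 0.0)
    return pd.DataFrame({"start": starts, "end": ends, "depth": np.round(vals, 4)})


def simulate_observed(
    truth: TruthSet,
    refs: ReferencePair,
    per_copy_depth: float = 50.0,
    mito_depth_multiplier: float = 20.0,
    bin_width: int = 10_000,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> SimulatedObservation:
    """Draw the hybrid's noisy VCF sites and binned depth track.

    Per site, DP ~ Poisson(per_copy_depth x copy number) and the alternate
    read count is binomial at the true allele-copy fraction with symmetric
    error leakage; sites none of whose inherited haplotypes carry the
    alternate produce no record.  Per bin, the mean depth is near-Gaussian
    around per_copy_depth x copies and truncated at zero.  The mitochondrial
    contig of the true mitotype is covered at per_copy_depth x
    mito_depth_multiplier; the other mitochondrion sees only error leakage.
    """
    if per_copy_depth <= 0:
        raise ValueError("per_copy_depth must be > 0")
    if bin_width < 1000:
        raise ValueError("bin_width must be >= 1 kb")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, seed, 7]))

    sites: list[VariantSite] = []
    frames: list[pd.DataFrame] = []
    leak = per_copy_depth * error_rate

    for chrom, length in refs.chromosomes.items():
        if chrom not in truth.karyotype.haplotypes:
            continue
        copies = truth.karyotype.copy_number(chrom)
        frame = _bin_depths(rng, length, bin_width, per_copy_depth * copies if copies else leak)
        frame.insert(0, "chrom", chrom)
        frames.append(frame)
        if copies == 0:
            continue
        for ts in truth.sites[chrom]:
            if ts.alt_copies == 0:
                continue
            dp, n_ref, n_alt = _observed_ad(
                rng, per_copy_depth * copies, ts.alt_copies / copies, error_rate
            )
            if dp == 0:
                continue
            qd, fs, mq = _passing_info(rng)
            gt = (1, 1) if ts.alt_copies == ts.total_copies else (0, 1)
            sites.append(
                VariantSite(
                    subgenome=subgenome_of(chrom), chrom=chrom, pos=ts.pos,
                    ref=ts.ref, alts=(ts.alt,), ad=(n_ref, n_alt), dp=dp,
                    qd=qd, fs=fs, mq=mq, genotype=gt,
                )
            )

    mito_cov: dict[str, float] = {}
    for sub in SUBGENOMES:
        name, length = refs.mito[sub]
        mean = per_copy_depth * (mito_depth_multiplier if sub == truth.mitotype else error_rate)
        frame = _bin_depths(rng, length, bin_width, mean)
        frame.insert(0, "chrom", name)
        frames.append(frame)
        widths = frame["end"] - frame["start"]
        mito_cov[sub] = float(np.average(frame["depth"], weights=widths))

    track = depthio.as_track(pd.concat(frames, ignore_index=True))
    return SimulatedObservation(sites=sites, track=track, mito_coverage=mito_cov)


def simulate_region_sites(
    n_sites: int,
    alt_copies: int,
    copy_number: int,
    per_copy_depth: float,
    seed: int,
    error_rate: float = DEFAULT_ERROR_RATE,
    chrom: str = "Sc_chrI",
) -> list[VariantSite]:
    """Simulate heterozygous sites in one region of fixed copy number.

    Convenience wrapper around the observation noise kernel: every site
    carries ``alt_copies`` alternate copies out of ``copy_number``, with
    DP ~ Poisson(per_copy_depth x copy_number).  Used to study the modal
    allele-frequency signatures of diploid/triploid/tetraploid regions.
    """
    if not 0 < alt_copies <= copy_number:
        raise ValueError("need 0 < alt_copies <= copy_number")
    rng = np.random.default_rng(np.random.SeedSequence([seed, alt_copies, copy_number]))
    sites = []
    for i in range(n_sites):
        dp, n_ref, n_alt = _observed_ad(
            rng, per_copy_depth * copy_number, alt_copies / copy_number, error_rate
        )
        if dp == 0:
            continue
        qd, fs, mq = _passing_info(rng)
        sites.append(
            VariantSite(
                subgenome=subgenome_of(chrom), chrom=chrom, pos=1000 * (i + 1),
                ref="A", alts=("G",), ad=(n_ref, n_alt), dp=dp,
                qd=qd, fs=fs, mq=mq,
                genotype=(1, 1) if alt_copies == copy_number else (0, 1),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# canned cross designs

def group3_cross_karyotype(
    refs: ReferencePair,
    segregant: str = "lager_segregant",
    ale: str = "ale_parent",
    mitotype: str = "Se",
    deleted_se: tuple[int, ...] = (2,),  # 0-based index -> Se_chr3 deleted
) -> KaryotypeSpec:
    """Karyotype of an allodiploid lager segregant x diploid ale cross.

    Every Sc chromosome gets both ale haplotypes plus the segregant's one
    (copy 3); every Se chromosome gets the segregant's single copy, except
    the listed deletions (by default Se_chr3, the deletion recurrently seen
    in de novo lager hybrids).  Modal karyotype 3:1, ploidy 4N.
    """
    haplotypes: dict[str, list[HapLabel]] = {}
    for chrom in refs.chromosomes:
        sub = subgenome_of(chrom)
        if sub == "Sc":
            haplotypes[chrom] = [(ale, 0), (ale, 1), (segregant, 0)]
        else:
            idx = list(refs.contigs_of("Se")).index(chrom)
            haplotypes[chrom] = [] if idx in deleted_se else [(segregant, 0)]
    return KaryotypeSpec(haplotypes=haplotypes, mitotype=mitotype)


def group3_parent_specs(
    segregant: str = "lager_segregant",
    ale: str = "ale_parent",
    het_density: float = 1.0,
    private_density: float = 2.0,
) -> list[ParentSpec]:
    """Parent specs for the allodiploid x diploid ale cross design."""
    return [
        ParentSpec(
            name=segregant, copies={"Sc": 1, "Se": 1},
            het_density=het_density, private_density=private_density, mitotype="Se",
        ),
        ParentSpec(
            name=ale, copies={"Sc": 2},
            het_density=het_density, private_density=private_density, mitotype="Sc",
        ),
    ]


def random_karyotype(
    refs: ReferencePair,
    parents: dict[str, ParentGenome],
    seed: int,
    max_copies: int = 4,
    mitotype: str | None = None,
) -> KaryotypeSpec:
    """Draw a random whole-chromosome karyotype from the parents' haplotypes.

    Copy numbers are drawn per chromosome from 0..max_copies with most mass
    on 1-3 (aneuploidies and occasional deletions), haplotypes drawn with
    replacement from the union of parental haplotypes for that subgenome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    weights = np.array([0.06, 0.34, 0.30, 0.22, 0.08][: max_copies + 1], dtype=float)
    weights /= weights.sum()
    haplotypes: dict[str, list[HapLabel]] = {}
    for chrom in refs.chromosomes:
        sub = subgenome_of(chrom)
        pool: list[HapLabel] = [
            (name, i)
            for name, parent in parents.items()
            for i in range(parent.spec.n_haplotypes(sub))
        ]
        if not pool:
            haplotypes[chrom] = []
            continue
        copies = int(rng.choice(len(weights), p=weights))
        idx = rng.integers(0, len(pool), size=copies)
        haplotypes[chrom] = [pool[int(i)] for i in idx]
    if all(len(h) == 0 for h in haplotypes.values()):
        first = next(iter(haplotypes))
        haplotypes[first] = [pool[0]]
    if mitotype is None:
        mitotype = str(rng.choice(SUBGENOMES))
    return KaryotypeSpec(haplotypes=haplotypes, mitotype=mitotype)
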