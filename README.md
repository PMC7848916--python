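# hybridkaryo

Genome characterization for interspecies *Saccharomyces* hybrids — the
kind of allopolyploid strains produced by mating *S. cerevisiae* with
*S. eubayanus* or with lager (*S. pastorianus*) segregants. Given variant
calls and a binned depth track from **competitive mapping** to a chimeric
two-subgenome reference (both parental species concatenated into one
reference, so each read settles on the subgenome it matches best),
`hybridkaryo` infers:

- **subgenome content** — covered proportion of each subgenome and the
  Se/Sc mapping ratio;
- **mitotype** — which species' mitochondria the strain inherited, from
  mitochondrial coverage dominance;
- **karyotype and ploidy** — an integer copy number per chromosome,
  combining allele-frequency modality with quantized read depth, plus
  chromosome duplication/deletion lists and a modal Sc:Se ratio;
- **parental origin** — how many copies of each chromosome came from
  each parent, traced through private homozygous SNPs.

A first-class simulator generates allopolyploid hybrids with known
ground truth (chimeric FASTA references, parent and hybrid VCFs,
bedGraph depth tracks), so the whole pipeline is testable with no
external data.

## The model

At a variant site with allele depths `AD`, the alternate allele
frequency is `f = max_alt AD_alt / sum(AD)`. In a region with `c`
chromosome copies, heterozygous sites cluster at multiples of `1/c`:
modal peaks at 0.5 indicate two alleles, 0.33/0.66 three, 0.25/0.5/0.75
four, and f ≈ 1 a homozygous or single-copy region. AF alone is
ambiguous (haploid vs homozygous-diploid; diploid vs 2+2 tetraploid),
so depth resolves it: with a per-copy depth unit `u`, a chromosome's
modal bin depth is ≈ `c·u`. `u` is estimated genome-wide by a grid
search maximizing a quantization score (bin depths should sit near
integer multiples of `u`), and `c = round(depth/u)`, with the AF peak
profile kept as an agreement flag.

Parental origin uses private homozygous SNPs: positions where one
parent is homozygous-alternate (GT 1/1) and the other carries only the
reference. In the hybrid, the fraction of reads with the marker allele
estimates the fraction of copies inherited from the owning parent — a
chromosome-wide median of 0.33 at copy 3 means one of three copies, and
the integer split `k_A + k_B = c` is chosen by joint consistency with
both parents' medians.

Variant sites are hard-filtered first with the strict thresholds
DP > 40, QD > 2, FS < 60, MQ > 40.

## Worked example

Simulate the cross of an allodiploid lager segregant (one Sc + one Se
chromosome set, Se mitotype) with a diploid ale strain, then fit:

```python
import hybridkaryo as hk
from hybridkaryo.simulate import group3_parent_specs, group3_cross_karyotype

refs = hk.build_references(n_chroms_per_subgenome=4, chrom_length=50_000,
                           divergence=0.05, seed=1)
parents = hk.simulate_parents(group3_parent_specs(), refs, seed=1)
truth = hk.mate(parents, group3_cross_karyotype(refs), seed=1)
obs = hk.simulate_observed(truth, refs, per_copy_depth=50.0, seed=1)

model = hk.HybridGenomeModel(obs.sites, obs.track, sample="hyb",
                             parents={n: p.sites for n, p in parents.items()})
print(model.fit().summary())
```

which prints (abridged):

```
Hybrid genome characterization: hyb
======================================================
variant sites            1265 kept of 1294 (DP>40, QD>2, FS<60, MQ>40)
per-copy depth (u)       49.89 reads
karyotype (Sc:Se)        3:1   ploidy 4N
mitotype                 Se  (mito depth Sc 0.1, Se 1000.2)
...
Se deletions             Se_chr3
------------------------------------------------------
chrom        copies    depth                 peaks  conf
Sc_chrI           3    148.7             0.33,0.67  high
Se_chr1           1     49.9                  0.99  high
...
parental contributions (copies per chromosome):
  Sc_chrI     lager_segregant: 1, ale_parent: 2  [determined]
  Se_chr1     lager_segregant: 1, ale_parent: 0  [determined]
```

Read: every *S. cerevisiae* chromosome is present in three copies (two
from the ale parent, one from the segregant), every *S. eubayanus*
chromosome in one copy (from the segregant) except the engineered
`Se_chr3` deletion — a 3:1 karyotype, 4N ploidy, *S. eubayanus*
mitotype. The Sc AF peaks at 0.33/0.67 are the triploid signature; the
Se peak near 1 with depth ≈ 1·u is the single-copy signature.

The same pipeline runs from the shell:

```sh
hybridkaryo run --config scenario.yaml --out outdir --seed 1
hybridkaryo filter hybrid.vcf --out filtered.vcf --min-dp 40
hybridkaryo metrics depth.bedgraph --sample s1 --out metrics.tsv
```

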