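# Methods

## Problem setting

An interspecies hybrid yeast carries two subgenomes — here labelled
`Sc` (*S. cerevisiae*-like) and `Se` (*S. eubayanus*-like) — each with
its own per-chromosome copy number, and a uniparentally inherited
mitochondrial genome. Sequencing reads are competitively aligned to a
chimeric reference concatenating one genome per species, variants are
called per subgenome, and read depth is binned along every contig.
`hybridkaryo` consumes those two observables (a single-sample VCF with
`GT:AD:DP` and `INFO DP/QD/FS/MQ`, and a 4-column bedGraph) and infers
subgenome content, mitotype, karyotype, ploidy and parental origin.
Everything upstream — alignment, duplicate marking, the caller itself —
is out of scope; the package starts at the VCF/bedGraph interface.

## Site filtering and allele frequency

Sites are hard-filtered with strict inequalities: DP > 40, QD > 2,
FS < 60, MQ > 40 (all configurable). Records missing any of the four
annotations are removed by default ("fail closed"); a permissive switch
keeps them, for VCFs from callers that do not emit GATK-style
annotations. Multi-allelic records are kept whole: the per-site
alternate allele frequency is the read fraction of the *most abundant*
alternate, `f = max_alt AD_alt / sum(AD)`, with ties broken toward the
lower allele index. The denominator is `sum(AD)` rather than `DP`
because `DP` may count reads assigned to no allele. Indels pass through
filtering but are excluded from AF/copy-number inference (their allele
depths are less reliable and SNPs fully exercise the frequency logic).

## Subgenome content and mitotype

The covered proportion of a subgenome is the length-weighted fraction
of its nuclear positions lying in bins with mean depth ≥ 1 read (the
cutoff is configurable; 1 read is the most literal reading of "covered").
The mapping ratio is `prop_Se / prop_Sc`; a pure-Se sample with
`prop_Sc = 0` yields a flagged infinite ratio, and a track with no
coverage at all is an error. Covered length is also reported in Mb; it
deliberately stands in for assembly-based genome length, and the column
is named `covered_*_mb` to avoid conflation.

Mitochondria are effectively uniparental, so mitotype is called by
coverage dominance: `Sc` if the Sc mitochondrial contig is covered at
least 5× more deeply than the Se one, `Se` for the converse, otherwise
`ambiguous`. The 5-fold default is conservative — in simulated and real
hybrids the dominance is typically orders of magnitude — and both-zero
coverage returns `ambiguous` with a warning rather than an error.

## Per-copy depth and copy number

The depth contributed by a single chromosome copy, `u`, is estimated
genome-wide by maximizing a quantization score over candidate units
`u ∈ [max_depth/8, max_depth]` (grid of 2000, locally refined):

    score(u) = mean over nonzero bins of exp(−(d/u − round(d/u))² / 2σ²)

with σ = 0.15 and `round(d/u)` clipped to [1, 8]. Any integer divisor
of the true unit ties this score, so near-ties (within 0.01) are broken
toward the **larger** unit — the fewest-copies interpretation; a genome
whose bins sit at a single depth level is therefore read as copy 1.
The copy ceiling of 8 is beyond observed whole-chromosome biology and
prevents degenerate small-`u` solutions. The known limitation of this
tie-break: a genome in which *every* chromosome has an even copy number
(e.g. a clean 2:2 tetraploid with no aneuploidy) is depth-compatible
with half its true ploidy; external ploidy evidence (flow cytometry) is
the usual disambiguation and is out of scope here.

Per chromosome, the modal bin depth is the median depth among bins of
the most common quantized copy state, and the depth-implied copy number
is `c = round(modal_depth / u)`, clipped to [0, 8]; an all-zero
chromosome is a full deletion (c = 0).

The AF peak profile of each chromosome is computed from a histogram of
per-site frequencies (bin width 0.02 on (0, 1], smoothed with a 3-bin
moving average); local maxima carrying ≥ 10% of the chromosome's sites
are peaks, and the canonical set {1}, {1/2}, {1/3, 2/3} or
{1/4, 1/2, 3/4} matching every peak within ±0.05 at the smallest total
distance is reported (ties go to the smaller set; fewer than 20 sites,
or no match, yields none). The canonical sets imply copy candidates
({1/2} → {2, 4}; {1/3, 2/3} → {3, 6}; {1/4, 1/2, 3/4} → {4}; {1} is
compatible with any copy number, since homozygosity is uninformative).
**Depth takes precedence**: the final call is always the depth-implied
`c`; the AF profile only sets an agreement flag, and a disagreement
demotes confidence to `low` — signals are never silently averaged.

The modal copy number per subgenome (ties toward the smaller value)
gives the karyotype ratio string ("3:1"), ploidy = modal Sc + modal Se
(reported as "4N"), duplications (chromosomes above their subgenome
modal) and deletions (below; c = 0 is a full deletion).

## Parental tracing

Private homozygous SNPs — GT 1/1 in one parent, homozygous-reference or
absent in the other, heterozygous and shared-alternate sites excluded —
are pooled from both parents. At such a marker the two parents'
haplotypes carry complementary alleles, so one hybrid site informs both
parents: the owner's frequency is the marker-allele read fraction and
the other parent's is the complementary fraction. A covered marker
position (bin depth ≥ 1) with no hybrid variant call is evidence of
non-inheritance and contributes frequency 0 for the owning parent;
dropping such sites instead would bias medians upward. Uncovered
positions are dropped.

Chromosome-wide medians per parent (≥ 20 informative sites, else
`undetermined`) are converted to integer contributions using the
chromosome's copy number `c` from the karyotype step:
`k_A` minimizes `|k_A − m_A·c| + |(c − k_A) − m_B·c|`, which guarantees
`k_A + k_B = c`; ties go to the parent with more informative sites. A
median deviating more than 0.15 from the nearest `k/c` sets confidence
`low` (copy-number variation within the chromosome and aggregation can
shift medians without invalidating the integer call). Chromosomes are
traced whole; sub-chromosomal (recombinant) origin is not modelled.

## The simulator

The simulator works at the variant/pileup level — allele depths and bin
means are drawn directly, read alignment is not emulated — because the
inference under test starts at the VCF/bedGraph interface.

- **References**: `n` chromosomes per subgenome (Sc named with Roman
  numerals, Se with Arabic ones) plus one mitochondrial contig each;
  the Se copy of each chromosome differs from its Sc partner at exactly
  `round(divergence × length)` recorded positions. Default desk-scale
  geometry in tests: 4–8 chromosomes of 50 kb per subgenome (a scaled
  stand-in for the ~12.5 Mb, 16-chromosome genomes), divergence 0.05.
- **Parents**: heterozygous sites (GT 0/1, only on subgenomes with ≥ 2
  copies) at 1 site/kb and private homozygous SNPs (GT 1/1) at 1–3
  sites/kb by scenario; a shared position registry guarantees private
  sites are never reused across parents in a run, and planted positions
  avoid the recorded inter-subgenome divergence.
- **Mating**: a karyotype spec lists, per chromosome, the exact
  parental haplotypes inherited (the list length *is* the copy number;
  empty = deletion). Per-site true alternate copies are counted over
  the inherited haplotypes; contributions per chromosome are haplotype
  counts per parent.
- **Observation**: per site `DP ~ Poisson(u·c)` and alternate reads
  `~ Binomial(DP, f(1−e) + (1−f)e)` with symmetric base-error leakage
  `e = 0.002`; per bin, mean depth `~ Normal(u·c, sqrt(u·c)/sqrt(w/150))`
  truncated at 0 (a bin of width `w` aggregates ~`w/150` read
  placements); the true mitotype's contig is covered at
  `u × mito_depth_multiplier` (default 20), the other only at error
  leakage. Defaults: per-copy depth 50, 10 kb bins. Identical seeds
  give byte-identical FASTA/VCF/bedGraph outputs.

What the simulator does **not** reproduce: cross-subgenome read
mis-mapping (real competitive mapping leaks a few percent of reads
between diverged subgenomes, which is why a pure *S. cerevisiae* strain
shows a small but nonzero Se mapping ratio on real data), indels, GC
and mappability bias in depth, and within-chromosome recombination/LOH
tracts. Passing recovery tests therefore demonstrate correctness of
the inference under the stated noise model, not robustness to
alignment artefacts.

## Numerical and design choices

- One global seed per simulation run; per-stream generators derive from
  it via seed sequences, so outputs are reproducible bit-for-bit.
- Degenerate inputs: empty depth tracks, all-zero chromosomes,
  `sum(AD) = 0` sites and both-mitochondria-uncovered tracks all have
  defined behaviour (error, deletion call, undefined-frequency error,
  `ambiguous`) rather than NaNs.
- Desk-scale problem sizes throughout the test suite (50 kb
  chromosomes, 500-site regions, 20-hybrid recovery batches) keep the
  full suite under a minute while leaving every statistical check with
  comfortable power; all sizes are plain function arguments.
- The package is organised around `HybridGenomeModel.fit() →
  HybridGenomeResults` (statsmodels-style): the model object holds the
  data, the results object holds estimates, evidence and `summary()`;
  the module-level functions remain the primitive API and the CLI is a
  thin wrapper over the pipeline driver.

## Known limitations

- Whole-chromosome resolution only: segmental CNVs appear as modal-copy
  disagreements or low-confidence flags, not as named events.
- The even-karyotype depth degeneracy described above.
- Mapping ratios on real data depend on cross-mapping behaviour the
  simulator does not model; thresholds tuned on simulations (e.g. the
  pure-strain ratio < 0.05 check) are stricter than what real
  competitive mapping produces.
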