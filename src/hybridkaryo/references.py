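"""Chimeric two-subgenome reference construction.

Interspecies hybrids are analysed by competitive mapping: reads are aligned
to a single reference that concatenates one genome per parental species
(here the two subgenomes are labelled ``Sc`` for the *S. cerevisiae*-like
and ``Se`` for the *S. eubayanus*-like one), so each read settles on the
subgenome it matches best.  This module builds desk-scale chimeric
references with a controlled, recorded divergence between the two
subgenomes, plus one mitochondrial contig per subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBGENOMES = ("Sc", "Se")

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def chrom_name(subgenome: str, index: int) -> str:
    """Contig name for the ``index``-th (0-based) chromosome of a subgenome.

    Sc chromosomes use Roman numerals (``Sc_chrI``), Se chromosomes Arabic
    numerals (``Se_chr1``), the convention used for lager-hybrid karyotype
    reports.
    """
    if subgenome == "Sc":
        return f"Sc_chr{_ROMAN[index]}"
    return f"Se_chr{index + 1}"


def mito_name(subgenome: str) -> str:
    return f"{subgenome}_mito"


def subgenome_of(contig: str) -> str | None:
    """Subgenome prefix of a contig name, or None for unknown contigs."""
    prefix = contig.split("_", 1)[0]
    return prefix if prefix in SUBGENOMES else None


def is_mito(contig: str) -> bool:
    return contig.endswith("_mito")


@dataclass
class ReferencePair:
    """A chimeric two-subgenome reference with recorded divergence.

    chromosomes : dict mapping contig name -> length (bp), nuclear only,
        covering both subgenomes; names are unique by construction.
    mito : dict mapping subgenome -> (contig name, length).
    divergence : fraction of positions at which each Se chromosome differs
        from its Sc partner, in (0, 0.5].
    sequences : contig name -> bases (bytes of ACGT).
    divergent_positions : Se contig name -> sorted 0-based positions where
        it differs from the partner Sc contig.
    """

    chromosomes: dict[str, int]
    mito: dict[str, tuple[str, int]]
    divergence: float
    sequences: dict[str, bytes] = field(default_factory=dict, repr=False)
    divergent_positions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def contigs_of(self, subgenome: str, include_mito: bool = False) -> list[str]:
        names = [c for c in self.chromosomes if subgenome_of(c) == subgenome]
        if include_mito:
            names.append(self.mito[subgenome][0])
        return names

    @property
    def all_lengths(self) -> dict[str, int]:
        out = dict(self.chromosomes)
        for name, length in self.mito.values():
            out[name] = length
        return out

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[name].decode()), id=name, description="")
            for name in self.all_lengths
        ]
        SeqIO.write(records, str(path), "fasta")


def build_references(
    n_chroms_per_subgenome: int,
    chrom_length: int,
    divergence: float,
    seed: int,
    mito_length: int = 20_000,
) -> ReferencePair:
    """Build a chimeric Sc+Se reference with fixed inter-subgenome divergence.

    Each Se chromosome is the corresponding Sc chromosome with exactly
    ``round(divergence * chrom_length)`` positions substituted to a
    different base; the substituted positions are recorded.  The two
    mitochondrial contigs diverge the same way.

    Parameters
    ----------
    n_chroms_per_subgenome : number of nuclear chromosomes per subgenome.
    chrom_length : chromosome length in bp (>= 10 kb).
    divergence : substitution fraction in (0, 0.5].
    seed : RNG seed; identical seeds give identical references.
    """
    if n_chroms_per_subgenome < 1:
        raise ValueError("need at least one chromosome per subgenome")
    if n_chroms_per_subgenome > len(_ROMAN):
        raise ValueError(f"at most {len(_ROMAN)} chromosomes per subgenome")
    if chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if not 0.0 < divergence <= 0.5:
        raise ValueError("divergence must lie in (0, 0.5]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chromosomes: dict[str, int] = {}
    sequences: dict[str, bytes] = {}
    divergent: dict[str, np.ndarray] = {}

    def _diverge(template: np.ndarray, n_sub: int) -> tuple[bytes, np.ndarray]:
        pos = np.sort(rng.choice(template.size, size=n_sub, replace=False))
        seq = template.copy()
        # shift each substituted base by 1-3 in ACGT order: always different
        idx = np.searchsorted(_BASES, seq[pos])
        seq[pos] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
        return seq.tobytes(), pos

    for i in range(n_chroms_per_subgenome):
        sc = chrom_name("Sc", i)
        se = chrom_name("Se", i)
        template = rng.choice(_BASES, size=chrom_length)
        sequences[sc] = template.tobytes()
        n_sub = round(divergence * chrom_length)
        sequences[se], divergent[se] = _diverge(template, n_sub)
        chromosomes[sc] = chrom_length
        chromosomes[se] = chrom_length

    mito: dict[str, tuple[str, int]] = {}
    template = rng.choice(_BASES, size=mito_length)
    sequences[mito_name("Sc")] = template.tobytes()
    seq, pos = _diverge(template, round(divergence * mito_length))
    sequences[mito_name("Se")] = seq
    divergent[mito_name("Se")] = pos
    mito["Sc"] = (mito_name("Sc"), mito_length)
    mito["Se"] = (mito_name("Se"), mito_length)

    return ReferencePair(
        chromosomes=chromosomes,
        mito=mito,
        divergence=divergence,
        sequences=sequences,
        divergent_positions=divergent,
    )


def read_fasta_lengths(path) -> dict[str, int]:
    """Contig name -> length for a FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
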