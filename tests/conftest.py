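"""Shared fixtures: small references, simulated parents and hybrids.

Everything is generated at test time from fixed seeds; the heavier
simulated scenario is session-scoped so the full cross is simulated and
fitted once.
"""

from __future__ import annotations

import pytest

import hybridkaryo as hk
from hybridkaryo.simulate import group3_cross_karyotype, group3_parent_specs


@pytest.fixture(scope="session")
def refs():
    """4+4 chromosomes of 50 kb, 5% inter-subgenome divergence."""
    return hk.build_references(
        n_chroms_per_subgenome=4, chrom_length=50_000, divergence=0.05, seed=11
    )


@pytest.fixture(scope="session")
def parents(refs):
    return hk.simulate_parents(group3_parent_specs(), refs, seed=11)


@pytest.fixture(scope="session")
def group3_truth(refs, parents):
    kspec = group3_cross_karyotype(refs)
    return hk.mate(parents, kspec, seed=11)


@pytest.fixture(scope="session")
def group3_observation(group3_truth, refs):
    return hk.simulate_observed(
        group3_truth, refs, per_copy_depth=50.0, bin_width=5_000, seed=11
    )


@pytest.fixture(scope="session")
def group3_results(group3_observation, parents):
    model = hk.HybridGenomeModel(
        group3_observation.sites,
        group3_observation.track,
        sample="hybrid1",
        parents={name: p.sites for name, p in parents.items()},
    )
    return model.fit()


def make_site(
    chrom="Sc_chrI",
    pos=100,
    ref="A",
    alts=("G",),
    ad=(50, 50),
    dp=None,
    qd=25.0,
    fs=1.0,
    mq=55.0,
    genotype=(0, 1),
):
    """Hand-built variant site with passing annotations by default."""
    return hk.VariantSite(
        subgenome="Sc" if chrom.startswith("Sc") else "Se",
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        ad=tuple(ad),
        dp=sum(ad) if dp is None else dp,
        qd=qd,
        fs=fs,
        mq=mq,
        genotype=genotype,
    )
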