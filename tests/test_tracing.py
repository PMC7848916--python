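"""Parental tracing: private markers, parental AF, contribution assignment."""

import numpy as np
import pandas as pd
import pytest

import hybridkaryo as hk
from hybridkaryo.depth import as_track
from hybridkaryo.simulate import KaryotypeSpec, ParentSpec
from hybridkaryo.tracing import assign_contributions, private_homozygous_snps

from conftest import make_site


def _hom_alt(chrom, pos, ref="A", alt="G"):
    return make_site(chrom=chrom, pos=pos, ref=ref, alts=(alt,), ad=(0, 90),
                     genotype=(1, 1))


def _hom_ref(chrom, pos):
    return make_site(chrom=chrom, pos=pos, ad=(90, 1), genotype=(0, 0))


def _het(chrom, pos):
    return make_site(chrom=chrom, pos=pos, ad=(45, 45), genotype=(0, 1))


class TestPrivateMarkers:
    def test_hom_alt_vs_absent_is_a_marker(self):
        markers = private_homozygous_snps([_hom_alt("Sc_chrI", 10)], [], "A", "B")
        assert len(markers) == 1
        m = markers[0]
        assert m.owner == "A" and m.parental_allele == "G" and m.other_allele == "A"

    def test_hom_alt_vs_hom_ref_is_a_marker_both_directions(self):
        a = [_hom_alt("Sc_chrI", 10)]
        b = [_hom_ref("Sc_chrI", 10), _hom_alt("Sc_chrI", 30)]
        markers = private_homozygous_snps(a, b, "A", "B")
        owners = {m.pos: m.owner for m in markers}
        assert owners == {10: "A", 30: "B"}

    def test_heterozygous_site_excluded(self):
        markers = private_homozygous_snps([_het("Sc_chrI", 10)], [], "A", "B")
        assert markers == []

    def test_shared_hom_alt_excluded(self):
        a = [_hom_alt("Sc_chrI", 10)]
        b = [_hom_alt("Sc_chrI", 10)]
        assert private_homozygous_snps(a, b, "A", "B") == []

    def test_hom_alt_against_het_excluded(self):
        a = [_hom_alt("Sc_chrI", 10)]
        b = [_het("Sc_chrI", 10)]
        assert private_homozygous_snps(a, b, "A", "B") == []


class TestParentalAlleleFrequency:
    def test_marker_frequencies_are_complementary(self):
        markers = private_homozygous_snps([_hom_alt("Sc_chrI", 10)], [], "A", "B")
        hybrid = [make_site(chrom="Sc_chrI", pos=10, ref="A", alts=("G",),
                            ad=(66, 33), genotype=(0, 1))]
        freqs = hk.parental_allele_frequency(markers, hybrid)
        by_parent = {row.parent: row.freq for row in freqs.itertuples()}
        assert by_parent["A"] == pytest.approx(1 / 3)
        assert by_parent[None] == pytest.approx(2 / 3)  # other-parent row

    def test_hybrid_homozygous_for_marker(self):
        markers = private_homozygous_snps([_hom_alt("Sc_chrI", 10)], [], "A", "B")
        hybrid = [make_site(chrom="Sc_chrI", pos=10, ref="A", alts=("G",),
                            ad=(0, 100), genotype=(1, 1))]
        freqs = hk.parental_allele_frequency(markers, hybrid)
        assert freqs[freqs["parent"] == "A"]["freq"].iloc[0] == 1.0

    def test_covered_absent_marker_contributes_zero_for_owner_only(self):
        markers = private_homozygous_snps([_hom_alt("Sc_chrI", 10)], [], "A", "B")
        track = as_track(pd.DataFrame([("Sc_chrI", 0, 1000, 80.0)],
                                      columns=["chrom", "start", "end", "depth"]))
        freqs = hk.parental_allele_frequency(markers, [], track=track)
        assert len(freqs) == 1
        assert freqs.iloc[0]["parent"] == "A" and freqs.iloc[0]["freq"] == 0.0

    def test_uncovered_absent_marker_dropped(self):
        markers = private_homozygous_snps([_hom_alt("Sc_chrI", 10)], [], "A", "B")
        track = as_track(pd.DataFrame([("Sc_chrI", 0, 1000, 0.2)],
                                      columns=["chrom", "start", "end", "depth"]))
        freqs = hk.parental_allele_frequency(markers, [], track=track)
        assert freqs.empty


class TestChromosomeMedian:
    def test_median_of_frequencies(self):
        df = pd.DataFrame(
            {"subgenome": "Sc", "chrom": "Sc_chrI", "pos": [1, 2, 3],
             "parent": "A", "freq": [0.3, 0.33, 0.35]}
        )
        out = hk.chromosome_median_frequency(df, min_sites=3)
        assert out["median_af"].iloc[0] == pytest.approx(0.33)
        assert out["status"].iloc[0] == "determined"

    def test_below_min_sites_is_undetermined(self):
        df = pd.DataFrame(
            {"subgenome": "Sc", "chrom": "Sc_chrI", "pos": range(5),
             "parent": "A", "freq": [0.5] * 5}
        )
        out = hk.chromosome_median_frequency(df, min_sites=20)
        assert out["status"].iloc[0] == "undetermined"


class TestAssignContributions:
    def test_one_of_three_and_two_of_three(self):
        c = assign_contributions({"A": 0.33, "B": 0.66}, {"A": 50, "B": 50}, 3,
                                 "Sc_chrI", "A", "B")
        assert c.contributions == {"A": 1, "B": 2}
        assert c.confidence == "high"

    def test_even_split(self):
        c = assign_contributions({"A": 0.5}, {"A": 40}, 2, "Sc_chrI", "A", "B")
        assert c.contributions == {"A": 1, "B": 1}

    def test_uniparental_chromosome(self):
        c = assign_contributions({"A": 1.0, "B": 0.0}, {"A": 30, "B": 25}, 1,
                                 "Se_chr1", "A", "B")
        assert c.contributions == {"A": 1, "B": 0}

    def test_contributions_always_sum_to_copy_number(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            copies = int(rng.integers(0, 7))
            m_a, m_b = rng.uniform(0, 1, size=2)
            c = assign_contributions({"A": m_a, "B": m_b},
                                     {"A": 30, "B": 30}, copies, "Sc_chrI", "A", "B")
            assert sum(c.contributions.values()) == copies

    def test_symmetry_under_parent_swap(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            copies = int(rng.integers(1, 6))
            m_a, m_b = rng.uniform(0, 1, size=2)
            # distinct site counts so the more-informative-parent tie rule
            # has a unique answer under relabelling
            n_a = int(rng.integers(20, 60))
            n_b = n_a + int(rng.integers(1, 10)) * (1 if rng.random() < 0.5 else -1)
            fwd = assign_contributions({"A": m_a, "B": m_b}, {"A": n_a, "B": n_b},
                                       copies, "Sc_chrI", "A", "B")
            rev = assign_contributions({"B": m_b, "A": m_a}, {"B": n_b, "A": n_a},
                                       copies, "Sc_chrI", "B", "A")
            assert fwd.contributions["A"] == rev.contributions["A"]
            assert fwd.contributions["B"] == rev.contributions["B"]

    def test_deleted_chromosome_with_signal_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            c = assign_contributions({"A": 0.4, "B": 0.6}, {"A": 30, "B": 30}, 0,
                                     "Se_chr3", "A", "B")
        assert c.contributions == {"A": 0, "B": 0}
        assert any("deleted" in r.message for r in caplog.records)

    def test_large_deviation_lowers_confidence(self):
        c = assign_contributions({"A": 0.5}, {"A": 40}, 1, "Sc_chrI", "A", "B")
        assert c.confidence == "low"  # 0.5 is 0.5 away from both 0/1 and 1/1


class TestEndToEndTracing:
    def test_noiseless_contributions_equal_truth(self, refs, parents, group3_truth):
        # noiseless: build hybrid sites straight from the truth fractions
        sites = []
        for chrom, truth_sites in group3_truth.sites.items():
            c = group3_truth.karyotype.copy_number(chrom)
            for ts in truth_sites:
                if ts.alt_copies == 0:
                    continue
                ad_alt = 60 * ts.alt_copies
                sites.append(make_site(
                    chrom=chrom, pos=ts.pos, ref=ts.ref, alts=(ts.alt,),
                    ad=(60 * (c - ts.alt_copies), ad_alt),
                    genotype=(1, 1) if ts.alt_copies == c else (0, 1)))
        (name_a, pa), (name_b, pb) = parents.items()
        contribs = hk.trace_parental_origin(
            pa.sites, pb.sites, name_a, name_b, hybrid_sites=sites,
            copy_numbers=group3_truth.copy_numbers(), min_sites=10,
        )
        for contrib in contribs:
            assert contrib.contributions == group3_truth.contributions[contrib.chrom]

    def test_stochastic_recovery_matches_truth(self, group3_results, group3_truth):
        for contrib in group3_results.contributions:
            assert contrib.contributions == group3_truth.contributions[contrib.chrom], (
                contrib.chrom
            )

    def test_median_frequency_recovery_two_of_three(self, refs):
        # parent B contributes 2 of 3 copies: median parental AF ~ 2/3
        specs = [
            ParentSpec("A", {"Sc": 2}, het_density=0.5, private_density=3.0),
            ParentSpec("B", {"Sc": 2}, het_density=0.5, private_density=3.0),
        ]
        both = hk.simulate_parents(specs, refs, seed=77)
        haplotypes = {c: [] for c in refs.chromosomes}
        haplotypes["Sc_chrI"] = [("A", 0), ("B", 0), ("B", 1)]
        truth = hk.mate(both, KaryotypeSpec(haplotypes, "Sc"), seed=77)
        obs = hk.simulate_observed(truth, refs, per_copy_depth=100.0 / 3,
                                   bin_width=5_000, seed=77)
        markers = private_homozygous_snps(both["A"].sites, both["B"].sites, "A", "B")
        assert sum(1 for m in markers if m.chrom == "Sc_chrI") >= 200
        freqs = hk.parental_allele_frequency(markers, obs.sites, obs.track)
        from hybridkaryo.tracing import _fill_other_parent

        freqs = _fill_other_parent(freqs, "A", "B")
        medians = hk.chromosome_median_frequency(freqs, min_sites=20)
        sel = medians[medians["chrom"] == "Sc_chrI"].set_index("parent")
        assert sel.loc["A", "median_af"] == pytest.approx(1 / 3, abs=0.03)
        assert sel.loc["B", "median_af"] == pytest.approx(2 / 3, abs=0.03)
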