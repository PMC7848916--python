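"""Copy-number inference: per-copy depth unit, AF peaks, karyotype calls."""

import numpy as np
import pytest

import hybridkaryo as hk
from hybridkaryo.karyotype import (
    CopyNumberCall,
    af_peak_profile,
    call_karyotype,
    estimate_per_copy_depth,
    infer_copy_number,
    modal_bin_depth,
    quantization_score,
    scaled_depth,
)
from hybridkaryo.simulate import simulate_region_sites

from conftest import make_site


def _call(chrom, copies, sub=None):
    return CopyNumberCall(
        subgenome=sub or ("Sc" if chrom.startswith("Sc") else "Se"),
        chrom=chrom, copies=copies, modal_depth=50.0 * copies, unit=50.0,
        profile=None, agreement=True, confidence="high",
    )


class TestPerCopyDepth:
    def test_uniform_depths_prefer_single_copy(self):
        # tie-break toward the larger unit: all-equal depths mean copy 1
        assert estimate_per_copy_depth([100.0] * 40) == pytest.approx(100.0)

    def test_noiseless_mixture_recovers_unit(self):
        # depths {50, 100, 150} in proportions {1/4, 1/2, 1/4}
        depths = np.array([50.0] * 25 + [100.0] * 50 + [150.0] * 25)
        u = estimate_per_copy_depth(depths)
        assert u == pytest.approx(50.0, rel=0.02)
        # independent brute-force oracle over an explicit candidate grid
        cand = np.linspace(150 / 8, 150, 4001)
        scores = []
        for c in cand:
            m = np.clip(np.round(depths / c), 1, 8)
            scores.append(np.exp(-((depths / c - m) ** 2) / (2 * 0.15**2)).mean())
        scores = np.array(scores)
        near_best = cand[scores >= scores.max() - 1e-9]
        assert near_best.max() == pytest.approx(50.0, rel=0.02)

    def test_recovery_under_poisson_noise(self):
        rng = np.random.default_rng(17)
        copies = rng.choice([1, 2, 3], size=500, p=[0.3, 0.5, 0.2])
        depths = rng.poisson(50.0 * copies)  # per-bin noise upper bound
        u = estimate_per_copy_depth(depths[depths > 0].astype(float))
        assert 45.0 <= u <= 55.0

    def test_no_signal_is_an_error(self):
        with pytest.raises(ValueError, match="no bins"):
            estimate_per_copy_depth([0.0, 0.0])

    def test_monotonicity_under_depth_doubling(self):
        rng = np.random.default_rng(3)
        depths = rng.poisson(50.0 * rng.choice([1, 2, 3], size=300)).astype(float)
        depths = depths[depths > 0]
        u1 = estimate_per_copy_depth(depths)
        u2 = estimate_per_copy_depth(2 * depths)
        assert u2 == pytest.approx(2 * u1, rel=0.01)
        c1 = np.round(depths / u1)
        c2 = np.round(2 * depths / u2)
        assert np.array_equal(c1, c2)

    def test_score_is_perfect_on_exact_multiples(self):
        assert quantization_score([50, 100, 150], 50.0) == pytest.approx(1.0)


class TestScaledDepth:
    def test_all_equal_maps_to_one(self):
        assert np.allclose(scaled_depth([70.0] * 10), 1.0)

    def test_linear_scaling(self):
        out = scaled_depth([0.0, 50.0, 100.0], robust_quantile=1.0)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_outlier_clipped(self):
        depths = [50.0] * 200 + [500.0]
        out = scaled_depth(depths)
        assert out[-1] == 1.0
        assert np.allclose(out[:-1], 1.0)  # robust max ~50, others unaffected


class TestAFPeakProfile:
    @pytest.mark.parametrize(
        "alt, total, expected",
        [(1, 2, (0.5,)), (1, 3, (1 / 3, 2 / 3)), (1, 4, (0.25, 0.5, 0.75)),
         (2, 2, (1.0,))],
    )
    def test_canonical_set_recovered(self, alt, total, expected):
        sites = simulate_region_sites(500, alt, total, 100.0 / total, seed=5)
        profile = af_peak_profile(sites, region="r")
        assert profile.canonical == pytest.approx(expected)

    def test_too_few_sites_gives_none(self):
        sites = simulate_region_sites(10, 1, 2, 50.0, seed=5)
        profile = af_peak_profile(sites, region="r")
        assert profile.canonical is None and profile.n_sites == 10

    def test_detected_peak_near_true_fraction(self):
        sites = simulate_region_sites(500, 1, 2, 50.0, seed=8)
        profile = af_peak_profile(sites)
        assert len(profile.peaks) == 1
        assert profile.peaks[0] == pytest.approx(0.5, abs=0.02)


class TestInferCopyNumber:
    @pytest.mark.parametrize(
        "canonical, modal_mult, expected_c, expected_agree",
        [
            ((0.5,), 2, 2, True),
            ((1.0,), 1, 1, True),
            ((0.5,), 4, 4, True),  # 0.5 peak is also consistent with 2+2 of 4
            ((1 / 3, 2 / 3), 3, 3, True),
            ((1 / 3, 2 / 3), 2, 2, False),  # depth wins, flagged
            ((1.0,), 5, 5, True),  # homozygous profile fits any copy number
        ],
    )
    def test_depth_precedence_and_agreement(self, canonical, modal_mult, expected_c,
                                            expected_agree):
        profile = hk.AFPeakProfile(region="Sc_chrI", peaks=canonical,
                                   canonical=canonical, n_sites=100)
        call = infer_copy_number(profile, modal_depth=50.0 * modal_mult, unit=50.0,
                                 chrom="Sc_chrI")
        assert call.copies == expected_c
        assert call.agreement is expected_agree
        assert call.confidence == ("high" if expected_agree else "low")

    def test_zero_depth_chromosome_is_a_deletion(self):
        call = infer_copy_number(None, modal_depth=0.0, unit=50.0, chrom="Se_chr3")
        assert call.copies == 0

    def test_noiseless_oracle_equivalence_all_copy_numbers(self):
        # exact depths c*u and exact AF fractions recover every c in 0..6
        u = 50.0
        for c in range(0, 7):
            depths = np.full(30, c * u)
            modal = modal_bin_depth(depths, u)
            if c == 0:
                sites = []
            else:
                ad_alt = 120 // c
                sites = [
                    make_site(pos=p, ad=(120 - ad_alt, ad_alt))
                    for p in range(1, 41)
                ]
            profile = af_peak_profile(sites, region="x")
            call = infer_copy_number(profile, modal, u, chrom="Sc_chrI")
            assert call.copies == c, f"copy {c} not recovered"


class TestCallKaryotype:
    def test_group3_pattern(self):
        # Sc all 3, Se all 1 except Se_chr3 deleted -> 3:1, 4N
        calls = [_call(f"Sc_chr{r}", 3) for r in ["I", "II", "III", "IV"]]
        calls += [_call(f"Se_chr{i}", 0 if i == 3 else 1) for i in range(1, 5)]
        result = call_karyotype(calls)
        assert result.ratio == "3:1"
        assert result.ploidy == 4 and result.ploidy_string == "4N"
        assert result.deletions["Se"] == ["Se_chr3"]
        assert result.duplications == {"Sc": [], "Se": []}

    def test_group2_pattern_no_events(self):
        calls = [_call(f"Sc_chr{r}", 2) for r in ["I", "II"]]
        calls += [_call(f"Se_chr{i}", 2) for i in (1, 2)]
        result = call_karyotype(calls)
        assert result.ratio == "2:2" and result.ploidy_string == "4N"
        assert not any(result.duplications.values())
        assert not any(result.deletions.values())

    def test_duplication_above_modal(self):
        calls = [_call(f"Sc_chr{r}", 3) for r in ["I", "II", "III"]]
        calls.append(_call("Sc_chrIX", 4))
        result = call_karyotype(calls)
        assert result.duplications["Sc"] == ["Sc_chrIX"]

    def test_modal_tie_broken_toward_smaller(self):
        calls = [_call("Sc_chrI", 2), _call("Sc_chrII", 3),
                 _call("Sc_chrIII", 2), _call("Sc_chrIV", 3)]
        result = call_karyotype(calls)
        assert result.modal["Sc"] == 2

    def test_duplicate_chromosome_rejected(self):
        with pytest.raises(ValueError, match="multiple calls"):
            call_karyotype([_call("Sc_chrI", 2), _call("Sc_chrI", 3)])

    def test_ploidy_consistency(self, group3_results):
        k = group3_results.karyotype
        assert k.ploidy == k.modal["Sc"] + k.modal["Se"]


class TestRecoveryOnSimulatedHybrids:
    def test_copy_calls_match_truth_across_random_karyotypes(self, refs, parents):
        # 20 random whole-chromosome karyotypes; >= 95% of copy calls must
        # match and every engineered deletion must be found
        total = matched = 0
        deletions_found = deletions_total = 0
        for i in range(20):
            kspec = hk.simulate.random_karyotype(refs, parents, seed=300 + i)
            truth = hk.mate(parents, kspec, seed=300 + i)
            obs = hk.simulate_observed(truth, refs, per_copy_depth=50.0,
                                       bin_width=5_000, seed=300 + i)
            model = hk.HybridGenomeModel(obs.sites, obs.track, sample=f"h{i}")
            res = model.fit()
            called = res.copy_numbers()
            for chrom, true_c in truth.copy_numbers().items():
                total += 1
                matched += called[chrom] == true_c
                if true_c == 0:
                    deletions_total += 1
                    deletions_found += called[chrom] == 0
        assert matched / total >= 0.95
        assert deletions_found == deletions_total
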