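"""GIS banding, variant filtering, concordance and survival statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recaplab import hr_integration as hri


class TestGisBanding:
    @pytest.mark.parametrize("score, band", [
        (0.10, "HRP"),
        (0.2299, "HRP"),
        (0.23, "HRDmid"),
        (0.48, "HRDmid"),
        (0.73, "HRDmid"),
        (0.7300001, "HRD"),
        (0.95, "HRD"),
    ])
    def test_band_edges(self, score, band):
        assert hri.classify_gis(score) == band

    def test_band_edges_derive_from_threshold_and_margin(self):
        assert hri.classify_gis(0.48 - 0.25) == "HRDmid"
        assert hri.classify_gis(0.48 + 0.25) == "HRDmid"
        assert hri.classify_gis(np.nextafter(0.48 - 0.25, 0)) == "HRP"
        assert hri.classify_gis(np.nextafter(0.48 + 0.25, 1)) == "HRD"

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                hri.classify_gis(bad)

    def test_monotone_in_score(self, rng):
        order = {"HRP": 0, "HRDmid": 1, "HRD": 2}
        scores = np.sort(rng.uniform(0, 1, 50))
        bands = [order[hri.classify_gis(s)] for s in scores]
        assert (np.diff(bands) >= 0).all()

    def test_binary_call_at_threshold(self):
        assert hri.gis_binary(0.48) == "HRD"
        assert hri.gis_binary(0.4799) == "HRP"


class TestVariantFilter:
    TOY = pd.DataFrame({
        "gene": ["BRCA1", "BRCA2", "TP53", "ATM", "PALB2", "CHEK2"],
        "vaf": [0.05, 0.049, 0.40, 0.30, 0.80, 0.02],
        "oncogenic": [True, True, False, False, True, False],
        "inactivating": [False, False, False, True, True, False],
    })

    def test_exact_rule_on_toy_table(self):
        out = hri.filter_variants(self.TOY)
        assert out.kept.tolist() == [True, False, False, True, True, False]
        assert set(out[out.kept].gene) == {"BRCA1", "ATM", "PALB2"}

    def test_boundary_vaf_inclusive(self):
        row = pd.DataFrame({"gene": ["g"], "vaf": [0.05],
                            "oncogenic": [True], "inactivating": [False]})
        assert hri.filter_variants(row).kept.all()

    def test_idempotent_and_order_independent(self):
        once = hri.filter_variants(self.TOY)
        twice = hri.filter_variants(once[once.columns[:4]])
        assert once.kept.tolist() == twice.kept.tolist()
        shuffled = hri.filter_variants(self.TOY.iloc[::-1])
        assert shuffled.kept.tolist() == once.kept.tolist()[::-1]

    def test_drop_reasons_populated(self):
        out = hri.filter_variants(self.TOY)
        assert (out.loc[~out.kept, "drop_reason"] != "").all()
        assert (out.loc[out.kept, "drop_reason"] == "").all()


class TestConcordance:
    def test_identical_calls_have_empty_off_diagonal(self):
        calls = {f"m{i}": ("HRD" if i % 2 else "HRP") for i in range(8)}
        table, reclassified = hri.concordance_table(calls, calls)
        assert reclassified == []
        off = table.to_numpy().sum() - np.trace(
            table.loc[["HRD", "HRP"], ["HRD", "HRP"]].to_numpy())
        assert off == 0

    def test_planted_discordant_models_listed(self):
        gis = {f"m{i:02d}": "HRP" for i in range(21)}
        recap = dict(gis)
        for m in ("m03", "m07", "m11"):
            recap[m] = "HRD"
        _, reclassified = hri.concordance_table(recap, gis)
        assert reclassified == ["m03", "m07", "m11"]

    def test_disjoint_ids_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            hri.concordance_table({"a": "HRD"}, {"b": "HRP"})


class TestKaplanMeier:
    def test_single_event_median(self):
        km = hri.km_estimate([5.0], [True])
        assert km.median == 5.0

    def test_uncensored_median_by_hand(self):
        km = hri.km_estimate(np.arange(1.0, 10.0), np.ones(9, bool))
        assert km.median == 5.0          # S(5) = 4/9 <= 0.5

    def test_uncensored_km_equals_empirical_survivor(self, rng):
        t = rng.exponential(10, 40)
        km = hri.km_estimate(t, np.ones(40, bool))
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx((t > ti).mean())

    def test_all_censored_median_undefined(self):
        km = hri.km_estimate([3.0, 4.0, 9.0], [False, False, False])
        assert km.median is None


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 5.0, 8.0]
        e = [True] * 4
        stat, p = hri.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_o_minus_e(self):
        """Two groups, events at 1,2 (A) and 3,4 (B), no censoring."""
        a, b = [1.0, 2.0], [3.0, 4.0]
        # hand O-E for A over event times 1,2,3,4:
        # t=1: O=1 E=2/4; t=2: O=1 E=1/3; t=3: O=0 E=0; t=4: O=0 E=0
        oe = (1 - 2 / 4) + (1 - 1 / 3)
        # variances: t=1: (2*2*1*3)/(16*3)=0.25; t=2: (1*2*1*2)/(9*2)=2/9
        var = 0.25 + 2 / 9
        stat, _ = hri.logrank_test(a, [True] * 2, b, [True] * 2)
        assert stat == pytest.approx(oe ** 2 / var)

    def test_label_swap_symmetry(self, rng):
        a = rng.exponential(5, 12)
        b = rng.exponential(9, 10)
        ea, eb = np.ones(12, bool), np.ones(10, bool)
        _, p1 = hri.logrank_test(a, ea, b, eb)
        _, p2 = hri.logrank_test(b, eb, a, ea)
        assert p1 == pytest.approx(p2)


class TestGehanBreslowWilcoxon:
    def test_identical_groups_null(self):
        t = [2.0, 4.0, 6.0]
        e = [True] * 3
        _, p = hri.gehan_breslow_wilcoxon(t, e, t, e)
        assert p == pytest.approx(1.0)

    def test_early_separation_weighted_above_logrank(self):
        # groups separate early then cross late
        a = [1.0, 1.5, 2.0, 9.0, 10.0]
        b = [4.0, 5.0, 6.0, 7.0, 8.0]
        ea = eb = [True] * 5
        gbw, _ = hri.gehan_breslow_wilcoxon(a, ea, b, eb)
        lr, _ = hri.logrank_test(a, ea, b, eb)
        assert gbw >= lr

    def test_weighted_oe_matches_pairwise_gehan_brute_force(self, rng):
        for _ in range(5):
            a = rng.exponential(5, 7)
            b = rng.exponential(10, 6)
            w_brute = -sum(np.sign(ai - bj) for ai in a for bj in b)
            oe = hri.gehan_weighted_oe(a, np.ones(7, bool), b, np.ones(6, bool))
            assert oe == pytest.approx(w_brute)


class TestMannWhitney:
    def test_identical_multisets_centered_u(self):
        x = [1.0, 2.0, 3.0]
        u, p = hri.mann_whitney(x, x)
        assert u == len(x) ** 2 / 2
        assert p > 0.99

    def test_complete_separation_exact_p(self):
        x = [10.0, 11.0, 12.0]
        y = [1.0, 2.0, 3.0, 4.0]
        u, p = hri.mann_whitney(x, y)
        assert u == 12
        from math import comb
        assert p == pytest.approx(2 / comb(7, 3))

    def test_exact_p_equals_label_enumeration(self, rng):
        x = rng.normal(0, 1, 3)
        y = rng.normal(1, 1, 3)
        _, p = hri.mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        obs = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").statistic
        n = len(pooled)
        mid = len(x) * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(n), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(n) if i not in idx]]
            u = sum((xi > yj) for xi in xs for yj in ys)
            count += abs(u - mid) >= abs(obs - mid) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hri.mann_whitney([], [1.0])


class TestCnvSimilarity:
    def test_identity_and_negation(self, rng):
        prof = rng.normal(0, 1, 200)
        assert hri.cnv_similarity(prof, prof) == pytest.approx(1.0)
        assert hri.cnv_similarity(prof, -prof) == pytest.approx(-1.0)

    def test_shared_segments_order_similarity(self, rng):
        base = np.repeat(rng.normal(0, 1, 20), 10)    # 20 segments x 10 bins
        mostly = base.copy()
        mostly[:40] = rng.normal(0, 1, 40)            # 80% shared
        barely = base.copy()
        barely[:160] = rng.normal(0, 1, 160)          # 20% shared
        assert hri.cnv_similarity(base, mostly) > hri.cnv_similarity(base, barely)

    def test_nan_bins_dropped_pairwise(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert hri.cnv_similarity(a, b) == pytest.approx(1.0)


class TestPlatinumRule:
    def test_six_month_boundary_inclusive(self):
        assert hri.platinum_sensitive(6.0)
        assert not hri.platinum_sensitive(5.999)
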