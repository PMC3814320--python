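"""QTL scan: HMM genotype probabilities, LOD engine, intervals, dominance."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from repeatqtl import qtl as q
from repeatqtl.simulate import QTLModel, default_map, simulate_f2
from .conftest import make_cross


def oracle_lod(y, xa, xd):
    """Independent least-squares oracle via explicit normal equations."""
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(y), xa, xd])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return (len(y) / 2.0) * np.log10(rss0 / rss1)


def chain_posterior_oracle(r1, r2, left, right):
    """Mid-locus genotype distribution given flanking F2 genotypes, by
    exhaustive enumeration of the two independent gamete chains."""
    states = list(itertools.product([0, 1], repeat=3))  # one gamete over 3 loci

    def gamete_p(path, r):
        p = 0.5
        for a, b, rr in zip(path, path[1:], r):
            p *= rr if a != b else 1 - rr
        return p

    post = np.zeros(3)
    norm = 0.0
    for g1 in states:
        for g2 in states:
            p = gamete_p(g1, (r1, r2)) * gamete_p(g2, (r1, r2))
            def geno(i):
                n_b = (g1[i] == 0) + (g2[i] == 0)
                return {2: 0, 1: 1, 0: 2}[n_b]  # index into (BB, BH, HH)
            if geno(0) != left or geno(2) != right:
                continue
            post[geno(1)] += p
            norm += p
    return post / norm


class TestTransitions:
    def test_haldane_limits(self):
        assert q.haldane_r(0.0) == 0.0
        assert q.haldane_r(10.0) == pytest.approx(0.0906346, abs=1e-6)
        assert q.haldane_r(1e6) == pytest.approx(0.5)

    def test_transition_rows_are_distributions(self):
        T = q.f2_transition_matrix(0.23)
        assert np.allclose(T.sum(axis=1), 1.0)
        # stationary under the F2 prior
        assert np.allclose(q.F2_PRIOR @ T, q.F2_PRIOR)


class TestGenotypeProbabilities:
    def test_observed_marker_has_unit_mass(self):
        cross = make_cross({"m1": ["BB"] * 10, "m2": ["HH"] * 10}, list(range(10)))
        gp = q.genotype_probabilities(cross, step_cm=1.0)
        probs = gp.probs["1"]
        i1 = gp.marker_at["1"].index("m1")
        i2 = gp.marker_at["1"].index("m2")
        assert np.allclose(probs[:, i1, :], [1, 0, 0])
        assert np.allclose(probs[:, i2, :], [0, 0, 1])
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-10)

    def test_all_missing_individual_gets_f2_prior(self):
        cross = make_cross(
            {"m1": [np.nan, "BB"] * 5, "m2": [np.nan, "BB"] * 5}, list(range(10))
        )
        gp = q.genotype_probabilities(cross, step_cm=2.0)
        assert np.allclose(gp.probs["1"][0], q.F2_PRIOR, atol=1e-12)

    @pytest.mark.parametrize("left,right", [(0, 0), (0, 2), (1, 1), (2, 0)])
    def test_midpoint_matches_chain_enumeration(self, left, right):
        codes = ["BB", "BH", "HH"]
        cross = make_cross(
            {"m1": [codes[left]] * 10, "m2": [codes[right]] * 10},
            list(range(10)),
            chrom_pos={"m1": ("1", 0.0), "m2": ("1", 20.0)},
        )
        gp = q.genotype_probabilities(cross, step_cm=10.0)
        mid = int(np.argmin(np.abs(gp.positions["1"] - 10.0)))
        r = float(q.haldane_r(10.0))
        expected = chain_posterior_oracle(r, r, left, right)
        assert np.allclose(gp.probs["1"][0, mid, :], expected, atol=1e-10)

    def test_step_must_be_positive(self):
        cross = make_cross({"m1": ["BB"] * 10}, list(range(10)))
        with pytest.raises(ValueError):
            q.genotype_probabilities(cross, step_cm=0.0)


class TestScan:
    def test_matches_least_squares_oracle(self, toy_cross_8):
        res = q.scan(toy_cross_8, method="marker")
        codes = {"BB": 1.0, "BH": 0.0, "HH": -1.0}
        for marker in ("m1", "m2"):
            g = toy_cross_8.genotypes[marker]
            xa = g.map(codes).to_numpy()
            xd = (g == "BH").to_numpy(float)
            expected = oracle_lod(toy_cross_8.phenotype.to_numpy(), xa, xd)
            got = float(res.table.loc[res.table["marker"] == marker, "lod"].iloc[0])
            assert got == pytest.approx(expected, abs=1e-10)

    def test_hk_equals_marker_regression_when_fully_typed(self, toy_cross_8):
        marker = q.scan(toy_cross_8, method="marker").table.set_index("marker")["lod"]
        hk = q.scan(toy_cross_8, method="hk", step_cm=5.0).table
        hk_at_markers = hk[hk["marker"] != ""].set_index("marker")["lod"]
        assert np.allclose(marker, hk_at_markers.loc[marker.index], atol=1e-8)

    def test_affine_phenotype_invariance(self, toy_cross_8):
        base = q.scan(toy_cross_8, method="hk", step_cm=5.0).table["lod"].to_numpy()
        trans = make_cross(
            {m: toy_cross_8.genotypes[m].tolist() for m in toy_cross_8.genotypes},
            (-3.2 * toy_cross_8.phenotype + 17.0).tolist(),
        )
        other = q.scan(trans, method="hk", step_cm=5.0).table["lod"].to_numpy()
        assert np.allclose(base, other, atol=1e-8)

    def test_lod_r2_identity_at_typed_markers(self, toy_cross_8):
        res = q.scan(toy_cross_8, method="marker")
        y = toy_cross_8.phenotype.to_numpy()
        rss0 = np.sum((y - y.mean()) ** 2)
        for _, row in res.table.iterrows():
            g = toy_cross_8.genotypes[row["marker"]]
            means = y.copy()
            for cls in q.GENOTYPES:
                sel = (g == cls).to_numpy()
                if sel.any():
                    means[sel] = y[sel].mean()
            r2_ls = 1.0 - np.sum((y - means) ** 2) / rss0
            assert q.r2_from_lod(row["lod"], int(row["n"])) == pytest.approx(r2_ls, abs=1e-8)

    def test_constant_phenotype_gives_zero_lod(self):
        cross = make_cross({"m1": ["BB", "BH", "HH"] * 4}, [1.0] * 12)
        with pytest.warns(UserWarning, match="constant"):
            res = q.scan(cross, method="hk", step_cm=5.0)
        assert (res.table["lod"] == 0).all()

    def test_too_few_individuals_rejected(self):
        cross = make_cross({"m1": ["BB", "BH", "HH", "BB"]}, [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            q.IntercrossModel(cross)

    def test_missing_phenotype_dropped(self):
        cross = make_cross(
            {"m1": ["BB", "BH", "HH"] * 4}, [1.0, 2.0, 0.5] * 3 + [np.nan] * 3
        )
        model = q.IntercrossModel(cross)
        assert model.n_used == 9

    def test_null_lod_calibration(self):
        # per-marker LOD under no linkage ~ chi2_2 / (2 ln 10): mean ~0.434
        gmap = q.GeneticMap(pd.DataFrame({"marker": ["m"], "chrom": ["1"], "cm": [0.0]}))
        rng = np.random.default_rng(42)
        lods = []
        n = 200
        for _ in range(1000):
            counts = rng.multinomial(1, [0.25, 0.5, 0.25], size=n).argmax(axis=1)
            codes = counts.astype(float)  # state index 0/1/2
            y = rng.normal(size=n)
            lods.append(float(q._marker_lod_profile(codes[:, None], y)[0]))
        assert 0.35 < np.mean(lods) < 0.52

    def test_parameter_recovery_at_typed_marker(self):
        gmap = default_map()
        a_hats, d_hats = [], []
        for s in range(60):
            cross = simulate_f2(gmap, QTLModel(), 69, seed=[77, s])
            res = q.IntercrossModel(cross).fit(method="marker")
            row = res.table[
                (res.table["chrom"] == "9") & np.isclose(res.table["pos_cm"], 37.5)
            ].iloc[0]
            a_hats.append(row["a_hat"])
            d_hats.append(row["d_hat"])
        for est, truth in ((a_hats, 1.0), (d_hats, 1.0)):
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * se


def profile_result(lods, bp=None, chrom="9"):
    """ScanResults built directly from a marker LOD profile."""
    markers = [f"mk{i}" for i in range(len(lods))]
    cross = make_cross(
        {m: ["BB", "BH", "HH"] * 4 for m in markers},
        list(np.linspace(0, 1, 12)),
        chrom_pos={m: (chrom, 10.0 * i) for i, m in enumerate(markers)},
        bp=bp,
    )
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_cm": [10.0 * i for i in range(len(lods))],
            "marker": markers,
            "lod": lods,
            "mu_hat": 0.0,
            "a_hat": 0.0,
            "d_hat": 0.0,
            "n": 12,
        }
    )
    return q.ScanResults(table, 12, "marker", cross)


class TestSupportInterval:
    def test_dip_at_the_line_does_not_terminate(self):
        res = profile_result([5.0, 9.0, 11.0, 14.0, 12.0, 13.0, 10.0, 9.5])
        si = res.support_interval(drop=2.0)
        # right: 12 and 13 stay inside (>= peak-2); 10 is the bounding marker
        assert si.right_marker == "mk6"
        assert si.left_marker == "mk2"  # 11 < 12 crossing just left of the peak

    def test_never_crossing_extends_to_chromosome_end(self):
        res = profile_result([13.0, 13.5, 14.0, 13.2])
        si = res.support_interval(drop=2.0)
        assert (si.left_marker, si.right_marker) == ("mk0", "mk3")

    def test_single_marker_chromosome(self):
        res = profile_result([7.0])
        si = res.support_interval(drop=2.0)
        assert si.left_marker == si.right_marker == "mk0"
        assert si.width_cm == 0.0

    def test_drop_zero_is_tight_around_peak(self):
        res = profile_result([1.0, 5.0, 9.0, 5.0, 1.0])
        si = res.support_interval(drop=0.0)
        assert si.cm_lo <= 20.0 <= si.cm_hi
        # bounds are the markers immediately encompassing the peak
        assert (si.left_marker, si.right_marker) == ("mk1", "mk3")

    def test_physical_bounds_from_marker_annotation(self):
        bp = {f"mk{i}": 1_000_000 * (i + 1) for i in range(5)}
        res = profile_result([1.0, 5.0, 14.0, 5.0, 1.0], bp=bp)
        si = res.support_interval(drop=2.0)
        assert si.bp_lo == bp["mk1"] and si.bp_hi == bp["mk3"]
        assert si.physical_width_mb == pytest.approx((bp["mk3"] - bp["mk1"] + 1) / 1e6)

    def test_interval_json_roundtrip(self, tmp_path):
        import json

        res = profile_result([1.0, 5.0, 14.0, 5.0, 1.0])
        path = tmp_path / "interval.json"
        res.support_interval().to_json(path)
        payload = json.loads(path.read_text())
        assert payload["chrom"] == "9" and payload["peak_lod"] == 14.0


@pytest.fixture(scope="module")
def null_cross():
    gmap = default_map()
    return simulate_f2(gmap, QTLModel(add_effect=0.0, dom_effect=0.0), 69, seed=21)


class TestPermutationThreshold:

    def test_threshold_in_expected_null_range(self, null_cross):
        thr = q.permutation_threshold(null_cross, n_perm=1000, alpha=0.05, seed=0)
        assert 2.5 < thr < 4.5

    def test_deterministic_given_seed(self, null_cross):
        a = q.permutation_threshold(null_cross, n_perm=200, seed=3)
        b = q.permutation_threshold(null_cross, n_perm=200, seed=3)
        assert a == b

    def test_alpha_one_returns_minimum(self, null_cross):
        model = q.IntercrossModel(null_cross)
        thr = model.permutation_threshold(n_perm=150, alpha=1.0, seed=4)
        rng_check = model.permutation_threshold(n_perm=150, alpha=0.5, seed=4)
        assert thr <= rng_check

    def test_too_few_permutations_rejected(self, null_cross):
        with pytest.raises(ValueError):
            q.permutation_threshold(null_cross, n_perm=50)


class TestDominance:
    def _cross_with_means(self, mean_bb, mean_bh, mean_hh):
        g = ["BB"] * 4 + ["BH"] * 4 + ["HH"] * 4
        rng = np.random.default_rng(0)
        y = ([mean_bb + 1e-3 * rng.normal() for _ in range(4)]
             + [mean_bh + 1e-3 * rng.normal() for _ in range(4)]
             + [mean_hh + 1e-3 * rng.normal() for _ in range(4)])
        return make_cross({"m1": g}, y)

    def test_complete_dominance(self):
        rep = q.dominance_assessment(self._cross_with_means(1, 1, 0), "m1")
        assert rep.classification == "B6-dominant"
        assert rep.d_hat / rep.a_hat == pytest.approx(1.0, abs=0.02)

    def test_additive(self):
        rep = q.dominance_assessment(self._cross_with_means(1, 0.5, 0), "m1")
        assert rep.classification == "additive"

    def test_recessive_side(self):
        rep = q.dominance_assessment(self._cross_with_means(1, 0, 0), "m1")
        assert rep.classification == "129-dominant"

    def test_empty_class_indeterminate(self):
        cross = make_cross({"m1": ["BB"] * 6 + ["BH"] * 6}, list(range(12)))
        rep = q.dominance_assessment(cross, "m1")
        assert rep.classification == "indeterminate"

    def test_simulated_dominant_study_classified_b6(self):
        gmap = default_map()
        hits = 0
        for s in range(30):
            cross = simulate_f2(gmap, QTLModel(), 69, seed=[55, s])
            res = q.IntercrossModel(cross).fit(method="marker")
            rep = q.dominance_assessment(cross, str(res.peak["marker"]))
            hits += rep.classification == "B6-dominant"
        assert hits / 30 >= 0.9


class TestCrossIO:
    def test_rqtl_csv_roundtrip(self, tmp_path):
        gmap = default_map(40)
        cross = simulate_f2(gmap, QTLModel(), 12, missing_rate=0.1, seed=8)
        path = tmp_path / "cross.csv"
        cross.to_rqtl_csv(path)
        back = q.CrossData.read_rqtl_csv(path)
        pd.testing.assert_frame_equal(back.genotypes, cross.genotypes)
        assert np.allclose(back.phenotype, cross.phenotype, atol=1e-5)
        assert back.map.markers == cross.map.markers

    def test_unknown_genotype_code_rejected(self):
        with pytest.raises(ValueError):
            make_cross({"m1": ["BB", "XX"] * 5}, list(range(10)))
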