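"""Local colocation quotient: kernel weights, shares, values, per-point test."""

import numpy as np
import pytest

import poicoloc as pc

from conftest import brute_lclq, make_pattern


class TestGaussianWeight:
    def test_unit_at_origin(self):
        assert pc.gaussian_weight(0.0, 2.0) == pytest.approx(1.0)

    def test_closed_forms(self):
        assert pc.gaussian_weight(3.0, 3.0) == pytest.approx(np.exp(-0.5))
        assert pc.gaussian_weight(6.0, 3.0) == pytest.approx(np.exp(-2.0))

    def test_strictly_decreasing(self):
        d = np.linspace(0, 5, 50)
        w = pc.gaussian_weight(d, 1.3)
        assert (np.diff(w) < 0).all()

    def test_degenerate_bandwidth_raises(self):
        with pytest.raises(ValueError, match="increase k"):
            pc.gaussian_weight(1.0, 0.0)


class TestLocalShare:
    def test_all_neighbours_b(self):
        pat = make_pattern([[0, 0], [1, 0], [0, 1], [1, 1]], "ABBB", area=4.0)
        s = pc.local_b_share(pat, "p0", "B", pc.BandwidthSpec(k=3))
        assert s == pytest.approx(1.0)

    def test_no_neighbour_b(self):
        pat = make_pattern([[0, 0], [1, 0], [0, 1], [9, 9]], "ACCB", area=100.0)
        s = pc.local_b_share(pat, "p0", "B", pc.BandwidthSpec(k=2))
        assert s == pytest.approx(0.0)

    def test_hand_laid_configuration(self):
        # focal at origin; neighbours at distances 1, 2, 3 of types B, C, B;
        # k = 3 so d_ib = 3; weights exp(-d^2/18)
        pat = make_pattern(
            [[0, 0], [1, 0], [0, 2], [-3, 0], [40, 40]],
            ["A", "B", "C", "B", "C"], area=10000.0,
        )
        s = pc.local_b_share(pat, "p0", "B", pc.BandwidthSpec(k=3))
        w = np.exp(np.array([-1 / 18, -4 / 18, -9 / 18]))
        assert s == pytest.approx((w[0] + w[2]) / w.sum())

    def test_shares_partition_unity(self, csr_two_cat):
        spec = pc.BandwidthSpec(k=6)
        for pid in ["p0", "p31", "p59"]:
            total = sum(
                pc.local_b_share(csr_two_cat, pid, b, spec) for b in "ABC"
            )
            assert total == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_bandwidth_raises(self):
        pat = make_pattern([[0, 0], [0, 0], [1, 1]], "AAB", area=4.0)
        with pytest.raises(ValueError, match="increase k"):
            pc.local_b_share(pat, "p0", "B", pc.BandwidthSpec(k=1))


class TestLCLQValue:
    def test_sole_neighbour_arithmetic(self):
        # N = 10, N_B = 3; focal's only meaningful neighbour is one B
        coords = [[0, 0], [0.001, 0]] + [[50 + i, 80 + i] for i in range(8)]
        labels = ["A", "B"] + ["B", "B", "C", "C", "C", "C", "C", "C"][:8]
        pat = make_pattern(coords, labels, area=40000.0)
        r = pc.lclq(pat, "p0", "B", pc.BandwidthSpec(k=1))
        assert r.value == pytest.approx(1 / (3 / 9))
        assert r.a_category == "A"

    def test_no_b_neighbours_gives_zero(self):
        pat = make_pattern([[0, 0], [1, 0], [0, 1], [9, 9]], "ACCB", area=100.0)
        r = pc.lclq(pat, "p0", "B", pc.BandwidthSpec(k=2))
        assert r.value == 0.0

    @pytest.mark.parametrize("k", [3, 8])
    def test_matches_bruteforce(self, csr_two_cat, k):
        labels = csr_two_cat.categories
        for i in np.flatnonzero(labels == "A")[:6]:
            r = pc.lclq(csr_two_cat, f"p{i}", "B", pc.BandwidthSpec(k=k))
            want, share, d_ib = brute_lclq(csr_two_cat.coords, labels, i, "B", k)
            assert r.value == pytest.approx(want, rel=1e-12)
            assert r.weighted_b_share == pytest.approx(share, rel=1e-12)
            assert r.bandwidth_distance == pytest.approx(d_ib, rel=1e-12)

    def test_same_category_correction(self, csr_two_cat):
        # A→A uses N_A - 1 in the expected share
        i = int(np.flatnonzero(csr_two_cat.categories == "A")[0])
        r = pc.lclq(csr_two_cat, f"p{i}", "A", pc.BandwidthSpec(k=5))
        scale = (csr_two_cat.n - 1) / (20 - 1)
        assert r.value == pytest.approx(r.weighted_b_share * scale, rel=1e-12)

    def test_flat_kernel_k1_reduces_to_per_point_gclq_share(self):
        # with all weights 1 and k = 1, LCLQ = f * (N-1)/N_B, the per-point
        # contribution of the global quotient
        pat = make_pattern(
            [[0, 0], [0.1, 0], [5, 5], [6, 6], [7, 7]], "ABBCC", area=100.0
        )
        r = pc.lclq(pat, "p0", "B", pc.BandwidthSpec(k=1, kernel="flat"))
        assert r.value == pytest.approx(1.0 * 4 / 2)

    def test_null_mean_near_one(self):
        # random labels on a fixed CSR scene: grand mean within 0.05 of 1
        base = pc.simulate_csr(200, (0, 0, 1, 1), 21)
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(100):
            labels = np.array(["A"] * 100 + ["B"] * 100)
            rng.shuffle(labels)
            pat = make_pattern(base.coords, labels)
            res = pc.lclq_all(pat, "A", "B", pc.BandwidthSpec(k=10), None)
            vals.extend(r.value for r in res)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestLCLQAll:
    def test_determinism(self, attraction_scene):
        cfg = pc.MonteCarloConfig(n_permutations=99, seed=11)
        spec = pc.BandwidthSpec(k=5)
        r1 = pc.lclq_all(attraction_scene, "B", "A", spec, cfg)
        r2 = pc.lclq_all(attraction_scene, "B", "A", spec, cfg)
        assert [x.p_value for x in r1] == [x.p_value for x in r2]
        assert [x.value for x in r1] == [x.value for x in r2]

    def test_rank_formula_floor(self):
        # focal A ringed by the scene's only 10 B points: observed share is 1
        # and no permutation of 10 B labels over 101 points can reproduce it,
        # so the one-sided p hits the (r+1)/(M+1) floor exactly
        rng = np.random.default_rng(13)
        theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = 0.5 + 0.001 * np.c_[np.cos(theta), np.sin(theta)]
        bg = rng.uniform(0, 1, size=(90, 2))
        coords = np.vstack([[[0.5, 0.5]], ring, bg])
        labels = ["A"] + ["B"] * 10 + ["C"] * 90
        pat = make_pattern(coords, labels)
        cfg = pc.MonteCarloConfig(n_permutations=999, seed=0)
        res = pc.lclq_all(pat, "A", "B", pc.BandwidthSpec(k=10), cfg)
        assert len(res) == 1
        assert res[0].weighted_b_share == pytest.approx(1.0)
        assert res[0].p_value == pytest.approx(1 / 1000)

    def test_localised_hotspot_detection(self):
        # B offspring planted around half the A points: hotspot As flag,
        # background As mostly do not
        region = (0.0, 0.0, 1.0, 1.0)
        hits_hot, hits_bg = [], []
        for seed in range(15):
            a = pc.simulate_csr(40, region, 100 + seed)
            hot = pc.CategoricalPointPattern(
                [f"h{i}" for i in range(20)], a.coords[:20], ["A"] * 20,
                region=a.region,
            )
            c = pc.simulate_csr(160, region, 300 + seed)
            b = pc.simulate_attracted(hot, "B", 80, sigma=0.003, seed=200 + seed)
            pat = pc.merge_patterns([a, c, b], ["A", "C", "B"], region)
            cfg = pc.MonteCarloConfig(n_permutations=199, seed=seed)
            res = pc.lclq_all(pat, "A", "B", pc.BandwidthSpec(k=3), cfg)
            sig = {r.focal_id for r in pc.significant_colocated(res)}
            hot_ids = {f"A-{i}" for i in range(20)}
            bg_ids = {f"A-{i}" for i in range(20, 40)}
            hits_hot.append(len(sig & hot_ids) / 20)
            hits_bg.append(len(sig & bg_ids) / 20)
        assert np.mean(hits_hot) > 0.5
        assert np.mean(hits_bg) < 0.15
        assert np.mean(hits_hot) > 3 * np.mean(hits_bg)

    def test_null_rejection_rate_calibrated(self):
        # per-point one-sided test at alpha=.05 under random labelling
        rej, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            coords = rng.uniform(0, 1, size=(100, 2))
            labels = np.array(["A"] * 50 + ["B"] * 50)
            rng.shuffle(labels)
            pat = make_pattern(coords, labels)
            cfg = pc.MonteCarloConfig(n_permutations=199, seed=seed)
            res = pc.lclq_all(pat, "A", "B", pc.BandwidthSpec(k=5), cfg)
            rej += sum(r.p_value <= 0.05 for r in res)
            total += len(res)
        assert 0.02 <= rej / total <= 0.09

    def test_bandwidth_smoothing_shrinks_dispersion(self):
        # as k grows towards N-1 the spread of LCLQ values cannot increase
        spreads = []
        for k in (5, 25, 99):
            sds = []
            for seed in range(8):
                rng = np.random.default_rng(900 + seed)
                coords = rng.uniform(0, 1, size=(100, 2))
                labels = np.array(["A"] * 50 + ["B"] * 50)
                rng.shuffle(labels)
                pat = make_pattern(coords, labels)
                res = pc.lclq_all(pat, "A", "B", pc.BandwidthSpec(k=k), None)
                sds.append(np.std([r.value for r in res]))
            spreads.append(np.mean(sds))
        assert spreads[0] >= spreads[1] >= spreads[2]


class TestFilter:
    def test_filter_rules(self):
        mk = lambda v, p: pc.LCLQResult("x", "A", "B", 1.0, 0.5, v, p)
        kept = pc.significant_colocated([
            mk(2.0, 0.01),   # kept
            mk(2.0, 0.20),   # dropped: not significant
            mk(0.8, 0.001),  # dropped: not colocated
            mk(1.0, 0.01),   # dropped: value must exceed 1
        ])
        assert len(kept) == 1
        assert kept[0].value == 2.0

    def test_unset_p_never_kept(self):
        r = pc.LCLQResult("x", "A", "B", 1.0, 0.5, 3.0, None)
        assert pc.significant_colocated([r]) == []
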