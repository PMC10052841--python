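import numpy as np
import pytest

from dipkit.io_formats import GenotypeMatrix, LocusDef
from dipkit.popgen_distances import (amova, da_distance, da_matrix,
                                     informativeness_in, pairwise_fst_matrix,
                                     wc_fst, wc_fst_components)
from dipkit.synthetic_data import (ContinentSpec, PopulationSpec,
                                   SyntheticConfig, make_dataset)


def _single_pop(name, dosages, continent="C"):
    d = np.asarray(dosages, dtype=float)
    loci = [LocusDef(f"rs{i}") for i in range(d.shape[1])]
    return GenotypeMatrix([f"{name}{i}" for i in range(d.shape[0])],
                          [name] * d.shape[0], [continent] * d.shape[0],
                          loci, d)


class TestWcFst:
    def test_opposite_fixation_gives_one(self):
        a = _single_pop("A", np.full((10, 4), 2.0))
        b = _single_pop("B", np.zeros((10, 4)))
        assert wc_fst(a, b) == pytest.approx(1.0)

    def test_random_split_of_one_population_near_zero(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, rng.uniform(0.3, 0.7, 57), (400, 57)).astype(float)
        a = _single_pop("A", d[:200])
        b = _single_pop("B", d[200:])
        assert abs(wc_fst(a, b)) < 0.02

    def test_hand_evaluated_components(self):
        """Two 10-sample populations with written-out genotype counts match
        a direct transcription of the variance-component formulas."""
        # pop A: 3x DD, 4x ID, 3x II  -> p = .5, h = .4
        # pop B: 6x DD, 2x ID, 2x II  -> p = .3, h = .2
        dA = np.array([0] * 3 + [1] * 4 + [2] * 3, dtype=float)
        dB = np.array([0] * 6 + [1] * 2 + [2] * 2, dtype=float)
        a, b, c = wc_fst_components([dA, dB])
        # direct evaluation with r=2, nbar=10, nc=10
        r, n1, n2, p1, p2, h1, h2 = 2, 10, 10, 0.5, 0.3, 0.4, 0.2
        nbar = 10.0
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a_want = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                      - hbar / 4) / (nbar - 1))
        b_want = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                        - (2 * nbar - 1) / (4 * nbar) * hbar)
        assert a == pytest.approx(a_want, abs=1e-12)
        assert b == pytest.approx(b_want, abs=1e-12)
        assert c == pytest.approx(hbar / 2, abs=1e-12)

    def test_balding_nichols_recovery(self):
        """Multi-locus theta recovers the generative FST within 3 MC SE."""
        F = 0.10
        cfg = SyntheticConfig(n_loci=600, continents=[
            ContinentSpec("C1", F, [PopulationSpec("P1", 150, 0.001)]),
            ContinentSpec("C2", F, [PopulationSpec("P2", 150, 0.001)]),
        ], seed=17)
        g, _ = make_dataset(cfg)
        theta = wc_fst(g.subset_population("P1"), g.subset_population("P2"))
        target = F + 0.001 * (1 - F)  # continental plus within-continent drift
        # per-locus theta numerators are ~ chi-square_1 scaled: relative MC
        # SE of the ratio estimator is about sqrt(2 / n_loci)
        se = target * np.sqrt(2 / 600)
        assert abs(theta - target) < 3 * se

    def test_matrix_and_clamp(self, small_dataset):
        g, _ = small_dataset
        d = pairwise_fst_matrix(g)
        assert d.labels == ["AFR1", "AFR2", "EAS1", "EAS2"]
        assert np.allclose(d.values, d.values.T)
        dc = d.clamp_nonnegative()
        assert (dc.values >= 0).all()

    def test_no_shared_loci_error(self):
        a = _single_pop("A", np.full((5, 2), np.nan))
        b = _single_pop("B", np.zeros((5, 2)))
        with pytest.raises(ValueError):
            wc_fst(a, b)


class TestDa:
    def test_identical_tables_zero(self):
        f = np.array([0.2, 0.5, 0.9])
        assert da_distance(f, f) == pytest.approx(0.0, abs=1e-15)

    def test_opposite_fixation_one(self):
        assert da_distance(np.ones(5), np.zeros(5)) == pytest.approx(1.0)

    def test_hand_value(self):
        want = 1 - (np.sqrt(0.9 * 0.6) + np.sqrt(0.1 * 0.4))
        assert da_distance(np.array([0.9]), np.array([0.6])) == pytest.approx(want)

    def test_relabel_invariance(self):
        """DA is unchanged by a consistent I <-> D swap."""
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0.1, 0.9, 30), rng.uniform(0.1, 0.9, 30)
        assert da_distance(x, y) == pytest.approx(da_distance(1 - x, 1 - y))

    def test_mismatched_loci_error(self):
        with pytest.raises(ValueError):
            da_distance(np.ones(3), np.ones(4))

    def test_matrix(self, small_dataset):
        _, truth = small_dataset
        d = da_matrix(truth)
        assert d.metric_name == "da"
        assert (d.values >= 0).all()


class TestInformativeness:
    def test_identical_frequencies_zero(self):
        p = np.tile(np.array([[0.4]]), (1, 5))
        assert informativeness_in(p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_ln2(self):
        assert informativeness_in(np.array([[1.0, 0.0]]))[0] == \
            pytest.approx(np.log(2))

    def test_hand_value_two_pops(self):
        p1, p2 = 0.9, 0.1
        pbar = 0.5
        want = 0.0
        for a1, a2 in [(p1, p2), (1 - p1, 1 - p2)]:
            m = (a1 + a2) / 2
            want += -m * np.log(m) + (a1 * np.log(a1) + a2 * np.log(a2)) / 2
        got = informativeness_in(np.array([[p1, p2]]))[0]
        assert got == pytest.approx(want, rel=1e-12)

    def test_bounds_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, (40, 4))
        vals = informativeness_in(p)
        assert np.all(vals >= 0) and np.all(vals <= np.log(4) + 1e-12)
        np.testing.assert_allclose(vals, informativeness_in(1 - p), atol=1e-12)


class TestAmova:
    def test_single_population_is_all_within(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, (50, 10)).astype(float)
        g = _single_pop("P", d)
        # split randomly into two pseudo-populations: among ~ 0
        g2 = GenotypeMatrix(g.sample_ids, ["A"] * 25 + ["B"] * 25,
                            ["C"] * 50, g.loci, d)
        res = amova(g2)
        assert res.design == "2-level"
        assert abs(res.percentages["among_populations"]) < 2.0
        assert sum(res.percentages.values()) == pytest.approx(100, abs=1e-6)

    def test_opposite_fixation_all_among(self):
        d = np.vstack([np.full((10, 6), 2.0), np.zeros((10, 6))])
        g = GenotypeMatrix([f"s{i}" for i in range(20)],
                           ["A"] * 10 + ["B"] * 10, ["C"] * 20,
                           [LocusDef(f"rs{i}") for i in range(6)], d)
        res = amova(g)
        assert res.percentages["among_populations"] == pytest.approx(100, abs=1e-6)

    def test_two_level_phi_matches_pairwise_theta(self, small_dataset):
        """Phi_ST of a two-population AMOVA agrees with W&C theta."""
        g, _ = small_dataset
        mask = [p in ("AFR1", "EAS1") for p in g.population]
        idx = np.where(mask)[0]
        sub = GenotypeMatrix([g.sample_ids[i] for i in idx],
                             [g.population[i] for i in idx],
                             [g.continent[i] for i in idx],
                             g.loci, g.dosage[idx])
        res = amova(sub)
        theta = wc_fst(g.subset_population("AFR1"), g.subset_population("EAS1"))
        assert res.phi["phi_ST"] == pytest.approx(theta, abs=0.01)

    def test_among_group_percentage_recovers_continental_fst(self):
        """Hierarchical Balding-Nichols with continental FST 0.12 across 5
        groups yields ~12% among-group variance."""
        conts = [ContinentSpec(f"G{i}", 0.12,
                               [PopulationSpec(f"G{i}P{j}", 60, 0.01)
                                for j in range(2)]) for i in range(5)]
        g, _ = make_dataset(SyntheticConfig(n_loci=300, continents=conts, seed=23))
        grouping = {p: c for p, c in zip(g.population, g.continent)}
        res = amova(g, grouping)
        assert res.design == "3-level"
        assert res.percentages["among_groups"] == pytest.approx(12.0, abs=2.5)
        assert sum(res.percentages.values()) == pytest.approx(100, abs=1e-6)
        assert res.sigma2_within >= 0

    def test_single_population_group_warns(self):
        d = np.random.default_rng(0).binomial(2, 0.5, (30, 5)).astype(float)
        g = GenotypeMatrix([f"s{i}" for i in range(30)],
                           ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                           ["X"] * 20 + ["Y"] * 10,
                           [LocusDef(f"rs{i}") for i in range(5)], d)
        with pytest.warns(UserWarning, match="single population"):
            amova(g, {"A": "X", "B": "X", "C": "Y"})
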