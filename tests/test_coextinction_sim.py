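"""Habitat removal, gradual loss, attack sequences and R50 comparison."""

import numpy as np
import pytest

from coralnet import (
    attack_sequence,
    compare_robustness,
    community_metrics,
    gradual_loss,
    remove_habitats,
)
from coralnet.coextinction_sim import (
    STRATEGIES,
    _compact_letter_display,
    _partial_row_removal,
)

from conftest import make_dataset


@pytest.fixture
def toy():
    # s0 only in h0; s1 in both; s2 only in h1
    return make_dataset(
        [[4, 1, 0], [0, 1, 1]],
        residency=["migrant", "resident", "migrant"],
    )


class TestRemoveHabitats:
    def test_exclusive_species_go_extinct(self, toy):
        res = remove_habitats(toy, ["h0"], compute_metrics=False)
        assert res.extinct_species == ("s0",)
        assert res.extinct_by_residency("migrant") == ["s0"]
        assert set(res.surviving.matrix.species_labels) == {"s1", "s2"}

    def test_no_exclusive_species_no_extinction(self):
        ds = make_dataset([[1, 1], [2, 3]])
        res = remove_habitats(ds, ["h0"], compute_metrics=False)
        assert res.extinct_species == ()

    def test_species_conservation(self, toy):
        res = remove_habitats(toy, ["h1"], compute_metrics=False)
        assert (
            len(res.extinct_species) + res.surviving.matrix.n_species
            == toy.matrix.n_species
        )

    def test_unknown_habitat_raises(self, toy):
        with pytest.raises(KeyError):
            remove_habitats(toy, ["h9"], compute_metrics=False)

    def test_metrics_recomputed_on_shrunk_network(self, surrogate):
        res = remove_habitats(surrogate, ["wetlands"], modularity_restarts=3)
        mets = res.metrics["included"]
        n_links = res.surviving.matrix.link_count()
        assert mets["connectance"] == pytest.approx(
            n_links / (4 * res.surviving.matrix.n_species)
        )
        assert mets["species_number"] == res.surviving.matrix.n_species


class TestGradualLoss:
    def test_zero_fraction_is_identity(self, toy):
        traj = gradual_loss(toy, "h0", [0.0], replicates=2, modularity_restarts=2)
        base = community_metrics(toy, modularity_restarts=2)
        for metric, value in base.items():
            got = traj[(traj.metric == metric) & (~traj.excluded)]["value"]
            assert got.tolist() == pytest.approx([value] * 2, nan_ok=True)

    def test_full_loss_matches_whole_removal(self, toy):
        # binary outcome at f=1: s0 extinct, s1 and s2 survive
        traj = gradual_loss(toy, "h0", [1.0], replicates=3, modularity_restarts=2)
        sp = traj[(traj.metric == "species_number") & (~traj.excluded)]["value"]
        assert sp.tolist() == [2.0, 2.0, 2.0]

    def test_full_loss_equals_remove_habitats_for_many_seeds(self, surrogate):
        removed = remove_habitats(surrogate, ["wetlands"], compute_metrics=False)
        expected = removed.surviving.matrix.n_species
        for seed in range(10):
            traj = gradual_loss(
                surrogate, "wetlands", [1.0],
                rng_seed=seed, replicates=1, modularity_restarts=1,
            )
            sp = traj[(traj.metric == "species_number") & (~traj.excluded)]
            assert sp["value"].iloc[0] == expected

    def test_unit_counts_are_hypergeometric_without_replacement(self):
        rng = np.random.default_rng(0)
        row = np.array([10, 5, 1])
        out = _partial_row_removal(row, 0.5, rng, "individual")
        assert out.sum() == 8  # 16 - floor(0.5*16)
        assert (out <= row).all() and (out >= 0).all()

    def test_link_unit_removes_whole_links(self):
        rng = np.random.default_rng(0)
        row = np.array([10, 5, 1, 0])
        out = _partial_row_removal(row, 0.5, rng, "link")
        # floor(0.5 * 3 links) = 1 link removed entirely
        assert ((out == 0) | (out == row)).all()
        assert np.count_nonzero(out) == 2

    def test_invalid_fraction_raises(self, toy):
        with pytest.raises(ValueError):
            gradual_loss(toy, "h0", [0.0, 1.5])


class TestAttackSequence:
    def test_orders_follow_strategy(self, surrogate):
        smallest = attack_sequence(surrogate, "smallest_area", replicates=1)
        assert smallest.removal_orders[0] == (
            "wetlands", "beaches", "grasslands", "shrublands", "forests",
        )
        most = attack_sequence(surrogate, "most_connected", replicates=1)
        assert most.removal_orders[0][0] == "wetlands"
        degs = dict(
            zip(surrogate.matrix.habitat_labels, surrogate.matrix.degrees())
        )
        order_degs = [degs[h] for h in most.removal_orders[0]]
        assert order_degs == sorted(order_degs, reverse=True)

    def test_survival_curves_monotone_non_increasing(self, surrogate):
        for strategy in STRATEGIES:
            rr = attack_sequence(surrogate, strategy, replicates=5, rng_seed=1)
            assert (np.diff(rr.survival_curves, axis=1) <= 1e-12).all()
            assert (rr.survival_curves[:, 0] == 1.0).all()
            assert (rr.survival_curves[:, -1] == 0.0).all()

    def test_r50_on_constructed_majority_habitat(self):
        # h0 exclusively hosts 6 of 10 species: removing it first
        # drops survival to 40% at step 1 of 2
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :6] = 1
        counts[1, 6:] = 1
        counts[0, 9] = 1  # h0 also touches one shared species
        ds = make_dataset(counts)
        rr = attack_sequence(ds, "most_connected", replicates=1)
        assert rr.removal_orders[0][0] == "h0"
        assert rr.r50[0] == pytest.approx(0.5)

    def test_random_strategy_reproducible_by_seed(self, surrogate):
        a = attack_sequence(surrogate, "random", replicates=4, rng_seed=9)
        b = attack_sequence(surrogate, "random", replicates=4, rng_seed=9)
        assert a.removal_orders == b.removal_orders
        assert (a.r50 == b.r50).all()


class TestCompareRobustness:
    def _fake(self, strategy, values):
        from coralnet.coextinction_sim import RobustnessResult

        values = np.asarray(values, dtype=float)
        return RobustnessResult(
            strategy=strategy,
            removal_orders=tuple(() for _ in values),
            survival_curves=np.ones((len(values), 2)),
            r50=values,
        )

    def test_identical_distributions_share_a_letter(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + 0.01 * rng.standard_normal(30)
        out = compare_robustness(
            [self._fake("a", vals), self._fake("b", vals)]
        )
        assert out["letters"]["a"] == out["letters"]["b"]

    def test_separated_distributions_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        lo = 0.2 + 0.01 * rng.standard_normal(30)
        hi = 0.8 + 0.01 * rng.standard_normal(30)
        out = compare_robustness(
            [self._fake("lo", lo), self._fake("hi", hi)]
        )
        assert out["anova_p"] < 1e-6
        assert not set(out["letters"]["lo"]) & set(out["letters"]["hi"])

    def test_all_constant_is_degenerate(self):
        out = compare_robustness(
            [self._fake("a", [0.4] * 5), self._fake("b", [0.4] * 5)]
        )
        assert out["degenerate"] is True
        assert out["anova_p"] is None

    def test_compact_letter_display_respects_significance(self):
        letters = _compact_letter_display(
            ["a", "b", "c"], {("a", "c")}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
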