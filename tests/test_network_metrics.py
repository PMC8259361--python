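"""Network-level metrics and per-habitat indices, checked against
independent oracles (literal NODF transcription, exhaustive partition
search for modularity) and hand-computed examples."""

import itertools

import numpy as np
import pytest

from coralnet import (
    barber_modularity,
    binarize,
    connectance,
    habitat_strength,
    interaction_asymmetry,
    nested_rank,
    nodf,
    specificity,
)
from coralnet.network_metrics import modularity_score, network_report

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# independent oracles


def nodf_oracle(counts) -> float:
    """Literal NODF transcription on python sets, one pair at a time."""
    b = np.asarray(counts) > 0
    rows = [frozenset(np.nonzero(r)[0]) for r in b]
    cols = [frozenset(np.nonzero(c)[0]) for c in b.T]

    def paired(sets):
        total = 0.0
        for u, v in itertools.permutations(range(len(sets)), 2):
            if len(sets[u]) > len(sets[v]) > 0:
                total += 100.0 * len(sets[u] & sets[v]) / len(sets[v])
        return total, len(sets) * (len(sets) - 1) // 2

    r_sum, r_pairs = paired(rows)
    c_sum, c_pairs = paired(cols)
    return (r_sum + c_sum) / (r_pairs + c_pairs)


def set_partitions(n):
    """All partitions of range(n) as restricted-growth label strings."""

    def rec(labels, k):
        i = len(labels)
        if i == n:
            yield tuple(labels)
            return
        for lab in range(k + 1):
            yield from rec(labels + [lab], max(k, lab + 1))

    yield from rec([], 0)


def modularity_oracle(matrix) -> float:
    """Exhaustive maximisation of Barber Q over all joint partitions."""
    n = matrix.n_habitats + matrix.n_species
    best = -np.inf
    for labels in set_partitions(n):
        q = modularity_score(
            matrix, labels[: matrix.n_habitats], labels[matrix.n_habitats:]
        )
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------


class TestConnectance:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[1, 0], [0, 1]], 0.5),
            ([[2, 0, 5], [0, 1, 0]], 0.5),
        ],
    )
    def test_examples(self, counts, expected):
        assert connectance(make_matrix(counts)) == pytest.approx(expected)


class TestNodf:
    def test_perfect_staircase_is_100(self):
        m = make_matrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert nodf(m) == pytest.approx(100.0)

    def test_equal_fills_everywhere_is_zero(self):
        assert nodf(make_matrix([[1, 0], [0, 1]])) == 0.0
        # all-equal row fills and column fills
        assert nodf(make_matrix([[1, 1], [1, 1]])) == 0.0

    def test_weights_are_ignored(self):
        m = make_matrix([[9, 7, 1], [3, 2, 0], [800, 0, 0]])
        assert nodf(m) == pytest.approx(nodf(binarize(m)))

    def test_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng)
        base = nodf(m)
        pr = rng.permutation(m.n_habitats)
        pc = rng.permutation(m.n_species)
        assert nodf(make_matrix(m.counts[np.ix_(pr, pc)])) == pytest.approx(base)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = random_matrix(rng)
            assert nodf(m) == pytest.approx(nodf_oracle(m.counts), abs=1e-9)


class TestBarberModularity:
    def test_two_disjoint_blocks(self):
        m = make_matrix([[1, 1, 0, 0], [0, 0, 1, 1]])
        res = barber_modularity(m, seed=1, restarts=5)
        assert res.q == pytest.approx(0.5)
        # the partition separates the two blocks
        gh, gs = res.habitat_modules, res.species_modules
        assert gh[0] != gh[1]
        assert gs[0] == gs[1] == gh[0] and gs[2] == gs[3] == gh[1]

    def test_single_module_q_is_zero(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng)
        q = modularity_score(m, [0] * m.n_habitats, [0] * m.n_species)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_is_self_consistent(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, max_rows=5, max_cols=8)
        res = barber_modularity(m, seed=0, restarts=5)
        assert res.q == pytest.approx(
            modularity_score(m, res.habitat_modules, res.species_modules)
        )
        assert res.q >= -1e-12  # never worse than the single-module split

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng)
        a = barber_modularity(m, seed=11, restarts=3)
        b = barber_modularity(m, seed=11, restarts=3)
        assert a.q == b.q
        assert a.habitat_modules == b.habitat_modules

    def test_optimizer_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for _ in range(8):
            m = random_matrix(rng, max_rows=4, max_cols=4, max_count=5)
            res = barber_modularity(m, seed=0, restarts=8)
            assert res.q == pytest.approx(modularity_oracle(m), abs=1e-9)


class TestHabitatStrength:
    def test_exclusive_habitat_gets_full_species_count(self):
        m = make_matrix([[2, 7, 1], [0, 0, 0]][:1])  # single habitat
        assert habitat_strength(m).iloc[0] == pytest.approx(3.0)

    def test_hand_example(self):
        s = habitat_strength(make_matrix([[2, 1], [0, 1]]))
        assert s.tolist() == pytest.approx([1.5, 0.5])

    def test_strengths_sum_to_species_count(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = random_matrix(rng)
            assert habitat_strength(m).sum() == pytest.approx(m.n_species)

    def test_zero_column_raises(self):
        m = make_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            habitat_strength(m)


class TestInteractionAsymmetry:
    def test_single_link_is_symmetric(self):
        m = make_matrix([[7]])
        assert interaction_asymmetry(m).iloc[0] == pytest.approx(0.0)

    def test_bounded(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = random_matrix(rng)
            vals = interaction_asymmetry(m)
            assert ((vals >= -1) & (vals <= 1)).all()

    def test_sign_convention(self):
        # habitat h0 holds nearly all of every species: it influences more
        m = make_matrix([[99, 99], [1, 1]])
        vals = interaction_asymmetry(m)
        assert vals["h0"] > 0 > vals["h1"]


class TestNestedRank:
    def test_reference_degree_ranking(self):
        habitats = ("wetlands", "forests", "grasslands", "beaches", "shrublands")
        degrees = (36, 22, 19, 17, 9)
        counts = np.zeros((5, 36), dtype=int)
        for i, d in enumerate(degrees):
            counts[i, :d] = 1
        ranks = nested_rank(make_matrix(counts, habitats=habitats))
        assert ranks.tolist() == pytest.approx([0, 0.25, 0.5, 0.75, 1.0])

    def test_two_habitats_take_endpoints(self):
        ranks = nested_rank(make_matrix([[1, 1], [1, 0]]))
        assert sorted(ranks.tolist()) == [0.0, 1.0]

    def test_degree_tie_broken_by_abundance_then_label(self):
        m = make_matrix([[1, 1, 0], [5, 5, 0], [1, 1, 1]])
        ranks = nested_rank(m)
        assert ranks["h2"] == 0.0  # highest degree
        assert ranks["h1"] == 0.5  # tie on degree, higher abundance
        assert ranks["h0"] == 1.0


class TestSpecificity:
    def test_proportional_usage_is_zero(self):
        # h0 uses species exactly in proportion to global availability
        m = make_matrix([[6, 3], [6, 3]])
        assert specificity(m)["h0"] == pytest.approx(0.0, abs=1e-12)

    def test_exclusive_single_species_habitat_is_one(self):
        m = make_matrix([[5, 0, 0], [0, 2, 9]])
        assert specificity(m)["h0"] == pytest.approx(1.0)

    def test_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = specificity(random_matrix(rng))
            assert ((vals >= 0) & (vals <= 1)).all()


class TestReport:
    def test_column_order_invariance(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, min_rows=3, min_cols=4)
        perm = rng.permutation(m.n_species)
        shuffled = make_matrix(
            m.counts[:, perm], species=tuple(m.species_labels[j] for j in perm)
        )
        for fn in (habitat_strength, interaction_asymmetry, nested_rank, specificity):
            a, b = fn(m), fn(shuffled)
            assert a.tolist() == pytest.approx(b.tolist())

    def test_bundle_is_consistent(self, surrogate):
        rep = network_report(surrogate.matrix, seed=0, restarts=5)
        assert rep.connectance == pytest.approx(connectance(surrogate.matrix))
        assert rep.per_habitat["strength"].sum() == pytest.approx(
            surrogate.matrix.n_species
        )
        assert set(rep.to_dict()["per_habitat"]) == set(
            surrogate.matrix.habitat_labels
        )
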