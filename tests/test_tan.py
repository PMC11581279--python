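"""TAN classifier: mutual information, spanning tree, CPTs, exact inference.

Oracles: a triple-loop conditional-mutual-information summation, exhaustive
spanning-tree enumeration via Prufer sequences, and posterior computation by
brute-force enumeration of the full attribute joint.
"""

import itertools
import math

import numpy as np
import pytest

from ecsurv.codebook import Variable, VariableCodebook, load_codebook
from ecsurv.cohort import Cohort, PatientRecord
from ecsurv.tan import (
    ALIVE,
    DEAD,
    TanModel,
    TanStructure,
    class_conditional_marginals,
    conditional_mutual_information,
    fit_tan,
    maximum_weight_spanning_tree,
    orient_tree,
    posterior_alive,
    posterior_alive_many,
    predict_status,
    sample_tan,
)

from conftest import make_random_cohort


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def cmi_triple_loop(classes, xa, xb, ka, kb) -> float:
    """Direct summation of I(A;B|C) over the empirical joint, in bits."""
    n = len(classes)
    total = 0.0
    for c in (0, 1):
        for a in range(ka):
            for b in range(kb):
                p_abc = np.mean((classes == c) & (xa == a) & (xb == b))
                if p_abc == 0:
                    continue
                p_c = np.mean(classes == c)
                p_ac = np.mean((classes == c) & (xa == a))
                p_bc = np.mean((classes == c) & (xb == b))
                total += p_abc * math.log2(p_abc * p_c / (p_ac * p_bc))
    return total


def all_spanning_trees(n):
    """Every labelled spanning tree on n nodes, via Prufer sequences."""
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        edges = []
        avail = sorted(i for i in range(n) if degree[i] == 1)
        for v in seq_list:
            leaf = avail.pop(0)
            edges.append((min(leaf, v), max(leaf, v)))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect

                bisect.insort(avail, v)
        edges.append((avail[0], avail[1]))
        yield edges


def posterior_by_enumeration(model: TanModel, levels: np.ndarray) -> float:
    """P(Alive | x) via the full joint: P(c, x) as an explicit product, with
    the normalizer summed over classes (no tree shortcuts)."""
    parent_of = model.structure.parent_of
    cb = model.codebook

    def joint(c: int) -> float:
        prob = model.class_prior[c]
        for name in model.structure.attributes:
            x = levels[cb.index_of(name)]
            cpt = model.cpts[name]
            if name == model.structure.root:
                prob *= cpt[c, x]
            else:
                xp = levels[cb.index_of(parent_of[name])]
                prob *= cpt[c, xp, x]
        return prob

    return joint(ALIVE) / (joint(ALIVE) + joint(DEAD))


def marginal_by_enumeration(model: TanModel, v: str) -> np.ndarray:
    """P(v | class) by summing the attribute joint over all configurations."""
    cb = model.codebook
    attrs = model.structure.attributes
    parent_of = model.structure.parent_of
    k = cb[v].n_levels
    out = np.zeros((2, k))
    ranges = [range(cb[a].n_levels) for a in attrs]
    for combo in itertools.product(*ranges):
        assign = dict(zip(attrs, combo))
        for c in (0, 1):
            prob = 1.0
            for name in attrs:
                cpt = model.cpts[name]
                if name == model.structure.root:
                    prob *= cpt[c, assign[name]]
                else:
                    prob *= cpt[c, assign[parent_of[name]], assign[name]]
            out[c, assign[v]] += prob
    return out


def tiny_model(seed=0, n_attrs=4, k=2, alpha=1.0) -> TanModel:
    """Random small TAN over a path structure."""
    rng = np.random.default_rng(seed)
    cb = load_codebook(
        [(f"x{i}", tuple(f"l{j}" for j in range(k))) for i in range(n_attrs)]
    )
    attrs = cb.names
    edges = tuple((attrs[i], attrs[i + 1]) for i in range(n_attrs - 1))
    structure = TanStructure(attrs, attrs[0], edges)
    prior = rng.dirichlet([2.0, 2.0])
    cpts = {attrs[0]: rng.dirichlet(np.ones(k), size=2)}
    for _, child in edges:
        cpts[child] = rng.dirichlet(np.ones(k), size=(2, k))
    return TanModel(cb, structure, prior, cpts, alpha)


# --------------------------------------------------------------------------
# conditional mutual information
# --------------------------------------------------------------------------

class TestConditionalMutualInformation:
    def _cohort(self, codebook, levels, classes):
        levels = np.asarray(levels)
        events = (np.asarray(classes) == 0).astype(int)
        months = np.full(len(events), 60)
        return Cohort(codebook, levels, months, events)

    def test_identical_binary_attributes_give_one_bit(self):
        cb = load_codebook([("a", ("0", "1")), ("b", ("0", "1"))])
        # within each class: a uniform over {0,1}, b == a
        levels = np.array([[0, 0], [1, 1]] * 4)
        classes = np.array([0, 0, 1, 1] * 2)
        cohort = self._cohort(cb, levels, classes)
        assert conditional_mutual_information(cohort, "a", "b") == pytest.approx(1.0)

    def test_conditional_independence_gives_zero(self):
        cb = load_codebook([("a", ("0", "1")), ("b", ("0", "1"))])
        # product counts within each class: exactly independent
        rows, classes = [], []
        for c, na, nb in ((0, 2, 3), (1, 3, 1)):
            for a in (0, 1):
                for b in (0, 1):
                    count = (na if a else 4 - na) * (nb if b else 4 - nb)
                    rows += [[a, b]] * count
                    classes += [c] * count
        cohort = self._cohort(cb, np.array(rows), np.array(classes))
        assert conditional_mutual_information(cohort, "a", "b") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_triple_loop_oracle(self, toy_codebook):
        cohort = make_random_cohort(toy_codebook, 200, seed=8)
        got = conditional_mutual_information(cohort, "a", "c")
        det = cohort.determinate()
        expect = cmi_triple_loop(
            det.label_array(), det.levels[:, 0], det.levels[:, 2], 3, 3
        )
        assert got == pytest.approx(expect, abs=1e-12)
        assert got >= -1e-12

    def test_same_attribute_rejected(self, random_toy_cohort):
        with pytest.raises(ValueError):
            conditional_mutual_information(random_toy_cohort, "a", "a")


# --------------------------------------------------------------------------
# spanning tree and orientation
# --------------------------------------------------------------------------

class TestSpanningTree:
    def test_triangle_drops_lightest_edge(self):
        w = np.array([[0, 0.5, 0.3], [0.5, 0, 0.1], [0.3, 0.1, 0]])
        edges = maximum_weight_spanning_tree(["A", "B", "C"], w)
        assert sorted(edges) == [("A", "B"), ("A", "C")]

    def test_single_node(self):
        assert maximum_weight_spanning_tree(["A"], np.zeros((1, 1))) == []

    def test_nonfinite_weight_rejected(self):
        w = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            maximum_weight_spanning_tree(["A", "B"], w)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_optimal_weight_vs_prufer_enumeration(self, n):
        rng = np.random.default_rng(n)
        w = rng.random((n, n))
        w = (w + w.T) / 2
        names = [f"v{i}" for i in range(n)]
        got = maximum_weight_spanning_tree(names, w)
        got_weight = sum(w[names.index(a), names.index(b)] for a, b in got)
        best = max(
            sum(w[i, j] for i, j in tree) for tree in all_spanning_trees(n)
        )
        assert got_weight == pytest.approx(best, abs=1e-12)

    def test_deterministic_under_ties(self):
        w = np.ones((4, 4))
        names = list("abcd")
        first = maximum_weight_spanning_tree(names, w)
        assert first == maximum_weight_spanning_tree(names, w)
        assert first == [("a", "b"), ("a", "c"), ("a", "d")]


class TestOrientTree:
    def test_path_and_star(self):
        assert orient_tree([("A", "B"), ("B", "C")], "A") == [("A", "B"), ("B", "C")]
        star = orient_tree([("X", "p"), ("X", "q"), ("X", "r")], "X")
        assert sorted(star) == [("X", "p"), ("X", "q"), ("X", "r")]

    def test_every_nonroot_gets_one_parent_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 11)
            # random tree: attach each node to a random earlier node
            edges = [
                (f"n{rng.integers(0, i)}", f"n{i}") for i in range(1, n)
            ]
            root = f"n{rng.integers(0, n)}"
            directed = orient_tree(edges, root)
            children = [v for _, v in directed]
            assert sorted(children) == sorted(
                f"n{i}" for i in range(n) if f"n{i}" != root
            )

    def test_root_not_in_tree_rejected(self):
        with pytest.raises(ValueError):
            orient_tree([("A", "B")], "Z")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            orient_tree([("A", "B"), ("B", "C"), ("C", "A")], "A")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

class TestFitTan:
    def test_two_attributes_single_possible_tree(self, toy_codebook):
        cohort = make_random_cohort(toy_codebook, 100, seed=3)
        model = fit_tan(cohort, ["a", "b"])
        assert model.structure.edges == (("a", "b"),)

    def test_laplace_zero_count_cell(self):
        """alpha=1, unseen level among k levels in a stratum of m records
        -> CPT entry 1/(m+k)."""
        cb = load_codebook([("x", ("l0", "l1", "l2"))])
        # class Dead: 4 records all at level 0 -> P(l2 | Dead) = 1/(4+3)
        levels = np.array([[0]] * 4 + [[1]] * 3)
        events = np.array([1] * 4 + [0] * 3)
        months = np.full(7, 60)
        cohort = Cohort(cb, levels, months, events)
        model = fit_tan(cohort, ["x"], alpha=1.0)
        assert model.cpts["x"][DEAD, 2] == pytest.approx(1.0 / 7.0)
        assert model.cpts["x"][DEAD, 0] == pytest.approx(5.0 / 7.0)

    def test_single_class_rejected(self, toy_codebook):
        cohort = make_random_cohort(toy_codebook, 50, seed=1, death_rate=0.0)
        with pytest.raises(ValueError, match="both classes"):
            fit_tan(cohort)

    def test_structure_recovery_from_known_tan(self):
        """Data sampled from a strongly dependent TAN recovers its tree."""
        rng = np.random.default_rng(2024)
        cb = load_codebook([(f"x{i}", ("0", "1")) for i in range(5)])
        attrs = cb.names
        edges = (("x0", "x1"), ("x1", "x2"), ("x1", "x3"), ("x3", "x4"))
        structure = TanStructure(attrs, "x0", edges)
        prior = np.array([0.4, 0.6])
        strong = np.array([[0.9, 0.1], [0.1, 0.9]])
        cpts = {"x0": np.array([[0.8, 0.2], [0.3, 0.7]])}
        for _, child in edges:
            # child strongly copies its parent, slightly modulated by class
            cpts[child] = np.stack([strong, strong * 0.96 + 0.02])
        truth = TanModel(cb, structure, prior, cpts, 1.0)
        levels, classes = sample_tan(truth, 5000, seed=99)
        months = np.where(classes == 0, 30, 60)
        cohort = Cohort(cb, levels, months, 1 - classes)
        learned = fit_tan(cohort, root="x0")
        learned_undirected = {frozenset(e) for e in learned.structure.edges}
        assert learned_undirected == {frozenset(e) for e in edges}


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

class TestPosterior:
    def test_class_independent_cpts_return_prior(self):
        model = tiny_model(seed=1)
        cpts = {
            name: np.broadcast_to(cpt[0:1], cpt.shape).copy()
            for name, cpt in model.cpts.items()
        }
        flat = TanModel(model.codebook, model.structure, model.class_prior, cpts, 1.0)
        rec = np.zeros((1, len(model.codebook)), dtype=int)
        assert posterior_alive_many(flat, rec)[0] == pytest.approx(
            model.class_prior[ALIVE], abs=1e-14
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_joint_enumeration(self, seed):
        model = tiny_model(seed=seed, n_attrs=4, k=3)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            levels = rng.integers(0, 3, size=len(model.codebook))
            got = posterior_alive_many(model, levels[None, :])[0]
            expect = posterior_by_enumeration(model, levels)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_posteriors_sum_to_one_and_interior(self):
        model = tiny_model(seed=7, n_attrs=5, k=2)
        rng = np.random.default_rng(7)
        levels = rng.integers(0, 2, size=(1000, 5))
        p_alive = posterior_alive_many(model, levels)
        assert np.all((p_alive > 0) & (p_alive < 1))
        # complement computed by swapping the class labels in the model
        swapped = TanModel(
            model.codebook,
            model.structure,
            model.class_prior[::-1].copy(),
            {k: v[::-1].copy() for k, v in model.cpts.items()},
            model.alpha,
        )
        p_dead = posterior_alive_many(swapped, levels)
        np.testing.assert_allclose(p_alive + p_dead, 1.0, atol=1e-12)

    def test_root_invariance(self, toy_codebook):
        """Re-rooting the same undirected tree leaves every posterior fixed.

        Exact for maximum-likelihood CPTs (alpha=0): the tree factorization
        encodes the same joint whatever the root. Per-CPT smoothing perturbs
        that identity by O(alpha/n), so the invariance is asserted unsmoothed
        on a cohort large enough that every count is positive.
        """
        cohort = make_random_cohort(toy_codebook, 2000, seed=21)
        rng = np.random.default_rng(3)
        records = np.column_stack(
            [rng.integers(0, v.n_levels, size=100) for v in toy_codebook]
        )
        posteriors = []
        for root in toy_codebook.names:
            model = fit_tan(cohort, alpha=0.0, root=root)
            posteriors.append(posterior_alive_many(model, records))
        for other in posteriors[1:]:
            assert np.max(np.abs(posteriors[0] - other)) < 1e-10

    def test_smoothed_root_sensitivity_is_small(self, toy_codebook):
        """With Laplace smoothing the root choice moves posteriors only at
        the O(alpha/n) level, so it stays practically inconsequential."""
        cohort = make_random_cohort(toy_codebook, 300, seed=21)
        rng = np.random.default_rng(3)
        records = np.column_stack(
            [rng.integers(0, v.n_levels, size=100) for v in toy_codebook]
        )
        posteriors = [
            posterior_alive_many(fit_tan(cohort, alpha=1.0, root=root), records)
            for root in toy_codebook.names
        ]
        for other in posteriors[1:]:
            assert np.max(np.abs(posteriors[0] - other)) < 0.02

    def test_class_conditional_marginals_match_enumeration(self):
        model = tiny_model(seed=5, n_attrs=4, k=3)
        marg = class_conditional_marginals(model)
        for v in model.structure.attributes:
            np.testing.assert_allclose(
                marg[v], marginal_by_enumeration(model, v), atol=1e-12
            )

    def test_out_of_range_level_rejected(self):
        model = tiny_model(seed=0, k=2)
        with pytest.raises(ValueError, match="out of range"):
            posterior_alive_many(model, np.array([[0, 5, 0, 0]]))


class TestPredictStatus:
    def test_threshold_rule_and_ties(self, toy_codebook):
        cohort = make_random_cohort(toy_codebook, 200, seed=2)
        model = fit_tan(cohort)
        rec = cohort[0]
        p = posterior_alive(model, rec)
        assert predict_status(model, rec, threshold=p) == "Alive"  # tie -> Alive
        assert predict_status(model, rec, threshold=min(0.999, p + 1e-9)) == "Dead"

    def test_half_threshold_is_bayes_rule(self, toy_codebook):
        cohort = make_random_cohort(toy_codebook, 400, seed=9)
        model = fit_tan(cohort)
        rng = np.random.default_rng(1)
        levels = np.column_stack(
            [rng.integers(0, v.n_levels, size=1000) for v in toy_codebook]
        )
        p = posterior_alive_many(model, levels)
        by_threshold = p >= 0.5
        by_argmax = p >= (1 - p)
        assert np.array_equal(by_threshold, by_argmax)
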