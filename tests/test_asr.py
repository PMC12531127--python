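"""Brownian-motion ancestral state reconstruction: closed forms, invariances,
and an independent cross-check against the R phytools implementation."""

import shutil
import subprocess

import numpy as np
import pytest

from tpdiverge import (
    ancestor_group_compare,
    asr_bm,
    random_ultrametric_tree,
    simulate_species_traits,
    welch_t,
)
from tpdiverge.trees import read_newick, write_newick


def rooted(newick: str):
    tree = read_newick(newick)
    tree.is_rooted = True
    return tree


class TestClosedForms:
    def test_star_tree_root_is_arithmetic_mean(self):
        star = rooted("(A:1,B:1,C:1,D:1);")
        params, _ = asr_bm(star, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        assert params.root_state == pytest.approx(3.0)

    def test_two_tip_inverse_distance_weighting(self):
        t1, t2, x1, x2 = 2.0, 3.0, 1.0, 4.0
        tree = rooted(f"(A:{t1},B:{t2});")
        params, _ = asr_bm(tree, {"A": x1, "B": x2})
        expected = (x1 / t1 + x2 / t2) / (1 / t1 + 1 / t2)
        assert params.root_state == pytest.approx(expected)

    def test_tip_estimates_equal_observations(self, rng):
        tree = random_ultrametric_tree([f"s{i}" for i in range(6)], rng)
        traits = {f"s{i}": float(i) for i in range(6)}
        _, estimates = asr_bm(tree, traits)
        for e in estimates:
            if e.is_tip:
                assert e.state_mean == traits[e.node_id]
                assert e.state_var == 0.0
                assert e.ci95 == (e.state_mean, e.state_mean)

    def test_missing_tip_value_rejected(self, rng):
        tree = random_ultrametric_tree(["a", "b", "c"], rng)
        with pytest.raises(ValueError):
            asr_bm(tree, {"a": 1.0, "b": 2.0})


class TestInvariances:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree([f"s{i}" for i in range(8)], rng)
        traits = simulate_species_traits(tree, 1.0, 0.0, seed=seed + 1)
        return tree, traits

    def test_tip_permutation_invariance(self):
        tree, traits = self._random_case(17)
        p1, e1 = asr_bm(tree, traits)
        shuffled = dict(sorted(traits.items(), reverse=True))
        p2, e2 = asr_bm(tree, shuffled)
        assert p1.root_state == pytest.approx(p2.root_state)
        assert p1.sigma2 == pytest.approx(p2.sigma2)

    def test_branch_rescaling(self):
        tree, traits = self._random_case(23)
        p1, e1 = asr_bm(tree, traits)
        scaled = tree.clone(depth=1)
        for edge in scaled.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length = edge.length * 10.0
        p2, e2 = asr_bm(scaled, traits)
        assert p2.root_state == pytest.approx(p1.root_state)
        assert p2.sigma2 == pytest.approx(p1.sigma2 / 10.0)
        for a, b in zip(e1, e2):
            assert a.state_mean == pytest.approx(b.state_mean)

    @staticmethod
    def _balanced_newick(n, height=1.0):
        import math

        levels = int(math.log2(n))
        bl = height / levels
        counter = [0]

        def rec(k):
            if k == 1:
                counter[0] += 1
                return f"x{counter[0]}:{bl}"
            return f"({rec(k // 2)},{rec(k // 2)}):{bl}"

        return f"({rec(n // 2)},{rec(n // 2)});"

    def test_root_rmse_shrinks_with_more_tips(self):
        """On balanced trees of equal height, more tips pin the root better."""
        rmse = {}
        for n in (8, 64):
            tree = rooted(self._balanced_newick(n))
            errs = []
            for rep in range(300):
                traits = simulate_species_traits(tree, 1.0, 0.0, seed=7000 + rep)
                params, _ = asr_bm(tree, traits)
                errs.append(params.root_state)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[64] < rmse[8]


class TestPhytoolsCrossCheck:
    def test_matches_fastanc_states_and_variances(self, tmp_path, rng):
        """Independent oracle: phytools::fastAnc must reproduce the node
        means exactly and the variances under the REML rate convention."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        tree = random_ultrametric_tree([f"t{i}" for i in range(10)], rng)
        traits = simulate_species_traits(tree, 2.0, 1.0, seed=99)
        write_newick(tree, tmp_path / "t.nwk")
        with open(tmp_path / "x.csv", "w") as fh:
            for k, v in traits.items():
                fh.write(f"{k},{v}\n")
        rcode = f"""
        suppressMessages(library(phytools))
        tree <- read.tree("{tmp_path}/t.nwk")
        x <- read.csv("{tmp_path}/x.csv", header=FALSE)
        fit <- fastAnc(tree, setNames(x$V2, x$V1), vars=TRUE)
        write.csv(data.frame(ace=fit$ace, var=fit$var), "{tmp_path}/out.csv")
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        import pandas as pd

        ref = pd.read_csv(tmp_path / "out.csv")
        _, estimates = asr_bm(tree, traits, reml=True)
        internal = [e for e in estimates if not e.is_tip]
        # fastAnc numbers internal nodes in the same preorder as asr_bm
        assert len(internal) == len(ref)
        np.testing.assert_allclose(
            [e.state_mean for e in internal], ref["ace"], rtol=1e-6
        )
        np.testing.assert_allclose(
            [e.state_var for e in internal], ref["var"], rtol=1e-6
        )


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_constant_groups(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_matches_hand_formula_on_random_data(self, rng):
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(3, 20)))
            b = rng.normal(loc=0.5, size=int(rng.integers(3, 20)))
            t, p = welch_t(a, b)
            # independent hand computation of Welch's statistic
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            from scipy.stats import t as tdist

            p_hand = 2 * tdist.sf(abs(t_hand), df)
            assert t == pytest.approx(t_hand)
            assert p == pytest.approx(p_hand)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_ancestor_group_compare_pairs(self):
        out = ancestor_group_compare(
            {"eudicot": [5.0, 6.0, 7.0], "chlorophyte": [1.0, 2.0, 1.5],
             "bryophyte": [3.0, 3.5, 4.0]}
        )
        assert len(out) == 3
        row = out[(out.group1 == "eudicot") & (out.group2 == "chlorophyte")]
        assert row.p.iloc[0] < 0.05

    def test_separated_groups_rejected_reliably(self):
        """Welch detects a 3-sigma mean shift essentially always at n=20."""
        hits = 0
        rng = np.random.default_rng(4242)
        for _ in range(300):
            a = rng.normal(0.0, 1.0, size=20)
            b = rng.normal(3.0, 1.0, size=20)
            hits += welch_t(a, b)[1] < 0.05
        assert hits / 300 >= 0.99
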