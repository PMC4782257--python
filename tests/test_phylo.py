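"""Tree I/O, phylogenetic covariance, contrasts and ancestral states."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import morphoevo as me
from morphoevo.errors import InvalidArgumentError, NewickParseError


def patristic(tree):
    C = me.phylo_covariance(tree).to_numpy()
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2 * C


class TestNewickIO:
    def test_two_tip_parse(self):
        t = me.parse_newick("(A:1,B:1):0;")
        assert t.n_tips == 2
        assert t.depth == pytest.approx(1.0)

    def test_round_trip_simulated_tree(self):
        t = me.simulate_tree(200, 0.5, seed=3)
        back = me.parse_newick(me.write_newick(t))
        assert back.tip_labels == t.tip_labels
        np.testing.assert_allclose(
            me.phylo_covariance(back).to_numpy(),
            me.phylo_covariance(t).to_numpy(),
            rtol=1e-10,
        )

    def test_polytomy_flagged(self):
        t = me.parse_newick("((A:1,B:1,C:1):1,D:2);")
        assert t.has_polytomies
        assert not t.is_bifurcating

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            me.parse_newick("((A:1,B:1;")


class TestResolvePolytomies:
    def test_bifurcating_tree_unchanged(self, small_tree):
        out = me.resolve_polytomies(small_tree, seed=1)
        np.testing.assert_allclose(patristic(out), patristic(small_tree), atol=1e-12)
        assert out.n_edges == small_tree.n_edges

    def test_trichotomy_resolution_edge_count(self):
        t = me.parse_newick("((A:1,B:1,C:1):1,(D:1,E:1):1);")
        out = me.resolve_polytomies(t, seed=0)
        assert out.is_bifurcating
        assert out.n_edges == 2 * 5 - 2

    def test_patristic_distances_preserved(self):
        t = me.parse_newick("((A:2,B:2,C:2,D:2):1,E:3);")
        out = me.resolve_polytomies(t, seed=5)
        a = pd.DataFrame(patristic(t), index=t.tip_labels, columns=t.tip_labels)
        b = pd.DataFrame(patristic(out), index=out.tip_labels, columns=out.tip_labels)
        np.testing.assert_allclose(
            a.loc[b.index, b.columns].to_numpy(), b.to_numpy(), atol=1e-12
        )

    def test_deterministic_given_seed(self):
        t = me.parse_newick("((A:1,B:1,C:1,D:1):1,E:2);")
        assert me.write_newick(me.resolve_polytomies(t, 7)) == me.write_newick(
            me.resolve_polytomies(t, 7)
        )


class TestPhyloCovariance:
    def test_two_tip(self):
        C = me.phylo_covariance(me.parse_newick("(A:1,B:1):0;"))
        np.testing.assert_allclose(C.to_numpy(), np.eye(2))

    def test_three_tip_path_arithmetic(self):
        C = me.phylo_covariance(me.parse_newick("((A:1,B:1):1,C:2);"))
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C.to_numpy()), [2, 2, 2])

    def test_simulated_tree_psd(self):
        C = me.phylo_covariance(me.simulate_tree(80, 1.0, seed=9)).to_numpy()
        assert np.linalg.eigvalsh(C).min() >= -1e-10
        np.testing.assert_allclose(C, C.T)


class TestPIC:
    def test_two_tip_formula(self):
        t = me.parse_newick("(A:1,B:1):0;")
        x = pd.DataFrame({"x": [3.0, 1.0]}, index=["A", "B"])
        cs = me.pic(t, x)
        assert abs(cs.contrasts.iloc[0, 0]) == pytest.approx(2 / np.sqrt(2), abs=1e-12)

    def test_row_count(self, small_tree):
        x = pd.DataFrame(
            np.random.default_rng(0).normal(size=(8, 3)), index=small_tree.tip_labels
        )
        assert me.pic(small_tree, x).contrasts.shape == (7, 3)

    def test_polytomy_rejected(self):
        t = me.parse_newick("((A:1,B:1,C:1):1,D:2);")
        x = pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=list("ABCD"))
        with pytest.raises(InvalidArgumentError, match="resolve"):
            me.pic(t, x)

    def test_label_matching_not_order(self, small_tree):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(8, 2)), index=small_tree.tip_labels)
        shuffled = x.sample(frac=1, random_state=4)
        pd.testing.assert_frame_equal(
            me.pic(small_tree, x).contrasts, me.pic(small_tree, shuffled).contrasts
        )

    def test_bm_contrast_variance_recovery(self):
        """Contrasts of BM data are iid with variance sigma^2 (oracle: the
        closed-form BM property, checked by Monte Carlo)."""
        tree = me.simulate_tree(100, 1.0, seed=12)
        C = me.phylo_covariance(tree).to_numpy()
        L = np.linalg.cholesky(C + 1e-12 * np.eye(100))
        rng = np.random.default_rng(99)
        sigma2 = 2.0
        variances = []
        for _ in range(500):
            x = np.sqrt(sigma2) * (L @ rng.standard_normal(100))
            cs = me.pic(tree, pd.DataFrame({"x": x}, index=tree.tip_labels))
            variances.append(float((cs.contrasts.to_numpy() ** 2).mean()))
        assert np.mean(variances) == pytest.approx(2.0, abs=0.1)

    def test_reml_identity_with_gls(self, small_tree):
        """Sum of squared contrasts equals the GLS residual sum of squares."""
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(8, 4)), index=small_tree.tip_labels)
        cs = me.pic(small_tree, x)
        C = me.phylo_covariance(small_tree)
        iC = np.linalg.inv(C.to_numpy())
        ones = np.ones(8)
        X = x.loc[C.index].to_numpy()
        root = (ones @ iC @ X) / (ones @ iC @ ones)
        R = X - root
        rss = np.einsum("ij,ik,kj->j", R, iC, R)
        np.testing.assert_allclose((cs.contrasts.to_numpy() ** 2).sum(0), rss, atol=1e-8)


class TestAncestralStates:
    def test_two_tip_midpoint(self):
        t = me.parse_newick("(A:1,B:1):0;")
        x = pd.DataFrame({"x": [3.0, 1.0]}, index=["A", "B"])
        anc = me.ancestral_states(t, x)
        assert anc.iloc[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_star_tree_mean(self):
        t = me.parse_newick("(A:1,B:1,C:1,D:1);")
        x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0]}, index=list("ABCD"))
        anc = me.ancestral_states(t, x)
        assert anc.iloc[0, 0] == pytest.approx(4.0, abs=1e-10)

    def test_matches_brute_force_minimizer(self):
        """States minimise sum (delta)^2 / branch length: compare against a
        direct numerical optimisation over all internal states."""
        tree = me.simulate_tree(6, 1.0, seed=21)
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=6), index=tree.tip_labels)
        anc = me.ancestral_states(tree, x.to_frame("x"))

        # enumerate edges as (parent_id, child_id, length)
        nodes = list(tree.dendropy_tree.preorder_node_iter())
        internal_ids = [n.morphoevo_id for n in nodes if not n.is_leaf()]
        edges = [
            (n.parent_node.morphoevo_id, n.morphoevo_id, n.edge.length)
            for n in nodes
            if n.parent_node is not None
        ]

        def objective(states):
            val = dict(zip(internal_ids, states))
            val.update(x.to_dict())
            return sum((val[a] - val[b]) ** 2 / l for a, b, l in edges)

        # the objective is a positive-definite quadratic: minimise it exactly
        # through its normal equations (weighted graph Laplacian), an
        # independent route from the implementation's GLS formula
        all_ids = internal_ids + list(x.index)
        pos = {nid: i for i, nid in enumerate(all_ids)}
        L = np.zeros((len(all_ids), len(all_ids)))
        for a, b, l in edges:
            w = 1.0 / l
            ia, ib = pos[a], pos[b]
            L[ia, ia] += w
            L[ib, ib] += w
            L[ia, ib] -= w
            L[ib, ia] -= w
        ni = len(internal_ids)
        states = np.linalg.solve(L[:ni, :ni], -L[:ni, ni:] @ x.to_numpy())
        assert objective(states) <= objective(states + 1e-3) + 1e-12  # sanity: a minimum
        np.testing.assert_allclose(
            anc.loc[internal_ids, "x"].to_numpy(), states, atol=1e-8
        )

    def test_root_equals_gls_estimate(self, small_tree):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(8, 2)), index=small_tree.tip_labels)
        anc = me.ancestral_states(small_tree, x)
        C = me.phylo_covariance(small_tree)
        iC = np.linalg.inv(C.to_numpy())
        ones = np.ones(8)
        root = (ones @ iC @ x.loc[C.index].to_numpy()) / (ones @ iC @ ones)
        np.testing.assert_allclose(anc.loc["node0"].to_numpy(), root, atol=1e-10)

    def test_root_invariant_to_branch_rescaling(self, small_tree):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(8, 3)), index=small_tree.tip_labels)
        a = me.ancestral_states(small_tree, x)
        b = me.ancestral_states(small_tree.rescaled(factor=7.3), x)
        np.testing.assert_allclose(
            a.loc["node0"].to_numpy(), b.loc["node0"].to_numpy(), atol=1e-10
        )

    def test_unweighted_mode_star_equivalence(self):
        """With equal branch lengths, weighted and unweighted modes agree."""
        t = me.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        x = pd.DataFrame({"x": [0.0, 2.0, 4.0, 6.0]}, index=list("ABCD"))
        w = me.ancestral_states(t, x, weighted=True)
        u = me.ancestral_states(t, x, weighted=False)
        np.testing.assert_allclose(w.to_numpy(), u.to_numpy(), atol=1e-10)


class TestAgainstApe:
    """Independent cross-checks against ape in R."""

    NEWICK = "((A:1,B:1):1,(C:0.5,D:0.5):1.5);"
    X = {"A": 1.0, "B": 3.0, "C": 2.0, "D": 5.0}

    def _run_r(self, script):
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        return np.array([float(v) for v in out.stdout.split()])

    def test_pic_matches_ape(self):
        got = me.pic(
            me.parse_newick(self.NEWICK),
            pd.DataFrame({"x": self.X}),
        ).contrasts["x"]
        want = self._run_r(
            'suppressMessages(library(ape));'
            f'tr <- read.tree(text="{self.NEWICK}");'
            "x <- c(A=1, B=3, C=2, D=5);"
            'cat(pic(x, tr), "\\n")'
        )
        # same magnitudes regardless of node ordering / sign convention
        np.testing.assert_allclose(
            np.sort(np.abs(got.to_numpy())), np.sort(np.abs(want)), atol=1e-6
        )

    def test_ancestral_states_match_ape_reml(self):
        tree = me.parse_newick(self.NEWICK)
        got = me.ancestral_states(tree, pd.DataFrame({"x": self.X}))
        want = self._run_r(
            'suppressMessages(library(ape));'
            f'tr <- read.tree(text="{self.NEWICK}");'
            "x <- c(A=1, B=3, C=2, D=5);"
            'cat(ace(x, tr, method="REML")$ace, "\\n")'
        )
        np.testing.assert_allclose(
            np.sort(got["x"].to_numpy()), np.sort(want), atol=1e-4
        )
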