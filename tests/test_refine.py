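import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from tophapplus.genotype_io import GenotypeMatrix, MISSING, MUT, WILD
from tophapplus.refine import (DOUBLET, UNINFORMATIVE, ErrorRates, assign_cells,
                               derive_clone_sequences, doublet_test,
                               estimate_error_rates, finalize_clone_phylogeny,
                               fisher_refine, run_doublet_tests,
                               sequence_log_likelihood, sequential_test)
from tophapplus.trees import CloneTree, GAIN, GERMLINE, LOSS, MutationEvent


def _matrix(rows, site_ids, cells=None):
    rows = np.array(rows, dtype=np.int8)
    return GenotypeMatrix(cells or [f"c{i}" for i in range(rows.shape[0])],
                          site_ids, rows)


def _tree(branches, site_ids):
    t = CloneTree(GERMLINE, site_ids)
    for node, (parent, events) in branches.items():
        t.add_node(node, parent,
                   events=[MutationEvent(s, d) for s, d in events])
    return t


class TestDeriveCloneSequences:
    def test_chain_accumulates(self):
        t = _tree({"A": (GERMLINE, [("s1", GAIN)]), "B": ("A", [("s2", GAIN)])},
                  ["s1", "s2"])
        seqs = derive_clone_sequences(t)
        assert list(seqs["A"]) == [MUT, WILD]
        assert list(seqs["B"]) == [MUT, MUT]
        assert list(seqs[GERMLINE]) == [WILD, WILD]

    def test_loss_cancels_gain(self):
        t = _tree({"A": (GERMLINE, [("s1", GAIN)]), "B": ("A", [("s1", LOSS)])},
                  ["s1"])
        seqs = derive_clone_sequences(t)
        assert list(seqs["B"]) == [WILD]

    def test_loss_without_gain_is_structural_error(self):
        t = _tree({"A": (GERMLINE, [("s1", LOSS)])}, ["s1"])
        with pytest.raises(ValueError, match="never gained"):
            derive_clone_sequences(t)

    def test_genotype_weight_equals_net_gains(self):
        rng = np.random.default_rng(4)
        sites = [f"s{j}" for j in range(13)]
        t = CloneTree(GERMLINE, sites)
        nodes = [GERMLINE]
        free = list(sites)
        for i in range(12):
            parent = nodes[int(rng.integers(len(nodes)))]
            s = free.pop()
            t.add_node(f"n{i}", parent, events=[MutationEvent(s, GAIN)])
            nodes.append(f"n{i}")
        seqs = derive_clone_sequences(t)
        for n in t.preorder():
            path_gains = sum(len(t.events.get(x, [])) for x in t.path_from_root(n))
            assert int((seqs[n] == MUT).sum()) == path_gains


class TestAssignCells:
    def _clones(self):
        return {
            GERMLINE: np.zeros(10, dtype=np.int8),
            "A": np.array([1] * 9 + [0], dtype=np.int8),
            "B": np.array([1] * 5 + [0] * 5, dtype=np.int8),
        }

    def test_exact_match_full_similarity(self):
        clones = self._clones()
        m = _matrix([clones["A"]], [f"s{j}" for j in range(10)])
        out = assign_cells(m, clones, m.site_ids)
        assert out.loc[0, "clone"] == "A"
        assert out.loc[0, "similarity"] == 1.0

    def test_best_fraction_wins(self):
        clones = self._clones()
        cell = clones["A"].copy()
        cell[0] = WILD  # 9/10 match to A, 6/10 to B
        m = _matrix([cell], [f"s{j}" for j in range(10)])
        out = assign_cells(m, clones, m.site_ids)
        assert out.loc[0, "clone"] == "A"
        assert out.loc[0, "similarity"] == pytest.approx(0.9)

    def test_tie_breaks_toward_fewer_mutations(self):
        clones = {GERMLINE: np.zeros(2, dtype=np.int8),
                  "A": np.array([1, 1], dtype=np.int8)}
        cell = np.array([MUT, WILD], dtype=np.int8)  # 1/2 match to both
        m = _matrix([cell], ["s1", "s2"])
        out = assign_cells(m, clones, m.site_ids)
        assert out.loc[0, "clone"] == GERMLINE

    def test_all_missing_is_uninformative(self):
        clones = self._clones()
        m = _matrix([[MISSING] * 10], [f"s{j}" for j in range(10)])
        out = assign_cells(m, clones, m.site_ids)
        assert out.loc[0, "clone"] == UNINFORMATIVE


class TestEstimateErrorRates:
    def test_perfect_data_zero_rates(self):
        clones = {"A": np.array([1, 1, 0, 0], dtype=np.int8)}
        m = _matrix([clones["A"]] * 3, ["s1", "s2", "s3", "s4"])
        a = assign_cells(m, clones, m.site_ids)
        r = estimate_error_rates(m, a, clones, m.site_ids)
        assert (r.fnr, r.fpr) == (0.0, 0.0)

    def test_pooled_quarter_rates(self):
        clones = {"A": np.array([1, 1, 0, 0], dtype=np.int8)}
        m = _matrix([[1, 0, 0, 0], [1, 1, 1, 0]], ["s1", "s2", "s3", "s4"])
        a = pd.DataFrame({"cell": ["c0", "c1"], "clone": ["A", "A"],
                          "similarity": [0.75, 0.75]})
        r = estimate_error_rates(m, a, clones, m.site_ids)
        assert r.fnr == pytest.approx(1 / 4)
        assert r.fpr == pytest.approx(1 / 4)

    def test_missing_excluded_from_both_sides(self):
        clones = {"A": np.array([1, 0], dtype=np.int8)}
        m = _matrix([[MISSING, MISSING], [1, 0]], ["s1", "s2"])
        a = pd.DataFrame({"cell": ["c0", "c1"], "clone": ["A", "A"],
                          "similarity": [np.nan, 1.0]})
        r = estimate_error_rates(m, a, clones, m.site_ids)
        assert (r.fnr_denominator, r.fpr_denominator) == (1, 1)

    def test_parameter_recovery_from_simulation(self):
        import tophapplus as tp
        cfg = tp.SimulationConfig(n_clones=8, n_snvs=60, n_cells=600, seed=10,
                                  doublet_rate=0, fpr=0.01, fnr=0.2,
                                  missing_rate=0.2, clone_frequency_scheme="uniform")
        obs, gt = tp.simulate_dataset(cfg)
        clones = {c: gt.true_tree.genotypes[c] for c in gt.clone_ids}
        a = pd.DataFrame({"cell": obs.cell_ids,
                          "clone": [gt.cell_to_clone[c] for c in obs.cell_ids],
                          "similarity": 1.0})
        r = estimate_error_rates(obs, a, clones, obs.site_ids)
        assert abs(r.fnr - 0.2) < 0.02
        assert abs(r.fpr - 0.01) < 0.005


# ---------------------------------------------------------------------------
# Fisher sequential-order test
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration with fixed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(x):
        return comb(row1, x, exact=True) * comb(row2, col1 - x, exact=True) / comb(n, col1, exact=True)

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


class TestSequentialTest:
    def test_expected_count_arithmetic(self):
        m = _matrix([[MUT, MUT]] * 17 + [[MUT, WILD]] * 3, ["a", "d"])
        st = sequential_test("a", "d", m, fnr=0.2)
        assert (st.c_a_minus, st.c_ad) == (3, 17)
        assert st.e_a_minus == pytest.approx(4.0)
        assert st.e_ad == pytest.approx(16.0)

    def test_zero_fnr_expected_row_is_degenerate_significant(self):
        m = _matrix([[MUT, MUT]] * 17 + [[MUT, WILD]] * 3, ["a", "d"])
        st = sequential_test("a", "d", m, fnr=0.0)
        assert st.e_a_minus == 0.0
        # the observed 3 intermediates cannot be explained by dropout
        _, p_scipy = stats.fisher_exact([[3, 17], [0, 20]])
        assert st.p_value == pytest.approx(p_scipy)

    def test_p_value_matches_enumeration_oracle(self):
        m = _matrix([[MUT, MUT]] * 17 + [[MUT, WILD]] * 3, ["a", "d"])
        st = sequential_test("a", "d", m, fnr=0.2)
        assert st.p_value == pytest.approx(fisher_two_sided_oracle([[3, 17], [4, 16]]))

    @pytest.mark.parametrize("table", [
        [[3, 17], [4, 16]], [[0, 20], [4, 16]], [[10, 0], [5, 5]],
        [[1, 1], [1, 1]], [[25, 25], [10, 40]], [[0, 0], [3, 7]],
    ])
    def test_scipy_fisher_matches_enumeration_for_small_margins(self, table):
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-12)


class TestFisherRefine:
    def _matrix_for(self, n_both, n_inter, n_out=10):
        rows = ([[MUT, MUT]] * n_both + [[MUT, WILD]] * n_inter
                + [[WILD, WILD]] * n_out)
        return _matrix(rows, ["a", "d"])

    def test_supported_sequential_order_kept(self):
        m = self._matrix_for(n_both=30, n_inter=30)
        t = _tree({"A": (GERMLINE, [("a", GAIN)]), "B": ("A", [("d", GAIN)])},
                  ["a", "d"])
        out, tests, n_merge, _ = fisher_refine(t, m, ErrorRates(0.1, 0.01))
        assert n_merge == 0
        assert "A" in out.parent

    def test_unsupported_intermediate_dissolved(self):
        # intermediates exactly at the dropout expectation -> merge
        m = self._matrix_for(n_both=40, n_inter=10)
        t = _tree({"A": (GERMLINE, [("a", GAIN)]), "B": ("A", [("d", GAIN)])},
                  ["a", "d"])
        out, tests, n_merge, _ = fisher_refine(t, m, ErrorRates(0.2, 0.01))
        assert n_merge == 1
        assert "A" not in out.parent
        assert [e.site_id for e in out.events["B"]] == ["a", "d"]

    def test_branching_ancestor_never_dissolved(self):
        m = _matrix([[MUT, MUT, WILD]] * 40 + [[MUT, WILD, MUT]] * 5,
                    ["a", "d", "e"])
        t = _tree({"A": (GERMLINE, [("a", GAIN)]),
                   "B": ("A", [("d", GAIN)]), "C": ("A", [("e", GAIN)])},
                  ["a", "d", "e"])
        out, tests, n_merge, n_skip = fisher_refine(t, m, ErrorRates(0.2, 0.01))
        assert n_merge == 0
        assert set(out.preorder()) == {GERMLINE, "A", "B", "C"}


# ---------------------------------------------------------------------------
# doublet likelihood-ratio test
# ---------------------------------------------------------------------------

def loglik_oracle(observed, expected, fnr, fpr):
    """Per-site loop over the four emission probabilities."""
    ll = 0.0
    for d, t in zip(observed, expected):
        if d == MISSING:
            continue
        if t == WILD:
            ll += math.log(1 - fpr) if d == WILD else math.log(fpr)
        else:
            ll += math.log(fnr) if d == WILD else math.log(1 - fnr)
    return ll


class TestSequenceLikelihood:
    def test_hand_product(self):
        T = np.array([MUT, MUT, WILD, WILD], dtype=np.int8)
        D = np.array([MUT, WILD, WILD, WILD], dtype=np.int8)
        L = math.exp(sequence_log_likelihood(D, T, fnr=0.2, fpr=0.01))
        assert L == pytest.approx(0.8 * 0.2 * 0.99 * 0.99)
        assert L == pytest.approx(0.156816)

    def test_emission_probabilities_sum_to_one(self):
        for fnr in (0.0, 0.2, 0.9):
            for fpr in (0.0, 0.01, 0.5):
                for t in (WILD, MUT):
                    T = np.array([t], dtype=np.int8)
                    p = sum(math.exp(sequence_log_likelihood(
                        np.array([d], dtype=np.int8), T, fnr, fpr))
                        for d in (WILD, MUT))
                    assert p == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_site_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.choice([WILD, MUT, MISSING], size=20).astype(np.int8)
        T = rng.choice([WILD, MUT], size=20).astype(np.int8)
        assert sequence_log_likelihood(D, T, 0.2, 0.01) == pytest.approx(
            loglik_oracle(D, T, 0.2, 0.01))


class TestDoubletTest:
    def _clones(self):
        return {
            GERMLINE: np.zeros(12, dtype=np.int8),
            "A": np.array([1] * 6 + [0] * 6, dtype=np.int8),
            "B": np.array([0] * 6 + [1] * 6, dtype=np.int8),
        }

    def test_clean_singleton_not_flagged(self):
        clones = self._clones()
        res = doublet_test(clones["A"], "A", clones, ErrorRates(0.2, 0.01))
        assert res is None  # no observed mutation outside the assigned clone

    def test_union_cell_flagged(self):
        clones = self._clones()
        union = np.ones(12, dtype=np.int8)
        res = doublet_test(union, "A", clones, ErrorRates(0.2, 0.01))
        assert res is not None
        assert res.partner_clone == "B"
        assert res.lr > 0
        assert res.is_doublet

    def test_boundary_rates_skip_test(self):
        clones = self._clones()
        union = np.ones(12, dtype=np.int8)
        assert doublet_test(union, "A", clones, ErrorRates(0.0, 0.0)) is None

    def test_lr_is_twice_loglik_difference(self):
        clones = self._clones()
        cell = np.array([1] * 6 + [1, 1] + [0] * 4, dtype=np.int8)
        res = doublet_test(cell, "A", clones, ErrorRates(0.2, 0.01))
        union = np.where((clones["A"] == MUT) | (clones["B"] == MUT), MUT, WILD)
        lnl_s = loglik_oracle(cell, clones["A"], 0.2, 0.01)
        lnl_d = loglik_oracle(cell, union.astype(np.int8), 0.2, 0.01)
        assert res.lr == pytest.approx(2 * (lnl_d - lnl_s))

    def test_simulated_doublets_detected(self):
        import tophapplus as tp
        cfg = tp.SimulationConfig(n_clones=6, n_snvs=60, n_cells=300, seed=3,
                                  doublet_rate=0.15, fpr=0.01, fnr=0.2,
                                  missing_rate=0.2, clone_frequency_scheme="uniform")
        obs, gt = tp.simulate_dataset(cfg)
        clones = {c: gt.true_tree.genotypes[c] for c in gt.clone_ids}
        clones[GERMLINE] = np.zeros(60, dtype=np.int8)
        a = assign_cells(obs, clones, obs.site_ids)
        rates = estimate_error_rates(obs, a, clones, obs.site_ids)
        out = run_doublet_tests(obs, a, clones, obs.site_ids, rates)
        flagged = set(out[out["clone"] == DOUBLET]["cell"])
        # doublets merging distinct clones with >=5 private mutations each
        strong = set()
        for cell, (ca, cb) in gt.doublet_cells.items():
            if ca == cb:
                continue
            ga, gb = gt.true_tree.genotypes[ca], gt.true_tree.genotypes[cb]
            if ((ga == MUT) & (gb == WILD)).sum() >= 5 and ((gb == MUT) & (ga == WILD)).sum() >= 5:
                strong.add(cell)
        assert strong
        recall = len(strong & flagged) / len(strong)
        assert recall >= 0.8
        # false-flag rate among true singletons stays far below recall; the
        # adaptive partner choice (maximised over clones) inflates the
        # nominal 1% level by up to the clone count
        singletons = set(obs.cell_ids) - set(gt.doublet_cells)
        fp_rate = len(flagged & singletons) / len(singletons)
        assert fp_rate <= 0.10


class TestFinalize:
    def test_all_supported_isomorphic(self):
        t = _tree({"A": (GERMLINE, [("a", GAIN)]), "B": ("A", [("d", GAIN)])},
                  ["a", "d"])
        a = pd.DataFrame({"cell": ["c1", "c2"], "clone": ["A", "B"],
                          "similarity": [1.0, 1.0]})
        out, counts = finalize_clone_phylogeny(t, a)
        assert set(out.preorder()) == {GERMLINE, "A", "B"}
        assert counts == {GERMLINE: 0, "A": 1, "B": 1}

    def test_zero_cell_tip_dropped(self):
        t = _tree({"A": (GERMLINE, [("a", GAIN)]), "B": ("A", [("d", GAIN)])},
                  ["a", "d"])
        a = pd.DataFrame({"cell": ["c1", "c2"], "clone": ["A", DOUBLET],
                          "similarity": [1.0, 1.0]})
        out, counts = finalize_clone_phylogeny(t, a)
        assert "B" not in out.parent
        assert counts == {GERMLINE: 0, "A": 1}

    def test_germline_cells_counted(self):
        t = _tree({"A": (GERMLINE, [("a", GAIN)])}, ["a"])
        a = pd.DataFrame({"cell": ["c1", "c2"], "clone": [GERMLINE, "A"],
                          "similarity": [1.0, 1.0]})
        out, counts = finalize_clone_phylogeny(t, a)
        assert counts[GERMLINE] == 1
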