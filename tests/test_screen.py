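"""Statistical core: AUC, Mann-Whitney, fold change, Bonferroni, screens."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

import iciscreen as ic
from iciscreen.screen import _mwu_asymptotic_batch, _screen_values


# --- independent oracles -----------------------------------------------------

def brute_force_auc(nonresp, resp):
    """Pair enumeration: P(nr > r) + 0.5 P(nr == r)."""
    pairs = [(a > b) + 0.5 * (a == b) for a in nonresp for b in resp]
    return sum(pairs) / (len(nonresp) * len(resp))


def enumerate_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label permutations."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    ranks = scipy.stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    total = 0
    count = 0
    for subset in combinations(range(n1 + n2), n1):
        u = sum(ranks[list(subset)]) - n1 * (n1 + 1) / 2
        total += 1
        if (u >= u_obs) if u_obs >= mu else (u <= u_obs):
            count += 1
    return min(1.0, 2 * count / total)


# --- roc_auc -----------------------------------------------------------------

class TestRocAuc:
    def test_complete_separation(self):
        assert ic.roc_auc([3, 4, 5], [1, 2]) == 1.0

    def test_all_ties(self):
        assert ic.roc_auc([5, 5], [5, 5]) == 0.5

    def test_interleaved_brute_force(self):
        nr, r = [2, 4, 6, 8], [1, 3, 5, 7]
        assert ic.roc_auc(nr, r) == 10 / 16
        assert ic.roc_auc(nr, r) == brute_force_auc(nr, r)

    def test_empty_group_rejected(self):
        with pytest.raises(ic.ValidationError):
            ic.roc_auc([], [1.0])

    @given(
        st.lists(st.integers(0, 12), min_size=1, max_size=12),
        st.lists(st.integers(0, 12), min_size=1, max_size=12),
    )
    def test_matches_brute_force_and_antisymmetry(self, a, b):
        auc = ic.roc_auc(a, b)
        assert auc == pytest.approx(brute_force_auc(a, b), abs=1e-12)
        assert auc + ic.roc_auc(b, a) == pytest.approx(1.0, abs=1e-12)


# --- mann_whitney ------------------------------------------------------------

class TestMannWhitney:
    def test_small_sample_exact(self):
        u, p = ic.mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(enumerate_exact_p([4, 5, 6], [1, 2, 3]), abs=1e-12)

    def test_total_ties(self):
        assert ic.mann_whitney([5, 5], [5, 5]) == (2.0, 1.0)

    def test_u_from_auc_identity_example(self):
        u, _ = ic.mann_whitney([2, 4, 6, 8], [1, 3, 5, 7])
        assert u == 0.625 * 16

    @given(
        st.lists(st.integers(-20, 20), min_size=2, max_size=40),
        st.lists(st.integers(-20, 20), min_size=2, max_size=40),
    )
    def test_u_auc_identity_with_ties(self, a, b):
        u, _ = ic.mann_whitney(a, b)
        assert u == pytest.approx(ic.roc_auc(a, b) * len(a) * len(b), abs=1e-9)

    @given(
        st.lists(st.integers(-30, 30), min_size=3, max_size=25).filter(
            lambda r: len(set(r)) == len(r)
        ),
    )
    def test_monotone_transform_invariance(self, pooled):
        """Any strictly increasing transform leaves U, p and AUC unchanged."""
        half = len(pooled) // 2
        a, b = pooled[:half], pooled[half:]
        if not a or not b:
            return
        fa = np.arctan(np.array(a, float) / 10)
        fb = np.arctan(np.array(b, float) / 10)
        assert ic.mann_whitney(a, b) == ic.mann_whitney(fa, fb)
        assert ic.roc_auc(a, b) == ic.roc_auc(fa, fb)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (8, 8), (2, 8)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(3):
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            _, p = ic.mann_whitney(x, y)
            assert p == pytest.approx(enumerate_exact_p(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        """Asymptotic p within 0.03 of exact enumeration, exhaustively.

        Checked over every achievable U for tie-free groups of 5..8
        observations each (the approximation degrades below that: the
        worst-case gap is 0.031 at 4 per group and 0.088 at 2 per group,
        which is why the exact method is used whenever it applies).
        """
        worst = 0.0
        for n1 in range(5, 9):
            for n2 in range(n1, 9):
                ranks = np.arange(1, n1 + n2 + 1)
                null = np.array([sum(c) - n1 * (n1 + 1) / 2
                                 for c in combinations(ranks, n1)])
                mu, sd = n1 * n2 / 2, np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
                for u in range(n1 * n2 + 1):
                    tail = (null >= u).sum() if u >= mu else (null <= u).sum()
                    exact = min(1.0, 2 * tail / null.size)
                    z = (max(u, n1 * n2 - u) - mu - 0.5) / sd
                    approx = min(1.0, 2 * scipy.stats.norm.sf(z))
                    worst = max(worst, abs(approx - exact))
        assert worst <= 0.03

    def test_batch_asymptotic_matches_scalar(self):
        """The vectorized screening path reproduces scipy row by row."""
        rng = np.random.default_rng(9)
        X = np.round(rng.lognormal(1, 1, size=(40, 30)), 1)  # ties present
        n1 = 13
        u, p = _mwu_asymptotic_batch(X, n1)
        for i in range(X.shape[0]):
            res = scipy.stats.mannwhitneyu(X[i, :n1], X[i, n1:],
                                           alternative="two-sided",
                                           method="asymptotic")
            assert u[i] == pytest.approx(res.statistic, abs=1e-9)
            assert p[i] == pytest.approx(res.pvalue, abs=1e-12)


# --- fold change & threshold -------------------------------------------------

class TestFoldChange:
    def test_resistance_orientation(self):
        assert ic.fold_change([22, 22], [10, 10]) == (2.2, ic.HIGHER_IN_NONRESPONDER)

    def test_equal_means_tie(self):
        assert ic.fold_change([5, 15], [10, 10]) == (1.0, ic.TIE)

    def test_sensitivity_orientation(self):
        fc, direction = ic.fold_change([10, 10], [15, 15])
        assert fc == pytest.approx(1.5)
        assert direction == ic.HIGHER_IN_RESPONDER

    def test_zero_mean_rejected(self):
        with pytest.raises(ic.ValidationError):
            ic.fold_change([0, 0], [1, 2])


class TestBonferroni:
    @pytest.mark.parametrize("m,display", [
        (29755, "1.6E-06"),
        (26819, "1.8E-06"),
        (22561, "2.2E-06"),
        (1, "5.0E-02"),
    ])
    def test_display_truncation(self, m, display):
        exact, disp = ic.bonferroni_threshold(m, 0.05)
        assert disp == display
        assert exact == 0.05 / m

    def test_invalid_inputs(self):
        with pytest.raises(ic.ValidationError):
            ic.bonferroni_threshold(0)
        with pytest.raises(ic.ValidationError):
            ic.bonferroni_threshold(10, alpha=1.5)


# --- cohort screens ----------------------------------------------------------

class TestScreenCohort:
    def test_worked_example_hand_values(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        r = res.get("RES1")
        assert r.auc == 1.0
        assert r.direction == ic.HIGHER_IN_NONRESPONDER
        assert r.u_statistic == 25
        assert r.p_raw == pytest.approx(2 / 252, abs=1e-12)  # exact enumeration
        s = res.get("SEN1")
        assert s.auc == pytest.approx(0.88)
        assert s.direction == ic.HIGHER_IN_RESPONDER
        n = res.get("NULL1")
        assert n.auc == 0.5 and n.direction == ic.TIE and n.p_raw == 1.0
        assert n.fold_change == 1.0

    def test_missing_gene_tested_on_available_samples(self, pd1_pre_cohort):
        # EXTRA1 exists only in dataset WX1: 3 responders / 3 non-responders
        r = ic.screen_cohort(pd1_pre_cohort).get("EXTRA1")
        assert (r.n_responder, r.n_nonresponder) == (3, 3)

    def test_min_class_size_excludes_sparse_genes(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort, min_class_size=4)
        assert "EXTRA1" in res.untested
        assert res.m_tested == 5

    def test_gene_filter_changes_m_and_threshold(self, pd1_pre_cohort):
        whitelist = {"RES1", "SEN1", "NULL1", "VAR1"}
        res = ic.screen_cohort(pd1_pre_cohort, gene_filter=whitelist)
        assert res.m_tested == 4
        assert res.threshold == 0.05 / 4
        assert {r.gene for r in res.results} == whitelist

    def test_gene_filter_predicate(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort,
                               gene_filter=lambda g: not g.startswith("NULL"))
        assert "NULL1" not in {r.gene for r in res.results}

    def test_significance_consistent_with_threshold(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        for r in res.results:
            assert r.significant == (r.p_raw <= res.threshold)
        assert res.threshold * res.m_tested == pytest.approx(res.alpha)

    def test_u_bounded_by_group_product(self, pd1_pre_cohort):
        for r in ic.screen_cohort(pd1_pre_cohort).results:
            assert 0 <= r.u_statistic <= r.n_responder * r.n_nonresponder

    def test_planted_marker_recovered(self):
        """A strong planted marker is significant among hundreds of null genes."""
        ds = ic.DatasetConfig("D", 120, responder_fraction=0.5,
                              outcome_mode="recist_only", censoring_fraction=0.0,
                              drug_class_probs=(1.0, 0.0, 0.0, 0.0),
                              timing_pre_fraction=1.0, balanced_labels=True)
        cfg = ic.SyntheticConfig(seed=3, n_genes=500, datasets=[ds],
                                 planted_markers=[ic.PlantedMarker("MARK", 0.95)])
        db = ic.simulate_database(cfg)
        labels, _ = ic.label_cohort(db.annotations)
        cohort = ic.build_cohort(ic.merge_datasets(db.matrices), db.annotations,
                                 labels, ic.CohortSpec("anti-PD-1", "pre-treatment"))
        res = ic.screen_cohort(cohort)
        r = res.get("MARK")
        assert r.significant
        assert r.auc == pytest.approx(0.95, abs=0.06)
        assert r.direction == ic.HIGHER_IN_NONRESPONDER


class TestEvaluatePanel:
    def test_absent_gene_reported_untested(self, pd1_pre_cohort):
        res = ic.evaluate_panel(pd1_pre_cohort, ["RES1", "SEN1", "NOPE"])
        assert res.m_tested == 2
        assert res.threshold == 0.05 / 2
        assert "NOPE" in res.untested

    def test_full_panel_reduces_to_screen(self, pd1_pre_cohort):
        full = ic.screen_cohort(pd1_pre_cohort)
        panel = ic.evaluate_panel(pd1_pre_cohort, list(pd1_pre_cohort.values.index))
        assert panel.m_tested == full.m_tested
        assert {(r.gene, r.p_raw, r.auc) for r in panel.results} == \
               {(r.gene, r.p_raw, r.auc) for r in full.results}

    def test_sensitivity_marker_direction(self, pd1_pre_cohort):
        r = ic.evaluate_panel(pd1_pre_cohort, ["SEN1"]).get("SEN1")
        assert r.direction == ic.HIGHER_IN_RESPONDER
        assert r.auc > 0.5

    def test_no_panel_gene_present_rejected(self, pd1_pre_cohort):
        with pytest.raises(ic.ValidationError):
            ic.evaluate_panel(pd1_pre_cohort, ["NOPE1", "NOPE2"])


class TestRankAgainst:
    def test_maximal_gene_ranks_zero(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        assert ic.rank_against(res, "RES1") == 0

    def test_counts_match_sort_oracle(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        aucs = {r.gene: r.auc for r in res.results}
        for gene, auc in aucs.items():
            expected = sum(1 for g, a in aucs.items() if g != gene and a > auc)
            assert ic.rank_against(res, gene) == expected

    def test_untested_gene_rejected(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        with pytest.raises(ic.ValidationError):
            ic.rank_against(res, "NOPE")


class TestAnnotateDruggable:
    def make_screen(self, n_sig=7, n_drug=3):
        results = []
        for i in range(10):
            sig = i < n_sig
            results.append(ic.GeneResult(
                f"G{i}", 5, 5, 20.0, 0.8, ic.HIGHER_IN_NONRESPONDER,
                (i + 1) * 1e-6 if sig else 0.5, 1.5, sig,
            ))
        screen = ic.ScreenResult(None, 10, 0.05, 5e-3, "5.0E-03", results)
        druggable = {f"G{i}" for i in range(0, 10, 3)}  # G0 G3 G6 among sig, G9 not sig
        return screen, druggable

    def test_summary_is_significant_druggable_resistance(self):
        screen, druggable = self.make_screen()
        hits = ic.annotate_druggable(screen, druggable)
        assert [r.gene for r in hits] == ["G0", "G3", "G6"]  # p ascending
        assert all(r.druggable for r in hits)

    def test_empty_druggable_set(self):
        screen, _ = self.make_screen()
        hits = ic.annotate_druggable(screen, set())
        assert hits == []
        assert all(r.druggable is False for r in screen.results)


class TestResponseScreen:
    def test_sklearn_contract(self):
        from sklearn.utils.estimator_checks import check_estimator  # noqa: F401
        est = ic.ResponseScreen(alpha=0.01, min_class_size=2)
        assert est.get_params() == {"alpha": 0.01, "min_class_size": 2}
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05

    def test_fit_transform_selects_significant(self):
        rng = np.random.default_rng(0)
        n = 60
        X = pd.DataFrame(rng.lognormal(0, 1, (n, 20)),
                         columns=[f"g{i}" for i in range(20)])
        y = np.array([1] * 30 + [0] * 30)
        X.loc[y == 0, "g0"] *= 50  # strong resistance marker
        scr = ic.ResponseScreen().fit(X, y)
        assert scr.m_tested_ == 20
        assert scr.results_.loc["g0", "significant"]
        assert scr.results_.loc["g0", "direction"] == ic.HIGHER_IN_NONRESPONDER
        kept = scr.transform(X)
        assert "g0" in kept.columns
        assert kept.shape[1] == scr.get_support().sum()

    def test_string_labels_accepted(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 1, (20, 5))
        y = [ic.RESPONDER] * 10 + [ic.NON_RESPONDER] * 10
        scr = ic.ResponseScreen().fit(X, y)
        assert scr.m_tested_ == 5

    def test_agrees_with_screen_cohort(self, pd1_pre_cohort):
        res = ic.screen_cohort(pd1_pre_cohort)
        X = pd1_pre_cohort.values.T
        scr = ic.ResponseScreen().fit(X, pd1_pre_cohort.y.values)
        for r in res.results:
            row = scr.results_.loc[r.gene]
            assert row["p_raw"] == pytest.approx(r.p_raw, abs=1e-15)
            assert row["auc"] == pytest.approx(r.auc, abs=1e-15)


def test_screen_rejects_single_class():
    values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
    y = pd.Series({"a": ic.RESPONDER, "b": ic.RESPONDER})
    with pytest.raises(ic.ValidationError):
        _screen_values(values, y)
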