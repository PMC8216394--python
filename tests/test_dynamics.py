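import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repdx.dynamics import (
    PairedRepertoire,
    detect_expanded_clones,
    jaccard_similarity,
    pearson_similarity,
    shared_expanded_clones,
    similarity_vs_covariate,
    storey_qvalues,
    top_clone_persistence,
)

from conftest import _cdr3, make_repertoire


def make_pair(pre_counts, post_counts, shared=None, weeks=9.0):
    """Pair with the first ``shared`` clones (default: all of the shorter
    list) carrying identical identities in pre and post."""
    n_shared = min(len(pre_counts), len(post_counts)) if shared is None else shared
    pre = make_repertoire(pre_counts, sample_id="P_pre")
    post_cdr3s = [_cdr3(i) for i in range(n_shared)] + [
        _cdr3(1000 + i) for i in range(len(post_counts) - n_shared)
    ]
    post = make_repertoire(
        post_counts, sample_id="P_post", timepoint_weeks=weeks, cdr3s=post_cdr3s
    )
    return PairedRepertoire(patient_id="P", pre=pre, post=post, elapsed_weeks=weeks)


def hypergeom_fisher_p(a, b, c, d):
    """Independent oracle: two-sided Fisher p by enumerating the
    hypergeometric distribution of the 2x2 table with fixed margins."""
    n1, n2 = a + b, c + d
    k = a + c
    xs = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = stats.hypergeom.pmf(xs, n1 + n2, n1, k)
    obs = stats.hypergeom.pmf(a, n1 + n2, n1, k)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = make_repertoire([3, 2, 1])
        assert jaccard_similarity(a, a) == 1.0
        b = make_repertoire([3, 2], cdr3s=[_cdr3(500), _cdr3(501)])
        assert jaccard_similarity(a, b) == 0.0

    def test_partial_overlap(self):
        # {0,1,2} vs {1,2,3} -> 2/4
        a = make_repertoire([1, 1, 1], cdr3s=[_cdr3(i) for i in (0, 1, 2)])
        b = make_repertoire([1, 1, 1], cdr3s=[_cdr3(i) for i in (1, 2, 3)])
        assert jaccard_similarity(a, b) == 0.5
        assert jaccard_similarity(b, a) == 0.5  # symmetric


class TestPearson:
    def test_self_correlation_is_one(self):
        a = make_repertoire([5, 4, 3, 2, 1])
        assert pearson_similarity(a, a) == pytest.approx(1.0)

    def test_perfect_linear_relation(self):
        pair = make_pair([10, 20, 40, 100], [20, 40, 80, 200])
        assert pearson_similarity(
            pair.pre, pair.post, transform="identity"
        ) == pytest.approx(1.0)

    def test_reversed_frequencies_hand_value(self):
        # pre (0.5, 0.3, 0.2) vs post (0.2, 0.3, 0.5): r = -13/14 by direct
        # evaluation of the Pearson formula
        pair = make_pair([5, 3, 2], [2, 3, 5])
        r = pearson_similarity(pair.pre, pair.post, transform="identity")
        assert r == pytest.approx(-13 / 14, abs=1e-9)

    def test_too_few_shared_clones_errors(self):
        pair = make_pair([5, 3], [2, 3])
        with pytest.raises(ValueError, match="aligned"):
            pearson_similarity(pair.pre, pair.post)


class TestTopClonePersistence:
    def test_identical_pair_delta_zero(self):
        pair = make_pair([5, 3, 2], [5, 3, 2])
        res = top_clone_persistence(pair, k=2)
        assert res["delta"] == pytest.approx(0.0)

    def test_vanished_top_clones(self):
        pair = make_pair([5, 3, 2], [1, 1], shared=0)
        res = top_clone_persistence(pair, k=2)
        assert res["post_abundance_of_same_clones"] == 0.0
        assert res["delta"] == pytest.approx(-res["pre_topk_abundance"])

    def test_partial_persistence(self):
        # pre top-2 = {clone0: 0.3, clone1: 0.2}; post has clone0 at 0.1 only
        pre = make_repertoire([30, 20, 50], cdr3s=[_cdr3(0), _cdr3(1), _cdr3(2)])
        post = make_repertoire(
            [10, 90], cdr3s=[_cdr3(0), _cdr3(99)], timepoint_weeks=9.0
        )
        # clone2 (0.5) is rank 1, clone0 (0.3) rank 2; use k=2 over those
        pair = PairedRepertoire("P", pre, post, 9.0)
        res = top_clone_persistence(pair, k=2)
        assert res["pre_topk_abundance"] == pytest.approx(0.8)
        assert res["post_abundance_of_same_clones"] == pytest.approx(0.1)
        assert res["delta"] == pytest.approx(-0.7)

    def test_post_abundance_bounded(self):
        pair = make_pair([4, 3, 2, 1], [1, 2, 3, 4])
        res = top_clone_persistence(pair, k=4)
        assert res["post_abundance_of_same_clones"] <= 1.0


class TestExpansionCalls:
    def test_fisher_example_1_vs_9_of_10(self):
        pair = make_pair([1, 9], [9, 1])
        calls = detect_expanded_clones(pair, min_count=1)
        p = calls.set_index("cdr3_nt")["p_value"].iloc[0]
        assert p == pytest.approx(hypergeom_fisher_p(1, 9, 9, 1), rel=1e-9)
        assert p == pytest.approx(0.0010926, rel=1e-3)

    def test_no_change_is_not_significant(self):
        pair = make_pair([50, 50], [50, 50])
        calls = detect_expanded_clones(pair, min_count=1)
        assert (calls["p_value"] == 1.0).all()
        assert not calls["significant"].any()
        assert (calls["direction"] == "none").all()

    def test_novel_dominant_clone_called_expanded(self):
        pre_counts = [1] + [111] * 9  # clone0 nearly absent pre
        post_counts = [50] + [105] * 9
        pair = make_pair(pre_counts, post_counts)
        calls = detect_expanded_clones(pair, min_count=1).set_index("cdr3_nt")
        nt0, _ = _cdr3(0)
        assert calls.loc[nt0, "direction"] == "expanded"
        assert calls.loc[nt0, "significant"]

    def test_q_values_dominate_p_and_alpha_monotonicity(self):
        rng = np.random.default_rng(5)
        pair = make_pair(list(rng.integers(1, 400, 40)), list(rng.integers(1, 400, 40)))
        calls = detect_expanded_clones(pair, min_count=1)
        assert (calls["q_value"] >= calls["p_value"] - 1e-12).all()
        n_strict = detect_expanded_clones(pair, alpha=0.01, min_count=1)["significant"].sum()
        n_loose = detect_expanded_clones(pair, alpha=0.10, min_count=1)["significant"].sum()
        assert n_strict <= n_loose

    def test_fisher_matches_hypergeometric_oracle_small_tables(self):
        # subset here; the exhaustive sweep lives in the acceptance suite
        for a, b, c, d in [(0, 5, 5, 0), (2, 3, 1, 4), (1, 9, 9, 1), (3, 3, 3, 3)]:
            p_impl = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p_impl == pytest.approx(hypergeom_fisher_p(a, b, c, d), rel=1e-9)

    def test_storey_qvalues_bounded_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestSharedExpanded:
    def _calls(self, sig_aa):
        return pd.DataFrame(
            {
                "cdr3_nt": ["TGCGCA"],
                "v_gene": ["TRBV15"],
                "j_gene": ["TRBJ1-3"],
                "cdr3_aa": [sig_aa],
                "significant": [True],
                "direction": ["expanded"],
            }
        )

    def test_clone_shared_by_two_patients(self):
        calls = {"P1": self._calls("CASSLGQGNTEAFF"), "P2": self._calls("CASSLGQGNTEAFF")}
        out = shared_expanded_clones(calls, min_patients=2)
        assert len(out) == 1
        assert out.iloc[0]["patients"] == "P1,P2"

    def test_private_clone_excluded(self):
        calls = {"P1": self._calls("CASSLGQGNTEAFF"), "P2": self._calls("CASSOTHER")}
        assert len(shared_expanded_clones(calls, min_patients=2)) == 0

    def test_empty_input(self):
        assert len(shared_expanded_clones({}, min_patients=2)) == 0


class TestSimilarityVsCovariate:
    def test_monotone_decreasing_gives_rho_minus_one(self):
        sim = pd.Series([0.9, 0.7, 0.5, 0.3], index=list("abcd"))
        weeks = pd.Series([3, 6, 9, 12], index=list("abcd"))
        rho, _ = similarity_vs_covariate(sim, weeks)
        assert rho == pytest.approx(-1.0)

    def test_identical_groups_not_significant(self):
        sim = pd.Series([0.5, 0.6, 0.5, 0.6], index=list("abcd"))
        therapy = pd.Series(
            ["single", "single", "combo", "combo"], index=list("abcd")
        )
        _, p = similarity_vs_covariate(sim, therapy)
        assert p > 0.5

    def test_constant_covariate_errors(self):
        sim = pd.Series([0.5, 0.6, 0.7], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            similarity_vs_covariate(sim, pd.Series([9, 9, 9], index=list("abc")))
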