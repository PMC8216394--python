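import itertools

import numpy as np
import pandas as pd
import pytest

from repdx.panel import (
    ANALYTES,
    SIGNATURE_1_MEMBERS,
    SignatureDefinition,
    baseline_comparison,
    canonical_analyte,
    correlation_clusters,
    default_signature1,
    fold_change,
    metric_analyte_association,
    qc_filter,
    signature_direction_groups,
    signature_score,
    ssgsea_score,
)


def naive_ssgsea(values_in_order, in_set_mask, alpha=0.25):
    """Index-wise loop oracle for the ssGSEA running sum: genes given in
    descending-expression order, weight = (N - position)**alpha."""
    n = len(values_in_order)
    w = [(n - i) ** alpha for i in range(n)]
    sum_in = sum(wi for wi, m in zip(w, in_set_mask) if m)
    n_out = sum(1 for m in in_set_mask if not m)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in range(n):
        if in_set_mask[i]:
            cum_in += w[i] / sum_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


def test_panel_vocabulary():
    assert len(ANALYTES) == 30
    assert len(SIGNATURE_1_MEMBERS) == 17
    sig = default_signature1()
    assert set(sig.members) <= set(ANALYTES)
    assert len(sig.subset("co_inhibitory")) == 5


def test_analyte_name_aliases():
    assert canonical_analyte("sIL-2Rα") == "sIL-2Ra"
    assert canonical_analyte("sCTLA4") == "sCTLA-4"
    assert canonical_analyte("SPD-L1") == "sPD-L1"
    with pytest.raises(KeyError):
        canonical_analyte("sNOTREAL")


class TestQcFilter:
    def test_cv_rule(self):
        panel = pd.DataFrame({"sCD27": [100.0], "sPD-1": [50.0], "sCD30": [30.0]})
        cv = pd.Series({"sCD27": 12.0, "sPD-1": 10.0, "sCD30": 3.0})
        with pytest.warns(UserWarning, match="sCD27"):
            out = qc_filter(panel, cv, max_cv=10.0)
        assert list(out.columns) == ["sPD-1", "sCD30"]  # exactly 10% retained

    def test_all_pass_is_identity(self):
        panel = pd.DataFrame({"sCD27": [100.0], "sCD30": [30.0]})
        cv = pd.Series({"sCD27": 5.0, "sCD30": 3.0})
        assert qc_filter(panel, cv).equals(panel)


class TestBaselineComparison:
    def test_constructed_ratio(self):
        ndb_vals = np.array([100.0, 110.0, 120.0, 130.0])
        panel = pd.DataFrame(
            {"sCD27": np.concatenate([ndb_vals * 1.1152, ndb_vals])},
            index=[f"P{i}" for i in range(8)],
        )
        labels = pd.Series(["DCB"] * 4 + ["NDB"] * 4, index=panel.index)
        out = baseline_comparison(panel, labels)
        assert out.iloc[0]["pct_diff"] == pytest.approx(11.52, abs=1e-9)

    def test_identical_groups(self):
        panel = pd.DataFrame({"sCD27": [1.0, 2.0, 1.0, 2.0]}, index=list("abcd"))
        labels = pd.Series(["DCB", "DCB", "NDB", "NDB"], index=panel.index)
        out = baseline_comparison(panel, labels)
        assert out.iloc[0]["pct_diff"] == 0.0
        assert out.iloc[0]["p_value"] > 0.5

    def test_single_patient_group_errors(self):
        panel = pd.DataFrame({"sCD27": [1.0, 2.0, 3.0]}, index=list("abc"))
        labels = pd.Series(["DCB", "NDB", "NDB"], index=panel.index)
        with pytest.raises(ValueError):
            baseline_comparison(panel, labels)


class TestFoldChange:
    def test_known_values(self):
        pre = pd.Series({"a": 10.0, "b": 7.0, "c": 100.0})
        post = pd.Series({"a": 20.0, "b": 7.0, "c": 25.0})
        fc = fold_change(pre, post)
        assert fc["a"] == pytest.approx(1.0)
        assert fc["b"] == pytest.approx(0.0)
        assert fc["c"] == pytest.approx(-2.0)

    def test_identity_is_zero(self):
        pre = pd.Series(np.linspace(1, 50, 10), index=[f"x{i}" for i in range(10)])
        assert np.allclose(fold_change(pre, pre), 0.0)

    def test_nonpositive_skipped_with_warning(self):
        pre = pd.Series({"a": 0.0, "b": 5.0})
        post = pd.Series({"a": 3.0, "b": 10.0})
        with pytest.warns(UserWarning, match="nonpositive"):
            fc = fold_change(pre, post)
        assert np.isnan(fc["a"]) and fc["b"] == pytest.approx(1.0)


class TestCorrelationClusters:
    def test_correlated_pair_vs_anticorrelated_singleton(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fc = pd.DataFrame({"A": x, "B": x + rng.normal(0, 0.1, 50), "C": -x})
        sigs = correlation_clusters(fc, min_r=0.6, min_size=1)
        by_size = sorted((set(s.members) for s in sigs), key=len, reverse=True)
        assert by_size[0] == {"A", "B"}
        assert {"C"} in by_size

    def test_independent_noise_mostly_singletons(self):
        rng = np.random.default_rng(1)
        fc = pd.DataFrame(
            rng.normal(size=(200, 8)), columns=[f"a{i}" for i in range(8)]
        )
        sigs = correlation_clusters(fc, min_r=0.6, min_size=1)
        sizes = [len(s.members) for s in sigs]
        assert max(sizes, key=sizes.count) == 1  # modal cluster size

    def test_two_perfectly_correlated_analytes(self):
        x = np.linspace(-1, 1, 20)
        fc = pd.DataFrame({"A": x, "B": 2 * x})
        sigs = correlation_clusters(fc, min_r=0.6)
        assert len(sigs) == 1 and set(sigs[0].members) == {"A", "B"}

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        fc = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"a{i}" for i in range(10)])
        sigs = correlation_clusters(fc, min_r=0.3, min_size=1)
        members = list(itertools.chain.from_iterable(s.members for s in sigs))
        assert sorted(members) == sorted(fc.columns)


class TestSignatureScore:
    def test_zscore_cohort_mean_zero(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.lognormal(size=(12, len(SIGNATURE_1_MEMBERS))),
            columns=SIGNATURE_1_MEMBERS,
        )
        score = signature_score(values, default_signature1())
        assert score.mean() == pytest.approx(0.0, abs=1e-12)

    def test_balanced_and_uniform_members(self):
        sig = SignatureDefinition("s", members=("a", "b"))
        # construct columns whose z-scores at patient 0 are +1 and -1
        values = pd.DataFrame({"a": [1.0, 0.0, -1.0], "b": [-1.0, 0.0, 1.0]})
        score = signature_score(values, sig)
        assert score.iloc[0] == pytest.approx(0.0)
        assert score.iloc[1] == pytest.approx(0.0)

    def test_no_members_present_errors(self):
        sig = SignatureDefinition("s", members=("zz",))
        with pytest.raises(ValueError):
            signature_score(pd.DataFrame({"a": [1.0]}), sig)


class TestSsgsea:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        expr = pd.Series(rng.normal(size=12), index=[f"g{i}" for i in range(12)])
        gene_set = {"g2", "g5", "g7"}
        s1 = ssgsea_score(expr, gene_set)
        s2 = ssgsea_score(np.exp(expr * 3) + 5, gene_set)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_top_gene_scores_higher_than_bottom_gene(self):
        expr = pd.Series(
            np.arange(10, 0, -1, dtype=float), index=[f"g{i}" for i in range(10)]
        )
        assert ssgsea_score(expr, {"g0"}) > ssgsea_score(expr, {"g9"})

    def test_matches_naive_running_sum_oracle(self):
        # score depends only on member rank positions, so sweeping all
        # position subsets covers every permutation of <= 8 genes
        for n in range(2, 9):
            expr = pd.Series(
                np.arange(n, 0, -1, dtype=float), index=[f"g{i}" for i in range(n)]
            )
            for k in (1, 2, 3):
                if k >= n:
                    continue
                for positions in itertools.combinations(range(n), k):
                    gene_set = {f"g{i}" for i in positions}
                    mask = [i in positions for i in range(n)]
                    assert ssgsea_score(expr, gene_set) == pytest.approx(
                        naive_ssgsea(expr.to_numpy(), mask), abs=1e-9
                    )

    def test_empty_intersection_errors(self):
        expr = pd.Series({"g1": 1.0})
        with pytest.raises(ValueError):
            ssgsea_score(expr, {"zz"})


class TestDirectionGroups:
    def test_signs(self):
        pre = pd.Series({"P1": 0.0, "P2": 0.5, "P3": 0.2})
        post = pd.Series({"P1": 0.4, "P2": 0.1, "P3": 0.2})
        with pytest.warns(UserWarning, match="zero"):
            out = signature_direction_groups(pre, post)
        assert out.to_dict() == {"P1": "upregulated", "P2": "downregulated"}


class TestMetricAnalyteAssociation:
    def test_exact_log_relation(self):
        analyte = pd.Series(np.exp([1.0, 2.0, 3.0, 4.0]), index=list("abcd"))
        metric = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, p = metric_analyte_association(metric, analyte)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_independent_pairs_have_small_r(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            metric = pd.Series(rng.normal(size=1000))
            analyte = pd.Series(rng.lognormal(size=1000))
            r, _ = metric_analyte_association(metric, analyte)
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            metric_analyte_association(
                pd.Series([1.0, 2.0], index=list("ab")),
                pd.Series([1.0, 2.0], index=list("ab")),
            )
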