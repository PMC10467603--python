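import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prognosig.scoring import (
    RecurrenceScoreClassifier,
    Signature,
    SignatureGene,
    classify_high_low,
    gene_point,
    oncotype_rs_u,
    recurrence_scores,
    score_based_oncotype,
)

from conftest import tiny_cohort
from oracles import exhaustive_cutpoint


class TestGenePoint:
    @pytest.mark.parametrize(
        "x, cutoff, direction, expected",
        [
            (5.01, 5.0, "unfavorable", 1),
            (4.99, 5.0, "unfavorable", 0),
            (5.01, 5.0, "favorable", 0),
            (4.99, 5.0, "favorable", 1),
            (5.0, 5.0, "unfavorable", 0),  # equality scores 0 in both directions
            (5.0, 5.0, "favorable", 0),
        ],
    )
    def test_strict_cutoff_rule(self, x, cutoff, direction, expected):
        assert gene_point(x, cutoff, direction) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_direction_flip_partitions_points(self, x, cutoff):
        """Away from the cut-off, exactly one direction earns the point."""
        total = gene_point(x, cutoff, "unfavorable") + gene_point(x, cutoff, "favorable")
        assert total == (0 if x == cutoff else 1)


class TestSignature:
    def test_packaged_15_gene_composition(self):
        sig = Signature.packaged("15gene")
        assert len(sig) == 15
        unfav = [g.gene for g in sig.genes if g.direction == "unfavorable"]
        fav = [g.gene for g in sig.genes if g.direction == "favorable"]
        assert len(unfav) == 9 and len(fav) == 6
        assert "JUP" in unfav and "ATOH1" in fav

    def test_json_round_trip(self, tmp_path):
        sig = Signature.packaged("15gene")
        sig.cutoffs["c"] = {g: 0.5 for g in sig.gene_names}
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = Signature.from_json(path)
        assert back.gene_names == sig.gene_names
        assert back.cutoffs == sig.cutoffs

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            Signature(genes=[SignatureGene("A", "favorable"), SignatureGene("A", "favorable")])


def scored_signature(n_unfav=9, n_fav=6, cohort_name="c"):
    """Signature with frozen cut-offs at 0 for direct score arithmetic."""
    genes = [SignatureGene(f"U{i}", "unfavorable") for i in range(n_unfav)]
    genes += [SignatureGene(f"F{i}", "favorable") for i in range(n_fav)]
    sig = Signature(genes=genes)
    sig.cutoffs[cohort_name] = {g.gene: 0.0 for g in sig.genes}
    return sig


def cohort_from_matrix(expr: pd.DataFrame, name="c"):
    n = expr.shape[1]
    rng = np.random.default_rng(0)
    clinical = pd.DataFrame(
        {"rfs_time_months": rng.uniform(10, 100, n), "rfs_event": rng.integers(0, 2, n)},
        index=expr.columns,
    )
    for col in ("os_time_months", "os_event", "pt", "grade", "msi", "kras", "age", "sex"):
        clinical[col] = np.nan
    from prognosig.cohorts import make_cohort

    return make_cohort(name, expr, clinical)


class TestRecurrenceScores:
    def test_extreme_samples_hit_bounds(self):
        sig = scored_signature()
        genes = sig.gene_names
        # worst: all unfavorable high, all favorable low; best: the reverse
        expr = pd.DataFrame(
            {"worst": [1.0] * 9 + [-1.0] * 6, "best": [-1.0] * 9 + [1.0] * 6},
            index=genes,
        )
        extra = {f"s{i}": np.zeros(15) for i in range(10)}  # pad for cohort rules
        expr = pd.concat([expr, pd.DataFrame(extra, index=genes)], axis=1)
        cohort = cohort_from_matrix(expr)
        scores = recurrence_scores(sig, cohort, frozen=True)
        assert scores["worst"] == 15  # the 0..15 range of a 15-gene signature
        assert scores["best"] == 0
        assert scores.between(0, 15).all()

    def test_partial_points_add_up(self):
        sig = scored_signature()
        vals = np.r_[np.where(np.arange(9) < 5, 1.0, -1.0), np.where(np.arange(6) < 2, -1.0, 1.0)]
        expr = pd.DataFrame({"s": vals}, index=sig.gene_names)
        expr = pd.concat(
            [expr, pd.DataFrame({f"p{i}": np.zeros(15) for i in range(10)}, index=sig.gene_names)],
            axis=1,
        )
        scores = recurrence_scores(sig, cohort_from_matrix(expr), frozen=True)
        assert scores["s"] == 5 + 2

    def test_missing_gene_named_in_error(self):
        sig = scored_signature()
        expr = pd.DataFrame(
            np.zeros((5, 12)), index=[f"U{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        with pytest.raises(KeyError, match="U5"):
            recurrence_scores(sig, cohort_from_matrix(expr), frozen=True)

    def test_direction_flip_conserves_score_total(self, rng):
        """score(sig) + score(flipped sig) = |genes| off-cutoff."""
        sig = scored_signature()
        flipped = Signature(
            genes=[
                SignatureGene(g.gene, "favorable" if g.direction == "unfavorable" else "unfavorable")
                for g in sig.genes
            ]
        )
        flipped.cutoffs["c"] = sig.cutoffs["c"]
        expr = pd.DataFrame(
            rng.choice([-2.0, -1.0, 1.0, 2.0], size=(15, 20)),
            index=sig.gene_names,
            columns=[f"s{i}" for i in range(20)],
        )
        cohort = cohort_from_matrix(expr)
        total = recurrence_scores(sig, cohort, frozen=True) + recurrence_scores(
            flipped, cohort, frozen=True
        )
        assert (total == 15).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 14), st.floats(0.1, 3.0))
    def test_monotone_in_gene_expression(self, gene_idx, bump):
        """Raising an unfavorable gene never lowers a score; raising a
        favorable gene never raises it."""
        sig = scored_signature()
        rng = np.random.default_rng(123)
        expr = pd.DataFrame(
            rng.normal(size=(15, 12)), index=sig.gene_names,
            columns=[f"s{i}" for i in range(12)],
        )
        cohort = cohort_from_matrix(expr)
        before = recurrence_scores(sig, cohort, frozen=True)
        bumped = expr.copy()
        bumped.iloc[gene_idx] += bump
        after = recurrence_scores(sig, cohort_from_matrix(bumped), frozen=True)
        direction = sig.genes[gene_idx].direction
        diff = after - before
        assert (diff >= 0).all() if direction == "unfavorable" else (diff <= 0).all()


class TestClassifyHighLow:
    def test_bimodal_scores_cut_between_modes(self):
        scores = np.r_[np.zeros(10), np.full(10, 10)]
        time = np.r_[np.full(10, 100.0), np.full(10, 10.0)]
        event = np.r_[np.zeros(10, int), np.ones(10, int)]
        labels, cutoff = classify_high_low(scores, time, event)
        assert 0 < cutoff < 10
        assert labels.sum() == 10
        assert np.mean(scores[labels]) > np.mean(scores[~labels])  # high = larger scores

    def test_matches_exhaustive_integer_scan(self, rng):
        scores = rng.integers(0, 8, size=60).astype(float)
        time = rng.exponential(50, size=60)
        event = rng.integers(0, 2, size=60)
        if event.sum() == 0:
            event[0] = 1
        labels, cutoff = classify_high_low(scores, time, event)
        oracle_cut, _ = exhaustive_cutpoint(scores, time, event)
        assert cutoff == pytest.approx(oracle_cut)

    def test_constant_scores_rejected(self):
        with pytest.raises(Exception):
            classify_high_low(np.full(20, 3), np.arange(1, 21.0), np.ones(20, int))

    def test_bit_exact_reproducibility(self, rng):
        scores = rng.integers(0, 6, size=50).astype(float)
        time = rng.exponential(40, size=50)
        event = rng.integers(0, 2, size=50)
        event[0] = 1
        a = classify_high_low(scores, time, event)
        b = classify_high_low(scores, time, event)
        assert a[1] == b[1] and (a[0] == b[0]).all()


class TestOncotype:
    def test_equal_inputs_cancel(self):
        expr = pd.DataFrame(
            {f"s{i}": [2.0] * 7 for i in range(3)},
            index=["BGN", "FAP", "INHBA", "MYBL2", "KI67", "MYC", "GADD45B"],
        )
        assert oncotype_rs_u(expr).eq(0.0).all()

    def test_printed_formula_arithmetic(self):
        expr = pd.DataFrame(
            {"s": [2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 3.0]},
            index=["BGN", "FAP", "INHBA", "MYBL2", "KI67", "MYC", "GADD45B"],
        )
        assert oncotype_rs_u(expr)["s"] == pytest.approx(0.15 * 2 - 0.3 * 1 + 0.15 * 3)
        assert oncotype_rs_u(expr)["s"] == pytest.approx(0.45)
        assert oncotype_rs_u(2 * expr)["s"] == pytest.approx(0.90)  # linearity

    def test_mki67_alias_accepted(self):
        expr = pd.DataFrame(
            {"s": np.arange(7.0)},
            index=["BGN", "FAP", "INHBA", "MYBL2", "MKI67", "MYC", "GADD45B"],
        )
        assert np.isfinite(oncotype_rs_u(expr)["s"])

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame({"s": [1.0]}, index=["BGN"])
        with pytest.raises(KeyError):
            oncotype_rs_u(expr)

    def test_score_based_variant_bounds_and_ranking(self):
        cohort = tiny_cohort(
            seed=9, n=80,
            genes=("BGN", "FAP", "INHBA", "MYBL2", "MKI67", "MYC", "GADD45B"),
        )
        scores = score_based_oncotype(cohort)
        assert scores.between(0, 7).all()
        rs = oncotype_rs_u(cohort.expr)
        rho = pd.Series(scores).corr(pd.Series(rs), method="spearman")
        assert rho > 0  # both orderings agree on well-separated samples


class TestRecurrenceScoreClassifier:
    def test_fit_predict_on_planted_cohort(self):
        cohort = tiny_cohort(seed=3, n=120, genes=("JUP", "ATOH1", "CD2BP2"), effect=1.2)
        sig = Signature(
            genes=[SignatureGene("JUP", "unfavorable"), SignatureGene("ATOH1", "favorable"),
                   SignatureGene("CD2BP2", "unfavorable")]
        )
        clf = RecurrenceScoreClassifier(signature=sig)
        X = cohort.expr.T
        y = cohort.survival("RFS")
        clf.fit(X, y)
        assert set(clf.cutoffs_) == {"JUP", "ATOH1", "CD2BP2"}
        scores = clf.decision_function(X)
        assert scores.min() >= 0 and scores.max() <= 3
        pred = clf.predict(X)
        assert set(np.unique(pred)) == {0, 1}
        # high-score group should relapse more in a planted cohort
        t, e = y
        assert e[pred == 1].mean() > e[pred == 0].mean()

    def test_structured_survival_array_accepted(self):
        cohort = tiny_cohort(seed=4, n=60, genes=("JUP", "ATOH1"))
        t, e = cohort.survival("RFS")
        y = np.empty(t.size, dtype=[("event", bool), ("time", float)])
        y["event"] = e.astype(bool)
        y["time"] = t
        sig = Signature(genes=[SignatureGene("JUP", "unfavorable"), SignatureGene("ATOH1", "favorable")])
        clf = RecurrenceScoreClassifier(signature=sig).fit(cohort.expr.T, y)
        assert hasattr(clf, "score_cutoff_")

    def test_sklearn_param_interface(self):
        clf = RecurrenceScoreClassifier(minprop=0.2)
        assert clf.get_params()["minprop"] == 0.2
        clf.set_params(minprop=0.1)
        assert clf.minprop == 0.1
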