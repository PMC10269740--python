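import numpy as np
import pandas as pd
import pytest

from crcmb.core_io import FeatureTable, SampleMetadata
from crcmb.ordination import OrdinationResult
from crcmb.survival_models import (
    PerfectSeparationError,
    communality_select,
    compute_alr,
    lme_alr,
    loading_quartile_sets,
    logistic_survival,
    stratify_scores,
)
from conftest import make_metadata


def _ordination(loadings):
    loadings = np.asarray(loadings, dtype=float)
    n_feat, k = loadings.shape
    s = np.linspace(2.0, 1.0, k)
    return OrdinationResult(
        sample_ids=tuple(f"s{i}" for i in range(3)),
        feature_ids=tuple(f"f{j}" for j in range(n_feat)),
        sample_scores=np.zeros((3, k)),
        feature_loadings=loadings,
        singular_values=s,
        proportion_explained=s**2 / (s**2).sum(),
    )


class TestCommunality:
    def test_selects_above_threshold(self):
        ords = _ordination([[0.1, 0.0, 0.0], [0.0, 0.0, 0.0], [0.005, 0.005, 0.005]])
        assert communality_select(ords, 0.01) == ["f0"]

    def test_boundary_inclusive(self):
        ords = _ordination([[0.01, 0.0], [0.001, 0.0]])
        assert "f0" in communality_select(ords, 0.01)

    def test_formula(self):
        ords = _ordination([[3.0, 4.0]])
        # sqrt(9 + 16) = 5 >= anything reasonable
        assert communality_select(ords, 4.9) == ["f0"]

    def test_empty_selection_errors(self):
        ords = _ordination([[0.0, 0.0]])
        with pytest.raises(ValueError):
            communality_select(ords, 0.01)


class TestQuartileSets:
    def test_hand_quartiles(self):
        ords = _ordination([[-3.0], [-1.0], [0.0], [1.0], [3.0]])
        upper, lower = loading_quartile_sets(ords, 0, list(ords.feature_ids))
        assert upper == ["f4"] and lower == ["f0"]

    def test_symmetric_set_balanced(self):
        vals = [-4.0, -2.0, -1.0, 1.0, 2.0, 4.0]
        ords = _ordination([[v] for v in vals])
        upper, lower = loading_quartile_sets(ords, 0, list(ords.feature_ids))
        assert len(upper) == len(lower)

    def test_candidates_respected(self):
        ords = _ordination([[v] for v in [-9.0, -3.0, -1.0, 0.0, 1.0, 3.0, 9.0]])
        cands = ["f1", "f2", "f3", "f4", "f5"]
        upper, lower = loading_quartile_sets(ords, 0, cands)
        assert set(upper) | set(lower) <= set(cands)

    def test_degenerate_errors(self):
        ords = _ordination([[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError):
            loading_quartile_sets(ords, 0, list(ords.feature_ids))


class TestComputeAlr:
    def _table(self, counts, features):
        counts = np.asarray(counts)
        return FeatureTable(
            tuple(f"s{i}" for i in range(counts.shape[0])), tuple(features), counts
        )

    def test_balanced_zero(self):
        t = self._table([[4, 2, 7]], ("a", "b", "c"))
        # num (4+1)+(2+1)=8, den 7+1=8
        alr = compute_alr(t, ["a", "b"], ["c"])
        assert alr.values[0] == pytest.approx(0.0)

    def test_hand_value(self):
        t = self._table([[3, 4, 7]], ("a", "b", "c"))
        alr = compute_alr(t, ["a", "b"], ["c"])
        assert alr.values[0] == pytest.approx(np.log2(9 / 8))
        assert abs(alr.values[0] - 0.170) < 1e-3

    def test_empty_denominator_errors(self):
        t = self._table([[1, 2]], ("a", "b"))
        with pytest.raises(ValueError):
            compute_alr(t, ["a"], [])

    def test_overlap_errors(self):
        t = self._table([[1, 2]], ("a", "b"))
        with pytest.raises(ValueError):
            compute_alr(t, ["a"], ["a", "b"])

    def test_scale_invariance_pc0(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, (4, 5))
        feats = tuple("abcde")
        a1 = compute_alr(self._table(counts, feats), ["a", "b"], ["d"], pseudocount=0)
        a2 = compute_alr(self._table(counts * 9, feats), ["a", "b"], ["d"], pseudocount=0)
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, (4, 5))
        feats = tuple("abcde")
        t = self._table(counts, feats)
        a1 = compute_alr(t, ["a", "c"], ["e"])
        t2 = t.select_samples(list(t.sample_ids[::-1])).select_features(list(feats[::-1]))
        a2 = compute_alr(t2, ["c", "a"], ["e"])
        np.testing.assert_allclose(a1.values[::-1], a2.values, atol=1e-12)


def _make_alr(metadata, values):
    from crcmb.survival_models import ALRIndex

    return ALRIndex(
        numerator=("x",),
        denominator=("y",),
        pseudocount=1.0,
        sample_ids=tuple(metadata.sample_ids),
        values=np.asarray(values, dtype=float),
    )


def _simulate_alr(n_subjects, tissue_shift, interaction=0.0, noise=0.3,
                  subject_sd=1.0, seed=0):
    md = make_metadata(n_subjects)
    rng = np.random.default_rng(seed)
    b = rng.normal(0, subject_sd, n_subjects)
    vals = []
    for sid in md.sample_ids:
        row = md.frame.loc[sid]
        i = int(row["subject_id"][1:]) - 1
        v = b[i] + rng.normal(0, noise)
        if row["tissue"] == "tumor":
            v += tissue_shift
            if row["survival"] == "short":
                v += interaction
        vals.append(v)
    return md, _make_alr(md, vals)


class TestLmeAlr:
    def test_recovers_tissue_shift(self):
        errs = []
        for seed in range(20):
            md, alr = _simulate_alr(100, 1.5, seed=seed)
            est = lme_alr(alr, md)
            errs.append(abs(est.coefficients.loc["tumor", "estimate"] - 1.5))
        assert np.median(errs) <= 0.2

    def test_null_coverage(self):
        covered = 0
        n_rep = 200
        for seed in range(n_rep):
            md, alr = _simulate_alr(40, 0.0, seed=1000 + seed)
            est = lme_alr(alr, md)
            row = est.coefficients.loc["tumor"]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert abs(covered / n_rep - 0.95) <= 0.04

    def test_balanced_design_equals_mean_paired_diff(self):
        md, alr = _simulate_alr(30, 0.8, seed=3)
        est = lme_alr(alr, md)
        frame = md.frame.copy()
        frame["alr"] = alr.values
        wide = frame.pivot_table(index="subject_id", columns="tissue", values="alr")
        expected = (wide["tumor"] - wide["normal"]).mean()
        assert est.coefficients.loc["tumor", "estimate"] == pytest.approx(
            expected, abs=1e-6
        )

    def test_interaction_design(self):
        md, alr = _simulate_alr(80, 1.0, interaction=1.2, seed=4)
        est = lme_alr(alr, md, design="tissue_x_survival")
        assert est.coefficients.loc["tumor_x_short", "estimate"] == pytest.approx(
            1.2, abs=0.4
        )

    def test_random_intercept_variance_positive(self):
        md, alr = _simulate_alr(60, 1.0, subject_sd=2.0, seed=5)
        est = lme_alr(alr, md)
        assert est.random_intercept_variance > 1.0


class TestLogisticSurvival:
    @staticmethod
    def _metadata_2x2(n_es, n_el, n_us, n_ul):
        rows = []
        i = 0
        exposure = {}
        for n, exposed, surv in (
            (n_es, 1, "short"), (n_el, 1, "long"), (n_us, 0, "short"), (n_ul, 0, "long"),
        ):
            for _ in range(n):
                i += 1
                subj = f"S{i:03d}"
                rows.append(
                    {"sample_id": f"{subj}.T", "subject_id": subj,
                     "tissue": "tumor", "survival": surv}
                )
                exposure[subj] = float(exposed)
        md = SampleMetadata(pd.DataFrame(rows))
        return md, pd.Series(exposure)

    def test_2x2_matches_cross_product(self):
        md, pred = self._metadata_2x2(10, 40, 20, 30)
        res = logistic_survival(pred, md)
        assert res.terms.loc["predictor", "OR"] == pytest.approx(0.375, abs=1e-6)

    def test_null_predictor(self):
        rng = np.random.default_rng(3)
        md = make_metadata(80)
        pred = pd.Series(
            rng.normal(size=80), index=[f"S{i + 1:03d}" for i in range(80)]
        )
        res = logistic_survival(pred, md)
        row = res.terms.loc["predictor"]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_coverage_of_true_log_or(self):
        covered = 0
        n_rep = 200
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            n = 300  # Wald CIs over-cover at smaller n
            x = rng.normal(0, 1, n)
            p = 1 / (1 + np.exp(-(0.1 - 0.5 * x)))
            y = rng.random(n) < p
            surv = np.where(y, "short", "long")
            md = make_metadata(n, survival=surv)
            pred = pd.Series(x, index=[f"S{i + 1:03d}" for i in range(n)])
            res = logistic_survival(pred, md)
            row = res.terms.loc["predictor"]
            covered += row["ci_low"] <= np.exp(-0.5) <= row["ci_high"]
        assert abs(covered / n_rep - 0.95) <= 0.04

    def test_adjusted_includes_covariate_terms(self):
        from crcmb import synthetic_cohort as sc

        bundle, _ = sc.generate_cohort(101, 50, 30, seed=8)
        rng = np.random.default_rng(8)
        pred = pd.Series(
            rng.normal(size=101), index=list(bundle.metadata.subject_ids)
        )
        res = logistic_survival(pred, bundle.metadata, adjust=True)
        assert res.model == "adjusted"
        for cov in ("age", "asa", "stage", "differentiation"):
            assert any(t.startswith(cov + "_") for t in res.terms.index)

    def test_perfect_separation_raises(self):
        md, pred = self._metadata_2x2(25, 0, 0, 25)
        with pytest.raises(PerfectSeparationError):
            logistic_survival(pred, md)


class TestStratify:
    def test_median_split(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
        labels = stratify_scores(s, "median_split")
        assert (labels == "high").sum() == 5
        assert (labels == "low").sum() == 5

    def test_tertiles(self):
        s = pd.Series(np.arange(9, dtype=float), index=[f"S{i}" for i in range(9)])
        labels = stratify_scores(s, "tertiles")
        assert labels.value_counts().tolist() == [3, 3, 3]

    def test_quadrants(self):
        rng = np.random.default_rng(9)
        idx = [f"S{i}" for i in range(12)]
        a = pd.Series(rng.normal(size=12), index=idx)
        b = pd.Series(rng.normal(size=12), index=idx)
        labels = stratify_scores(a, "quadrants", second=b)
        assert labels.value_counts().sum() == 12
        assert set(labels.unique()) <= {"low/low", "low/high", "high/low", "high/high"}

    def test_all_tied_errors(self):
        s = pd.Series(np.ones(5), index=[f"S{i}" for i in range(5)])
        with pytest.raises(ValueError):
            stratify_scores(s, "median_split")
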