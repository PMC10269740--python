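import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcmb import synthetic_cohort as sc
from crcmb.core_io import FeatureTable
from crcmb.diff_ranking import (
    DEFAULT_PRIOR_SD,
    DifferentialRanks,
    fit_differentials,
    select_extreme_cover,
)
from crcmb.preprocess import filter_dr
from conftest import make_metadata


def _recovery_cohort(seed, n_subjects=40, nf=80, design="tissue"):
    rng = np.random.default_rng(seed)
    truth = sc.SyntheticTruth(
        baseline_log_abundance=rng.normal(0, 1.5, nf),
        subject_sd=1.0,
        tissue_effect=rng.uniform(-2, 2, nf),
        interaction_effect=np.zeros(nf),
        nb_dispersion=0.5,
        depth_log_mean=np.log(20000),
        depth_log_sd=0.5,
        seed=seed,
    )
    bundle, truth = sc.generate_cohort(n_subjects, n_subjects // 2, truth=truth)
    return bundle, truth


def _true_centered(truth, feature_ids):
    idx = [int(f[1:]) - 1 for f in feature_ids]
    t = truth.tissue_effect[idx]
    return t - t.mean()


class TestFitDifferentials:
    def test_map_recovers_continuous_effects(self):
        bundle, truth = _recovery_cohort(1)
        table = filter_dr(bundle.table)
        ranks = fit_differentials(table, bundle.metadata, method="map")
        est = ranks.differentials("tissue")
        rho = stats.spearmanr(_true_centered(truth, est.index), est.to_numpy()).statistic
        assert rho >= 0.8

    def test_depth_doubling_leaves_differentials(self):
        # needs a reasonably informative cohort: at small n the per-feature
        # estimation noise itself exceeds the 0.1 log2 tolerance
        bundle, _ = _recovery_cohort(2, n_subjects=80, nf=50)
        table = filter_dr(bundle.table)
        doubled = FeatureTable(
            table.sample_ids, table.feature_ids, table.counts * 2
        )
        r1 = fit_differentials(table, bundle.metadata, method="map")
        r2 = fit_differentials(doubled, bundle.metadata, method="map")
        diff = (r1.differentials("tissue") - r2.differentials("tissue")).abs()
        assert diff.max() < 0.1

    def test_null_cohort_small_differentials(self):
        nf = 50
        rng = np.random.default_rng(3)
        truth = sc.SyntheticTruth(
            rng.normal(0, 1.5, nf), 1.0, np.zeros(nf), np.zeros(nf),
            0.5, np.log(20000), 0.5, 3,
        )
        bundle, _ = sc.generate_cohort(30, 15, truth=truth)
        table = filter_dr(bundle.table)
        ranks = fit_differentials(table, bundle.metadata, method="map")
        est = ranks.differentials("tissue")
        # mean |differential| clearly below a weak true effect of 0.5 log2
        assert est.abs().mean() < 0.5

    def test_true_positives_at_extremes(self):
        # strong tumor-enriched features occupy the top decile of ranks
        nf = 60
        rng = np.random.default_rng(4)
        te = np.zeros(nf)
        te[:4] = 2.0  # strong tumor-enriched
        truth = sc.SyntheticTruth(
            rng.normal(0, 1.0, nf), 1.0, te, np.zeros(nf),
            0.5, np.log(20000), 0.5, 4,
        )
        bundle, _ = sc.generate_cohort(40, 20, truth=truth)
        table = filter_dr(bundle.table)
        ranks = fit_differentials(table, bundle.metadata, method="map")
        frame = ranks.frame[ranks.frame["contrast"] == "tissue"].set_index("feature")
        enriched = [f for f in table.feature_ids if int(f[1:]) <= 4]
        top_decile = max(1, len(table.feature_ids) // 10)
        mean_rank = frame.loc[enriched, "rank"].mean()
        assert mean_rank <= top_decile + 2

    def test_interaction_null_indistinguishable(self):
        nf = 40
        rng = np.random.default_rng(5)
        truth = sc.SyntheticTruth(
            rng.normal(0, 1.0, nf), 1.0, rng.uniform(-1, 1, nf), np.zeros(nf),
            0.5, np.log(20000), 0.5, 5,
        )
        bundle, _ = sc.generate_cohort(30, 15, truth=truth)
        table = filter_dr(bundle.table)
        ranks = fit_differentials(
            table, bundle.metadata, design="tissue_x_survival", method="map"
        )
        inter = ranks.differentials("interaction")
        idx = [int(f[1:]) - 1 for f in inter.index]
        rho = stats.spearmanr(truth.interaction_effect[idx], inter.to_numpy())
        assert np.isnan(rho.statistic) or abs(rho.statistic) < 0.35
        # centered interaction differentials look like noise around zero
        assert abs(inter.mean()) < 1e-8
        assert inter.abs().mean() < 0.5

    def test_feature_relabeling_invariance(self):
        bundle, _ = _recovery_cohort(6, n_subjects=15, nf=30)
        table = filter_dr(bundle.table)
        r1 = fit_differentials(table, bundle.metadata, method="map")
        perm = list(table.feature_ids[::-1])
        r2 = fit_differentials(
            table.select_features(perm), bundle.metadata, method="map"
        )
        d1 = r1.differentials("tissue")
        d2 = r2.differentials("tissue")
        np.testing.assert_allclose(d1[perm].to_numpy(), d2.to_numpy(), atol=1e-4)

    def test_ranks_are_permutation_and_centered(self):
        bundle, _ = _recovery_cohort(7, n_subjects=12, nf=25)
        table = filter_dr(bundle.table)
        ranks = fit_differentials(table, bundle.metadata, method="map")
        # DifferentialRanks.__post_init__ enforces both; just re-assert here
        sub = ranks.frame[ranks.frame["contrast"] == "tissue"]
        assert sorted(sub["rank"]) == list(range(1, len(sub) + 1))
        assert abs(sub["differential"].mean()) < 1e-8

    def test_mcmc_agrees_with_map(self):
        bundle, truth = _recovery_cohort(8, n_subjects=20, nf=30)
        table = filter_dr(bundle.table)
        r_map = fit_differentials(table, bundle.metadata, method="map")
        r_mc = fit_differentials(
            table, bundle.metadata, method="mcmc", iterations=600, seed=1
        )
        rho = stats.spearmanr(
            r_map.differentials("tissue").to_numpy(),
            r_mc.differentials("tissue").to_numpy(),
        ).statistic
        assert rho > 0.9
        assert (r_mc.frame["sd"] > 0).all()

    def test_unpaired_design_errors(self):
        bundle, _ = _recovery_cohort(9, n_subjects=10, nf=25)
        table = filter_dr(bundle.table)
        drop = bundle.table.sample_ids[0]
        keep = [s for s in table.sample_ids if s != drop]
        with pytest.raises(ValueError, match="paired"):
            fit_differentials(
                table.select_samples(keep),
                bundle.metadata.select_samples(keep),
                method="map",
            )

    def test_prior_translation_default(self):
        assert DEFAULT_PRIOR_SD == pytest.approx(np.log(5) / 2)


def _toy_ranks(feature_ids, diffs, contrast="tissue"):
    diffs = np.asarray(diffs, dtype=float)
    centered = diffs - diffs.mean()
    order = np.argsort(-centered, kind="stable")
    rank = np.empty(len(diffs), dtype=int)
    rank[order] = np.arange(1, len(diffs) + 1)
    frame = pd.DataFrame(
        {
            "feature": feature_ids,
            "contrast": contrast,
            "differential": centered,
            "sd": 0.1,
            "rank": rank,
        }
    )
    return DifferentialRanks(frame, "tissue", 0, 0, "fixture")


class TestExtremeCover:
    def _fixture(self):
        # 4 samples x 5 features; presence pattern chosen so the greedy
        # replay is non-trivial
        presence = np.array(
            [
                [1, 0, 0, 1, 0],
                [0, 1, 0, 1, 0],
                [0, 0, 1, 0, 1],
                [0, 0, 0, 0, 1],
            ]
        )
        md = make_metadata(2)
        table = FeatureTable(
            md.sample_ids, tuple(f"f{j}" for j in range(5)), presence * 7
        )
        ranks = _toy_ranks(table.feature_ids, [5.0, 4.0, 3.0, 2.0, 1.0])
        return table, md, ranks

    def test_single_feature_cover(self):
        md = make_metadata(2)
        counts = np.ones((4, 2), dtype=int)
        counts[:, 1] = [1, 0, 0, 1]
        table = FeatureTable(md.sample_ids, ("fa", "fb"), counts)
        ranks = _toy_ranks(table.feature_ids, [3.0, 1.0])
        cover = select_extreme_cover(ranks, table, md)
        assert cover.features == ("fa",)

    def test_matches_literal_replay(self):
        table, md, ranks = self._fixture()
        cover = select_extreme_cover(ranks, table, md, direction="high")
        # literal replay: add f0 (covers s0), f1 (s1), f2 (s2), f3 (nothing
        # new), f4 (s3) -> stop
        assert cover.features == ("f0", "f1", "f2", "f3", "f4")
        assert cover.covered["f3"] == ()

    def test_cover_invariants(self):
        table, md, ranks = self._fixture()
        cover = select_extreme_cover(ranks, table, md, direction="high")
        covered_all = {s for ss in cover.covered.values() for s in ss}
        assert covered_all == set(table.sample_ids)
        # dropping the last feature breaks coverage
        last = cover.features[-1]
        remaining = [f for f in cover.features if f != last]
        idx = {f: i for i, f in enumerate(table.feature_ids)}
        still = (table.counts[:, [idx[f] for f in remaining]] > 0).any(axis=1)
        assert not still.all()

    def test_low_direction(self):
        table, md, ranks = self._fixture()
        cover = select_extreme_cover(ranks, table, md, direction="low")
        assert cover.features[0] == "f4"

    def test_same_tissue_scope(self):
        table, md, ranks = self._fixture()
        cover = select_extreme_cover(
            ranks, table, md, direction="high", scope="same_tissue", tissue="tumor"
        )
        tumor_samples = {
            s for s in table.sample_ids
            if md.frame.loc[s, "tissue"] == "tumor"
        }
        assert set(cover.scope_samples) == tumor_samples

    def test_unattainable_coverage_names_sample(self):
        md = make_metadata(2)
        counts = np.ones((4, 2), dtype=int)
        counts[2, :] = 0
        table = FeatureTable(md.sample_ids, ("fa", "fb"), counts)
        ranks = _toy_ranks(table.feature_ids, [2.0, 1.0])
        with pytest.raises(ValueError, match=table.sample_ids[2]):
            select_extreme_cover(ranks, table, md)
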