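"""CCA/PCA/targeted maps, robust scaling, directionality orientation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from netage.model import (NetworkAgeModel, cca_directions, fit_cca_map,
                          fit_pca_map, fit_targeted_map, orient_directionality,
                          robust_scale)


def make_factors(n_rows, n_feats, seed=0, days=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, n_feats))
    df = pd.DataFrame(X, columns=[f"f_{i:03d}" for i in range(n_feats)])
    df.insert(0, "day", np.arange(n_rows) % days)
    df.insert(0, "bee_id", np.arange(n_rows))
    return df


def make_descriptors(factors, weights=None, noise=0.0, seed=1):
    """Descriptor = softmax of linear functions of the factors."""
    rng = np.random.default_rng(seed)
    cols = [c for c in factors.columns if c.startswith("f_")]
    X = factors[cols].to_numpy()
    if weights is None:
        weights = rng.standard_normal((X.shape[1], 4))
    Z = X @ weights + noise * rng.standard_normal((len(X), 4))
    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    out = factors[["bee_id", "day"]].copy()
    for i, a in enumerate(["brood", "dance_floor", "honey", "exit"]):
        out[f"p_{a}"] = P[:, i]
    out["n_samples"] = 100
    return out


class TestCCA:
    def test_exact_linear_relation_gives_correlation_one(self):
        factors = make_factors(400, 10)
        desc = factors[["bee_id", "day"]].copy()
        cols = [c for c in factors.columns if c.startswith("f_")]
        lin = factors[cols].to_numpy() @ np.random.default_rng(2).random((10, 4))
        for i, a in enumerate(["brood", "dance_floor", "honey", "exit"]):
            desc[f"p_{a}"] = lin[:, i]
        nmap = fit_cca_map(factors, desc, k=3)
        assert nmap.canonical_correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_independent_views_give_small_correlation(self):
        factors = make_factors(5000, 96)
        desc = make_descriptors(factors)
        rng = np.random.default_rng(3)
        shuffled = desc.copy()
        cols = [c for c in desc.columns if c.startswith("p_")]
        shuffled[cols] = desc[cols].to_numpy()[rng.permutation(len(desc))]
        nmap = fit_cca_map(factors, shuffled, k=3)
        assert nmap.canonical_correlations[0] < 0.2

    def test_projection_has_k_columns(self):
        factors = make_factors(300, 8)
        nmap = fit_cca_map(factors, make_descriptors(factors), k=3)
        assert nmap.projection.shape == (8, 3)

    def test_agrees_with_sklearn_cca(self):
        # independent route: scikit-learn's iterative CCA on the same data
        from sklearn.cross_decomposition import CCA as SkCCA
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 12))
        Y = X @ rng.random((12, 3)) + 0.5 * rng.standard_normal((500, 3))
        Wx, Wy, corr = cca_directions(X, Y, 2)
        sk = SkCCA(n_components=2, max_iter=2000).fit(X, Y)
        u, v = sk.transform(X, Y)
        for j in range(2):
            sk_corr = abs(np.corrcoef(u[:, j], v[:, j])[0, 1])
            assert corr[j] == pytest.approx(sk_corr, abs=1e-4)
        ours = (X - X.mean(0)) @ Wx
        for j in range(2):
            r = abs(np.corrcoef(ours[:, j], u[:, j])[0, 1])
            assert r > 0.999

    def test_too_few_rows_errors(self):
        factors = make_factors(50, 96)
        with pytest.raises(ValueError, match="reduce dimensionality"):
            fit_cca_map(factors, make_descriptors(factors), k=3)


class TestApplyMap:
    def test_zero_variance_column_contributes_nothing(self):
        factors = make_factors(200, 4)
        factors["f_003"] = 7.0
        desc = make_descriptors(factors)
        nmap = fit_cca_map(factors, desc, k=1)
        raw1 = nmap.transform(factors)
        bumped = factors.copy()
        bumped["f_003"] = -7.0
        raw2 = nmap.transform(bumped)
        np.testing.assert_allclose(raw1["raw_1"], raw2["raw_1"])

    def test_header_mismatch_errors(self):
        factors = make_factors(200, 4)
        nmap = fit_cca_map(factors, make_descriptors(factors), k=1)
        wrong = factors.rename(columns={"f_003": "f_009"})
        with pytest.raises(ValueError, match="columns"):
            nmap.transform(wrong)

    def test_deterministic(self):
        factors = make_factors(200, 4)
        nmap = fit_cca_map(factors, make_descriptors(factors), k=2)
        pd.testing.assert_frame_equal(nmap.transform(factors),
                                      nmap.transform(factors))


class TestRobustScale:
    @staticmethod
    def raw_frame(values, day=0):
        return pd.DataFrame({"bee_id": np.arange(len(values)), "day": day,
                             "raw_1": values})

    def test_uniform_grid_midpoint(self):
        scaled = robust_scale(self.raw_frame(np.arange(101.0)))
        v50 = scaled.loc[scaled["raw_1"] == 50.0, "network_age"].iloc[0]
        assert v50 == pytest.approx(40 * (50 - 5) / (95 - 5))

    def test_percentile_endpoints(self):
        vals = np.arange(101.0)
        scaled = robust_scale(self.raw_frame(vals))
        p5, p95 = np.percentile(vals, [5, 95])
        at5 = scaled.loc[scaled["raw_1"] == p5, "network_age"].iloc[0]
        at95 = scaled.loc[scaled["raw_1"] == p95, "network_age"].iloc[0]
        assert at5 == pytest.approx(0.0, abs=1e-12)
        assert at95 == pytest.approx(40.0, abs=1e-12)

    def test_ninety_percent_inside_range(self):
        rng = np.random.default_rng(5)
        scaled = robust_scale(self.raw_frame(rng.standard_normal(10000)))
        frac = scaled["network_age"].between(0, 40).mean()
        assert frac == pytest.approx(0.90, abs=0.005)

    def test_degenerate_day_maps_to_midpoint(self):
        with pytest.warns(UserWarning, match="degenerate"):
            scaled = robust_scale(self.raw_frame(np.full(10, 3.0)))
        assert (scaled["network_age"] == 20.0).all()

    def test_scaling_is_per_day(self):
        raw = pd.concat([self.raw_frame(np.arange(100.0), day=0),
                         self.raw_frame(1000 + np.arange(100.0), day=1)],
                        ignore_index=True)
        scaled = robust_scale(raw)
        for _, grp in scaled.groupby("day"):
            assert grp["network_age"].between(0, 40).mean() == pytest.approx(
                0.90, abs=0.02)


class TestOrientation:
    @staticmethod
    def ages_for(raw):
        # biological age increases with the raw value
        return pd.DataFrame({"bee_id": raw["bee_id"], "day": raw["day"],
                             "age": raw["raw_1"].rank()})

    def test_already_oriented_unchanged(self):
        raw = TestRobustScale.raw_frame(np.random.default_rng(6).normal(size=500))
        scaled, sign = orient_directionality(raw, self.ages_for(raw))
        assert sign == 1.0

    def test_negated_series_flipped_back(self):
        raw = TestRobustScale.raw_frame(np.random.default_rng(7).normal(size=500))
        ages = self.ages_for(raw)
        ref, _ = orient_directionality(raw, ages)
        negated = raw.copy()
        negated["raw_1"] = -negated["raw_1"]
        flipped, sign = orient_directionality(negated, ages)
        assert sign == -1.0
        np.testing.assert_allclose(flipped["network_age"], ref["network_age"],
                                   atol=1e-9)

    def test_pipeline_output_positively_correlated_with_age(self, default_colony):
        merged = default_colony.network_age.merge(default_colony.ages,
                                                  on=["bee_id", "day"])
        assert spearmanr(merged["network_age"], merged["age"]).statistic > 0


class TestPCA:
    def test_recovers_planted_dominant_direction(self):
        rng = np.random.default_rng(8)
        direction = rng.standard_normal(20)
        direction /= np.linalg.norm(direction)
        scores = 10 * rng.standard_normal(1000)
        X = np.outer(scores, direction) + 0.1 * rng.standard_normal((1000, 20))
        factors = pd.DataFrame(X, columns=[f"f_{i:03d}" for i in range(20)])
        factors.insert(0, "day", 0)
        factors.insert(0, "bee_id", np.arange(1000))
        nmap = fit_pca_map(factors, k=1)
        # standardization rescales; compare against the standardized direction
        Xs = (X - X.mean(0)) / X.std(0)
        proj = Xs @ nmap.projection[:, 0]
        r = abs(np.corrcoef(proj, scores)[0, 1])
        assert r > 0.99

    def test_isotropic_noise_flat_spectrum(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20000, 10))
        evr = PCA(n_components=1, svd_solver="full").fit(
            (X - X.mean(0)) / X.std(0)).explained_variance_ratio_[0]
        factors = pd.DataFrame(X, columns=[f"f_{i:03d}" for i in range(10)])
        factors.insert(0, "day", 0)
        factors.insert(0, "bee_id", np.arange(len(X)))
        nmap = fit_pca_map(factors, k=1)
        assert nmap.projection.shape == (10, 1)
        assert evr == pytest.approx(1 / 10, abs=0.02)

    def test_single_component_by_default(self):
        factors = make_factors(300, 8)
        res = NetworkAgeModel(factors, variant="pca").fit()
        assert res.map.k == 1


class TestTargeted:
    def test_linear_target_correlation_one(self):
        factors = make_factors(400, 10)
        cols = [c for c in factors.columns if c.startswith("f_")]
        target = factors[["bee_id", "day"]].copy()
        target["y"] = factors[cols].to_numpy() @ np.arange(1, 11.0)
        nmap = fit_targeted_map(factors, target, "y", k=1)
        assert nmap.canonical_correlations[0] == pytest.approx(1.0, abs=1e-6)
        assert nmap.projection.shape[1] == 1

    def test_constant_target_errors(self):
        factors = make_factors(300, 6)
        target = factors[["bee_id", "day"]].assign(y=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_targeted_map(factors, target, "y")

    def test_beats_task_cca_on_its_own_target(self, default_colony):
        """A days-until-death embedding predicts death better than the
        task-guided network age does."""
        from netage.evaluation import fit_task_model
        gt = default_colony.ground_truth
        death = gt.roles[["bee_id", "day"]].merge(
            gt.bees[["bee_id", "death_day"]], on="bee_id")
        death["days_until_death"] = death["death_day"] - death["day"]
        target = death[["bee_id", "day", "days_until_death"]]
        nmap = fit_targeted_map(default_colony.factors, target,
                                "days_until_death", k=1)
        targeted = nmap.transform(default_colony.factors).rename(
            columns={"raw_1": "feat"})[["bee_id", "day", "feat"]]
        na = default_colony.network_age.rename(
            columns={"network_age": "feat"})[["bee_id", "day", "feat"]]
        fit_t = fit_task_model(targeted, target, family="gaussian",
                               area="days_until_death", weight_col=None)
        fit_n = fit_task_model(na, target, family="gaussian",
                               area="days_until_death", weight_col=None)
        assert fit_t.r2 > fit_n.r2


class TestModelResults:
    def test_summary_mentions_variant_and_scaling(self, default_colony):
        text = default_colony.results.summary()
        assert "cca_task" in text
        assert "95" in text and "40" in text

    def test_map_json_roundtrip(self, tmp_path, default_colony):
        nmap = default_colony.results.map
        nmap.to_json(tmp_path / "map.json")
        from netage.model import NetworkAgeMap
        back = NetworkAgeMap.from_json(tmp_path / "map.json")
        np.testing.assert_allclose(back.projection, nmap.projection)
        raw1 = nmap.transform(default_colony.factors)
        raw2 = back.transform(default_colony.factors)
        pd.testing.assert_frame_equal(raw1, raw2)

    def test_subsampling_robustness(self, default_colony):
        """Retaining a quarter of the bees degrades role recovery by <= 0.15."""
        from netage.config import ColonyConfig
        from netage.pipeline import run_colony_pipeline
        from netage.simulate import simulate_ground_truth
        cfg = ColonyConfig(seed=1)
        gt = simulate_ground_truth(cfg)
        rng = np.random.default_rng(0)
        keep = rng.choice(gt.bees["bee_id"].to_numpy(), size=50, replace=False)
        full = default_colony
        merged = full.network_age.merge(gt.roles, on=["bee_id", "day"])
        rho_full = abs(spearmanr(merged["network_age"], merged["role"]).statistic)

        from netage.embeddings import embed_daily_networks
        from netage.model import NetworkAgeModel
        from netage.pipeline import (descriptors_from_ground_truth,
                                     rank_transform_all)
        from netage.simulate import simulate_affinity_timeseries
        from netage.networks import AffinityMatrix
        nets = simulate_affinity_timeseries(gt, cfg)
        sub_nets = {}
        for day, mats in nets.items():
            sub = {}
            for mode, m in mats.items():
                idx = [i for i, b in enumerate(m.index) if b in set(keep)]
                if len(idx) <= 8:
                    break
                sub[mode] = AffinityMatrix(
                    day=day, mode=mode, index=[m.index[i] for i in idx],
                    values=m.values[np.ix_(idx, idx)], symmetric=m.symmetric)
            else:
                sub_nets[day] = sub
        factors = embed_daily_networks(rank_transform_all(sub_nets))
        desc = descriptors_from_ground_truth(gt)
        ages = gt.biological_ages()
        res = NetworkAgeModel(factors, descriptors=desc, ages=ages).fit()
        merged = res.network_age.merge(gt.roles, on=["bee_id", "day"])
        rho_sub = abs(spearmanr(merged["network_age"], merged["role"]).statistic)
        assert rho_full - rho_sub <= 0.15
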