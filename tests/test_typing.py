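import numpy as np
import pandas as pd
import pytest

from aerotox.aerosol_typing import (
    build_matrix,
    characterize_cluster,
    cluster_pnsd,
    pca_pnsd,
    traffic_cluster_index,
    type_campaign,
)
from aerotox.grids import make_size_grid
from aerotox.lognormal import LognormalMode, evaluate_modes
from aerotox.pnsd import integrate_number


def _frame(rows, grid, start="2021-01-26 08:00", freq="10min"):
    idx = pd.date_range(start, periods=len(rows), freq=freq)
    return pd.DataFrame(np.asarray(rows), index=idx,
                        columns=[f"{d:.3f}" for d in grid.mid_diameters_nm])


class TestBuildMatrix:
    def test_identical_records_flagged_degenerate(self, grid):
        df = _frame([np.ones(grid.n_bins)] * 100, grid)
        X, info = build_matrix(df)
        assert info["degenerate"]
        assert np.allclose(X, 0)

    def test_none_transform_returns_raw(self, grid):
        rng = np.random.default_rng(0)
        df = _frame(rng.uniform(0, 100, (12, grid.n_bins)), grid)
        X, info = build_matrix(df, transform="none")
        assert np.array_equal(X, df.to_numpy())

    def test_nan_bins_rejected_with_timestamps(self, grid):
        rows = np.ones((12, grid.n_bins))
        rows[3, 5] = np.nan
        df = _frame(rows, grid)
        with pytest.raises(ValueError, match=str(df.index[3].year)):
            build_matrix(df)

    def test_too_few_records_rejected(self, grid):
        with pytest.raises(ValueError):
            build_matrix(_frame(np.ones((5, grid.n_bins)), grid))


class TestPCA:
    def test_rank_one_matrix_first_component_explains_all(self, grid):
        rng = np.random.default_rng(0)
        base = evaluate_modes([LognormalMode(1000, 50, 1.8)], grid)
        df = _frame(np.outer(rng.uniform(0.5, 2, 50), base), grid)
        X, _ = build_matrix(df, transform="none")
        res = pca_pnsd(X)
        assert res.explained_variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sorted_and_complete(self, grid):
        rng = np.random.default_rng(1)
        df = _frame(rng.uniform(0, 100, (60, grid.n_bins)), grid)
        X, _ = build_matrix(df)
        res = pca_pnsd(X)
        evr = res.explained_variance_fractions
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention(self, grid):
        rng = np.random.default_rng(2)
        df = _frame(rng.uniform(0, 100, (40, grid.n_bins)), grid)
        X, _ = build_matrix(df)
        for row in pca_pnsd(X).components:
            assert row[np.argmax(np.abs(row))] > 0


class TestClustering:
    def test_separable_populations_pure_labels(self, grid):
        small = evaluate_modes([LognormalMode(5000, 18, 1.5)], grid)
        large = evaluate_modes([LognormalMode(1000, 300, 1.6)], grid)
        rng = np.random.default_rng(0)
        rows = [small * f for f in rng.uniform(0.8, 1.2, 30)] + \
               [large * f for f in rng.uniform(0.8, 1.2, 30)]
        df = _frame(rows, grid)
        X, _ = build_matrix(df)
        res = cluster_pnsd(X, df, k=2, seed=0)
        first, second = res.labels[:30], res.labels[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1 and first[0] != second[0]

    def test_permutation_invariance_of_means(self, grid):
        # separable populations: the optimum is unique, so record order is immaterial
        rng = np.random.default_rng(3)
        pops = [evaluate_modes([LognormalMode(n, g, 1.5)], grid)
                for n, g in ((5000, 15), (2000, 70), (800, 350))]
        rows = [p * f for p in pops for f in rng.uniform(0.9, 1.1, 15)]
        df = _frame(rows, grid)
        X, _ = build_matrix(df)
        a = cluster_pnsd(X, df, k=3, seed=1)
        perm = rng.permutation(len(df))
        b = cluster_pnsd(X[perm], df.iloc[perm], k=3, seed=1)
        got = np.sort(a.cluster_mean_pnsds.to_numpy().sum(axis=1))
        want = np.sort(b.cluster_mean_pnsds.to_numpy().sum(axis=1))
        assert np.allclose(got, want)

    def test_k_one_returns_overall_mean(self, grid):
        rng = np.random.default_rng(4)
        df = _frame(rng.uniform(0, 100, (20, grid.n_bins)), grid)
        X, _ = build_matrix(df)
        res = cluster_pnsd(X, df, k=1, seed=0)
        assert np.allclose(res.cluster_mean_pnsds.iloc[0], df.mean())

    def test_k_exceeding_records_rejected(self, grid):
        rng = np.random.default_rng(5)
        df = _frame(rng.uniform(0, 100, (12, grid.n_bins)), grid)
        X, _ = build_matrix(df)
        with pytest.raises(ValueError):
            cluster_pnsd(X, df, k=50, seed=0)


class TestCharacterize:
    def test_nucleation_only_is_traffic(self, grid):
        y = evaluate_modes([LognormalMode(8000, 18, 1.6), LognormalMode(1500, 48, 1.7)], grid)
        res, label = characterize_cluster(y, grid)
        assert label == "traffic_nucleation"
        assert res.modes[0].gmd == pytest.approx(18, abs=2)

    def test_accumulation_dominated_is_aged(self, grid):
        y = evaluate_modes([LognormalMode(900, 250, 1.6), LognormalMode(300, 60, 1.7)], grid)
        _, label = characterize_cluster(y, grid)
        assert label == "urban_aged"

    def test_midday_nucleation_is_regional_npf(self, grid):
        y = evaluate_modes([LognormalMode(5000, 18, 1.5), LognormalMode(800, 180, 1.6)], grid)
        _, label = characterize_cluster(y, grid, midday_npf=True)
        assert label == "regional_npf"

    def test_zero_distribution_unclassified(self, grid):
        res, label = characterize_cluster(np.zeros(grid.n_bins), grid)
        assert res is None and label == "unclassified"


class TestEndToEnd:
    def test_traffic_cluster_rush_hour_occupancy(self, winter):
        """Traffic cluster occupies weekday rush windows, not the weekend."""
        res = type_campaign(winter.pnsd, winter.grid, seed=1)
        tc = traffic_cluster_index(res.cluster_labels)
        assert res.archetypes[tc] == "traffic_nucleation"
        idx = res.cluster_labels.index
        in_c = res.cluster_labels.to_numpy() == tc
        rush = idx.hour.isin((7, 8, 9, 17, 18, 19)) & (idx.dayofweek < 5)
        weekend = idx.dayofweek >= 5
        occ_rush = (in_c & rush).sum() / in_c.sum()
        occ_weekend = (in_c & weekend).sum() / in_c.sum()
        assert occ_rush > 2 * occ_weekend

    def test_n820_tracks_traffic_membership(self, winter):
        res = type_campaign(winter.pnsd, winter.grid, seed=1)
        tc = traffic_cluster_index(res.cluster_labels)
        n820 = integrate_number(winter.pnsd.to_numpy(), winter.grid, 8, 20)
        member = (res.cluster_labels.to_numpy() == tc).astype(float)
        r = np.corrcoef(n820, member)[0, 1]
        assert r > 0.8
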