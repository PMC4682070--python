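"""Colony structure, variance decomposition, heritable variation, signature."""

import numpy as np
import pandas as pd
import pytest

from morphomodes import (heritable_variation, identify_colonies,
                         proximity_correlation, signature_and_classification,
                         signature_features, synthesize_cell_table,
                         variance_decomposition)
from morphomodes.heritability import UNASSIGNED


def clone_table(n=5000, seed=0, colony_cv=0.1, residual_cv=0.1,
                n_colonies=40, phase_probs=(1.0, 0.0, 0.0)):
    """Size = colony factor x residual, equal log-variances by default."""
    return synthesize_cell_table(
        n, seed=seed, n_colonies=n_colonies, colony_size_cv=colony_cv,
        size_cv=residual_cv, phase_probs=phase_probs,
        phase_size_coupling=False)


class TestIdentifyColonies:
    def test_recovers_four_grid_colonies(self):
        rng = np.random.default_rng(1)
        centers = np.array([[500, 500], [3000, 500], [500, 3000], [3000, 3000]],
                           float)
        cid = np.repeat(np.arange(4), 100)
        pos = centers[cid] + rng.normal(0, 40.0, (400, 2))
        df = pd.DataFrame({"x": pos[:, 0], "y": pos[:, 1], "colony_id": cid})
        ids = identify_colonies(df, linkage_distance=400.0)
        # membership must match the generator's colonies up to relabeling
        cross = pd.crosstab(ids, df["colony_id"])
        assert (cross.to_numpy() > 0).sum() == 4
        assert len(np.unique(ids[ids >= 0])) == 4

    def test_chained_cells_form_one_colony(self):
        df = pd.DataFrame({"x": np.arange(20) * 5.0, "y": np.zeros(20)})
        ids = identify_colonies(df, linkage_distance=10.0, min_size=5)
        assert len(set(ids)) == 1
        assert ids[0] != UNASSIGNED

    def test_small_groups_unassigned(self):
        df = pd.DataFrame({"x": [0.0, 1000.0], "y": [0.0, 0.0]})
        ids = identify_colonies(df, linkage_distance=50.0, min_size=5)
        assert set(ids) == {UNASSIGNED}


class TestProximityCorrelation:
    def test_heritable_effect_elevates_near_correlation(self):
        df = clone_table(n=500, seed=2, colony_cv=0.15, n_colonies=25)
        df["phase"] = df["phase_true"]
        out = proximity_correlation(df, "R_N",
                                    distance_bins=[0, 150, 800, 2400],
                                    n_permutations=200, seed=0)
        near = out.iloc[0]
        assert near["correlation"] > near["null_hi"]

    def test_no_colony_effect_stays_in_null_band(self):
        # the 2.5-97.5% band excludes a correct null ~5% of the time per
        # bin, so assert on the aggregate per-bin violation rate
        checks, violations = 0, 0
        for seed in range(20):
            df = clone_table(n=250, seed=seed, colony_cv=0.0, n_colonies=25)
            df["phase"] = df["phase_true"]
            out = proximity_correlation(df, "R_N",
                                        distance_bins=[0, 150, 800, 2400],
                                        n_permutations=150, seed=seed)
            out = out[out["n_pairs"] > 10]
            inside = ((out["correlation"] >= out["null_lo"] - 1e-12)
                      & (out["correlation"] <= out["null_hi"] + 1e-12))
            checks += len(inside)
            violations += int((~inside).sum())
        assert violations / checks <= 0.10

    def test_deterministic_given_seed(self):
        df = clone_table(n=200, seed=3, colony_cv=0.1, n_colonies=10)
        a = proximity_correlation(df, "R_C", [0, 200, 2000],
                                  n_permutations=120, seed=5)
        b = proximity_correlation(df, "R_C", [0, 200, 2000],
                                  n_permutations=120, seed=5)
        assert a.equals(b)

    def test_too_few_bins_rejected(self):
        df = clone_table(n=100, seed=0)
        with pytest.raises(ValueError):
            proximity_correlation(df, "R_N", [0, 100], n_permutations=100)


class TestVarianceDecomposition:
    def test_all_population_scaled_variance_is_one(self):
        df = clone_table(seed=4)
        df["phase"] = df["phase_true"]
        vd = variance_decomposition(df)
        ones = vd[vd.condition == "all"]["scaled_variance"]
        assert np.allclose(ones, 1.0)

    def test_within_clone_half_when_variances_equal(self):
        vals = []
        for seed in range(10):
            df = clone_table(seed=seed)
            df["phase"] = df["phase_true"]
            vd = variance_decomposition(df)
            vals.append(vd[(vd.feature == "R_N")
                           & (vd.condition == "clone_all")]
                        ["scaled_variance"].iloc[0])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_homogeneous_population_all_near_one(self):
        df = clone_table(seed=5, colony_cv=0.0)
        df["phase"] = df["phase_true"]
        vd = variance_decomposition(df)
        avail = vd.dropna(subset=["scaled_variance"])
        assert np.abs(avail["scaled_variance"] - 1.0).max() < 0.15

    def test_permuting_colonies_restores_unit_variance(self):
        df = clone_table(seed=6)
        df["phase"] = df["phase_true"]
        rng = np.random.default_rng(0)
        df["colony_id"] = rng.permutation(df["colony_id"].to_numpy())
        vd = variance_decomposition(df)
        v = vd[(vd.feature == "R_N") & (vd.condition == "clone_all")]
        assert abs(v["scaled_variance"].iloc[0] - 1.0) < 0.1


class TestHeritableVariation:
    def test_three_colony_factors_hand_computed(self):
        rng = np.random.default_rng(0)
        rows = []
        for cid, f in enumerate((0.8, 1.0, 1.2)):
            for i in range(200):
                rows.append({"colony_id": cid, "phase": "G0G1",
                             "R_N": f * (1 + rng.normal(0, 1e-6)),
                             "R_C": f * (1 + rng.normal(0, 1e-6))})
        out = heritable_variation(pd.DataFrame(rows))
        # CV of the colony means {0.8, 1.0, 1.2} with the sample (n-1)
        # standard deviation: sd = 0.2, mean = 1.0
        assert abs(out["R_N"] - 0.2) < 1e-3

    def test_identical_colonies_zero_cv(self):
        df = pd.DataFrame({
            "colony_id": np.repeat([0, 1, 2], 10),
            "R_N": np.tile(np.linspace(1, 2, 10), 3),
            "R_C": np.tile(np.linspace(2, 4, 10), 3),
        })
        out = heritable_variation(df)
        assert out["R_N"] < 1e-12
        assert out["R_C"] < 1e-12

    def test_sampling_shrinkage_of_colony_means(self):
        # identical colonies of m = 100 cells with per-cell CV 10%:
        # colony-mean CV ~ 0.1/sqrt(100) = 1%, within a factor of two
        cvs = []
        for seed in range(20):
            df = clone_table(n=2000, seed=seed, colony_cv=0.0,
                             residual_cv=0.1, n_colonies=20)
            cvs.append(heritable_variation(df.assign(phase="G0G1"))["R_N"])
        assert 0.005 < np.mean(cvs) < 0.02

    def test_too_few_colonies_rejected(self):
        df = clone_table(n=50, seed=0, n_colonies=2)
        with pytest.raises(ValueError):
            heritable_variation(df)


def two_class_records(seed=0, n_per=1200, separable=True):
    frames, labels = [], {}
    for i in range(4):
        hi = i < 2
        if separable:
            probs = (np.full(5, 0.2) if hi
                     else np.array([0.8, 0.05, 0.05, 0.05, 0.05]))
            cv = 0.25 if hi else 0.10
        else:
            probs = np.full(5, 0.2)
            cv = 0.15
        sid = f"P{i}"
        frames.append(synthesize_cell_table(
            n_per, seed=seed * 10 + i, sample_id=sid,
            nucleus_mode_probs=probs, cell_mode_probs=probs, size_cv=cv))
        labels[sid] = "PT" if hi else "LM"
    return pd.concat(frames, ignore_index=True), labels


class TestSignature:
    def test_separable_classes_reach_high_accuracy(self):
        records, labels = two_class_records(seed=1)
        _, acc = signature_and_classification(
            records, labels, K_N=5, subsample_sizes=(50, 150, 400),
            n_repeats=10, seed=0)
        assert acc["mean_accuracy"].iloc[-1] >= 0.95
        diffs = np.diff(acc["mean_accuracy"])
        assert np.all(diffs >= -0.05)

    def test_identical_generators_give_chance_accuracy(self):
        accs = []
        for seed in range(6):
            records, labels = two_class_records(seed=seed, n_per=500,
                                                separable=False)
            _, acc = signature_and_classification(
                records, labels, K_N=5, subsample_sizes=(200,),
                n_repeats=10, seed=seed)
            accs.append(acc["mean_accuracy"].iloc[0])
        assert abs(np.mean(accs) - 0.5) <= 0.25

    def test_full_subsample_reproduces_full_features(self):
        records, labels = two_class_records(seed=2, n_per=300)
        one = records[records.sample_id == "P0"]
        full = signature_features(one, K_N=5)
        sigs, _ = signature_and_classification(
            records, labels, K_N=5, subsample_sizes=(300,), n_repeats=2,
            seed=0)
        for key, val in full.items():
            assert np.isclose(sigs.loc["P0", key], val)

    def test_single_sample_class_rejected(self):
        records, labels = two_class_records(seed=3, n_per=200)
        labels["P0"] = "NM"
        with pytest.raises(ValueError):
            signature_and_classification(records, labels, K_N=5)
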