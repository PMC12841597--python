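import warnings

import numpy as np
import pandas as pd
import pytest

from panepiclock import clocks
from panepiclock.gene_matrix import GeneMatrix


def sheet(rows):
    return pd.DataFrame(rows, columns=["sample_id", "donor_id", "species", "tissue",
                                       "layer", "dataset", "age_years", "diet"])


def toy_matrix(samples: pd.DataFrame, n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(rng.normal(size=(len(samples), n_genes)),
                          index=pd.Index(samples["sample_id"], name="sample_id"),
                          columns=[f"g{i}" for i in range(n_genes)])
    return GeneMatrix(values, samples)


class TestFilterClockDataset:
    def base_sheet(self):
        rows = []
        for i in range(60):
            rows.append((f"s{i}", f"d{i}", "human", "liver", "H3K4me3", "ds1", 30.0, "standard"))
        return rows

    def test_small_tissue_dropped(self):
        rows = self.base_sheet()
        for i in range(49):
            rows.append((f"k{i}", f"kd{i}", "human", "kidney", "H3K4me3", "ds1", 30.0, "standard"))
        matrix = toy_matrix(sheet(rows))
        train, _ = clocks.filter_clock_dataset(matrix, min_libraries=50)
        assert set(train.samples["tissue"]) == {"liver"}

    def test_non_clock_layers_dropped(self):
        rows = self.base_sheet()
        rows.append(("x1", "dx", "human", "liver", "H3K9me3", "ds1", 30.0, "standard"))
        rows.append(("x2", "dy", "human", "liver", "H3K36me3", "ds1", 30.0, "standard"))
        train, _ = clocks.filter_clock_dataset(toy_matrix(sheet(rows)), min_libraries=10)
        assert not set(train.samples["layer"]) & {"H3K9me3", "H3K36me3"}

    def test_cr_samples_moved_to_withheld(self):
        rows = self.base_sheet()
        rows.append(("cr1", "dcr", "mouse", "liver", "H3K4me3", "ds2", 1.0, "CR"))
        train, withheld = clocks.filter_clock_dataset(toy_matrix(sheet(rows)), min_libraries=10)
        assert "cr1" not in train.samples.index
        assert list(withheld.samples.index) == ["cr1"]

    def test_excluded_tissue_list(self):
        rows = self.base_sheet()
        rows.append(("p1", "dp", "human", "placenta", "H3K4me3", "ds1", 30.0, "standard"))
        train, withheld = clocks.filter_clock_dataset(toy_matrix(sheet(rows)), min_libraries=10)
        assert "p1" not in train.samples.index and "p1" not in withheld.samples.index


class TestMakeFolds:
    def donors_sheet(self, n_donors, profiles_per_donor=1):
        rows = []
        for d in range(n_donors):
            for p in range(profiles_per_donor):
                rows.append((f"s{d}_{p}", f"d{d:03d}", "human", "liver", "H3K4me3",
                             "ds1", 10.0 + d, "standard"))
        return sheet(rows)

    def test_one_donor_per_fold_when_counts_match(self):
        folds = clocks.make_folds(self.donors_sheet(10), n_folds=10, seed=0)
        assert sorted(folds.values()) == list(range(10))

    def test_all_profiles_of_donor_share_fold(self):
        samples = self.donors_sheet(20, profiles_per_donor=5)
        folds = clocks.make_folds(samples, n_folds=4, seed=1)
        per_sample = samples["donor_id"].map(folds)
        assert samples.groupby("donor_id").apply(
            lambda g: per_sample[g.index].nunique(), include_groups=False).eq(1).all()

    def test_deterministic_given_seed(self):
        samples = self.donors_sheet(30, profiles_per_donor=2)
        assert clocks.make_folds(samples, 5, seed=7) == clocks.make_folds(samples, 5, seed=7)

    def test_quintile_profile_balance(self):
        samples = self.donors_sheet(50)
        folds = clocks.make_folds(samples, n_folds=5, seed=0)
        fold_of = samples["donor_id"].map(folds)
        ages = samples.groupby("donor_id")["age_years"].first()
        quintile = pd.qcut(ages, 5, labels=False)
        for q in range(5):
            donors_q = quintile[quintile == q].index
            counts = fold_of[samples["donor_id"].isin(donors_q)].value_counts()
            counts = counts.reindex(range(5), fill_value=0)
            assert counts.max() - counts.min() <= 1

    def test_fewer_donors_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            clocks.make_folds(self.donors_sheet(3), n_folds=5, seed=0)


class TestSelectFeatures:
    def species_matrix(self, rho_spec):
        """rho_spec: gene -> (direction_human, direction_mouse, strength)."""
        rng = np.random.default_rng(0)
        rows, data = [], {}
        n = 40
        ages_h = np.linspace(20, 100, n)
        ages_m = np.linspace(0.2, 3.2, n)
        for i in range(n):
            rows.append((f"h{i}", f"hd{i}", "human", "liver", "H3K4me3", "ds1", ages_h[i], "standard"))
        for i in range(n):
            rows.append((f"m{i}", f"md{i}", "mouse", "liver", "H3K4me3", "ds2", ages_m[i], "standard"))
        samples = sheet(rows)
        for gene, (dh, dm, strength) in rho_spec.items():
            noise = rng.normal(0, 1, 2 * n)
            signal_h = dh * strength * np.linspace(0, 4, n)
            signal_m = dm * strength * np.linspace(0, 4, n)
            data[gene] = np.concatenate([signal_h, signal_m]) + noise
        values = pd.DataFrame(data, index=pd.Index(samples["sample_id"], name="sample_id"))
        return GeneMatrix(values, samples)

    def test_concordant_strong_gene_kept(self):
        m = self.species_matrix({"good": (1, 1, 3.0), "weak": (1, 1, 0.05)})
        features = clocks.select_features(m, threshold=0.2)
        assert "good" in features and "weak" not in features

    def test_sign_discordant_gene_dropped(self):
        m = self.species_matrix({"good": (1, 1, 3.0), "flip": (1, -1, 3.0)})
        assert "flip" not in clocks.select_features(m, threshold=0.2)

    def test_single_species_warns(self):
        m = self.species_matrix({"good": (1, 1, 3.0)})
        human_only = m.select_species("human")
        with pytest.warns(UserWarning, match="single-species"):
            features = clocks.select_features(human_only, threshold=0.2)
        assert "good" in features

    def test_empty_selection_advises_threshold(self):
        m = self.species_matrix({"weak": (1, 1, 0.01)})
        with pytest.raises(ValueError, match="threshold"):
            clocks.select_features(m, threshold=0.9)

    def test_union_mode_recovers_gene_cancelled_by_pooling(self):
        """A gene trending up in one layer and down in another washes out
        when profiles are pooled, but per-layer union selection keeps it."""
        a = self.species_matrix({"g": (1, 1, 3.0)})
        b = self.species_matrix({"g": (-1, -1, 3.0)})
        b.samples["layer"] = "H3K27ac"
        b.samples.index = b.values.index = pd.Index(
            [f"x{i}" for i in range(b.n_samples)], name="sample_id")
        b.samples["sample_id"] = b.samples.index
        from panepiclock.gene_matrix import concat_matrices
        both = concat_matrices([clocks.GeneMatrix(a.values, a.samples.reset_index(drop=True)
                                                  .assign(sample_id=a.values.index)),
                                clocks.GeneMatrix(b.values, b.samples.reset_index(drop=True)
                                                  .assign(sample_id=b.values.index))])
        with pytest.raises(ValueError):
            clocks.select_features(both, threshold=0.2, mode="pooled")
        assert clocks.select_features(both, threshold=0.2, mode="union") == ["g"]


class TestZeroInterceptSlope:
    def test_closed_form_example(self):
        # rho grid {(10, 0.5), (100, 1.0)}: b = (1*0.5 + 2*1.0) / (1 + 4) = 0.5
        assert clocks.zero_intercept_slope(np.log10([10, 100]), [0.5, 1.0]) == pytest.approx(0.5)

    def test_all_zero_rho(self):
        assert clocks.zero_intercept_slope(np.log10([10, 100]), [0.0, 0.0]) == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            clocks.zero_intercept_slope([0.0, 0.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def trained_cv(small_cohort_scaled):
    config, scaled, truth = small_cohort_scaled
    train, withheld = clocks.filter_clock_dataset(scaled, min_libraries=10)
    cfg = clocks.ClockConfig(mode="pan", n_folds=5, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models, records, folds = clocks.cross_validate_clock(train, cfg, withheld=withheld)
    return train, withheld, cfg, models, records, folds


class TestCrossValidatedClock:
    def test_no_sample_predicted_by_model_trained_on_its_donor(self, trained_cv):
        train, _, _, _, records, folds = trained_cv
        held = records[records["fold"] >= 0]
        assert (held["donor_id"].map(folds) == held["fold"]).all()

    def test_every_training_sample_predicted_once(self, trained_cv):
        train, _, _, _, records, _ = trained_cv
        held = records[records["fold"] >= 0]
        assert sorted(held["sample_id"]) == sorted(train.samples.index)
        assert held["predicted_years"].notna().all()

    def test_predictions_within_lifespan(self, trained_cv):
        _, _, _, _, records, _ = trained_cv
        human = records[records["species"] == "human"]
        mouse = records[records["species"] == "mouse"]
        assert human["predicted_years"].between(0, 120).all()
        assert mouse["predicted_years"].between(0, 4).all()

    def test_withheld_cr_predicted_by_fold_average(self, trained_cv):
        train, withheld, _, models, records, _ = trained_cv
        cr = records[records["fold"] < 0]
        assert sorted(cr["sample_id"]) == sorted(withheld.samples.index)
        stacked = np.vstack([m.predict(withheld) for m in models]).mean(axis=0)
        got = cr.set_index("sample_id").loc[withheld.samples.index, "predicted_scaled"]
        assert got.to_numpy() == pytest.approx(stacked)

    def test_fold_models_differ_in_fitted_parameters(self, trained_cv):
        _, _, _, models, _, _ = trained_cv
        # leakage audit: models fitted on different training rows must not
        # share identical INT tables
        t0 = next(iter(models[0].normalizer_.int_.tables_.values()))[1]
        t1 = next(iter(models[1].normalizer_.int_.tables_.values()))[1]
        assert t0.shape != t1.shape or not np.allclose(t0, t1)

    def test_refitting_fold_reproduces_features_exactly(self, trained_cv):
        train, _, cfg, models, _, folds = trained_cv
        fold_of = train.samples["donor_id"].map(folds).to_numpy()
        refit = clocks.EpigeneticClock(seed=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit.fit(train.subset(fold_of != 0))
        assert refit.features_ == models[0].features_

    def test_determinism_same_config_same_predictions(self, small_cohort_scaled):
        config, scaled, _ = small_cohort_scaled
        train, _ = clocks.filter_clock_dataset(scaled, min_libraries=10)
        sub = train.subset(train.samples["layer"].isin(["DNAm"]).to_numpy())
        cfg = clocks.ClockConfig(mode="single", layers=("DNAm",), n_folds=4, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, rec1, _ = clocks.cross_validate_clock(sub, cfg)
            _, rec2, _ = clocks.cross_validate_clock(sub, cfg)
        pd.testing.assert_frame_equal(rec1, rec2)


class TestEvaluate:
    def records(self, predicted, actual, layer="DNAm", n=None):
        n = n or len(predicted)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "donor_id": [f"d{i}" for i in range(n)],
            "species": "human", "tissue": "liver", "layer": layer,
            "diet": "standard", "fold": 0,
            "predicted_scaled": 0.0, "predicted_years": predicted,
            "actual_years": actual,
        })

    def test_perfect_predictions(self):
        actual = np.linspace(20, 80, 10)
        rho = clocks.evaluate(self.records(actual, actual), "layer")
        assert rho["DNAm"] == pytest.approx(1.0)

    def test_constant_predictions_flagged_zero(self):
        actual = np.linspace(20, 80, 10)
        with pytest.warns(UserWarning, match="constant"):
            rho = clocks.evaluate(self.records(np.full(10, 50.0), actual), "layer")
        assert rho["DNAm"] == 0.0

    def test_small_group_excluded(self):
        actual = np.array([20.0, 30.0])
        with pytest.warns(UserWarning, match="excluded"):
            rho = clocks.evaluate(self.records(actual, actual), "layer")
        assert "DNAm" not in rho.index

    def test_donor_predictions_averaged_over_tissues(self):
        rec = pd.DataFrame({
            "sample_id": ["a", "b"], "donor_id": ["d1", "d1"], "species": "human",
            "tissue": ["liver", "blood"], "layer": "DNAm", "diet": "standard",
            "fold": 0, "predicted_scaled": 0.0,
            "predicted_years": [50.0, 60.0], "actual_years": [50.0, 50.0],
        })
        points = clocks.donor_level(rec)
        assert len(points) == 1
        assert points["predicted_years"].iloc[0] == pytest.approx(55.0)
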