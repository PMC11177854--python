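import numpy as np
import pandas as pd
import pytest

import flashkin as fk
from flashkin.stats import PARAM_COLUMNS
from test_stats import records_frame


def two_class_records(n=40, sep=3.0, seed=0):
    """Two species separated by `sep` within-class SDs in log10-PI."""
    rng = np.random.default_rng(seed)
    cols_a = {"pi_photons_s": 10 ** (9.0 + 0.2 * rng.standard_normal(n)),
              "rt_ms": 50 * np.exp(0.2 * rng.standard_normal(n))}
    cols_b = {"pi_photons_s": 10 ** (9.0 + 0.2 * (sep + rng.standard_normal(n))),
              "rt_ms": 50 * np.exp(0.2 * rng.standard_normal(n))}
    return records_frame({"A": cols_a, "B": cols_b})


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.linspace(1, 10, 20)
        records = records_frame({"A": {"rt_ms": x, "dt_ms": 2 * x + 1}})
        assert fk.correlation(records, "RT", "DT") == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.linspace(1, 10, 20)
        records = records_frame({"A": {"rt_ms": x, "dt_ms": 30 - x}})
        assert fk.correlation(records, "RT", "DT") == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        records = records_frame({"A": {"rt_ms": np.full(10, 5.0)}})
        with pytest.raises(ValueError, match="variance"):
            fk.correlation(records, "RT", "DT")

    def test_too_few_records(self):
        records = records_frame({"A": {"rt_ms": np.array([1.0, 2.0])}})
        with pytest.raises(ValueError):
            fk.correlation(records, "RT", "DT")

    def test_pooled_intensity_correlation(self, cohort_records):
        """Across the pooled multi-species cohort, PI and FF-MSL are
        near-collinear on the raw scale, as in field measurements."""
        assert fk.correlation(cohort_records, "PI", "FF-MSL") >= 0.99
        assert fk.correlation(cohort_records, "DT", "FD") >= 0.90


class TestSelectFeatures:
    def test_duplicated_feature_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(3, 10, 40)
        y = rng.gamma(3, 10, 40)
        records = records_frame(
            {"A": {"fd_ms": x[:20], "dt_ms": x[:20], "rt_ms": y[:20]},
             "B": {"fd_ms": x[20:] * 2, "dt_ms": x[20:] * 2, "rt_ms": y[20:]}}
        )
        ft = fk.select_features(records, candidates=("FD", "RT", "DT"))
        assert "FD" in ft.features  # higher priority copy survives
        assert "DT" not in ft.features  # r = 1 with FD
        assert "RT" in ft.features

    def test_independent_features_all_kept(self):
        rng = np.random.default_rng(1)
        records = records_frame(
            {s: {col: rng.gamma(3, 10, 30) for col in PARAM_COLUMNS.values()}
             for s in ("A", "B")}
        )
        ft = fk.select_features(records)
        assert set(ft.features) == {"PI", "FD", "RT", "EF", "DT", "FF-MSL"}

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        records = records_frame(
            {"A": {"rt_ms": np.full(20, 5.0), "fd_ms": rng.gamma(3, 10, 20)},
             "B": {"rt_ms": np.full(20, 5.0), "fd_ms": rng.gamma(3, 10, 20)}}
        )
        with pytest.warns(UserWarning, match="RT"):
            ft = fk.select_features(records, candidates=("FD", "RT"))
        assert ft.features == ("FD",)

    def test_cohort_reproduces_field_feature_set(self, cohort_records):
        """On a full simulated cohort the pruning drops DT and FF-MSL and
        keeps {PI, FD, RT, EF} - the published discriminant feature set."""
        ft = fk.select_features(cohort_records)
        assert set(ft.features) == {"PI", "FD", "RT", "EF"}


class TestSpeciesMeanTable:
    def test_single_record_per_species(self):
        records = records_frame(
            {"A": {"rt_ms": np.array([42.0])}, "B": {"rt_ms": np.array([24.0])}}
        )
        table = fk.species_mean_table(records)
        assert table.loc["A", "rt_ms"] == 42.0
        assert table.loc["B", "rt_ms"] == 24.0

    def test_cohort_shape(self, cohort_records):
        table = fk.species_mean_table(cohort_records)
        assert table.shape == (7, 6)

    def test_zero_sd_cohort_recovers_library_means(self, library):
        """Noiseless traces from a dispersion-free library round-trip to the
        library means within extraction discretization."""
        entry = library["Pyrodinium bahamense"]
        zero = fk.SpeciesEntry(
            species_name=entry.species_name, genus=entry.genus,
            n_observed=entry.n_observed, means=dict(entry.means),
            sds={k: 0.0 for k in entry.sds},
            feasibility_limited=entry.feasibility_limited,
        )
        lib = fk.SpeciesLibrary([zero])
        traces, _ = fk.simulate_cohort(
            [(zero.species_name, 20)], lib,
            fk.AcquisitionConfig.noiseless(), seed=5,
        )
        table = fk.species_mean_table(fk.extract_first_flash(traces))
        period_ms = 1000.0 / 60.0
        for col, key in [("rt_ms", "rt"), ("dt_ms", "dt"), ("fd_ms", "fd"),
                         ("ef_ms", "ef")]:
            assert abs(table.iloc[0][col] - zero.means[key]) < 2 * period_ms
        assert table.iloc[0]["pi_photons_s"] == pytest.approx(
            zero.means["pi"], rel=0.15
        )


class TestHierarchicalCluster:
    def test_identical_species_merge_at_zero(self):
        table = pd.DataFrame(
            {c: [10.0, 10.0, 99.0] for c in PARAM_COLUMNS.values()},
            index=["A", "B", "C"],
        )
        res = fk.hierarchical_cluster(table)
        assert res.merges[0][2] == pytest.approx(0.0)
        assert res.merge_order()[0] == {"A", "B"}

    def test_library_means_structure(self, library):
        """The ctenophore is the dendrogram outlier and the two Pyrocystis
        species are each other's first merge, matching the field analysis."""
        res = fk.hierarchical_cluster(library.mean_table())
        assert res.last_joining_leaf() == "Mnemiopsis leidyi"
        pyro = {"Pyrocystis fusiformis", "Pyrocystis noctiluca"}
        assert pyro in res.merge_order()

    def test_heights_non_decreasing(self, library):
        res = fk.hierarchical_cluster(library.mean_table())
        heights = [m[2] for m in res.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_two_species_minimum(self):
        table = pd.DataFrame(
            {c: [10.0] for c in PARAM_COLUMNS.values()}, index=["A"]
        )
        with pytest.raises(ValueError):
            fk.hierarchical_cluster(table)


class TestTrainLDA:
    def test_closed_form_fisher_axis(self):
        """Two classes, hand-specified 2-D covariance: the discriminant axis
        matches W^-1 (mu1 - mu2) from the closed form."""
        rng = np.random.default_rng(0)
        w = np.array([[2.0, 0.5], [0.5, 1.0]])
        chol = np.linalg.cholesky(w)
        mu = {"A": np.array([0.0, 0.0]), "B": np.array([2.0, 1.0])}
        frames = {}
        for s in ("A", "B"):
            x = mu[s] + rng.standard_normal((4000, 2)) @ chol.T
            frames[s] = {"rt_ms": np.exp(x[:, 0] / 5 + 4),
                         "dt_ms": np.exp(x[:, 1] / 5 + 5)}
        records = records_frame(frames)
        ft = fk.FeatureTransform.make(["RT", "DT"], log_transform=True).fit(records)
        model = fk.train_lda(records, ft)
        # empirical closed form on the transformed data
        x = ft.apply(records)
        y = records["species"].to_numpy()
        xa, xb = x[y == "A"], x[y == "B"]
        sw = np.cov(xa.T) * (len(xa) - 1) + np.cov(xb.T) * (len(xb) - 1)
        direction = np.linalg.solve(sw / (len(x) - 2), xb.mean(0) - xa.mean(0))
        direction /= np.linalg.norm(direction)
        axis = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
        assert abs(abs(direction @ axis) - 1.0) < 1e-6

    def test_explained_variance_properties(self, cohort_records, library):
        ft = fk.FeatureTransform.make(["PI", "FD", "RT", "EF"]).fit(cohort_records)
        model = fk.train_lda(
            cohort_records, ft,
            excluded_species=("Pyrodinium bahamense",),
            genus_map=library.genus_map,
        )
        ev = model.explained_variance
        assert ev.sum() == pytest.approx(1.0)
        assert np.all(np.diff(ev) <= 1e-12)
        assert model.axes.shape == (4, 4)  # min(4 features, 6 classes - 1)
        assert "Pyrodinium bahamense" not in model.classes

    def test_matches_sklearn_reference(self, cohort_records, library):
        """Independent oracle: scikit-learn's pooled-covariance LDA yields
        the same posteriors and predictions on identical inputs."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        excl = ["Pyrodinium bahamense"]
        sub = cohort_records[~cohort_records.species.isin(excl)]
        ft = fk.FeatureTransform.make(["PI", "FD", "RT", "EF"]).fit(sub)
        model = fk.train_lda(sub, ft, excluded_species=excl,
                             genus_map=library.genus_map)
        res = fk.predict_posteriors(model, sub)
        x = ft.apply(sub)
        ref = sklearn.LinearDiscriminantAnalysis(
            priors=np.full(len(model.classes), 1 / len(model.classes))
        ).fit(x, sub.species.to_numpy())
        assert np.array_equal(ref.predict(x), res.predicted_species.to_numpy())
        np.testing.assert_allclose(
            ref.predict_proba(x),
            res.posteriors[list(ref.classes_)].to_numpy(),
            atol=1e-9,
        )

    def test_class_minimum_enforced(self):
        records = two_class_records(n=2)
        ft = fk.FeatureTransform.make(["PI", "RT"]).fit(records)
        with pytest.raises(ValueError, match="n_features"):
            fk.train_lda(records, ft)


class TestPredict:
    def test_posterior_normalization_and_class_mean(self):
        records = two_class_records()
        ft = fk.FeatureTransform.make(["PI", "RT"]).fit(records)
        model = fk.train_lda(records, ft)
        res = fk.predict_posteriors(model, records)
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.genus_posteriors.sum(axis=1), 1.0, atol=1e-9)
        # records of class B with high separation go to B
        assert (res.predicted_species[records.species == "B"] == "B").mean() > 0.9

    def test_midpoint_posterior_is_half(self):
        """1-D two-class symmetric problem: a record at the midpoint of the
        class means has posterior (0.5, 0.5)."""
        rng = np.random.default_rng(3)
        a = 40.0 * np.exp(0.1 * rng.standard_normal(200))
        b = a * 4.0  # same log-variance, shifted mean
        records = records_frame({"A": {"rt_ms": a}, "B": {"rt_ms": b}})
        ft = fk.FeatureTransform.make(["RT"]).fit(records)
        model = fk.train_lda(records, ft)
        mid_z = model.class_means.mean()  # transformed-space midpoint
        raw = 10 ** (mid_z * ft.scale["RT"] + ft.center["RT"])
        probe = records_frame({"A": {"rt_ms": np.array([raw])}})
        res = fk.predict_posteriors(model, probe)
        assert res.posteriors.iloc[0]["A"] == pytest.approx(0.5, abs=1e-9)
        assert res.posteriors.iloc[0]["B"] == pytest.approx(0.5, abs=1e-9)

    def test_missing_feature_errors(self):
        records = two_class_records()
        ft = fk.FeatureTransform.make(["PI", "RT"]).fit(records)
        model = fk.train_lda(records, ft)
        with pytest.raises(ValueError, match="missing feature"):
            fk.predict_posteriors(model, records.drop(columns=["rt_ms"]))

    def test_affine_rescaling_invariance(self):
        """With log10 + standardization, multiplying one raw feature by a
        constant leaves every prediction unchanged."""
        records = two_class_records(seed=5)
        scaled = records.copy()
        scaled["pi_photons_s"] = scaled["pi_photons_s"] * 137.0
        out = []
        for recs in (records, scaled):
            ft = fk.FeatureTransform.make(["PI", "RT"]).fit(recs)
            model = fk.train_lda(recs, ft)
            out.append(fk.predict_posteriors(model, recs).posteriors.to_numpy())
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)


class TestValidate:
    def test_training_means_classify_perfectly(self):
        records = two_class_records(sep=6.0)
        ft = fk.FeatureTransform.make(["PI", "RT"]).fit(records)
        model = fk.train_lda(records, ft)
        cm = fk.validate(model, records)
        assert cm.overall_accuracy > 0.99
        assert cm.counts.to_numpy().sum() == len(records)

    def test_genus_accuracy_dominates(self, cohort_records, library):
        excl = ["Pyrodinium bahamense"]
        train, test = fk.split_train_test(cohort_records, 0.3, seed=0)
        sub = train[~train.species.isin(excl)]
        ft = fk.FeatureTransform.make(["PI", "FD", "RT", "EF"]).fit(sub)
        model = fk.train_lda(sub, ft, excluded_species=excl,
                             genus_map=library.genus_map)
        cm = fk.validate(model, test[~test.species.isin(excl)])
        assert cm.genus_accuracy >= cm.overall_accuracy
        assert cm.counts.to_numpy().sum() == len(test[~test.species.isin(excl)])

    def test_accuracy_monotone_in_separation(self):
        """Fixed seeds, growing class separation: held-out accuracy never
        decreases."""
        accs = []
        for sep in (0.0, 1.0, 2.0, 4.0, 8.0):
            records = two_class_records(n=60, sep=sep, seed=9)
            train, test = fk.split_train_test(records, 0.3, seed=9)
            ft = fk.FeatureTransform.make(["PI", "RT"]).fit(train)
            model = fk.train_lda(train, ft)
            accs.append(fk.validate(model, test).overall_accuracy)
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_empty_or_unlabeled_test_set(self):
        records = two_class_records()
        ft = fk.FeatureTransform.make(["PI", "RT"]).fit(records)
        model = fk.train_lda(records, ft)
        with pytest.raises(ValueError, match="empty"):
            fk.validate(model, records.iloc[:0])
        unlabeled = records.copy()
        unlabeled["species"] = ""
        with pytest.raises(ValueError, match="labels"):
            fk.validate(model, unlabeled)


class TestModelIO:
    def test_json_round_trip(self, cohort_records, library, tmp_path):
        ft = fk.FeatureTransform.make(["PI", "FD", "RT", "EF"]).fit(cohort_records)
        model = fk.train_lda(cohort_records, ft, genus_map=library.genus_map)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = fk.LDAModel.load(path)
        assert loaded.classes == model.classes
        np.testing.assert_allclose(loaded.class_means, model.class_means)
        np.testing.assert_allclose(loaded.axes, model.axes)
        res_a = fk.predict_posteriors(model, cohort_records)
        res_b = fk.predict_posteriors(loaded, cohort_records)
        np.testing.assert_allclose(
            res_a.posteriors.to_numpy(), res_b.posteriors.to_numpy()
        )


class TestSplit:
    def test_stratified_disjoint_deterministic(self, cohort_records):
        train, test = fk.split_train_test(cohort_records, 0.3, seed=1)
        assert len(train) + len(test) == len(cohort_records)
        assert not set(train["trace_id"]) & set(test["trace_id"])
        for species, group in cohort_records.groupby("species"):
            n_test = (test["species"] == species).sum()
            assert abs(n_test - 0.3 * len(group)) <= 1
        train2, test2 = fk.split_train_test(cohort_records, 0.3, seed=1)
        assert train.equals(train2) and test.equals(test2)
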