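import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfa import feature_selection as fs
from vfa import inference as inf
from vfa import synthetic_data as syn
from vfa.nn import NetworkConfig

FAST_Q = NetworkConfig(hidden=(32, 16), dropout=0.0, epochs=600, patience=80)
FAST_C = NetworkConfig(loss="bce", hidden=(32, 8), dropout=0.0, epochs=400)


@pytest.fixture(scope="module")
def training(small_cohort):
    return fs.TrainingSet.from_cohort(small_cohort)


class TestMSLE:
    def test_identical_vectors_zero(self):
        assert inf.msle([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_closed_form_single_pair(self):
        assert inf.msle([0.0], [np.e - 1]) == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        y, yh = rng.uniform(0, 50, 40), rng.uniform(0, 50, 40)
        loop = sum(
            (np.log(1 + b) - np.log(1 + a)) ** 2 for a, b in zip(y, yh)
        ) / len(y)
        assert abs(inf.msle(y, yh) - loop) < 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            inf.msle([-1.0], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        y=st.lists(st.floats(0, 100), min_size=1, max_size=10),
        reps=st.integers(2, 5),
    )
    def test_mean_property_under_replication(self, y, reps):
        # appending identical pairs leaves the mean unchanged
        yh = [v + 1 for v in y]
        assert inf.msle(y * reps, yh * reps) == pytest.approx(inf.msle(y, yh))


class TestFeatureVector:
    def test_length_is_conditions_plus_batches(self, training, small_cohort):
        prep = inf.Preprocessing.fit(
            training, conditions=["Ab", "Ag", "Ag-low", "Mix1", "Mix2"]
        )
        t = small_cohort.tests[0]
        x = inf.build_feature_vector(t, prep, t.rid, t.fid)
        # 5 condition signals + one-hot RID (2) + one-hot FID (3)
        assert len(x) == 5 + 2 + 3

    def test_training_mean_maps_to_zero(self, training):
        prep = inf.Preprocessing.fit(training)
        X = prep.transform_training(training)
        n_cond = len(prep.conditions)
        assert np.allclose(X[:, :n_cond].mean(axis=0), 0.0, atol=1e-12)

    def test_batch_encoding_round_trip(self):
        B = inf.encode_batches(np.array([1, 2, 1]), np.array([3, 1, 2]),
                               [1, 2], [1, 2, 3])
        # decode by argmax and category lookup
        rids = [([1, 2])[i] for i in B[:, :2].argmax(axis=1)]
        fids = [([1, 2, 3])[i] for i in B[:, 2:].argmax(axis=1)]
        assert rids == [1, 2, 1] and fids == [3, 1, 2]

    def test_unseen_batch_label_rejected(self, training, small_cohort):
        prep = inf.Preprocessing.fit(training)
        t = small_cohort.tests[0]
        with pytest.raises(ValueError, match="RID"):
            inf.build_feature_vector(t, prep, 99, t.fid)


class TestClassifier:
    def test_linearly_separable_features_fit_exactly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (40, 3)), rng.normal(2, 0.3, (8, 3))])
        y = np.r_[np.zeros(40), np.ones(8)]
        model = inf.MLP(FAST_C)
        model.fit(X, y)
        assert (model.predict(X) == y).all()

    def test_synthetic_cohort_classified(self, training):
        prep = inf.Preprocessing.fit(training)
        clf = inf.train_classifier(training, prep, FAST_C)
        X = prep.transform_training(training)
        acc = (clf.predict(X) == training.acute).mean()
        assert acc == 1.0

    def test_single_class_rejected(self, training):
        hs_only = training.subset_tests(~training.acute)
        prep = inf.Preprocessing.fit(training)
        with pytest.raises(ValueError, match="both classes"):
            inf.train_classifier(hs_only, prep, FAST_C)


class TestQuantifier:
    def test_noise_free_cohort_fits_training(self, default_map, dose_models):
        design = syn.CohortDesign(n_hs_samples=40, replicates=1,
                                  acute_concentrations=())
        cohort = syn.simulate_cohort(
            design, default_map,
            noise_model=syn.NoiseModel(cv=0.0, background_sd=0.0),
            seed=0,
        )
        tr = fs.TrainingSet.from_cohort(cohort)
        prep = inf.Preprocessing.fit(tr)
        q = inf.train_quantifier(tr, prep, FAST_Q)
        pred = np.expm1(q.decision_function(prep.transform_training(tr)))
        r = np.corrcoef(pred, tr.concentration)[0, 1]
        assert r**2 >= 0.99

    def test_constant_target_predicts_constant(self, training):
        const = training.subset_tests(~training.acute)
        const.concentration[:] = 5.0
        prep = inf.Preprocessing.fit(const)
        # strong L2 drives the weights to zero under a constant target,
        # leaving the output bias as a constant predictor
        cfg = NetworkConfig(hidden=(16,), dropout=0.0, l2=0.1,
                            epochs=3000, patience=400)
        q = inf.train_quantifier(const, prep, cfg)
        pred = np.expm1(q.decision_function(prep.transform_training(const)))
        assert pred.std() < 0.01 * pred.mean()


@pytest.fixture(scope="module")
def bundle(training):
    return inf.train_model_bundle(
        training, classifier_config=FAST_C, quantifier_config=FAST_Q, seed=0
    )


class TestBundlePredict:
    def test_acute_sample_routed_acute(self, bundle, small_cohort):
        t = next(t for t in small_cohort.tests if t.truth_mg_l == 1000.0)
        res = inf.predict(bundle, t)
        assert res.mode == "acute"
        assert res.confidence > 0.5

    def test_hs_sample_quantified_with_stratum(self, bundle, small_cohort):
        t = min(
            (t for t in small_cohort.tests if t.truth_mg_l <= 10),
            key=lambda t: abs(t.truth_mg_l - 2.0),
        )
        res = inf.predict(bundle, t)
        assert res.mode == "quantified"
        assert res.concentration >= 0

    def test_inference_deterministic(self, bundle, small_cohort):
        t = small_cohort.tests[0]
        a = inf.predict(bundle, t)
        b = inf.predict(bundle, t)
        assert (a.mode, a.concentration, a.confidence) == (
            b.mode, b.concentration, b.confidence,
        )

    def test_qc_failed_input_rejected(self, bundle, small_cohort):
        t = small_cohort.tests[0]
        bad = fs.SignalTable(
            t.data.copy(), test_id="bad", rid=t.rid, fid=t.fid,
            qc_pass=False, qc_reasons=["misalignment"],
        )
        with pytest.raises(ValueError, match="QC"):
            inf.predict(bundle, bad)

    def test_save_load_round_trip(self, bundle, small_cohort, tmp_path):
        bundle.save(tmp_path / "b")
        back = inf.ModelBundle.load(tmp_path / "b")
        t = small_cohort.tests[0]
        a, b = inf.predict(bundle, t), inf.predict(back, t)
        assert a.mode == b.mode
        assert a.confidence == pytest.approx(b.confidence)
        if a.concentration is not None:
            assert a.concentration == pytest.approx(b.concentration)


class TestHyperparameterSearch:
    def test_single_draw_returns_it(self, training):
        space = {"hidden": [(8,)], "dropout": [0.0]}
        cfg, table = inf.hyperparameter_search(
            training, space, n_draws=1, k=2, seed=0
        )
        assert cfg.hidden == (8,) and len(table) == 1

    def test_capacity_ordering_prefers_wider_net(self, training):
        space = {"hidden": [(1,), (32, 16)], "epochs": [300]}
        cfg, table = inf.hyperparameter_search(
            training, space, n_draws=6, k=2, seed=1
        )
        assert cfg.hidden == (32, 16)

    def test_identical_seed_identical_table(self, training):
        space = {"hidden": [(4,), (8,)], "dropout": [0.0, 0.2]}
        _, t1 = inf.hyperparameter_search(training, space, n_draws=4, k=2, seed=5)
        _, t2 = inf.hyperparameter_search(training, space, n_draws=4, k=2, seed=5)
        assert t1.equals(t2)

    def test_empty_space_rejected(self, training):
        with pytest.raises(ValueError, match="empty"):
            inf.hyperparameter_search(training, {}, n_draws=1, k=2, seed=0)


class TestBaseline:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        n = 50
        conc = rng.uniform(0.5, 9.5, n)
        # channels summing to a constant: after normalization the first
        # feature is conc/10, exactly linear in concentration
        net = np.column_stack([conc, 10.0 - conc])
        tr_fs = fs.TrainingSet(
            net_signals=net,
            spots=[(0, 0), (0, 1)],
            spot_conditions=np.array(["a", "b"]),
            concentration=conc,
            rid=np.ones(n, dtype=int),
            fid=np.ones(n, dtype=int),
            sample_id=np.array([f"s{i}" for i in range(n)]),
            test_id=np.array([f"t{i}" for i in range(n)]),
        )
        model = inf.baseline_regression(tr_fs)
        X = model.preprocessing.transform_training(tr_fs)
        pred = model.predict_features(X)
        assert np.corrcoef(pred, conc)[0, 1] ** 2 > 1 - 1e-9

    def test_matches_normal_equations_oracle(self, training):
        # the least-squares fitted values are the projection onto the design
        # column space, so they must match a pinv normal-equations solution
        # regardless of how the collinear one-hot blocks are parameterized
        model = inf.baseline_regression(training)
        hs = ~training.acute
        X = model.preprocessing.transform_training(training.subset_tests(hs))
        A = np.column_stack([X, np.ones(len(X))])
        beta = np.linalg.pinv(A.T @ A) @ A.T @ training.concentration[hs]
        assert np.allclose(model.predict_features(X), A @ beta, atol=1e-8)

    def test_hook_data_baseline_below_network(self, paper_scale_splits):
        wins = 0
        for training, test_t in paper_scale_splits:
            bundle = inf.train_model_bundle(
                training, classifier_config=FAST_C,
                quantifier_config=NetworkConfig(hidden=(64, 32), dropout=0.0,
                                                epochs=1000, patience=100),
                seed=0,
            )
            base = inf.baseline_regression(training)
            hs_tests = [t for t in test_t if t.truth_mg_l <= 10]
            truth = np.array([t.truth_mg_l for t in hs_tests])
            net_pred, base_pred = [], []
            for t in hs_tests:
                res = inf.predict(bundle, t)
                net_pred.append(res.concentration if res.mode == "quantified"
                                else 10.0)
                base_pred.append(base.predict_table(t))
            r2_net = np.corrcoef(net_pred, truth)[0, 1] ** 2
            r2_base = np.corrcoef(base_pred, truth)[0, 1] ** 2
            wins += r2_base < r2_net
        assert wins >= 4  # network beats OLS on hook-affected data
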