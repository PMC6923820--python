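import numpy as np
import pytest

from mvfae import losses, model_core, netprep, synthdata, training
from mvfae.losses import LossWeights
from mvfae.training import (
    SplitAssignment,
    TrainConfig,
    evaluate,
    run_experiment,
    split_dataset,
    train,
)


class TestTrainConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate_initial == 5e-4
        assert cfg.iters_per_phase == 500
        assert cfg.lr_drop_factor == 10.0
        assert cfg.weight_decay == 1e-4
        assert cfg.split_fractions == (0.7, 0.1, 0.2)
        assert cfg.learning_rate_at(0) == 5e-4
        assert cfg.learning_rate_at(499) == 5e-4
        assert cfg.learning_rate_at(500) == pytest.approx(5e-5)
        assert cfg.total_iterations == 1000

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fractions=(0.5, 0.5, 0.5))

    def test_invalid_lr(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate_initial=0)


class TestSplitDataset:
    def test_sizes_for_ten(self):
        s = split_dataset(10, (0.7, 0.1, 0.2), seed=0)
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (7, 1, 2)

    def test_seed_determinism(self):
        s1 = split_dataset(50, seed=3)
        s2 = split_dataset(50, seed=3)
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        np.testing.assert_array_equal(s1.test_idx, s2.test_idx)

    def test_partition_property(self):
        s = split_dataset(23, seed=1)
        merged = np.sort(np.concatenate([s.train_idx, s.val_idx, s.test_idx]))
        np.testing.assert_array_equal(merged, np.arange(23))

    def test_remainder_goes_train_first(self):
        s = split_dataset(12, (0.7, 0.1, 0.2), seed=0)
        # floors are (8, 1, 2); the one leftover sample joins train
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (9, 1, 2)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            split_dataset(3, (0.7, 0.1, 0.2), seed=0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitAssignment(np.array([0, 1]), np.array([1]), np.array([2]))


class TestGradients:
    """Finite-difference checks of the analytic gradients."""

    @pytest.fixture
    def instance(self):
        rng = np.random.default_rng(4)
        spec = synthdata.SyntheticSpec(
            N=12,
            views=(synthdata.ViewGenSpec(7, 0.2), synthdata.ViewGenSpec(5, 0.2)),
            k_true=3,
            n_clusters=3,
            seed=2,
        )
        b = synthdata.generate(spec)
        arrays = [v.values for v in b.views]
        laps = [netprep.graph_laplacian(g).matrix for g in b.networks]
        specs = tuple(
            model_core.ViewSpec(f"v{i}", a.shape[1], (6, 3))
            for i, a in enumerate(arrays)
        )
        model = model_core.build_model(specs, 2, seed=3)
        return model, arrays, b.labels, laps

    @pytest.mark.parametrize(
        "weights",
        [
            LossWeights(eta=0, alpha=0, beta=0),
            LossWeights(eta=0.7, alpha=1.3, beta=0),
        ],
    )
    def test_matches_finite_differences(self, instance, weights):
        model, arrays, labels, laps = instance
        _, grads = training._forward_backward(model, arrays, labels, laps, weights)

        def total():
            bd, _ = training._forward_backward(model, arrays, labels, laps, weights)
            return bd.total

        state = model_core.model_state(model)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, p in state.items():
            flat_idx = rng.choice(p.size, size=min(4, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                f1 = total()
                p[idx] = old - eps
                f2 = total()
                p[idx] = old
                numeric = (f1 - f2) / (2 * eps)
                analytic = grads[name][idx]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-6), name

    def test_beta_gradient_matches_frozen_laplacian(self, instance):
        """The beta term's gradient treats L_S as a constant (stop-gradient);
        verify against finite differences of the frozen-L_S objective."""
        model, arrays, labels, laps = instance
        weights = LossWeights(eta=0.7, alpha=1.3, beta=0.9)
        _, grads = training._forward_backward(model, arrays, labels, laps, weights)
        names = model.view_names
        latents = [model_core.encode(model, v, a) for v, a in zip(names, arrays)]
        fused = model_core.fuse_views(latents)
        S = losses.fuse_similarity(
            [losses.cosine_similarity_network(x) for x in latents],
            losses.cosine_similarity_network(fused),
        )
        L_S = losses.similarity_laplacian(S).matrix

        def frozen_total():
            lat = [model_core.encode(model, v, a) for v, a in zip(names, arrays)]
            fz = model_core.fuse_views(lat)
            ce = losses.cross_entropy(labels, model_core.classify(model, fz))
            rec = sum(
                losses.reconstruction_loss(a, model_core.decode(model, v, x))
                for v, a, x in zip(names, arrays, lat)
            )
            fr = sum(
                losses.feature_network_regularizer(model.decoders[v], L)
                for v, L in zip(names, laps)
            )
            vr = sum(losses.view_similarity_regularizer(x, L_S) for x in lat)
            return ce + weights.eta * rec + weights.alpha * fr + weights.beta * vr

        state = model_core.model_state(model)
        eps = 1e-6
        rng = np.random.default_rng(1)
        for name, p in state.items():
            for fi in rng.choice(p.size, size=min(3, p.size), replace=False):
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                f1 = frozen_total()
                p[idx] = old - eps
                f2 = frozen_total()
                p[idx] = old
                numeric = (f1 - f2) / (2 * eps)
                assert numeric == pytest.approx(grads[name][idx], rel=1e-4, abs=1e-6)

    def test_full_similarity_gradient_not_implemented(self, instance):
        model, arrays, labels, laps = instance
        with pytest.raises(NotImplementedError):
            training._forward_backward(
                model, arrays, labels, laps, LossWeights(),
                stop_gradient_similarity=False,
            )


def _quick_train(bundle, weights, seed=0, iters=50, lr=5e-3, on_step=None):
    cfg = TrainConfig(
        weights=weights, learning_rate_initial=lr, iters_per_phase=iters, seed=seed
    )
    split = split_dataset(bundle.n_samples, cfg.split_fractions, seed=seed)
    specs = tuple(
        model_core.ViewSpec(f"v{i}", v.n_features, (8, 4))
        for i, v in enumerate(bundle.views)
    )
    model = model_core.build_model(specs, 2, seed=seed)
    laps = [netprep.graph_laplacian(g) for g in bundle.networks]
    best, hist = train(
        model, [v.values for v in bundle.views], bundle.labels, laps, cfg, split,
        on_step=on_step,
    )
    return best, hist, split


class TestTrain:
    def test_determinism(self, tiny_bundle):
        _, h1, _ = _quick_train(tiny_bundle, LossWeights(beta=1e-4), iters=20)
        _, h2, _ = _quick_train(tiny_bundle, LossWeights(beta=1e-4), iters=20)
        for r1, r2 in zip(h1.records, h2.records):
            assert r1 == r2

    def test_history_length(self, tiny_bundle):
        _, hist, _ = _quick_train(tiny_bundle, LossWeights(alpha=0, beta=0), iters=15)
        assert len(hist.records) == 30
        assert len(hist.val_accuracy) == 30

    def test_separable_task_reaches_full_training_accuracy(self):
        # classification-only objective on strongly separable synthetic labels
        spec = synthdata.SyntheticSpec(
            N=60,
            views=(synthdata.ViewGenSpec(10, 0.01),),
            k_true=2,
            label_strength=50.0,
            n_clusters=3,
            seed=9,
        )
        b = synthdata.generate(spec)
        w = LossWeights(eta=0, alpha=0, beta=0)
        split = split_dataset(b.n_samples, seed=9)
        views = [v.values for v in b.views]
        train_acc = []

        def track(it, model, record):
            if it % 50 == 49:
                train_acc.append(
                    evaluate(model, views, b.labels, split.train_idx)["accuracy"]
                )

        _quick_train(b, w, seed=9, iters=300, lr=1e-2, on_step=track)
        assert max(train_acc) == 1.0

    def test_best_iteration_is_argmax_of_history(self, tiny_bundle):
        _, hist, _ = _quick_train(tiny_bundle, LossWeights(alpha=0, beta=0), iters=25)
        accs = np.asarray(hist.val_accuracy)
        assert hist.best_iteration == int(np.argmax(accs))

    def test_decoder_norms_after_every_step(self, tiny_bundle):
        norms_ok = []

        def check(it, model, record):
            for Y in model.decoders.values():
                p = Y.shape[1]
                norms = np.linalg.norm(Y, axis=0)
                norms_ok.append(np.allclose(norms, 1 / np.sqrt(p), atol=1e-6))

        _quick_train(tiny_bundle, LossWeights(beta=1e-4), iters=10, on_step=check)
        assert norms_ok and all(norms_ok)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nonfinite_loss_aborts_with_term_name(self, tiny_bundle):
        views = [v.values.copy() for v in tiny_bundle.views]
        views[0][0, 0] = np.inf
        cfg = TrainConfig(weights=LossWeights(alpha=0, beta=0), iters_per_phase=2)
        split = split_dataset(tiny_bundle.n_samples, seed=0)
        specs = tuple(
            model_core.ViewSpec(f"v{i}", v.shape[1], (4, 2))
            for i, v in enumerate(views)
        )
        model = model_core.build_model(specs, 2, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, views, tiny_bundle.labels, None, cfg, split)

    def test_loss_trend_non_increasing(self, tiny_bundle):
        _, hist, _ = _quick_train(
            tiny_bundle, LossWeights(alpha=1.0, beta=1e-4), iters=100
        )
        totals = np.array([r["total"] for r in hist.records])
        # linear-fit slope over each non-overlapping 100-iteration window
        for start in range(0, 200, 100):
            window = totals[start : start + 100]
            slope = np.polyfit(np.arange(100), window, 1)[0]
            assert slope < 0


class TestEvaluate:
    def _constant_model(self):
        spec = [model_core.ViewSpec("v", 2, (2,))]
        return model_core.build_model(spec, 2, seed=0)

    def test_metric_oracle_four_samples(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        # exhaustive pair enumeration: 3 of 4 (pos, neg) pairs concordant
        pairs = [(i, j) for i in range(4) for j in range(4)
                 if labels[i] == 1 and labels[j] == 0]
        concordant = sum(scores[i] > scores[j] for i, j in pairs)
        assert concordant / len(pairs) == 0.75
        assert roc_auc_score(labels, scores) == pytest.approx(0.75)
        # step-wise precision-recall sum: positives at ranks 1 and 3
        assert average_precision_score(labels, scores) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3)
        )

    def test_perfect_ranking(self, tiny_bundle):
        best, _, split = _quick_train(
            tiny_bundle, LossWeights(alpha=0, beta=0), iters=5
        )
        # direct check through the evaluate() contract with a rigged model is
        # impractical; instead verify bounds on real outputs
        m = evaluate(best, [v.values for v in tiny_bundle.views], tiny_bundle.labels,
                     split.test_idx)
        assert 0 <= m["auc"] <= 1 and 0 <= m["average_precision"] <= 1

    def test_single_class_subset_reports_missing(self, tiny_bundle):
        best, _, _ = _quick_train(tiny_bundle, LossWeights(alpha=0, beta=0), iters=5)
        idx = np.where(tiny_bundle.labels == 1)[0][:4]
        with pytest.warns(UserWarning, match="single-class"):
            m = evaluate(best, [v.values for v in tiny_bundle.views],
                         tiny_bundle.labels, idx)
        assert m["auc"] is None and m["average_precision"] is None

    def test_out_of_range_indices(self, tiny_bundle):
        best, _, _ = _quick_train(tiny_bundle, LossWeights(alpha=0, beta=0), iters=5)
        with pytest.raises(ValueError, match="out of range"):
            evaluate(best, [v.values for v in tiny_bundle.views],
                     tiny_bundle.labels, np.array([1000]))


class TestRunExperiment:
    def test_ablation_grid_term_activation(self, tiny_bundle):
        """The four objectives differ exactly by which terms are weighted in."""
        combos = {
            "mae": (0.0, 0.0),
            "feat_int": (100.0, 0.0),
            "view_sim": (0.0, 1e-4),
            "both": (100.0, 1e-4),
        }
        results = {}
        for name, (alpha, beta) in combos.items():
            cfg = TrainConfig(
                weights=LossWeights(eta=1, alpha=alpha, beta=beta),
                iters_per_phase=5,
                learning_rate_initial=5e-3,
                seed=0,
            )
            results[name] = run_experiment(tiny_bundle, cfg, hidden_dims=(8, 4))
        for name, res in results.items():
            rec = res["history"].records[0]
            alpha, beta = combos[name]
            weighted_feat = alpha * rec["feature_reg_total"]
            weighted_view = beta * rec["view_reg_total"]
            expected = (
                rec["classification"]
                + rec["reconstruction_total"]
                + weighted_feat
                + weighted_view
            )
            assert rec["total"] == pytest.approx(expected, rel=1e-6)
            if alpha == 0:
                assert rec["total"] == pytest.approx(
                    rec["total"] - weighted_feat, rel=1e-12
                )

    def test_rerun_reproduces_results(self, tiny_bundle):
        cfg = TrainConfig(weights=LossWeights(beta=1e-4), iters_per_phase=10, seed=5)
        r1 = run_experiment(tiny_bundle, cfg, hidden_dims=(8, 4))
        r2 = run_experiment(tiny_bundle, cfg, hidden_dims=(8, 4))
        assert r1["metrics"] == r2["metrics"]
        assert r1["best_iteration"] == r2["best_iteration"]
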