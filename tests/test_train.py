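"""Partitions, composite sampling, and the adversarial training loop."""

import numpy as np
import pandas as pd
import pytest

from histobias.biasaudit import BiasSpec, squared_distance_correlation
from histobias.model import DenseStack, NetworkSpec, bias_loss_grad, build_state
from histobias.synthgen import SynthConfig, synthesize_dataset
from histobias.train import (TrainConfig, adversarial_iteration,
                             composite_weights, extract_features,
                             grouped_kfold_split, predict_proba, train_model)


def _manifest(patients, tiles_per_patient, labels):
    rows = []
    for p, n, lab in zip(patients, tiles_per_patient, labels):
        rows += [(p, lab)] * n
    return pd.DataFrame(rows, columns=["patient", "msi_label"])


class TestGroupedKFold:
    def test_two_patients_per_validation_fold(self):
        m = _manifest([f"p{i}" for i in range(10)], [3] * 10,
                      ["MSS"] * 8 + ["MSI-H"] * 2)
        plan = grouped_kfold_split(m, k=5, seed=0)
        for f in range(5):
            val_patients = set(m["patient"].iloc[plan.val_indices(f)])
            assert len(val_patients) == 2

    def test_no_patient_spans_train_and_validation(self, small_cohort):
        m = small_cohort.manifest
        plan = grouped_kfold_split(m, k=5, seed=1)
        seen_in_val = []
        for f in range(5):
            tr = set(m["patient"].iloc[plan.train_indices(f)])
            va = set(m["patient"].iloc[plan.val_indices(f)])
            assert not tr & va
            assert len(plan.train_indices(f)) + len(plan.val_indices(f)) == len(m)
            seen_in_val.append(va)
        # every patient validates exactly once
        all_val = [p for s in seen_in_val for p in s]
        assert sorted(all_val) == sorted(m["patient"].unique())

    def test_fold_sizes_within_one_patient(self):
        m = _manifest([f"p{i}" for i in range(13)], [2] * 13, ["MSS"] * 13)
        plan = grouped_kfold_split(m, k=5, seed=2)
        sizes = [len({p for p, f in plan.patient_fold.items() if f == k})
                 for k in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, small_cohort):
        m = small_cohort.manifest
        a = grouped_kfold_split(m, k=5, seed=3)
        b = grouped_kfold_split(m, k=5, seed=3)
        assert a.patient_fold == b.patient_fold
        assert all(np.array_equal(a.val_indices(f), b.val_indices(f))
                   for f in range(5))

    def test_more_folds_than_patients_rejected(self):
        m = _manifest(["p0", "p1"], [2, 2], ["MSS", "MSI-H"])
        with pytest.raises(ValueError):
            grouped_kfold_split(m, k=5)


class TestCompositeWeights:
    def test_monte_carlo_matches_closed_form(self):
        """MSS patients A (10 tiles) and B (30), MSI-H patient C (5):
        empirical draws split classes 50/50 and A vs B equally."""
        m = _manifest(["A", "B", "C"], [10, 30, 5],
                      ["MSS", "MSS", "MSI-H"])
        w = composite_weights(m)
        assert w.sum() == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(m), size=100_000, replace=True, p=w)
        pat = m["patient"].to_numpy()[draws]
        cls = m["msi_label"].to_numpy()[draws]
        assert abs((cls == "MSS").mean() - 0.5) < 0.01
        assert abs((pat == "A").mean() - (pat == "B").mean()) < 0.01

    def test_closed_form_class_and_patient_expectations(self):
        m = _manifest(["A", "B", "C", "D"], [7, 13, 5, 25],
                      ["MSS", "MSS", "MSI-H", "MSI-H"])
        w = composite_weights(m)
        for cls in ("MSS", "MSI-H"):
            assert w[(m["msi_label"] == cls).to_numpy()].sum() == \
                pytest.approx(0.5)
        for pat in "ABCD":
            assert w[(m["patient"] == pat).to_numpy()].sum() == \
                pytest.approx(0.25)

    def test_single_patient_per_class_equal_tiles_uniform(self):
        m = _manifest(["A", "B"], [4, 4], ["MSS", "MSI-H"])
        assert np.allclose(composite_weights(m), 1 / 8)

    def test_empirical_frequencies_within_3_sigma(self):
        m = _manifest(["A", "B", "C"], [10, 30, 5], ["MSS", "MSS", "MSI-H"])
        w = composite_weights(m)
        n = 50_000
        rng = np.random.default_rng(1)
        counts = np.bincount(rng.choice(len(m), n, replace=True, p=w),
                             minlength=len(m))
        sigma = np.sqrt(n * w * (1 - w))
        assert (np.abs(counts - n * w) <= 3.3 * sigma).mean() > 0.97

    def test_missing_class_rejected(self):
        m = _manifest(["A"], [5], ["MSS"])
        with pytest.raises(ValueError):
            composite_weights(m)


class TestAdversarialIteration:
    SPEC = NetworkSpec(input_px=4, feature_dim=8, head_hidden=8)

    def _inputs(self, n=32, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, self.SPEC.input_dim))
        y = rng.integers(0, 2, n)
        enc = np.zeros((n, 2))
        enc[np.arange(n), rng.integers(0, 2, n)] = 1.0
        return X, y, enc

    def test_small_rho_subbatch_skips_adversarial_steps(self):
        X, y, enc = self._inputs()
        state = build_state(self.SPEC, [BiasSpec("b", ("0", "1"))], seed=0)
        before = state.bes[0].copy_parameters()
        rho = np.zeros(len(X), dtype=bool)
        rho[:3] = True  # below min_bias_batch
        m = adversarial_iteration(X, y, [enc], rho, state, min_bias_batch=8)
        assert m["bias_steps_skipped"]
        for a, b in zip(before, state.bes[0].parameters()):
            assert np.array_equal(a, b)

    def test_step_two_learns_a_linearly_predictable_bias(self):
        """With the feature extractor frozen, repeated head updates on a
        fixed batch drive corr²(b, b̂) up (the head masters its bias)."""
        rng = np.random.default_rng(4)
        state = build_state(self.SPEC, [BiasSpec("b", ("0", "1"))],
                            lr=1e-2, seed=4)
        X = rng.normal(size=(64, self.SPEC.input_dim))
        F = state.fe.forward(X, cache=False)
        # a bias carried linearly by the frozen features
        b = (F[:, 0] > np.median(F[:, 0])).astype(float)[:, None]
        corr2 = []
        be = state.bes[0]
        for _ in range(50):
            out = be.forward(F)
            loss, dout = bias_loss_grad(np.hstack([b, 1 - b]), out)
            corr2.append(-loss)
            _, g = be.backward(dout)
            state.opt_bes[0].step(be.parameters(), g)
        assert corr2[-1] > corr2[0] + 0.5
        assert corr2[-1] > 1.5  # near-perfect on both columns

    def test_toy_bias_coordinate_removed_signal_kept(self):
        """Inputs where one coordinate is the bias and another the label:
        after adversarial training a freshly fitted probe can no longer
        predict the bias from F on held-out conditioned-class rows, while
        MSI accuracy survives."""
        rng = np.random.default_rng(6)
        spec = self.SPEC
        n = 256
        X = rng.normal(size=(n, spec.input_dim)) * 0.1
        y = rng.integers(0, 2, n)
        bias = rng.integers(0, 2, n)
        X[:, 0] = y * 2.0 - 1.0 + 0.2 * rng.normal(size=n)
        X[:, 1] = bias * 2.0 - 1.0 + 0.2 * rng.normal(size=n)
        enc = np.stack([1.0 - bias, bias], axis=1)
        state = build_state(spec, [BiasSpec("b", ("0", "1"))],
                            lam=4.0, lr=3e-3, seed=6)
        rho = y == 0  # "MSS"-conditioned
        for _ in range(500):
            idx = rng.choice(n, 64, replace=False)
            adversarial_iteration(X[idx], y[idx], [enc[idx]], rho[idx], state)
        # held-out probe data from the same generative law
        Xh = rng.normal(size=(n, spec.input_dim)) * 0.1
        yh = rng.integers(0, 2, n)
        bh = rng.integers(0, 2, n)
        Xh[:, 0] = yh * 2.0 - 1.0 + 0.2 * rng.normal(size=n)
        Xh[:, 1] = bh * 2.0 - 1.0 + 0.2 * rng.normal(size=n)
        F = extract_features(state, Xh)
        msi_acc = (predict_proba(state, Xh)[:, 1].round() == yh).mean()
        assert msi_acc > 0.9
        # fresh linear probe for the bias on the conditioned class
        from sklearn.linear_model import LinearRegression

        mask = yh == 0
        probe = LinearRegression().fit(F[mask], bh[mask])
        pred = probe.predict(F[mask])
        r = np.corrcoef(pred, bh[mask])[0, 1]
        assert (0.0 if np.isnan(r) else r * r) < 0.2


class TestTrainModel:
    def test_lambda_zero_reduces_to_baseline_bitwise(self, lambda_zero_pair):
        base, ablated = lambda_zero_pair
        for a, b in zip(base.state.fe.parameters(),
                        ablated.state.fe.parameters()):
            assert np.array_equal(a, b)
        for a, b in zip(base.state.msi.parameters(),
                        ablated.state.msi.parameters()):
            assert np.array_equal(a, b)

    def test_no_msih_patients_rejected(self):
        cfg = SynthConfig(n_patients=12, tiles_per_patient_range=(3, 4),
                          msi_prevalence=0.0, tile_px=32, seed=1)
        ds = synthesize_dataset(cfg)
        plan = grouped_kfold_split(ds.manifest, k=3, seed=1)
        tc = TrainConfig(network=NetworkSpec(), epochs=1, batch_size=16, seed=1)
        with pytest.raises(ValueError):
            train_model(ds.manifest, ds.images, plan, 0, tc, ablate=False)

    def test_dc_trace_monitoring(self):
        cfg = SynthConfig(n_patients=24, tiles_per_patient_range=(4, 6),
                          msi_prevalence=0.3, tile_px=32, seed=2,
                          project_confound=0.8)
        ds = synthesize_dataset(cfg)
        plan = grouped_kfold_split(ds.manifest, k=4, seed=2)
        tc = TrainConfig(network=NetworkSpec(), lam=1.0, epochs=2,
                         batch_size=32, seed=2, log_dc=True)
        res = train_model(ds.manifest, ds.images, plan, 0, tc, ablate=True)
        assert {"dc_msi", "dc_project", "dc_patient",
                "dc_glass"} <= set(res.trace.columns)
        dc_cols = res.trace.filter(like="dc_")
        assert ((dc_cols >= 0) & (dc_cols <= 1)).all().all()
        assert len(res.trace) == res.state.iteration

    def test_overfitting_signature_beyond_epoch_cap(self):
        """Trained far past the epoch cap, the baseline memorises: training
        loss keeps shrinking while the generalisation gap opens up."""
        from histobias.model import msi_loss
        from histobias.preprocess import tiles_to_network_input

        cfg = SynthConfig(n_patients=40, tiles_per_patient_range=(8, 12),
                          msi_prevalence=0.25, tile_px=64, seed=3,
                          signal_strength=0.4, patient_texture_sd=0.08,
                          project_confound=0.0)
        ds = synthesize_dataset(cfg)
        plan = grouped_kfold_split(ds.manifest, k=5, seed=3)
        tc = TrainConfig(network=NetworkSpec(), lam=0.0, lr=1e-3,
                         batch_size=64, epochs=40, seed=3, log_dc=True)
        res = train_model(ds.manifest, ds.images, plan, 0, tc, ablate=False)
        per_epoch = res.trace.groupby("epoch")["loss_msi"].mean() / tc.batch_size
        X = tiles_to_network_input(ds.images, 16)
        y = (ds.manifest["msi_label"] == "MSI-H").astype(int).to_numpy()
        val_loss = msi_loss(y[res.val_indices],
                            predict_proba(res.state, X[res.val_indices])
                            ) / len(res.val_indices)
        assert per_epoch.iloc[-1] < 0.5 * per_epoch.iloc[0]
        assert val_loss > 1.5 * per_epoch.iloc[-1]

    def test_early_stopping_patience(self):
        cfg = SynthConfig(n_patients=24, tiles_per_patient_range=(4, 6),
                          msi_prevalence=0.3, tile_px=32, seed=4)
        ds = synthesize_dataset(cfg)
        plan = grouped_kfold_split(ds.manifest, k=4, seed=4)
        tc = TrainConfig(network=NetworkSpec(), lam=0.0, epochs=30,
                         batch_size=32, seed=4, log_dc=True, patience=2)
        res = train_model(ds.manifest, ds.images, plan, 0, tc, ablate=False)
        assert res.trace["epoch"].max() < 29  # stopped before the cap
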