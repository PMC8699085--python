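"""Adversarial bias-distillation training.

The end-to-end system plays a min-max game

    min_{θfe, θmsi}  max_{θbe}   Lmsi − λ Σₙ Lbeₙ

executed as three sub-steps per iteration, in order:

1. back-propagate the classification loss ``Lmsi`` and update θfe and θmsi;
2. for each bias, with θfe fixed, minimise that head's ``Lbe`` (making the
   head as good as possible at predicting its bias) and update θbe;
3. for each bias, with θbe fixed, maximise ``Lbe`` scaled by λ and update
   θfe — distilling the bias signature out of the features.

Steps 2–3 run only on the ρ-conditioned sub-batch (by default the MSS
samples), so the features become *conditionally* independent of each bias
given the label rather than being stripped of everything the bias happens
to correlate with.

Sampling follows the cohort-imbalance recipe: each tile's draw probability
is proportional to ``1 / (tiles of its patient × patients in its class)``,
which balances classes and patients simultaneously; partitions are grouped
by patient so no patient ever spans train and validation of a fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import model as _model
from .biasaudit import BiasSpec, squared_distance_correlation
from .preprocess import tiles_to_network_input

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "TrainResult",
    "grouped_kfold_split",
    "composite_weights",
    "adversarial_iteration",
    "train_model",
    "extract_features",
    "predict_proba",
    "default_bias_specs",
]


# ---------------------------------------------------------------------------
# partitions and sampling
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Patient-grouped k-fold partition of a tile manifest."""

    k: int
    patient_fold: dict            # patient id -> validation fold index
    folds: list                   # fold -> dict(train=indices, val=indices)

    def train_indices(self, fold: int) -> np.ndarray:
        return self.folds[fold]["train"]

    def val_indices(self, fold: int) -> np.ndarray:
        return self.folds[fold]["val"]


def grouped_kfold_split(manifest: pd.DataFrame, k: int = 5,
                        seed: int = 0) -> FoldPlan:
    """Split tiles into k folds at the patient level.

    Patients are shuffled deterministically under ``seed`` and dealt into k
    nearly equal groups (sizes within ±1 patient); a fold's validation set
    is all tiles of its patient group and its training set is everything
    else, so no patient's images ever appear on both sides.
    """
    patients = np.asarray(sorted(manifest["patient"].unique()))
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the {len(patients)} patients available")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 41])))
    shuffled = patients[rng.permutation(len(patients))]
    groups = np.array_split(shuffled, k)
    patient_fold = {p: f for f, grp in enumerate(groups) for p in grp}
    fold_of_tile = manifest["patient"].map(patient_fold).to_numpy()
    folds = []
    for f in range(k):
        val = np.flatnonzero(fold_of_tile == f)
        train = np.flatnonzero(fold_of_tile != f)
        assert not set(manifest["patient"].iloc[val]) & set(manifest["patient"].iloc[train])
        folds.append({"train": train, "val": val})
    return FoldPlan(k=k, patient_fold=patient_fold, folds=folds)


def composite_weights(manifest: pd.DataFrame) -> np.ndarray:
    """Per-tile sampling weights balancing class and patient simultaneously.

    Weight ∝ 1 / (tiles of the patient × patients in the class).  Under
    with-replacement sampling the expected class draw is ½ each and, within
    a class, every patient is drawn uniformly regardless of tile count.
    """
    classes = manifest["msi_label"].unique()
    if not {"MSI-H", "MSS"}.issubset(set(classes)) and len(classes) < 2:
        raise ValueError("both MSI-H and MSS tiles are required")
    tiles_per_patient = manifest.groupby("patient")["patient"].transform("size")
    patients_per_class = manifest.groupby("msi_label")["patient"].transform("nunique")
    w = 1.0 / (tiles_per_patient.to_numpy() * patients_per_class.to_numpy())
    return w / w.sum()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_bias_specs(manifest: pd.DataFrame,
                       names: Sequence[str] = ("project", "patient", "glass"),
                       conditioning_group: str = "MSS") -> list:
    """One BiasSpec per protected variable, levels read off the manifest."""
    return [
        BiasSpec(name=n, levels=tuple(sorted(manifest[n].unique())),
                 conditioning_group=conditioning_group)
        for n in names
    ]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``lam`` is the adversarial weight λ (0 disables the fooling step and
    reduces the trainer exactly to the baseline); ``epochs`` defaults to the
    3-epoch cap beyond which tile-level models memorise patient signatures;
    ``min_bias_batch`` is the smallest ρ-conditioned sub-batch on which the
    adversarial steps still run.  ``batch_size`` 128 is the desk-scale
    default (512 at full scale).  ``patience``, if set, stops early when
    validation loss fails to improve that many epochs in a row.
    """

    network: _model.NetworkSpec = field(default_factory=_model.NetworkSpec)
    lam: float = 1.0
    lr: float = 3e-4
    lr_bias: Optional[float] = None
    batch_size: int = 128
    epochs: int = 3
    min_bias_batch: int = 8
    seed: int = 0
    log_dc: bool = True
    patience: Optional[int] = None


@dataclass
class TrainResult:
    state: _model.TrainState
    trace: pd.DataFrame           # per-iteration dc monitoring rows
    train_indices: np.ndarray
    val_indices: np.ndarray
    skipped_bias_steps: int = 0


# ---------------------------------------------------------------------------
# the three-step iteration
# ---------------------------------------------------------------------------

def _encode_fixed(values: np.ndarray, levels: Sequence) -> np.ndarray:
    """Fixed-width indicator encoding against a frozen level list (training
    heads need a constant output width; levels absent from a batch yield
    constant zero columns that contribute nothing to the correlation)."""
    index = {lev: i for i, lev in enumerate(levels)}
    mat = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        j = index.get(v)
        if j is not None:  # values outside the frozen list encode as zero rows
            mat[i, j] = 1.0
    return mat


def adversarial_iteration(
    X_batch: np.ndarray,
    y_batch: np.ndarray,
    bias_encodings: Sequence[np.ndarray],
    rho_mask: np.ndarray,
    state: _model.TrainState,
    min_bias_batch: int = 8,
) -> dict:
    """One optimisation iteration of the min-max objective.

    ``bias_encodings`` holds one full-batch N×K indicator matrix per
    declared bias; ``rho_mask`` selects the ρ-conditioned rows on which the
    adversarial steps operate.  Returns a metrics dict (losses, whether the
    bias steps were skipped).  When the sub-batch is smaller than
    ``min_bias_batch`` — or when the state carries no adversarial heads —
    steps 2–3 are skipped; at λ=0 the fooling step (3) is skipped so the
    FE/MSI trajectory is exactly the baseline's.
    """
    # -- step 1: classification update of θfe, θmsi ------------------------
    F = state.fe.forward(X_batch)
    logits = state.msi.forward(F)
    loss_msi, dlogits = _model.msi_loss_grad(y_batch, logits)
    dlogits /= len(X_batch)  # mean-scaled gradient for batch-size-free steps
    dF, g_msi = state.msi.backward(dlogits)
    _, g_fe = state.fe.backward(dF)
    state.opt_msi.step(state.msi.parameters(), g_msi)
    state.opt_fe.step(state.fe.parameters(), g_fe)

    metrics = {"loss_msi": loss_msi, "bias_steps_skipped": False,
               "loss_be": [math.nan] * state.n_biases}
    state.iteration += 1
    if state.n_biases == 0:
        return metrics
    sub = np.flatnonzero(rho_mask)
    if len(sub) < min_bias_batch:
        metrics["bias_steps_skipped"] = True
        return metrics

    X_sub = X_batch[sub]
    # -- step 2: train each head to predict its bias (θfe fixed) ----------
    F_sub_fixed = state.fe.forward(X_sub, cache=False)
    for n, be in enumerate(state.bes):
        b = bias_encodings[n][sub]
        out = be.forward(F_sub_fixed)
        loss_be, dout = _model.bias_loss_grad(b, out)
        _, g_be = be.backward(dout)
        state.opt_bes[n].step(be.parameters(), g_be)
        metrics["loss_be"][n] = loss_be

    # -- step 3: fool each head by updating θfe against λ·Lbe --------------
    if state.lam > 0.0:
        for n, be in enumerate(state.bes):
            b = bias_encodings[n][sub]
            F_sub = state.fe.forward(X_sub)
            out = be.forward(F_sub)
            _, dout = _model.bias_loss_grad(b, out)
            dF_sub, _ = be.backward(dout)
            # ascend Lbe wrt θfe == descend on −λ·Lbe
            _, g_fe = state.fe.backward(-state.lam * dF_sub)
            state.opt_fe.step(state.fe.parameters(), g_fe)
    return metrics


# ---------------------------------------------------------------------------
# full training
# ---------------------------------------------------------------------------

def extract_features(state: _model.TrainState, X: np.ndarray,
                     chunk: int = 4096) -> np.ndarray:
    """FE features for pre-flattened network inputs, in memory-bounded chunks."""
    return np.concatenate([
        state.fe.forward(X[i:i + chunk], cache=False)
        for i in range(0, len(X), chunk)
    ])


def predict_proba(state: _model.TrainState, X: np.ndarray,
                  chunk: int = 4096) -> np.ndarray:
    """MSI-head probabilities, column 1 = P(MSI-H)."""
    return np.concatenate([
        _model.softmax(state.msi.forward(
            state.fe.forward(X[i:i + chunk], cache=False), cache=False))
        for i in range(0, len(X), chunk)
    ])


def train_model(
    manifest: pd.DataFrame,
    images: np.ndarray,
    fold_plan: FoldPlan,
    fold: int,
    config: TrainConfig,
    ablate: bool,
    bias_specs: Optional[Sequence[BiasSpec]] = None,
) -> TrainResult:
    """Train one fold, either the baseline (FE+MSI) or the bias-ablated
    system (FE+MSI plus one adversarial head per protected variable).

    The sampler, parameter initialisation and data order depend only on the
    seed — never on ``ablate`` — so a λ=0 ablated run reproduces the
    baseline's FE/MSI trajectory bit for bit.  When ``log_dc`` is on, the
    squared distance correlation between the batch features and the label
    and every bias is recorded per iteration (the monitoring curves).
    """
    train_idx = fold_plan.train_indices(fold)
    val_idx = fold_plan.val_indices(fold)
    sub = manifest.iloc[train_idx]
    if not (sub["msi_label"] == "MSI-H").any():
        raise ValueError("training fold contains no MSI-H patients")

    if bias_specs is None:
        bias_specs = default_bias_specs(sub) if ablate else []
    bias_specs = list(bias_specs) if ablate else []

    X_all = tiles_to_network_input(images, config.network.input_px)
    y_all = (manifest["msi_label"].to_numpy() == "MSI-H").astype(int)

    # frozen level lists from the training cohort give each head its width
    level_lists = [tuple(sorted(sub[bs.name].unique())) for bs in bias_specs]
    enc_all = [_encode_fixed(manifest[bs.name].to_numpy(), levels)
               for bs, levels in zip(bias_specs, level_lists)]
    rho_all = np.zeros(len(manifest), dtype=bool)
    if bias_specs:
        # all specs share the conditioning group in this implementation
        groups = {bs.conditioning_group for bs in bias_specs}
        if len(groups) != 1:
            raise ValueError("heads with mixed conditioning groups are not supported")
        rho_all = manifest["msi_label"].to_numpy() == groups.pop()

    state = _model.build_state(
        config.network, bias_specs,
        bias_widths=[len(lv) for lv in level_lists],
        lam=config.lam, lr=config.lr,
        lr_bias=config.lr_bias, seed=config.seed,
    )

    weights = composite_weights(sub)
    sampler = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([config.seed, 31])))
    iters_per_epoch = max(1, math.ceil(len(train_idx) / config.batch_size))

    trace_rows = []
    skipped = 0
    best_val = np.inf
    stale = 0
    for epoch in range(config.epochs):
        for it in range(iters_per_epoch):
            pick = sampler.choice(len(train_idx), size=config.batch_size,
                                  replace=True, p=weights)
            idx = train_idx[pick]
            encs = [e[idx] for e in enc_all]
            m = adversarial_iteration(
                X_all[idx], y_all[idx], encs, rho_all[idx], state,
                min_bias_batch=config.min_bias_batch)
            if m["bias_steps_skipped"]:
                skipped += 1
            if config.log_dc:
                F = extract_features(state, X_all[idx])
                row = {"epoch": epoch, "iteration": state.iteration,
                       "loss_msi": m["loss_msi"],
                       "dc_msi": squared_distance_correlation(
                           F, _encode_fixed(y_all[idx], (0, 1)))}
                for bs, e in zip(bias_specs, encs):
                    row[f"dc_{bs.name}"] = squared_distance_correlation(F, e)
                trace_rows.append(row)
        if config.patience is not None:
            pv = predict_proba(state, X_all[val_idx])
            vloss = _model.msi_loss(y_all[val_idx], pv) / len(val_idx)
            if vloss < best_val - 1e-6:
                best_val, stale = vloss, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    trace = pd.DataFrame(trace_rows)
    if skipped:
        warnings.warn(f"adversarial steps skipped on {skipped} iterations "
                      f"(ρ sub-batch below {config.min_bias_batch})",
                      stacklevel=2)
    return TrainResult(state=state, trace=trace, train_indices=train_idx,
                       val_indices=val_idx, skipped_bias_steps=skipped)
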