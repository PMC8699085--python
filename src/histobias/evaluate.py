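"""Evaluation: tile→patient aggregation and screening-oriented metrics.

Tile-level probabilities are aggregated per patient by majority vote of the
hard tile labels (ties break toward MSI-H: in a screening setting a false
positive costs a confirmatory test, a false negative costs a missed
diagnosis) with the mean tile probability as the patient-level score for
AUC.  Because study cohorts rarely match the population MSI-H prevalence,
accuracy and the predictive values are reported *prevalence-adjusted*:

    accuracy = S·P + E·(1−P)
    PPV      = S·P / (S·P + (1−E)·(1−P))
    NPV      = E·(1−P) / (E·(1−P) + (1−S)·P)

with sensitivity S, specificity E and an assumed population prevalence P
(default 15%).  Confidence intervals: exact Clopper–Pearson (Beta
quantiles) for S, E and accuracy; standard logit intervals for the
predictive values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "PatientPrediction",
    "MetricsReport",
    "aggregate_patient",
    "aggregate_patients",
    "auc",
    "prevalence_adjusted_metrics",
    "clopper_pearson_ci",
    "logit_ci_predictive",
    "stratified_error_rates",
    "evaluate_fold",
]

DEFAULT_PREVALENCE = 0.15
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PatientPrediction:
    """Aggregated MSI call for one patient."""

    patient: str
    n_positive: int
    n_total: int
    mean_probability: float
    label: str  # "MSI-H" or "MSS"

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("inconsistent vote counts")
        if not 0.0 <= self.mean_probability <= 1.0:
            raise ValueError("mean probability outside [0, 1]")


def aggregate_patient(patient: str, tile_probs: Sequence[float],
                      threshold: float = DEFAULT_THRESHOLD,
                      tie_break: str = "MSI-H") -> PatientPrediction:
    """Majority-vote a patient's tile probabilities into one call.

    Hard tile labels are ``prob >= threshold``; the patient is MSI-H when
    positive votes are the strict majority, and an even split goes to
    ``tie_break`` (MSI-H by default, favouring sensitivity; set
    ``tie_break="mean"`` to resolve ties by thresholding the mean
    probability instead).  The continuous patient score is the mean tile
    MSI-H probability.
    """
    probs = np.asarray(tile_probs, dtype=float)
    if probs.size == 0:
        raise ValueError(f"patient {patient!r} has no tiles")
    pos = int((probs >= threshold).sum())
    n = int(probs.size)
    if 2 * pos > n:
        label = "MSI-H"
    elif 2 * pos < n:
        label = "MSS"
    elif tie_break == "mean":
        label = "MSI-H" if probs.mean() >= threshold else "MSS"
    else:
        label = tie_break
    return PatientPrediction(patient=patient, n_positive=pos, n_total=n,
                             mean_probability=float(probs.mean()), label=label)


def aggregate_patients(tile_frame: pd.DataFrame, prob_col: str = "prob",
                       patient_col: str = "patient",
                       threshold: float = DEFAULT_THRESHOLD,
                       tie_break: str = "MSI-H") -> pd.DataFrame:
    """Vectorised :func:`aggregate_patient` over a tile prediction table."""
    rows = [
        aggregate_patient(p, g[prob_col].to_numpy(), threshold, tie_break)
        for p, g in tile_frame.groupby(patient_col, sort=True)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = _stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def prevalence_adjusted_metrics(S: float, E: float,
                                P: float = DEFAULT_PREVALENCE) -> dict:
    """Accuracy, PPV and NPV at an assumed population prevalence."""
    for name, v in (("S", S), ("E", E), ("P", P)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    acc = S * P + E * (1.0 - P)
    ppv_den = S * P + (1.0 - E) * (1.0 - P)
    npv_den = E * (1.0 - P) + (1.0 - S) * P
    return {
        "accuracy": acc,
        "ppv": S * P / ppv_den if ppv_den > 0 else float("nan"),
        "npv": E * (1.0 - P) / npv_den if npv_den > 0 else float("nan"),
        "balanced_accuracy": (S + E) / 2.0,
    }


def clopper_pearson_ci(k: int, n: int, alpha: float = 0.05) -> tuple:
    """Exact binomial confidence interval from Beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo = 0.0 if k == 0 else float(_stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(_stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def logit_ci_predictive(value: float, components: dict,
                        alpha: float = 0.05) -> tuple:
    """Standard logit confidence interval for a predictive value.

    ``components`` supplies the ingredients of the prevalence-adjusted
    predictive value: ``S``, ``E``, the case/control sample sizes
    ``n_pos`` / ``n_neg`` they were estimated from, and which value this is
    (``kind`` = "ppv" or "npv").  The delta-method variance of
    logit(PPV/NPV) combines the binomial variances of S and E.
    """
    S, E = components["S"], components["E"]
    n1, n0 = components["n_pos"], components["n_neg"]
    kind = components.get("kind", "ppv")
    if not 0.0 < value < 1.0:
        raise ValueError("logit interval needs a value strictly inside (0, 1)")
    if kind == "ppv":
        var = (1.0 - S) / (S * n1) + E / ((1.0 - E) * n0)
    elif kind == "npv":
        var = S / ((1.0 - S) * n1) + (1.0 - E) / (E * n0)
    else:
        raise ValueError("kind must be 'ppv' or 'npv'")
    z = _stats.norm.ppf(1.0 - alpha / 2.0)
    logit = np.log(value / (1.0 - value))
    lo, hi = logit - z * np.sqrt(var), logit + z * np.sqrt(var)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return float(expit(lo)), float(expit(hi))


def stratified_error_rates(tile_frame: pd.DataFrame, stratum_col: str,
                           prob_col: str = "prob", label_col: str = "y",
                           fold_col: Optional[str] = None,
                           threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """FPR and FNR per stratum (tissue type or magnification).

    FPR = FP/(FP+TN) over the stratum's true-negative tiles, FNR =
    FN/(FN+TP) over its true positives; with a ``fold_col`` the rates are
    computed per fold and reported as mean ± sd across folds.  Strata with
    no negatives (FPR) or no positives (FNR) get NaN entries.
    """
    df = tile_frame.copy()
    df["_pred"] = (df[prob_col] >= threshold).astype(int)

    def _rates(g):
        y = g[label_col].to_numpy().astype(int)
        p = g["_pred"].to_numpy()
        neg, pos = y == 0, y == 1
        fpr = float(p[neg].mean()) if neg.any() else float("nan")
        fnr = float(1 - p[pos].mean()) if pos.any() else float("nan")
        return pd.Series({"fpr": fpr, "fnr": fnr, "n": len(g)})

    if fold_col is None:
        out = df.groupby(stratum_col).apply(_rates, include_groups=False)
        return out.reset_index()
    per_fold = (df.groupby([stratum_col, fold_col])
                  .apply(_rates, include_groups=False).reset_index())
    agg = per_fold.groupby(stratum_col).agg(
        fpr_mean=("fpr", "mean"), fpr_sd=("fpr", "std"),
        fnr_mean=("fnr", "mean"), fnr_sd=("fnr", "std"),
        n=("n", "sum"))
    return agg.reset_index()


@dataclass
class MetricsReport:
    """Full evaluation of one model: discrimination, screening metrics, CIs."""

    auc_tile: float
    auc_patient: float
    sensitivity: float
    specificity: float
    prevalence: float
    accuracy: float
    ppv: float
    npv: float
    balanced_accuracy: float
    n_patients: int
    n_tiles: int
    ci: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("auc_tile", "auc_patient", "sensitivity", "specificity",
                     "prevalence", "accuracy", "ppv", "npv", "balanced_accuracy"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "auc_tile", "auc_patient", "sensitivity", "specificity",
            "prevalence", "accuracy", "ppv", "npv", "balanced_accuracy",
            "n_patients", "n_tiles")}
        d["ci"] = self.ci
        d["strata"] = self.strata
        return d

    def to_json(self, path=None):
        if path is None:
            return json.dumps(self.to_dict(), indent=2)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_fold(tile_frame: pd.DataFrame, prob_col: str = "prob",
                  label_col: str = "msi_label", patient_col: str = "patient",
                  prevalence: float = DEFAULT_PREVALENCE,
                  threshold: float = DEFAULT_THRESHOLD,
                  strata_cols: Sequence[str] = ()) -> MetricsReport:
    """Evaluate one validation fold's tile predictions end to end.

    ``tile_frame`` needs one row per tile with the MSI-H probability, the
    true label and the patient id.  Sensitivity/specificity come from the
    majority-voted patient calls at the given operating threshold; accuracy
    and predictive values are prevalence-adjusted.
    """
    y_tile = (tile_frame[label_col] == "MSI-H").astype(int).to_numpy()
    auc_tile = auc(tile_frame[prob_col].to_numpy(), y_tile)

    patients = aggregate_patients(tile_frame, prob_col, patient_col, threshold)
    truth = tile_frame.groupby(patient_col, sort=True)[label_col].first()
    y_pat = (truth == "MSI-H").astype(int).to_numpy()
    auc_patient = auc(patients["mean_probability"].to_numpy(), y_pat)

    pred_pos = (patients["label"] == "MSI-H").to_numpy()
    tp = int((pred_pos & (y_pat == 1)).sum())
    fn = int((~pred_pos & (y_pat == 1)).sum())
    tn = int((~pred_pos & (y_pat == 0)).sum())
    fp = int((pred_pos & (y_pat == 0)).sum())
    n1, n0 = tp + fn, tn + fp
    S = tp / n1 if n1 else float("nan")
    E = tn / n0 if n0 else float("nan")
    adj = prevalence_adjusted_metrics(S, E, prevalence)

    ci = {}
    if n1:
        ci["sensitivity"] = clopper_pearson_ci(tp, n1)
    if n0:
        ci["specificity"] = clopper_pearson_ci(tn, n0)
    if n1 and n0:
        k_acc = round(adj["accuracy"] * (n1 + n0))
        ci["accuracy"] = clopper_pearson_ci(int(k_acc), n1 + n0)
        for kind in ("ppv", "npv"):
            v = adj[kind]
            if 0.0 < v < 1.0 and 0.0 < S < 1.0 and 0.0 < E < 1.0:
                ci[kind] = logit_ci_predictive(
                    v, {"S": S, "E": E, "n_pos": n1, "n_neg": n0, "kind": kind})

    strata = {}
    df = tile_frame.copy()
    df["y"] = y_tile
    for col in strata_cols:
        strata[col] = stratified_error_rates(
            df, col, prob_col=prob_col, label_col="y",
            threshold=threshold).to_dict(orient="records")

    return MetricsReport(
        auc_tile=auc_tile, auc_patient=auc_patient, sensitivity=S,
        specificity=E, prevalence=prevalence, accuracy=adj["accuracy"],
        ppv=adj["ppv"], npv=adj["npv"],
        balanced_accuracy=adj["balanced_accuracy"],
        n_patients=int(len(patients)), n_tiles=int(len(tile_frame)),
        ci=ci, strata=strata)
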