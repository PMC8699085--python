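"""Batch-effect auditing of learned representations.

The central quantity is the squared distance correlation (Székely's dCor²),
a dependence measure between random vectors that is zero (in the population)
if and only if the vectors are statistically independent.  Computed between
the feature matrix ``F`` extracted by a trained network and the encoding of a
protected variable (source project, patient identity, TMA glass), it
quantifies how much batch-effect signature the representation carries; the
same statistic against the class label quantifies task-relevant signal.

The audit proceeds globally per variable and then within each level of a
grouping variable (backward-selection style subgroup analysis), flagging
hidden interactions whenever a subgroup's dependence clearly exceeds the
global one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiasSpec",
    "FeatureBatch",
    "AuditEntry",
    "AuditReport",
    "squared_distance_correlation",
    "encode_bias",
    "bias_audit",
    "pca_projection",
]

# Default margin by which a subgroup dc must exceed the global dc before an
# interaction flag is raised.  A monitoring heuristic, not a test.
INTERACTION_THRESHOLD = 0.10


@dataclass(frozen=True)
class BiasSpec:
    """A protected variable whose signature the model must not exploit.

    Parameters
    ----------
    name : str
        Variable name; conventionally one of ``project``, ``patient``,
        ``glass``, but any categorical manifest column works.
    levels : tuple of str
        The declared category set.
    conditioning_group : str
        Target class on whose samples the adversarial head for this
        variable trains (the rho-conditioned cohort).  Default ``"MSS"``:
        batch effects are modelled on the majority/stable class so the
        features become conditionally independent of the bias given the
        label.
    """

    name: str
    levels: tuple
    conditioning_group: str = "MSS"

    def __post_init__(self):
        if len(self.levels) == 0:
            raise ValueError(f"BiasSpec {self.name!r} has an empty level set")
        if self.conditioning_group not in ("MSI-H", "MSS"):
            raise ValueError(
                f"conditioning_group must be 'MSI-H' or 'MSS', "
                f"got {self.conditioning_group!r}"
            )


@dataclass
class FeatureBatch:
    """Aligned container of extracted features, labels and encoded biases.

    ``F`` is the N×D feature matrix, ``y`` the N class labels and
    ``bias_matrices`` maps each protected variable name to its N×K indicator
    encoding.  All row counts must agree.
    """

    F: np.ndarray
    y: np.ndarray
    bias_matrices: dict = field(default_factory=dict)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.y = np.asarray(self.y)
        if self.F.ndim != 2:
            raise ValueError("F must be a 2-D matrix")
        n = self.F.shape[0]
        if self.y.shape[0] != n:
            raise ValueError("y length does not match F rows")
        for name, mat in self.bias_matrices.items():
            if np.asarray(mat).shape[0] != n:
                raise ValueError(f"bias matrix {name!r} rows do not match F")

    @property
    def n(self) -> int:
        return self.F.shape[0]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("input must be 1-D or 2-D")
    return X


def _double_centered_distances(X: np.ndarray) -> np.ndarray:
    # exact pairwise Euclidean distances (difference-based, not the Gram
    # trick, which costs ~1e-9 of precision), then double centering:
    # subtract row means, column means, add the grand mean
    from scipy.spatial.distance import cdist

    d = cdist(X, X)
    rm = d.mean(axis=1, keepdims=True)
    cm = d.mean(axis=0, keepdims=True)
    return d - rm - cm + d.mean()


def squared_distance_correlation(X, Y) -> float:
    """Squared distance correlation between two row-aligned matrices.

    Uses the classical (biased) V-statistic: pairwise Euclidean distance
    matrices are double-centered (row, column and grand means removed) and

        dc = dCov²(X, Y) / sqrt(dVar²(X) · dVar²(Y))

    where dCov² is the mean elementwise product of the centered matrices.
    The value lies in [0, 1] and is zero in the population iff X and Y are
    independent.  By convention the function returns 0.0 when either
    distance variance vanishes (a constant sample carries no dependence).

    Parameters
    ----------
    X, Y : array-like, shape (N, p) and (N, q)
        Row-aligned samples; 1-D inputs are treated as single columns.

    Raises
    ------
    ValueError
        If N < 2, if the row counts differ, or if either input contains
        non-finite values.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("inputs must be finite (no NaN/inf)")

    A = _double_centered_distances(X)
    B = _double_centered_distances(Y)
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    return float(dcov2 / np.sqrt(dvar_x * dvar_y))


def encode_bias(values: Sequence, spec: BiasSpec) -> np.ndarray:
    """Indicator-encode a categorical variable, one column per present level.

    Only levels actually present in ``values`` produce columns (a level
    absent from a batch would yield an all-zero, hence constant, column);
    column order is the sorted level names.  Every value must belong to the
    spec's declared level set.

    Returns an N×K float matrix with unit row sums.
    """
    values = np.asarray(values)
    declared = set(spec.levels)
    present = sorted(set(values.tolist()))
    unknown = [v for v in present if v not in declared]
    if unknown:
        raise ValueError(
            f"value(s) {unknown!r} not in declared levels of bias {spec.name!r}"
        )
    cols = {lev: i for i, lev in enumerate(present)}
    mat = np.zeros((len(values), len(present)), dtype=float)
    for i, v in enumerate(values.tolist()):
        mat[i, cols[v]] = 1.0
    return mat


@dataclass(frozen=True)
class AuditEntry:
    subset: str  # "all" or "<group_var>=<level>"
    variable: str
    dc: float
    n: int


@dataclass
class AuditReport:
    """Distance-correlation audit: global and subgroup dependence values.

    ``entries`` holds one (subset, variable, dc, N) row per computed value;
    ``interaction_flags`` lists the (subset, variable) pairs whose subgroup
    dc exceeded the global dc by at least the interaction threshold.
    """

    entries: list = field(default_factory=list)
    interaction_flags: list = field(default_factory=list)

    def add(self, subset: str, variable: str, dc: float, n: int) -> None:
        if not (-1e-9 <= dc <= 1.0 + 1e-9):
            raise ValueError(f"dc out of [0,1]: {dc}")
        self.entries.append(AuditEntry(subset, variable, float(dc), int(n)))

    def global_dc(self, variable: str) -> float:
        for e in self.entries:
            if e.subset == "all" and e.variable == variable:
                return e.dc
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.subset, e.variable, e.dc, e.n) for e in self.entries],
            columns=["subset", "variable", "dc", "n"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        obj = {
            "entries": [e.__dict__ for e in self.entries],
            "interaction_flags": [list(f) for f in self.interaction_flags],
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def bias_audit(
    features: np.ndarray,
    metadata: pd.DataFrame,
    variables: Iterable[BiasSpec],
    subset_plan: Sequence[str] = (),
    interaction_threshold: float = INTERACTION_THRESHOLD,
) -> AuditReport:
    """Audit a representation for batch-effect dependence, with subgroups.

    For every protected variable the squared distance correlation between
    ``features`` and the variable's indicator encoding is computed on the
    full cohort, then re-computed within each level of each grouping column
    in ``subset_plan``.  A subgroup whose dc exceeds the global dc by
    ``interaction_threshold`` or more raises an interaction flag — the
    signature of a bias hiding inside one stratum (e.g. a glass tint present
    in only one source project).

    Parameters
    ----------
    features : (N, D) array
        Extracted features, one row per example.
    metadata : DataFrame with N rows
        Must contain every variable's name and every subset column.
    variables : iterable of BiasSpec
    subset_plan : sequence of column names to stratify by.

    Subgroups with fewer than 2 rows are skipped.
    """
    features = _as_matrix(features)
    if len(metadata) != features.shape[0]:
        raise ValueError("metadata rows must match feature rows")
    variables = list(variables)
    report = AuditReport()
    for spec in variables:
        enc = encode_bias(metadata[spec.name].to_numpy(), spec)
        report.add("all", spec.name, squared_distance_correlation(features, enc), len(metadata))
    for group_col in subset_plan:
        for level, idx in metadata.groupby(group_col, sort=True).indices.items():
            if len(idx) < 2:
                import warnings

                warnings.warn(
                    f"subgroup {group_col}={level!r} has <2 rows; skipped",
                    stacklevel=2,
                )
                continue
            sub_meta = metadata.iloc[idx]
            sub_feat = features[idx]
            for spec in variables:
                if spec.name == group_col:
                    continue
                enc = encode_bias(sub_meta[spec.name].to_numpy(), spec)
                dc = squared_distance_correlation(sub_feat, enc)
                subset = f"{group_col}={level}"
                report.add(subset, spec.name, dc, len(idx))
                if dc - report.global_dc(spec.name) >= interaction_threshold:
                    report.interaction_flags.append((subset, spec.name))
    return report


def pca_projection(F: np.ndarray, color_values=None, plot_path=None):
    """Project features onto their first two principal components.

    Used to eyeball whether the representation space organises itself by a
    protected variable (clusters per TMA glass in a baseline model) or has
    become invariant to it after ablation.

    Returns ``(embedding, explained_variance_ratio)``; if ``plot_path`` is
    given a scatter coloured by ``color_values`` is written there.
    """
    from sklearn.decomposition import PCA

    F = _as_matrix(F)
    if F.shape[0] < 3:
        raise ValueError("need at least 3 observations for a 2-D projection")
    if not np.any(np.linalg.norm(F - F.mean(axis=0), axis=1) > 0):
        raise ValueError("rank-0 input: all rows identical")
    pca = PCA(n_components=2, svd_solver="full")
    emb = pca.fit_transform(F)
    evr = pca.explained_variance_ratio_
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if color_values is not None:
            cats = pd.Categorical(np.asarray(color_values))
            for code in range(len(cats.categories)):
                m = cats.codes == code
                ax.scatter(emb[m, 0], emb[m, 1], s=8, label=str(cats.categories[code]))
            if len(cats.categories) <= 12:
                ax.legend(fontsize=6, markerscale=1.5)
        else:
            ax.scatter(emb[:, 0], emb[:, 1], s=8)
        ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return emb, evr
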