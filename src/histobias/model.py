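"""Network contracts and losses for the bias-rejecting MSI classifier.

Three cooperating modules share a feature space:

* ``FE`` — feature extractor mapping a tile to a D-dimensional vector F;
* ``MSI`` — two-hidden-layer head predicting MSI-H vs MSS from F;
* ``BE``  — one adversarial head per protected variable, trying to predict
  that variable's indicator encoding from F.

The classification loss is a summed cross-entropy; each adversarial loss is
the negative sum of squared Pearson correlations between the columns of the
true bias encoding and the head's output.  Training (see
:mod:`histobias.train`) plays a min-max game: the heads minimise their loss
while FE is updated to maximise it, scaled by the adversarial weight λ.

The numerical core is a small fully-connected stack with hand-derived
gradients — everything runs on the CPU in double precision, which keeps
runs bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .biasaudit import BiasSpec

__all__ = [
    "NetworkSpec",
    "DenseStack",
    "Adam",
    "TrainState",
    "build_state",
    "msi_loss",
    "msi_loss_grad",
    "bias_loss",
    "bias_loss_grad",
    "forward",
    "softmax",
]

_EPS = 1e-8  # variance guard in Pearson denominators


@dataclass(frozen=True)
class NetworkSpec:
    """Shapes of the FE / MSI / BE modules.

    ``backbone`` selects the feature extractor: ``"small-mlp"`` is a
    fully-connected stack over block-averaged tile pixels sized for CPU
    experiments.  ``feature_dim`` is the width D of F (128 at desk scale;
    512 mirrors a ResNet34 trunk).  Heads have two hidden layers of
    ``head_hidden`` units with ReLU and a linear output: 2 logits for the
    MSI head, K outputs for the BE head of a K-level bias.
    """

    backbone: str = "small-mlp"
    input_px: int = 16  # tiles are block-averaged to input_px × input_px × 3
    feature_dim: int = 128
    head_hidden: int = 128
    msi_out: int = 2

    def __post_init__(self):
        if self.backbone != "small-mlp":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.feature_dim <= 0 or self.head_hidden <= 0:
            raise ValueError("feature_dim and head_hidden must be positive")

    @property
    def input_dim(self) -> int:
        return 3 * self.input_px * self.input_px


class DenseStack:
    """Fully-connected ReLU stack with manual forward/backward.

    ``dims = (d0, d1, ..., dL)`` builds L layers; ReLU follows every layer
    except, optionally, the last (linear heads).  He-normal initialisation
    from the supplied generator makes construction deterministic.
    """

    def __init__(self, dims: Sequence[int], rng: np.random.Generator,
                 final_relu: bool = False):
        self.dims = tuple(int(d) for d in dims)
        self.final_relu = final_relu
        self.W = []
        self.b = []
        for din, dout in zip(self.dims[:-1], self.dims[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
            self.b.append(np.zeros(dout))
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        return self.W + self.b

    def copy_parameters(self):
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params):
        n = len(self.W)
        for i in range(n):
            self.W[i][...] = params[i]
            self.b[i][...] = params[n + i]

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acts = [X]
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last or self.final_relu:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def backward(self, dout: np.ndarray):
        """Backprop ``dout`` (grad wrt the stack output) through the cached
        forward pass.  Returns ``(dX, grads)`` where ``grads`` aligns with
        :meth:`parameters`."""
        if self._cache is None:
            raise RuntimeError("forward(cache=True) must precede backward")
        acts = self._cache
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        last = len(self.W) - 1
        g = np.asarray(dout, dtype=float)
        for i in range(last, -1, -1):
            if i < last or self.final_relu:
                g = g * (acts[i + 1] > 0.0)
            dW[i] = acts[i].T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g, dW + db


class Adam:
    """Adam over one parameter collection (one network module)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainState:
    """Parameters and optimiser state of the full system.

    Parameter collections of FE, MSI head and the B adversarial heads are
    disjoint by construction (separate :class:`DenseStack` objects).  ``lam``
    is the adversarial weight λ ≥ 0 applied when FE is updated to fool the
    heads; ``bias_specs`` fixes the heads' order of processing.
    """

    spec: NetworkSpec
    fe: DenseStack
    msi: DenseStack
    bes: list
    bias_specs: list
    lam: float
    opt_fe: Adam
    opt_msi: Adam
    opt_bes: list
    seed: int
    iteration: int = 0

    @property
    def n_biases(self) -> int:
        return len(self.bes)


def build_state(
    spec: NetworkSpec,
    bias_specs: Sequence[BiasSpec] = (),
    bias_widths: Optional[Sequence[int]] = None,
    lam: float = 1.0,
    lr: float = 1e-4,
    lr_bias: Optional[float] = None,
    seed: int = 0,
) -> TrainState:
    """Construct a :class:`TrainState` with deterministic initialisation.

    FE and MSI parameters are drawn from generators derived only from
    ``seed``, never from the number of attached BE heads, so a baseline
    model (no heads) and an ablated model share identical FE/MSI starting
    points under the same seed.  ``bias_widths`` gives each BE head's output
    width K (the bias's encoding width); it defaults to the declared number
    of levels.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    bias_specs = list(bias_specs)
    if bias_widths is None:
        bias_widths = [len(bs.levels) for bs in bias_specs]
    if len(bias_widths) != len(bias_specs):
        raise ValueError("bias_widths must align with bias_specs")

    rng_fe = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 11])))
    rng_msi = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 13])))
    rng_be = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 17])))

    d_in, D, H = spec.input_dim, spec.feature_dim, spec.head_hidden
    fe = DenseStack((d_in, 2 * D, D), rng_fe, final_relu=True)
    msi = DenseStack((D, H, H, spec.msi_out), rng_msi, final_relu=False)
    bes = [DenseStack((D, H, H, k), rng_be, final_relu=False) for k in bias_widths]

    return TrainState(
        spec=spec,
        fe=fe,
        msi=msi,
        bes=bes,
        bias_specs=bias_specs,
        lam=float(lam),
        opt_fe=Adam(fe.parameters(), lr=lr),
        opt_msi=Adam(msi.parameters(), lr=lr),
        opt_bes=[Adam(be.parameters(), lr=lr_bias if lr_bias is not None else lr)
                 for be in bes],
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_indicator(y: np.ndarray, m: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 1:
        out = np.zeros((y.shape[0], m))
        out[np.arange(y.shape[0]), y.astype(int)] = 1.0
        return out
    return np.asarray(y, dtype=float)


def msi_loss(y, y_hat, eps: float = 1e-12) -> float:
    """Summed cross-entropy  −Σᵢ Σₘ y_im log(ŷ_im).

    ``y`` may be class indices or one-hot rows; ``y_hat`` rows must be
    probability vectors.  The loss is non-negative and zero only for a
    perfectly confident correct prediction.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    if np.any(y_hat < 0) or np.any(y_hat > 1 + 1e-9):
        raise ValueError("y_hat entries must lie in [0, 1]")
    y = _as_indicator(y, y_hat.shape[1])
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat shapes do not align")
    return float(-(y * np.log(np.clip(y_hat, eps, 1.0))).sum())


def msi_loss_grad(y, logits) -> tuple:
    """Loss and gradient wrt the MSI head's logits (softmax + summed CE)."""
    p = softmax(np.asarray(logits, dtype=float))
    y = _as_indicator(y, p.shape[1])
    loss = float(-(y * np.log(np.clip(p, 1e-12, 1.0))).sum())
    return loss, p - y


def _column_corr2_and_grad(b: np.ndarray, bhat: np.ndarray):
    """Squared Pearson correlation of two vectors plus d(corr²)/d(bhat)."""
    u = b - b.mean()
    v = bhat - bhat.mean()
    suu = float(u @ u)
    svv = float(v @ v)
    if suu < _EPS or svv < _EPS:
        return 0.0, np.zeros_like(bhat)
    suv = float(u @ v)
    corr2 = suv * suv / (suu * svv)
    g = (2.0 * suv / (suu * svv)) * u - (2.0 * suv * suv / (suu * svv * svv)) * v
    g -= g.mean()  # centring projection (a no-op up to rounding)
    return corr2, g


def bias_loss(b: np.ndarray, b_hat: np.ndarray) -> float:
    """Adversarial bias loss  −Σₖ corr²(bₖ, b̂ₖ)  over the K columns.

    ``b`` is the true N×K bias encoding on the conditioned sub-batch, ``b_hat``
    the BE head's output.  Columns with (numerically) zero variance in either
    vector contribute 0.  The value lies in [−K, 0]; −K means the head
    predicts the bias perfectly, 0 means it has no linear handle on it.
    """
    b = np.asarray(b, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if b.shape != b_hat.shape:
        raise ValueError("b and b_hat must share a shape")
    if b.ndim == 1:
        b, b_hat = b[:, None], b_hat[:, None]
    if b.shape[0] < 2:
        raise ValueError("need at least 2 rows to correlate")
    total = 0.0
    for k in range(b.shape[1]):
        c2, _ = _column_corr2_and_grad(b[:, k], b_hat[:, k])
        total += c2
    return -total


def bias_loss_grad(b: np.ndarray, b_hat: np.ndarray):
    """Loss and gradient of :func:`bias_loss` wrt ``b_hat``."""
    b = np.asarray(b, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if b.ndim == 1:
        b, b_hat = b[:, None], b_hat[:, None]
    grad = np.zeros_like(b_hat)
    total = 0.0
    for k in range(b.shape[1]):
        c2, g = _column_corr2_and_grad(b[:, k], b_hat[:, k])
        total += c2
        grad[:, k] = -g
    return -total, grad


def save_state(state: TrainState, path) -> None:
    """Checkpoint parameters + config; a JSON sidecar describes the shapes."""
    import dataclasses
    import json
    from pathlib import Path

    arrays = {}
    for i, p in enumerate(state.fe.parameters()):
        arrays[f"fe_{i}"] = p
    for i, p in enumerate(state.msi.parameters()):
        arrays[f"msi_{i}"] = p
    for n, be in enumerate(state.bes):
        for i, p in enumerate(be.parameters()):
            arrays[f"be{n}_{i}"] = p
    np.savez(path, **arrays)
    sidecar = {
        "spec": dataclasses.asdict(state.spec),
        "lam": state.lam,
        "seed": state.seed,
        "iteration": state.iteration,
        "fe_dims": state.fe.dims,
        "msi_dims": state.msi.dims,
        "be_dims": [be.dims for be in state.bes],
        "biases": [
            {"name": bs.name, "levels": list(bs.levels),
             "conditioning_group": bs.conditioning_group}
            for bs in state.bias_specs
        ],
    }
    with open(Path(str(path)).with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_state(path, lr: float = 1e-4) -> TrainState:
    """Restore a checkpoint written by :func:`save_state` (fresh optimisers)."""
    import json
    from pathlib import Path

    with open(Path(str(path)).with_suffix(".json")) as fh:
        sc = json.load(fh)
    spec = NetworkSpec(**sc["spec"])
    specs = [BiasSpec(b["name"], tuple(b["levels"]), b["conditioning_group"])
             for b in sc["biases"]]
    widths = [dims[-1] for dims in sc["be_dims"]]
    state = build_state(spec, specs, bias_widths=widths, lam=sc["lam"],
                        lr=lr, seed=sc["seed"])
    data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
    state.fe.set_parameters([data[f"fe_{i}"] for i in range(2 * len(state.fe.W))])
    state.msi.set_parameters([data[f"msi_{i}"] for i in range(2 * len(state.msi.W))])
    for n, be in enumerate(state.bes):
        be.set_parameters([data[f"be{n}_{i}"] for i in range(2 * len(be.W))])
    state.iteration = sc["iteration"]
    return state


def forward(X_batch: np.ndarray, state: TrainState):
    """Run the full system on a batch of flattened network inputs.

    Returns ``(F, y_hat, b_hats)`` where F is N×D, ``y_hat`` rows are
    softmax probabilities over (MSS, MSI-H), and ``b_hats`` holds one N×K
    output per adversarial head, in declared bias order.  Purely functional
    (no parameter updates); identical inputs give identical rows.
    """
    X_batch = np.asarray(X_batch, dtype=float)
    if X_batch.ndim != 2 or X_batch.shape[1] != state.spec.input_dim:
        raise ValueError(
            f"expected N×{state.spec.input_dim} input, got {X_batch.shape}"
        )
    F = state.fe.forward(X_batch, cache=False)
    y_hat = softmax(state.msi.forward(F, cache=False))
    b_hats = [be.forward(F, cache=False) for be in state.bes]
    return F, y_hat, b_hats
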