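"""Single-hidden-layer perceptron regression with BFGS training and
Garson connection-weight sensitivity.

The network mirrors the study's setup: a 20-wide input layer (one-hot
collection dates, varieties and areas plus scaled infection % and harvest
number), 3–5 hidden neurons, and 5 outputs (the three polyphenol classes
plus the two antioxidant IC50s).  Training minimizes the sum-of-squares
error with the BFGS quasi-Newton method; model quality is screened by the
Pearson correlation between observed and predicted values on a 70/15/15
train/validation/test split.  Garson's weight-partitioning attributes a
relative importance share to each input factor.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize as _opt

from .datamodel import SampleCondition

__all__ = [
    "ACTIVATIONS",
    "MLPArchitecture",
    "MLPModel",
    "DataSplit",
    "expand_inputs",
    "split_data",
    "train_mlp",
    "predict_mlp",
    "evaluate",
    "model_search",
    "default_candidates",
    "garson_importance",
]

_CLIP = 50.0  # pre-activation clamp for exp/logistic, guards overflow


def _identity(z):
    return z


def _identity_d(z, a):
    return np.ones_like(z)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_CLIP, _CLIP)))


def _logistic_d(z, a):
    return a * (1.0 - a)


def _tanh(z):
    return np.tanh(z)


def _tanh_d(z, a):
    return 1.0 - a * a


def _exponential(z):
    return np.exp(np.clip(z, -_CLIP, _CLIP))


def _exponential_d(z, a):
    return a


#: activation name -> (function, derivative given (z, activation))
ACTIVATIONS = {
    "identity": (_identity, _identity_d),
    "logistic": (_logistic, _logistic_d),
    "tanh": (_tanh, _tanh_d),
    "exponential": (_exponential, _exponential_d),
}


@dataclass(frozen=True)
class MLPArchitecture:
    """Layer sizes and activation choices; named "MLP k_i-k_h-k_o"."""

    n_inputs: int
    n_hidden: int
    n_outputs: int
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self):
        for v in (self.n_inputs, self.n_hidden, self.n_outputs):
            if v < 1:
                raise ValueError("layer sizes must be >= 1")
        for a in (self.hidden_activation, self.output_activation):
            if a not in ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def name(self) -> str:
        return f"MLP {self.n_inputs}-{self.n_hidden}-{self.n_outputs}"

    def n_params(self) -> int:
        return (
            self.n_inputs * self.n_hidden
            + self.n_hidden
            + self.n_hidden * self.n_outputs
            + self.n_outputs
        )


@dataclass
class MLPModel:
    """Trained network: weights, standardization and training metadata."""

    architecture: MLPArchitecture
    W: np.ndarray  # input -> hidden, (n_inputs, n_hidden)
    b_hidden: np.ndarray
    V: np.ndarray  # hidden -> output, (n_hidden, n_outputs)
    b_output: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    seed: int
    loss_log: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def to_json(self, path: str | Path) -> None:
        a = self.architecture
        payload = {
            "architecture": {
                "n_inputs": a.n_inputs, "n_hidden": a.n_hidden,
                "n_outputs": a.n_outputs,
                "hidden_activation": a.hidden_activation,
                "output_activation": a.output_activation,
            },
            "W": self.W.tolist(), "b_hidden": self.b_hidden.tolist(),
            "V": self.V.tolist(), "b_output": self.b_output.tolist(),
            "x_mean": self.x_mean.tolist(), "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(), "y_scale": self.y_scale.tolist(),
            "seed": self.seed, "loss_log": self.loss_log,
            "converged": self.converged, "n_iter": self.n_iter,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            architecture=MLPArchitecture(**d["architecture"]),
            W=np.asarray(d["W"]), b_hidden=np.asarray(d["b_hidden"]),
            V=np.asarray(d["V"]), b_output=np.asarray(d["b_output"]),
            x_mean=np.asarray(d["x_mean"]), x_scale=np.asarray(d["x_scale"]),
            y_mean=np.asarray(d["y_mean"]), y_scale=np.asarray(d["y_scale"]),
            seed=d["seed"], loss_log=list(d["loss_log"]),
            converged=d["converged"], n_iter=d["n_iter"],
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test index sets covering range(n)."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    fractions: tuple[float, float, float]
    seed: int


def expand_inputs(
    conditions: list[SampleCondition],
    levels: dict | None = None,
    train_index: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One-hot factor expansion to the network's input encoding.

    Dates, varieties and areas become one indicator column per observed
    level; infection % and harvest number stay continuous, standardized to
    zero mean / unit variance over *train_index* rows (all rows by
    default).  For the study design (7 dates, 9 varieties, 2 areas) this
    yields the 20-column input layer.

    Returns the feature matrix and a column map (column, factor) used to
    fold one-hot importances back onto their parent factor.
    """
    if not conditions:
        raise ValueError("no conditions to expand")
    if levels is None:
        from .datamodel import VARIETIES

        # dates/areas: observed levels; variety: the closed 9-member
        # catalog of the sampling plan (one batch's variety may be absent
        # from a subsample) -> 7 + 9 + 2 + 2 = 20 inputs on the study design
        levels = {
            "date": sorted({c.collection_date for c in conditions}),
            "variety": list(VARIETIES),
            "area": sorted({c.area for c in conditions}),
        }
    for c in conditions:
        for key, value in (
            ("date", c.collection_date), ("variety", c.variety), ("area", c.area)
        ):
            if value not in levels[key]:
                raise ValueError(f"unseen {key} level {value!r}")

    cols, names, factors = [], [], []
    for key, attr in (
        ("date", "collection_date"), ("variety", "variety"), ("area", "area")
    ):
        for lvl in levels[key]:
            cols.append([1.0 if getattr(c, attr) == lvl else 0.0 for c in conditions])
            names.append(f"{key}={lvl}")
            factors.append(key)
    cols.append([c.infection_level for c in conditions])
    names.append("infection")
    factors.append("infection")
    cols.append([float(c.harvest_number) for c in conditions])
    names.append("harvest")
    factors.append("harvest")

    X = np.array(cols, dtype=float).T
    idx = np.arange(len(conditions)) if train_index is None else np.asarray(train_index)
    for j, f in enumerate(factors):
        if f in ("infection", "harvest"):
            mu = X[idx, j].mean()
            sd = X[idx, j].std()
            X[:, j] = (X[:, j] - mu) / (sd if sd > 0 else 1.0)
    column_map = pd.DataFrame({"column": names, "factor": factors})
    return X, column_map


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_data(
    n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15), seed: int = 0
) -> DataSplit:
    """Seeded 70/15/15 partition; n = 27 gives sizes (19, 4, 4).

    Validation and test sizes are the fractions rounded half-up; the
    remainder goes to training.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = _round_half_up(fractions[1] * n)
    n_test = _round_half_up(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split leaves no training rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DataSplit(
        train=tuple(int(i) for i in perm[:n_train]),
        validation=tuple(int(i) for i in perm[n_train:n_train + n_val]),
        test=tuple(int(i) for i in perm[n_train + n_val:]),
        fractions=fractions,
        seed=seed,
    )


def _unpack(theta: np.ndarray, a: MLPArchitecture):
    i, h, o = a.n_inputs, a.n_hidden, a.n_outputs
    k = 0
    W = theta[k:k + i * h].reshape(i, h); k += i * h
    bh = theta[k:k + h]; k += h
    V = theta[k:k + h * o].reshape(h, o); k += h * o
    bo = theta[k:k + o]
    return W, bh, V, bo


def _forward(X, theta, a: MLPArchitecture):
    W, bh, V, bo = _unpack(theta, a)
    f_h, _ = ACTIVATIONS[a.hidden_activation]
    f_o, _ = ACTIVATIONS[a.output_activation]
    Zh = X @ W + bh
    Ah = f_h(Zh)
    Zo = Ah @ V + bo
    return f_o(Zo), (Zh, Ah, Zo)


def _sos_and_grad(theta, X, Y, a: MLPArchitecture):
    W, bh, V, bo = _unpack(theta, a)
    _, dh = ACTIVATIONS[a.hidden_activation]
    _, do = ACTIVATIONS[a.output_activation]
    Yhat, (Zh, Ah, Zo) = _forward(X, theta, a)
    E = Yhat - Y
    loss = float(np.sum(E * E))
    # backprop of the SOS loss
    Go = 2.0 * E * do(Zo, Yhat)
    gV = Ah.T @ Go
    gbo = Go.sum(axis=0)
    Gh = (Go @ V.T) * dh(Zh, Ah)
    gW = X.T @ Gh
    gbh = Gh.sum(axis=0)
    grad = np.concatenate([gW.ravel(), gbh, gV.ravel(), gbo])
    return loss, grad


def train_mlp(
    architecture: MLPArchitecture,
    features: np.ndarray,
    targets: np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MLPModel:
    """Fit the network by BFGS on the sum-of-squares error.

    Inputs and targets are standardized internally (stored on the model);
    weights start uniform on [-0.5, 0.5] from *seed*.  ``max_iter=0``
    returns the initialized network unchanged.  *tol* is the gradient
    max-norm stopping criterion.
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite training data")
    a = architecture
    if X.shape[1] != a.n_inputs or Y.shape[1] != a.n_outputs:
        raise ValueError("data shapes inconsistent with architecture")

    x_mean, x_scale = X.mean(axis=0), X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean, y_scale = Y.mean(axis=0), Y.std(axis=0)
    y_scale[y_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    Ys = (Y - y_mean) / y_scale

    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=a.n_params())

    log: list[float] = []
    loss0, _ = _sos_and_grad(theta0, Xs, Ys, a)
    log.append(loss0)
    if max_iter == 0:
        theta, converged, n_iter = theta0, False, 0
    else:
        res = _opt.minimize(
            _sos_and_grad, theta0, args=(Xs, Ys, a), jac=True, method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
            callback=lambda tk: log.append(_sos_and_grad(tk, Xs, Ys, a)[0]),
        )
        theta = res.x if res.fun <= loss0 else theta0
        converged, n_iter = bool(res.success), int(res.nit)
    final_loss, _ = _sos_and_grad(theta, Xs, Ys, a)
    if not np.isfinite(final_loss):
        raise FloatingPointError(
            f"non-finite SOS loss for {a.name} "
            f"({a.hidden_activation}/{a.output_activation})"
        )
    W, bh, V, bo = _unpack(theta, a)
    return MLPModel(
        architecture=a, W=W.copy(), b_hidden=bh.copy(), V=V.copy(),
        b_output=bo.copy(), x_mean=x_mean, x_scale=x_scale,
        y_mean=y_mean, y_scale=y_scale, seed=seed,
        loss_log=log, converged=converged, n_iter=n_iter,
    )


def predict_mlp(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Network predictions on the original target scale."""
    X = (np.asarray(features, dtype=float) - model.x_mean) / model.x_scale
    a = model.architecture
    f_h, _ = ACTIVATIONS[a.hidden_activation]
    f_o, _ = ACTIVATIONS[a.output_activation]
    Yhat = f_o(f_h(X @ model.W + model.b_hidden) @ model.V + model.b_output)
    return Yhat * model.y_scale + model.y_mean


def evaluate(
    model: MLPModel, features: np.ndarray, targets: np.ndarray
) -> pd.DataFrame:
    """Per-output Pearson r, R² and RMSE of the network on given rows."""
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 rows to evaluate")
    Yhat = predict_mlp(model, features)
    rows = []
    for j in range(Y.shape[1]):
        y, yh = Y[:, j], Yhat[:, j]
        sse = float(((y - yh) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0.0 or np.std(yh) == 0.0:
            warnings.warn(f"zero variance in output {j}; r undefined", stacklevel=2)
            r = float("nan")
        else:
            r = float(np.corrcoef(y, yh)[0, 1])
        r2 = float("nan") if sst == 0.0 else 1.0 - sse / sst
        rows.append({"output": j, "pearson_r": r, "r2": r2,
                     "rmse": float(np.sqrt(sse / len(y)))})
    return pd.DataFrame(rows)


def default_candidates(
    n_inputs: int, n_outputs: int, n_candidates: int = 20,
    hidden_sizes: tuple[int, ...] = (3, 4, 5),
    hidden_activations: tuple[str, ...] = ("tanh", "logistic", "exponential", "identity"),
    output_activations: tuple[str, ...] = ("identity",),
) -> list[MLPArchitecture]:
    """Deterministic candidate pool cycling over sizes and activations."""
    cands = []
    for k in range(n_candidates):
        cands.append(
            MLPArchitecture(
                n_inputs=n_inputs,
                n_hidden=hidden_sizes[k % len(hidden_sizes)],
                n_outputs=n_outputs,
                hidden_activation=hidden_activations[k % len(hidden_activations)],
                output_activation=output_activations[k % len(output_activations)],
            )
        )
    return cands


def _candidate_key(a: MLPArchitecture) -> tuple:
    return (a.n_hidden, a.hidden_activation, a.output_activation, a.n_inputs, a.n_outputs)


def model_search(
    candidates: list[MLPArchitecture],
    features: np.ndarray,
    targets: np.ndarray,
    split: DataSplit,
    seed: int = 0,
    n_retain: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> list[tuple[MLPModel, float]]:
    """Train every candidate, retain the best *n_retain* by mean
    validation Pearson r.

    Each candidate's init seed derives from the master seed and its spec
    (plus an occurrence index for duplicated specs), so the retained set
    and its ranking are invariant to the order candidates are supplied.
    Ties break toward fewer hidden neurons.
    """
    if len(candidates) < n_retain:
        raise ValueError(f"need at least {n_retain} candidates")
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    tr, va = list(split.train), list(split.validation)

    canonical = sorted(candidates, key=_candidate_key)
    occurrence: dict[tuple, int] = {}
    scored = []
    failures = []
    for rank_in_pool, arch in enumerate(canonical):
        key = _candidate_key(arch)
        occ = occurrence.get(key, 0)
        occurrence[key] = occ + 1
        cand_seed = (seed * 1000003 + rank_in_pool * 7919 + occ) % (2**31 - 1)
        try:
            model = train_mlp(arch, X[tr], Y[tr], seed=cand_seed,
                              max_iter=max_iter, tol=tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ev = evaluate(model, X[va], Y[va])
            score = float(np.nanmean(ev["pearson_r"].to_numpy()))
            if not np.isfinite(score):
                raise FloatingPointError("validation correlation undefined")
        except (FloatingPointError, ValueError) as exc:
            failures.append((arch.name, str(exc)))
            continue
        scored.append((model, score))
    if not scored:
        raise RuntimeError(f"all candidates failed: {failures}")
    scored.sort(
        key=lambda ms: (-ms[1], ms[0].architecture.n_hidden, ms[0].seed)
    )
    return scored[:n_retain]


def garson_importance(
    model: MLPModel,
    column_map: pd.DataFrame | None = None,
    output: int = 0,
) -> pd.Series:
    """Garson relative importance of each input for one output.

    Input x's share through hidden neuron b is |W_xb| / sum_a |W_ab|
    weighted by |V_b|; summing over hidden neurons and normalizing over
    inputs gives RI_x with sum 1.  With a *column_map*, one-hot columns
    are folded into their parent factor.
    """
    absW = np.abs(model.W)  # (inputs, hidden)
    col_sums = absW.sum(axis=0)  # per hidden neuron
    if np.all(absW == 0):
        raise ValueError("all input->hidden weights are zero; importance undefined")
    v = np.abs(model.V[:, output])
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(col_sums > 0, absW / col_sums, 0.0) * v
    ri = shares.sum(axis=1)
    total = ri.sum()
    if total == 0:
        raise ValueError("hidden->output weights are zero; importance undefined")
    ri = ri / total
    if column_map is None:
        return pd.Series(ri, index=[f"x{j}" for j in range(len(ri))], name="RI")
    s = pd.Series(ri, index=column_map["factor"].to_numpy(), name="RI")
    return s.groupby(level=0).sum()
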