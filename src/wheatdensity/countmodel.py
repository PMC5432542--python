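"""Plants-per-object regression with a one-hidden-layer network.

The number of plants contained in each segmented object is estimated
from its 13 morphological features with a feed-forward network: one
hidden layer of ``k_n`` tangent-sigmoid nodes and a single linear
output.  Inputs are z-scored per feature; the target stays in plant
units and predictions are continuous (an expected count), clipped below
at zero but never rounded.

Feature selection uses weight-based recursive feature elimination: the
importance of feature j is sum_h |W1[h, j]| * |w2[h]|, the least
important feature is dropped, the network retrained, and the smallest
subset whose cross-validated RMSE stays below 1.02 x the best RMSE over
all subset sizes is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .errors import SchemaError, WheatDensityError
from .objects import FEATURE_NAMES

__all__ = [
    "CountModel",
    "TrainReport",
    "RfeTrace",
    "train_network",
    "select_architecture",
    "feature_importance",
    "recursive_feature_elimination",
    "predict_counts",
    "evaluate",
]

DEFAULT_K_N = 2  # hidden nodes retained at every site in the reference runs
RFE_TOLERANCE = 1.02


def _as_matrix(X, feature_subset):
    """Extract the (n, m) matrix for ``feature_subset`` from X."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_subset if f not in X.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        return X[list(feature_subset)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_subset):
        raise SchemaError(
            f"expected {len(feature_subset)} feature columns, got {X.shape}"
        )
    return X


def _feature_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [c for c in X.columns if c in FEATURE_NAMES] or list(X.columns)
    return [f"F{j + 1}" for j in range(np.asarray(X).shape[1])]


@dataclass
class CountModel:
    """Trained network mapping object features to an expected plant count."""

    k_n: int
    input_weights: np.ndarray      # (k_n, m)
    input_biases: np.ndarray       # (k_n,)
    output_weights: np.ndarray     # (k_n,)
    output_bias: float
    feature_subset: list[str]
    norm_mean: np.ndarray          # (m,)
    norm_sd: np.ndarray            # (m,)
    seed: int = 0

    def __post_init__(self):
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.input_biases = np.asarray(self.input_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_sd = np.asarray(self.norm_sd, dtype=float)
        m = len(self.feature_subset)
        if self.input_weights.shape != (self.k_n, m):
            raise WheatDensityError("inconsistent weight shapes")
        if np.any(self.norm_sd <= 0):
            raise WheatDensityError("normalization sd must be positive")

    def raw_predict(self, X) -> np.ndarray:
        """Network output before clipping (may be negative)."""
        M = _as_matrix(X, self.feature_subset)
        Z = (M - self.norm_mean) / self.norm_sd
        hidden = np.tanh(Z @ self.input_weights.T + self.input_biases)
        return hidden @ self.output_weights + self.output_bias

    def to_json(self, path=None) -> str:
        payload = {
            "k_n": self.k_n,
            "input_weights": self.input_weights.tolist(),
            "input_biases": self.input_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "feature_subset": list(self.feature_subset),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CountModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            k_n=payload["k_n"],
            input_weights=np.array(payload["input_weights"]),
            input_biases=np.array(payload["input_biases"]),
            output_weights=np.array(payload["output_weights"]),
            output_bias=payload["output_bias"],
            feature_subset=payload["feature_subset"],
            norm_mean=np.array(payload["norm_mean"]),
            norm_sd=np.array(payload["norm_sd"]),
            seed=payload.get("seed", 0),
        )


@dataclass
class TrainReport:
    """Held-out performance: R2, RMSE and Bias = mean(pred - obs)."""

    r2: float
    rmse: float
    bias: float
    n_test: int


@dataclass
class RfeTrace:
    """Recursive-feature-elimination history.

    ``records`` runs from the full feature set down to one feature; each
    entry holds (n, feature ids, cross-validated RMSE_n).
    """

    records: list = field(default_factory=list)  # (n, [features], rmse)
    rmse_best: float = float("nan")
    chosen_n: int = 0
    chosen_features: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "records": [
                {"n": n, "features": f, "rmse": r} for n, f, r in self.records
            ],
            "rmse_best": self.rmse_best,
            "chosen_n": self.chosen_n,
            "chosen_features": self.chosen_features,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def train_network(X, y, k_n: int = DEFAULT_K_N, seed: int = 0) -> CountModel:
    """Fit the one-hidden-layer tanh network on (features, counts).

    Inputs are z-scored; zero-variance features are dropped with a
    warning.  Weights are optimized by batch L-BFGS on the mean squared
    error with a fixed 200-iteration budget, deterministic for a given
    seed.
    """
    names = _feature_names(X)
    M = _as_matrix(X, names)
    y = np.asarray(y, dtype=float).ravel()
    if M.size == 0 or len(y) != len(M):
        raise WheatDensityError("empty or mismatched training data")

    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        M = M[:, keep]
        sd = sd[keep]
    if M.shape[1] == 0:
        raise WheatDensityError("no informative features left")
    mean = M.mean(axis=0)
    Z = (M - mean) / sd

    net = MLPRegressor(
        hidden_layer_sizes=(k_n,),
        activation="tanh",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=200,
        random_state=int(seed) % (2 ** 31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from lbfgs
        net.fit(Z, y)
    return CountModel(
        k_n=k_n,
        input_weights=net.coefs_[0].T,
        input_biases=net.intercepts_[0],
        output_weights=net.coefs_[1].ravel(),
        output_bias=float(net.intercepts_[1][0]),
        feature_subset=names,
        norm_mean=mean,
        norm_sd=sd,
        seed=seed,
    )


def _splits(n: int, reps: int, seed: int, test_frac: float = 0.1):
    """``reps`` random 90/10 train/test index splits."""
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_frac * n)))
    out = []
    for _ in range(reps):
        perm = rng.permutation(n)
        out.append((perm[n_test:], perm[:n_test]))
    return out


def _cv_rmse(X, y, features, k_n, reps, seed) -> float:
    """Mean held-out RMSE over ``reps`` random 90/10 splits."""
    M = _as_matrix(X, features)
    y = np.asarray(y, dtype=float).ravel()
    rmses = []
    for r, (tr, te) in enumerate(_splits(len(y), reps, seed)):
        model = train_network(
            pd.DataFrame(M[tr], columns=features), y[tr], k_n=k_n,
            seed=seed + 17 * r + 1,
        )
        pred = predict_counts(model, pd.DataFrame(M[te], columns=features))
        rmses.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return float(np.mean(rmses))


def select_architecture(
    X, y, k_range=range(1, 11), reps: int = 5, seed: int = 0
) -> int:
    """Hidden-node count minimizing cross-validated RMSE (ties: smaller)."""
    ks = list(k_range)
    rmse = [_cv_rmse(X, y, _feature_names(X), k, reps, seed) for k in ks]
    return ks[int(np.argmin(rmse))]


def feature_importance(model: CountModel) -> list[tuple[str, float]]:
    """Weight-magnitude importance ranking, descending.

    importance(j) = sum_h |W1[h, j]| * |w2[h]|; ties broken by feature
    position in the model's subset.
    """
    imp = np.abs(model.input_weights).T @ np.abs(model.output_weights)
    order = sorted(
        range(len(imp)), key=lambda j: (-imp[j], j)
    )
    return [(model.feature_subset[j], float(imp[j])) for j in order]


def recursive_feature_elimination(
    X, y, k_n: int = DEFAULT_K_N, reps: int = 5, seed: int = 0
) -> tuple[RfeTrace, CountModel]:
    """Weight-based RFE over the feature set.

    At each subset size the cross-validated RMSE is recorded, a network
    trained on all rows ranks the features, and the least important one
    is dropped.  The chosen size is the smallest n with
    RMSE_n < 1.02 * min_n RMSE_n; the returned model is retrained on the
    chosen subset.
    """
    features = list(_feature_names(X))
    y = np.asarray(y, dtype=float).ravel()
    trace = RfeTrace()
    current = list(features)
    while current:
        n = len(current)
        # common random splits across subset sizes: RMSE differences then
        # reflect the features, not the split draw
        rmse_n = _cv_rmse(X, y, current, k_n, reps, seed)
        trace.records.append((n, list(current), rmse_n))
        if n == 1:
            break
        ranking_model = train_network(
            pd.DataFrame(_as_matrix(X, current), columns=current), y,
            k_n=k_n, seed=seed + 1000 + n,
        )
        ranked = feature_importance(ranking_model)
        victim = ranked[-1][0]
        current = [f for f in current if f != victim]

    rmses = np.array([r for _, _, r in trace.records])
    sizes = np.array([n for n, _, _ in trace.records])
    trace.rmse_best = float(rmses.min())
    ok = rmses < RFE_TOLERANCE * trace.rmse_best
    chosen_idx = int(np.argmax(sizes == sizes[ok].min()))
    trace.chosen_n = int(sizes[chosen_idx])
    trace.chosen_features = list(trace.records[chosen_idx][1])
    final = train_network(
        pd.DataFrame(_as_matrix(X, trace.chosen_features),
                     columns=trace.chosen_features),
        y, k_n=k_n, seed=seed,
    )
    return trace, final


def predict_counts(model: CountModel, X) -> np.ndarray:
    """Continuous plants-per-object predictions, clipped below at 0."""
    return np.maximum(model.raw_predict(X), 0.0)


def evaluate(model: CountModel, X_test, y_test) -> TrainReport:
    """R2, RMSE and Bias of the model on a held-out set."""
    y = np.asarray(y_test, dtype=float).ravel()
    if len(y) == 0:
        raise WheatDensityError("empty test set")
    pred = predict_counts(model, X_test)
    resid = pred - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return TrainReport(
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        bias=float(np.mean(resid)),
        n_test=len(y),
    )
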