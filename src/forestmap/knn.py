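"""Multivariate k-nearest-neighbour imputation with inverse-distance weights.

The prediction at a query point is the inverse-distance-weighted mean of the
k nearest training plots in standardized feature space,

    y_hat = sum_l w_l * y_l,     w_l ~ 1 / max(d_l, epsilon),  sum w_l = 1,

computed jointly for all three responses (volume, AGB, conifer proportion)
from one shared neighbour set. The per-pixel uncertainty is the standard
deviation of the neighbour responses about the prediction,

    s = sqrt( sum_l (y_l - y_hat)^2 / k ),

with unweighted deviations and divisor k. Distances are Euclidean; a query
coinciding with a training plot is handled by flooring distances at a small
epsilon, which makes that plot dominate the weights. Neighbour search is an
exhaustive blocked scan with a stable sort, so ties at the k-th neighbour
deterministically keep the lower training-row index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .training import FeatureScaler, RESPONSES, TrainingSet

DEFAULT_K = 7
DEFAULT_EPSILON = 1e-9  # distance floor, standardized units


@dataclass(frozen=True)
class KnnConfig:
    k: int = DEFAULT_K
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class Prediction:
    """Point prediction and uncertainty for (vol, agb, dcp)."""

    y_hat: np.ndarray  # shape (3,)
    s: np.ndarray  # shape (3,), >= 0


class KnnModel:
    """Fitted model: training features/responses, scaler and parameters."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, scaler: FeatureScaler,
                 config: KnnConfig, plot_ids: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if len(X) < config.k:
            raise ValueError(f"need at least k={config.k} training plots, got {len(X)}")
        self.X = X
        self.Y = Y
        self.scaler = scaler
        self.config = config
        self.plot_ids = (
            np.asarray(plot_ids, dtype=object) if plot_ids is not None
            else np.arange(len(X)).astype(object)
        )

    # -- neighbour search ---------------------------------------------------

    def kneighbors(self, Q: np.ndarray, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Indices and Euclidean distances of the k nearest training rows.

        Exhaustive search in row blocks; squared distances are the plain sum
        of squared per-feature differences and ordering uses a stable sort,
        so equal distances resolve to the lower training-row index.
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
        if Q.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"query has {Q.shape[1]} features, model expects {self.X.shape[1]}"
            )
        k = self.config.k
        nq = len(Q)
        idx = np.empty((nq, k), dtype=np.intp)
        dist = np.empty((nq, k), dtype=np.float64)
        for start in range(0, nq, chunk):
            q = Q[start:start + chunk]
            d2 = ((q[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
            order = np.argsort(d2, axis=1, kind="stable")[:, :k]
            idx[start:start + chunk] = order
            dist[start:start + chunk] = np.sqrt(np.take_along_axis(d2, order, axis=1))
        return idx, dist

    # -- prediction ---------------------------------------------------------

    def predict_batch(self, Q: np.ndarray, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Predictions and uncertainties for each row of Q (standardized).

        Returns (Y_hat, S), each of shape (n_queries, 3) in response order
        (vol, agb, dcp).
        """
        idx, dist = self.kneighbors(Q, chunk=chunk)
        w = 1.0 / np.maximum(dist, self.config.epsilon)
        w /= w.sum(axis=1, keepdims=True)
        Yn = self.Y[idx]  # (nq, k, 3)
        y_hat = np.einsum("qk,qkr->qr", w, Yn)
        s = np.sqrt(((Yn - y_hat[:, None, :]) ** 2).sum(axis=1) / self.config.k)
        return y_hat, s

    def predict(self, x: np.ndarray) -> Prediction:
        """Single-query prediction; x must be standardized with the model's
        scaler and laid out in the model's column order."""
        y_hat, s = self.predict_batch(np.atleast_2d(x))
        return Prediction(y_hat=y_hat[0], s=s[0])

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize the model to one .npz archive."""
        path = Path(path)
        meta = {
            "k": self.config.k,
            "epsilon": self.config.epsilon,
            "columns": list(self.scaler.columns),
            "scaling_mode": self.scaler.mode,
            "responses": list(RESPONSES),
        }
        np.savez_compressed(
            path,
            X=self.X,
            Y=self.Y,
            center=self.scaler.center,
            scale=self.scaler.scale,
            plot_ids=self.plot_ids.astype(str),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "KnnModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            scaler = FeatureScaler(
                columns=tuple(meta["columns"]),
                center=z["center"],
                scale=z["scale"],
                mode=meta["scaling_mode"],
            )
            return cls(
                X=z["X"],
                Y=z["Y"],
                scaler=scaler,
                config=KnnConfig(k=int(meta["k"]), epsilon=float(meta["epsilon"])),
                plot_ids=z["plot_ids"].astype(object),
            )


def fit(training: TrainingSet, config: KnnConfig | None = None) -> KnnModel:
    """Fit a kNN model on an assembled training set."""
    if config is None:
        config = KnnConfig()
    return KnnModel(
        X=training.X, Y=training.Y, scaler=training.scaler,
        config=config, plot_ids=training.plot_ids,
    )
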