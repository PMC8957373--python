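"""Shallow feed-forward network mapping 16-channel spectra to SO2 (%).

The regressor is a classic one-hidden-layer network

    yhat = W2 . tanh(W1 . x_s + b1) + b2

trained by Levenberg-Marquardt (damped Gauss-Newton) on a weighted
mean-square error, with early stopping on a held-out validation split and
best-validation-weights restore.  Inputs and targets are min-max scaled
to [-1, 1] on the training split (tanh saturation control); predictions
are inverse-scaled back to % and deliberately NOT clipped to [0, 100] —
the reference itself reports slightly out-of-range values, and clipping
would bias downstream agreement statistics.

:class:`ShallowANNRegressor` follows the scikit-learn estimator API
(``fit``/``predict``/``get_params``) and composes with sklearn model
selection; fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .mosaic import CubeStage, DataCube, N_BANDS
from .sampling import normalize_rows

__all__ = ["AffineScaler", "ShallowANNRegressor", "predict_map"]


@dataclass(frozen=True)
class AffineScaler:
    """Invertible per-feature affine map x_s = (x - offset) * scale."""

    offset: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit_minmax(cls, x: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> "AffineScaler":
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        xmin, xmax = x.min(axis=0), x.max(axis=0)
        rng = xmax - xmin
        if np.any(rng <= 0):
            raise ValueError("cannot scale a feature with zero range")
        scale = (hi - lo) / rng
        offset = xmin - lo / scale
        return cls(offset=offset, scale=scale)

    @classmethod
    def identity(cls, n: int) -> "AffineScaler":
        return cls(offset=np.zeros(n), scale=np.ones(n))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.offset) * self.scale

    def inverse(self, xs: np.ndarray) -> np.ndarray:
        return np.asarray(xs, dtype=np.float64) / self.scale + self.offset


class ShallowANNRegressor(RegressorMixin, BaseEstimator):
    """16 -> n_hidden -> 1 tanh network trained by Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int, default 3
        Hidden-layer width.  Three nodes suffice for the 16-channel
        SO2 regression; larger layers change the error only marginally.
    max_epochs, max_val_failures, mu0, mu_dec, mu_inc, mu_max, grad_min :
        Levenberg-Marquardt schedule.  An epoch computes the Jacobian of
        the (sqrt-weight-scaled) residuals, then retries the damped
        normal-equation step with mu <- mu * mu_inc until the training
        SSE decreases; an accepted step multiplies mu by mu_dec.
        Training stops at max_epochs, when mu exceeds mu_max, when the
        gradient infinity-norm falls below grad_min, or after
        max_val_failures consecutive epochs without a new best
        validation error.  The returned weights are those of the best
        validation epoch.
    val_fraction, test_fraction : float
        Random per-sample split inside ``fit`` (the remainder trains).
        The test split takes no part in training or stopping; it is held
        out for reporting.  Set val_fraction=0 to disable early stopping.
    random_state : int or None
        Seeds the weight initialization (and the split, unless
        ``split_random_state`` is given).
    split_random_state : int or None
        Separate seed for the train/val/test split, so repeated
        trainings can share identical splits while re-initializing
        weights.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : network weights (hidden H x 16, H, H, scalar).
    input_scaler_, target_scaler_ : fitted [-1, 1] min-max maps.
    split_indices_ : dict of train/val/test index arrays.
    history_ : per-epoch record (mu, train and validation weighted MSE).
    n_iter_ : number of accepted epochs.
    """

    def __init__(self, n_hidden: int = 3, max_epochs: int = 1000,
                 max_val_failures: int = 6, mu0: float = 1e-3,
                 mu_dec: float = 0.1, mu_inc: float = 10.0,
                 mu_max: float = 1e10, grad_min: float = 1e-7,
                 val_fraction: float = 0.15, test_fraction: float = 0.15,
                 random_state: int | None = None,
                 split_random_state: int | None = None):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.max_val_failures = max_val_failures
        self.mu0 = mu0
        self.mu_dec = mu_dec
        self.mu_inc = mu_inc
        self.mu_max = mu_max
        self.grad_min = grad_min
        self.val_fraction = val_fraction
        self.test_fraction = test_fraction
        self.random_state = random_state
        self.split_random_state = split_random_state

    # ----- architecture helpers -------------------------------------------

    @property
    def n_parameters_(self) -> int:
        h = self.n_hidden
        return (N_BANDS + 1) * h + (h + 1)

    def initialize(self, rng: np.random.Generator | None = None) -> "ShallowANNRegressor":
        """Draw fresh weights (layer-width-aware Nguyen-Widrow style).

        Hidden rows are random unit directions scaled so the tanh active
        regions tile the [-1, 1] input box; biases spread the fold
        locations.  Distinct seeds give distinct weights, which is what
        re-initialized training repetitions rely on.
        """
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        rng = np.random.default_rng(self.random_state) if rng is None else rng
        h = self.n_hidden
        magnitude = 0.7 * h ** (1.0 / N_BANDS)
        w = rng.standard_normal((h, N_BANDS))
        w *= magnitude / np.linalg.norm(w, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=h)
        if h == 1:
            b = np.zeros(1)
        else:
            b = magnitude * np.linspace(-1.0, 1.0, h) * signs
        self.W1_, self.b1_ = w, b
        self.W2_ = rng.uniform(-1.0, 1.0, size=h) / np.sqrt(h)
        self.b2_ = float(rng.uniform(-0.1, 0.1))
        self.input_scaler_ = AffineScaler.identity(N_BANDS)
        self.target_scaler_ = AffineScaler.identity(1)
        return self

    @classmethod
    def from_weights(cls, W1, b1, W2, b2,
                     input_scaler: AffineScaler | None = None,
                     target_scaler: AffineScaler | None = None) -> "ShallowANNRegressor":
        """Build a ready-to-predict model from explicit weights."""
        W1 = np.atleast_2d(np.asarray(W1, dtype=np.float64))
        model = cls(n_hidden=W1.shape[0])
        model.W1_ = W1
        model.b1_ = np.asarray(b1, dtype=np.float64).ravel()
        model.W2_ = np.asarray(W2, dtype=np.float64).ravel()
        model.b2_ = float(b2)
        model.input_scaler_ = input_scaler or AffineScaler.identity(W1.shape[1])
        model.target_scaler_ = target_scaler or AffineScaler.identity(1)
        return model

    # ----- parameter vector packing ---------------------------------------

    def _pack(self) -> np.ndarray:
        return np.concatenate([self.W1_.ravel(), self.b1_, self.W2_, [self.b2_]])

    def _unpack(self, theta: np.ndarray) -> None:
        h = self.n_hidden
        k = h * N_BANDS
        self.W1_ = theta[:k].reshape(h, N_BANDS)
        self.b1_ = theta[k:k + h]
        self.W2_ = theta[k + h:k + 2 * h]
        self.b2_ = float(theta[-1])

    # ----- forward / jacobian ---------------------------------------------

    def _forward_scaled(self, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = np.tanh(xs @ self.W1_.T + self.b1_)
        return u @ self.W2_ + self.b2_, u

    def _jacobian(self, xs: np.ndarray, u: np.ndarray) -> np.ndarray:
        """d(yhat_s)/d(theta), rows per sample, columns matching _pack."""
        d = (1.0 - u ** 2) * self.W2_          # N x H
        j_w1 = np.einsum("nh,nj->nhj", d, xs).reshape(len(xs), -1)
        ones = np.ones((len(xs), 1))
        return np.concatenate([j_w1, d, u, ones], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """SO2 predictions in %, one per input spectrum."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != N_BANDS:
            raise ValueError(f"expected {N_BANDS} input channels, got {X.shape[1]}")
        ys, _ = self._forward_scaled(self.input_scaler_.transform(X))
        return self.target_scaler_.inverse(ys[:, None]).ravel()

    # ----- training --------------------------------------------------------

    def _split(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        perm = rng.permutation(n)
        n_val = int(round(self.val_fraction * n))
        n_test = int(round(self.test_fraction * n))
        return {"val": np.sort(perm[:n_val]),
                "test": np.sort(perm[n_val:n_val + n_test]),
                "train": np.sort(perm[n_val + n_test:])}

    def fit(self, X: np.ndarray, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "ShallowANNRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[1] != N_BANDS:
            raise ValueError(f"expected {N_BANDS} input channels, got {X.shape[1]}")
        w = (np.ones_like(y) if sample_weight is None
             else np.asarray(sample_weight, dtype=np.float64).ravel())
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("sample weights must be nonnegative, not all zero")

        rng = np.random.default_rng(self.random_state)
        split_rng = (rng if self.split_random_state is None
                     else np.random.default_rng(self.split_random_state))
        self.split_indices_ = self._split(len(y), split_rng)
        tr = self.split_indices_["train"]
        va = self.split_indices_["val"]

        self.initialize(rng=rng)
        self.input_scaler_ = AffineScaler.fit_minmax(X[tr])
        self.target_scaler_ = AffineScaler.fit_minmax(y[tr, None])
        xs_tr = self.input_scaler_.transform(X[tr])
        ts_tr = self.target_scaler_.transform(y[tr, None]).ravel()
        sw_tr = np.sqrt(w[tr])
        xs_va = self.input_scaler_.transform(X[va]) if len(va) else None
        ts_va = self.target_scaler_.transform(y[va, None]).ravel() if len(va) else None
        w_va = w[va] if len(va) else None

        theta = self._pack()
        mu = self.mu0
        history: list[dict] = []

        def train_sse(th: np.ndarray) -> float:
            self._unpack(th)
            ys, _ = self._forward_scaled(xs_tr)
            r = sw_tr * (ys - ts_tr)
            return float(r @ r)

        def val_perf() -> float:
            ys, _ = self._forward_scaled(xs_va)
            return float(np.sum(w_va * (ys - ts_va) ** 2) / np.sum(w_va))

        sse = train_sse(theta)
        best_theta, best_val = theta.copy(), np.inf
        if xs_va is not None:
            best_val = val_perf()
        val_failures = 0
        stop = None
        n_epochs = 0
        p = self.n_parameters_

        for _ in range(self.max_epochs):
            self._unpack(theta)
            ys, u = self._forward_scaled(xs_tr)
            r = sw_tr * (ys - ts_tr)
            jac = self._jacobian(xs_tr, u) * sw_tr[:, None]
            grad = jac.T @ r
            if np.max(np.abs(2.0 * grad)) < self.grad_min:
                stop = "gradient floor"
                break
            jtj = jac.T @ jac
            accepted = False
            while mu <= self.mu_max:
                try:
                    cho = linalg.cho_factor(jtj + mu * np.eye(p))
                    step = linalg.cho_solve(cho, -grad)
                except linalg.LinAlgError:
                    mu *= self.mu_inc
                    continue
                candidate = theta + step
                new_sse = train_sse(candidate)
                if new_sse < sse:
                    theta, sse = candidate, new_sse
                    mu = max(mu * self.mu_dec, np.finfo(float).tiny)
                    accepted = True
                    break
                mu *= self.mu_inc
            if not accepted:
                stop = "mu ceiling"
                break
            n_epochs += 1
            self._unpack(theta)
            record = {"epoch": n_epochs, "mu": mu,
                      "train_mse": sse / float(np.sum(w[tr]))}
            if xs_va is not None:
                vp = val_perf()
                record["val_mse"] = vp
                if vp < best_val:
                    best_val, best_theta = vp, theta.copy()
                    val_failures = 0
                else:
                    val_failures += 1
                    if val_failures >= self.max_val_failures:
                        history.append(record)
                        stop = "validation"
                        break
            else:
                best_theta = theta.copy()
            history.append(record)
        else:
            stop = "max epochs"
        if stop in ("gradient floor", "mu ceiling"):
            if xs_va is None:
                best_theta = theta.copy()
            elif np.isinf(best_val):
                best_theta = theta.copy()

        self._unpack(best_theta)
        self.history_ = history
        self.n_iter_ = n_epochs
        self.stop_reason_ = stop
        return self

    # ----- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_,
            "input_offset": self.input_scaler_.offset.tolist(),
            "input_scale": self.input_scaler_.scale.tolist(),
            "target_offset": self.target_scaler_.offset.tolist(),
            "target_scale": self.target_scaler_.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShallowANNRegressor":
        return cls.from_weights(
            d["W1"], d["b1"], d["W2"], d["b2"],
            input_scaler=AffineScaler(np.asarray(d["input_offset"]),
                                      np.asarray(d["input_scale"])),
            target_scaler=AffineScaler(np.asarray(d["target_offset"]),
                                       np.asarray(d["target_scale"])))


def predict_map(model: ShallowANNRegressor, cube: DataCube,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Pixelwise SO2 map (%) from a reflectance cube.

    Each kept pixel's spectrum is mean-normalized and pushed through the
    network; masked-out pixels are NaN.
    """
    if cube.stage is not CubeStage.REFLECTANCE:
        raise ValueError("prediction requires a reflectance-stage cube")
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    out = np.full((rows, cols), np.nan)
    if not mask.any():
        return out
    spectra = normalize_rows(cube.values[mask])
    out[mask] = model.predict(spectra)
    return out
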