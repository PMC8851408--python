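"""Per-region neural-network surrogates and the shape objective.

Two small feedforward networks per region — one for normalized activation
area A(a, t), one for eccentricity E(a, t) — each with a single hidden layer
of 10 hyperbolic-tangent units and a linear output, trained by
Levenberg–Marquardt on the responsive trials recorded so far.  Inputs are
min–max scaled to [0, 1] internally.

The stimulation objective is

    f(a, t) = |A(a, t) - C| + E(a, t)

where C is the electrode area in the same normalized units (activation and
electrode areas are both divided by the region's maximum observed activation
area).  Its ideal value 0 corresponds to a response exactly covering the
electrode with zero elongation — a focal, round activation patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from focalstim.imaging import SPARSE_ACTIVITY_FLOOR_PX, ResponseShape
from focalstim.stimulus import PulseParams, DURATION_RATIOS
from focalstim.synthetic import ELECTRODE_AREA_UM2

N_HIDDEN = 10
WEIGHT_DECAY = 5e-4      # LM damping on the weights: keeps the 41-parameter
                         # fit well-posed when trials number fewer than weights,
                         # and suppresses tanh oscillation in the sub-threshold
                         # amplitude band that carries no training points
                         # (unanchored wiggles there create spurious corner
                         # minima in the objective landscape)
N_RESTARTS = 3


class InsufficientDataError(ValueError):
    """Fewer than three responsive trials; surrogates cannot be fit."""


# ---------------------------------------------------------------------------
# the 2-10-1 tanh network


class TanhNet:
    """y(x) = w2 . tanh(W1 x + b1) + b2 for 2-D scaled inputs.

    Parameters are packed as [W1.ravel() (20), b1 (10), w2 (10), b2 (1)].
    """

    n_params = 2 * N_HIDDEN + N_HIDDEN + N_HIDDEN + 1

    def __init__(self, theta: np.ndarray, input_lo: np.ndarray, input_hi: np.ndarray,
                 clip: tuple[float, float] | None = None):
        self.theta = np.asarray(theta, dtype=float)
        self.input_lo = np.asarray(input_lo, dtype=float)
        self.input_hi = np.asarray(input_hi, dtype=float)
        self.clip = clip

    # -- parameter views
    def _unpack(self):
        th = self.theta
        W1 = th[:20].reshape(N_HIDDEN, 2)
        b1 = th[20:30]
        w2 = th[30:40]
        b2 = th[40]
        return W1, b1, w2, b2

    def _scale(self, a, t):
        x = np.stack([np.asarray(a, dtype=float), np.asarray(t, dtype=float)], axis=-1)
        return (x - self.input_lo) / (self.input_hi - self.input_lo)

    def __call__(self, a, t):
        """Predict at raw coordinates (amplitude µA, type index)."""
        W1, b1, w2, b2 = self._unpack()
        z = self._scale(a, t)
        h = np.tanh(z @ W1.T + b1)
        y = h @ w2 + b2
        if self.clip is not None:
            y = np.clip(y, *self.clip)
        return y if y.ndim else float(y)

    def gradient(self, a, t) -> np.ndarray:
        """Analytic d y / d (a, t) at one raw point (before any clipping)."""
        W1, b1, w2, b2 = self._unpack()
        z = self._scale(float(a), float(t))
        h = np.tanh(W1 @ z + b1)
        dz = W1.T @ (w2 * (1.0 - h ** 2))
        return dz / (self.input_hi - self.input_lo)

    def to_dict(self) -> dict:
        return {"theta": self.theta.tolist(), "input_lo": self.input_lo.tolist(),
                "input_hi": self.input_hi.tolist(), "clip": self.clip,
                "architecture": f"2-{N_HIDDEN}-1 tanh/linear"}

    @classmethod
    def from_dict(cls, d: dict) -> "TanhNet":
        clip = tuple(d["clip"]) if d.get("clip") else None
        return cls(np.asarray(d["theta"]), np.asarray(d["input_lo"]),
                   np.asarray(d["input_hi"]), clip)


def _net_residuals_jac(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Residuals and Jacobian for LM: data misfit plus weight decay."""
    W1 = theta[:20].reshape(N_HIDDEN, 2)
    b1 = theta[20:30]
    w2 = theta[30:40]
    b2 = theta[40]
    H = np.tanh(X @ W1.T + b1)                    # (n, 10)
    pred = H @ w2 + b2
    res = pred - y
    n = X.shape[0]
    J = np.empty((n, TanhNet.n_params))
    G = (1.0 - H ** 2) * w2                        # (n, 10)
    J[:, :20] = (G[:, :, None] * X[:, None, :]).reshape(n, 20)
    J[:, 20:30] = G
    J[:, 30:40] = H
    J[:, 40] = 1.0
    sw = np.sqrt(WEIGHT_DECAY)
    res_full = np.concatenate([res, sw * theta])
    J_full = np.vstack([J, sw * np.eye(TanhNet.n_params)])
    return res_full, J_full


def _fit_tanh_net(X: np.ndarray, y: np.ndarray, Xval: np.ndarray, yval: np.ndarray,
                  rng: np.random.Generator, input_lo, input_hi,
                  clip=None) -> tuple[TanhNet, float]:
    """Levenberg–Marquardt fit with random restarts selected on validation MSE."""
    best_net, best_val = None, np.inf
    for _ in range(N_RESTARTS):
        theta0 = rng.normal(0.0, 0.5, TanhNet.n_params)
        sol = least_squares(
            lambda th: _net_residuals_jac(th, X, y)[0], theta0,
            jac=lambda th: _net_residuals_jac(th, X, y)[1],
            method="lm", xtol=1e-10, ftol=1e-10, max_nfev=400,
        )
        net = TanhNet(sol.x, input_lo, input_hi, clip=clip)
        val_pred = np.tanh(Xval @ sol.x[:20].reshape(N_HIDDEN, 2).T + sol.x[20:30]) @ sol.x[30:40] + sol.x[40]
        val_mse = float(np.mean((val_pred - yval) ** 2))
        if val_mse < best_val:
            best_net, best_val = net, val_mse
    return best_net, best_val


# ---------------------------------------------------------------------------
# training-set assembly and the surrogate pair


def prepare_training_set(trials: list[tuple[PulseParams, ResponseShape]],
                         electrode_area: float = ELECTRODE_AREA_UM2) -> tuple[pd.DataFrame, float]:
    """Build the regression table from responsive trials.

    Trials with no calcium response (active-pixel count below the sparse
    floor) are excluded.  Areas are normalized by the maximum observed
    activation area of the region so far; the returned normalization
    constant also converts the electrode area into the objective's C.

    Returns
    -------
    (table, area_max) : (pandas.DataFrame, float)
        columns: amplitude, type_index, area_normalized, eccentricity.

    Raises
    ------
    InsufficientDataError
        if fewer than 3 responsive trials remain after exclusion.
    """
    rows = []
    for pulse, shape in trials:
        if shape.n_active_pixels < SPARSE_ACTIVITY_FLOOR_PX:
            continue
        rows.append((pulse.cathodic_amplitude, pulse.type_index,
                     shape.area, shape.eccentricity))
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} responsive trials (need >= 3) — enlarge the sample"
        )
    df = pd.DataFrame(rows, columns=["amplitude", "type_index", "area", "eccentricity"])
    area_max = float(df["area"].max())
    df["area_normalized"] = df["area"] / area_max
    return df[["amplitude", "type_index", "area_normalized", "eccentricity"]], area_max


def _split_sizes(n: int) -> tuple[int, int, int]:
    """Train/val/test row counts within the 60–80 / 10–20 / 10–20 bands."""
    if n < 5:
        # degenerate small-sample fallback: train on everything, reuse the
        # last row for validation and test
        return n, 1, 1
    n_val = max(1, int(round(0.15 * n)))
    n_te = max(1, int(round(0.15 * n)))
    return n - n_val - n_te, n_val, n_te


@dataclass
class SurrogatePair:
    """Trained area and eccentricity surrogates for one region."""

    area_net: TanhNet
    ecc_net: TanhNet
    region_area_max: float             # µm², normalization constant
    C: float                           # normalized electrode area
    box: tuple[tuple[float, float], tuple[float, float]]   # (a bounds, t bounds)
    split_sizes: tuple[int, int, int]
    metrics: dict = field(default_factory=dict)   # MSE per net per split
    architecture: str = f"2-{N_HIDDEN}-1 tanh hidden, linear output"

    def predict(self, a, t) -> tuple:
        return self.area_net(a, t), self.ecc_net(a, t)

    def to_dict(self) -> dict:
        return {"area_net": self.area_net.to_dict(), "ecc_net": self.ecc_net.to_dict(),
                "region_area_max": self.region_area_max, "C": self.C,
                "box": [list(self.box[0]), list(self.box[1])],
                "split_sizes": list(self.split_sizes), "metrics": self.metrics,
                "architecture": self.architecture}


def train_surrogates(table: pd.DataFrame, seed: int,
                     area_max: float,
                     box: tuple[tuple[float, float], tuple[float, float]],
                     electrode_area: float = ELECTRODE_AREA_UM2) -> SurrogatePair:
    """Train the area and eccentricity networks on one regression table.

    Rows are shuffled deterministically and split into train/validation/test
    subsets (the split fractions adapt to the sample size within the
    60–80 / 10–20 / 10–20 bands).  Each network is fit by damped
    Levenberg–Marquardt from several random initializations; the fit with the
    lowest validation MSE is kept and its held-out test MSE reported in
    ``metrics``.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    order = rng.permutation(n)
    n_tr, n_val, n_te = _split_sizes(n)
    if n < 5:
        idx_tr, idx_val, idx_te = order, order[-1:], order[-1:]
    else:
        idx_tr = order[:n_tr]
        idx_val = order[n_tr:n_tr + n_val]
        idx_te = order[n_tr + n_val:]

    (a_lo, a_hi), (t_lo, t_hi) = box
    lo = np.array([a_lo, t_lo])
    hi = np.array([a_hi, t_hi])
    raw = table[["amplitude", "type_index"]].to_numpy(dtype=float)
    X = (raw - lo) / (hi - lo)

    metrics = {}
    nets = {}
    for name, clip in (("area", (0.0, None)), ("eccentricity", (0.0, 1.0))):
        y = table[name if name == "eccentricity" else "area_normalized"].to_numpy(dtype=float)
        clip_t = (clip[0], np.inf) if clip[1] is None else clip
        net, val_mse = _fit_tanh_net(X[idx_tr], y[idx_tr], X[idx_val], y[idx_val],
                                     rng, lo, hi, clip=clip_t)
        pred_te = np.array([net(raw[i, 0], raw[i, 1]) for i in idx_te])
        pred_tr = np.array([net(raw[i, 0], raw[i, 1]) for i in idx_tr])
        metrics[name] = {
            "train_mse": float(np.mean((pred_tr - y[idx_tr]) ** 2)),
            "val_mse": float(val_mse),
            "test_mse": float(np.mean((pred_te - y[idx_te]) ** 2)),
        }
        nets[name] = net

    return SurrogatePair(
        area_net=nets["area"], ecc_net=nets["eccentricity"],
        region_area_max=float(area_max),
        C=float(electrode_area / area_max),
        box=box, split_sizes=(len(idx_tr), len(idx_val), len(idx_te)),
        metrics=metrics,
    )


# ---------------------------------------------------------------------------
# the objective


def objective(pair: SurrogatePair, a, t) -> float:
    """f(a, t) = |A(a, t) - C| + E(a, t); 0 is the focal-round ideal."""
    A, E = pair.predict(a, t)
    return np.abs(A - pair.C) + E


def objective_gradient(pair: SurrogatePair, a, t) -> np.ndarray:
    """Analytic gradient of the objective (subgradient 0 at A = C)."""
    A = pair.area_net(a, t)
    E_raw_grad = pair.ecc_net.gradient(a, t)
    # eccentricity clipping: zero gradient where the prediction is clipped
    E_unclipped = TanhNet(pair.ecc_net.theta, pair.ecc_net.input_lo,
                          pair.ecc_net.input_hi, clip=None)(a, t)
    g_E = E_raw_grad if 0.0 < E_unclipped < 1.0 else np.zeros(2)
    g_A = pair.area_net.gradient(a, t) * np.sign(A - pair.C)
    return g_A + g_E


@dataclass
class ObjectiveSurface:
    """Dense objective evaluation for maps and the brute-force oracle."""

    amplitudes: np.ndarray
    types: np.ndarray
    values: np.ndarray            # (n_types, n_amplitudes)
    C: float

    def argmin(self) -> tuple[float, float, float]:
        """(amplitude, type, value) of the grid minimum."""
        i, j = np.unravel_index(np.argmin(self.values), self.values.shape)
        return float(self.amplitudes[j]), float(self.types[i]), float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"amplitude": float(a), "type": float(t), "f": float(self.values[i, j])}
            for i, t in enumerate(self.types) for j, a in enumerate(self.amplitudes)
        ]
        return pd.DataFrame(recs)


def objective_map(pair: SurrogatePair, amplitude_step: float = 2.0,
                  type_step: float = 1.0) -> ObjectiveSurface:
    """Evaluate f on a dense grid (default 2 µA x 1 type-index resolution)."""
    (a_lo, a_hi), (t_lo, t_hi) = pair.box
    amps = np.arange(a_lo, a_hi + 1e-9, amplitude_step)
    types = np.arange(t_lo, t_hi + 1e-9, type_step)
    A = pair.area_net(amps[None, :].repeat(len(types), 0),
                      types[:, None].repeat(len(amps), 1))
    E = pair.ecc_net(amps[None, :].repeat(len(types), 0),
                     types[:, None].repeat(len(amps), 1))
    values = np.abs(A - pair.C) + E
    return ObjectiveSurface(amplitudes=amps, types=types, values=values, C=pair.C)
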