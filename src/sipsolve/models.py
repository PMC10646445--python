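"""Benchmark forward models for stochastic inverse problems.

Each model wraps a map ``y = M(x)`` (deterministic) or ``y = M(x, eps)``
(stochastic, with ``eps`` a vector of embedded physical noise) behind a common
batched interface.  Models keep a monotone counter of simulator evaluations so
solvers can be compared at a fixed simulation budget, and differentiable
models expose analytic Jacobians so gradient-based solvers can backpropagate
through the simulator.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForwardModel",
    "DomainError",
    "NonlinearSystem",
    "TiltmeterSpec",
    "Tiltmeter",
    "Rosenbrock",
    "AvgPool",
    "eval_nonlinear_system",
    "eval_tiltmeter",
    "eval_avg_pool",
    "SurrogateModel",
    "fit_surrogate",
    "make_model",
    "MODEL_REGISTRY",
]


class DomainError(ValueError):
    """Raised when a parameter vector falls outside a model's domain."""


class ForwardModel(abc.ABC):
    """Batched forward map with simulation accounting.

    Attributes
    ----------
    dim_x : int
        Parameter dimension.
    dim_y : int
        Observation dimension.
    dim_eps : int
        Dimension of the embedded noise vector; 0 for deterministic models.
    differentiable : bool
        Whether analytic Jacobians (``jac_x``, ``jac_eps``) are available.
    n_simulations : int
        Monotone counter, incremented by the batch size on every evaluation.
    """

    dim_x: int
    dim_y: int
    dim_eps: int = 0
    differentiable: bool = False

    def __init__(self) -> None:
        self._n_simulations = 0

    @property
    def n_simulations(self) -> int:
        return self._n_simulations

    def evaluate(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the model on ``n`` parameter vectors.

        ``x`` has shape (n, dim_x); ``eps``, when the model is stochastic,
        has shape (n, dim_eps).  Returns observations of shape (n, dim_y)
        and increments :attr:`n_simulations` by ``n``.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim_x:
            raise ValueError(
                f"expected parameter vectors of dimension {self.dim_x}, "
                f"got shape {x.shape}"
            )
        if self.dim_eps:
            if eps is None:
                eps = np.zeros((x.shape[0], self.dim_eps))
            eps = np.atleast_2d(np.asarray(eps, dtype=float))
            if eps.shape != (x.shape[0], self.dim_eps):
                raise ValueError(
                    f"noise must have shape {(x.shape[0], self.dim_eps)}, "
                    f"got {eps.shape}"
                )
        elif eps is not None and np.any(np.asarray(eps) != 0):
            raise ValueError("deterministic model does not accept noise input")
        y = self._evaluate(x, eps)
        self._n_simulations += x.shape[0]
        return y

    __call__ = evaluate

    @abc.abstractmethod
    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        ...

    def jac_x(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        """d y / d x, shape (n, dim_y, dim_x). Does not count as a simulation."""
        raise NotImplementedError(f"{type(self).__name__} is not differentiable")

    def jac_eps(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        """d y / d eps, shape (n, dim_y, dim_eps)."""
        raise NotImplementedError(f"{type(self).__name__} has no noise input")


# ---------------------------------------------------------------------------
# Nonlinear system benchmark
# ---------------------------------------------------------------------------

def eval_nonlinear_system(x1: float, x2: float) -> float:
    """Output y2 of the two-equation nonlinear system

        x1*y1**2 + y2**2 = 1
        y1**2 - x2*y2**2 = 1

    solved in closed form for the non-negative root:
    ``y2 = sqrt((1 - x1) / (1 + x1*x2))``.  The non-negative branch is the
    one compatible with target observation distributions supported on
    positive outputs.
    """
    denom = 1.0 + x1 * x2
    if denom <= 0:
        raise DomainError(
            f"degenerate denominator 1 + x1*x2 = {denom} for x1={x1}, x2={x2}"
        )
    rad = (1.0 - x1) / denom
    if rad < 0:
        raise DomainError(
            f"negative radicand (1 - x1)/(1 + x1*x2) = {rad} for x1={x1}, x2={x2}"
        )
    return float(np.sqrt(rad))


class NonlinearSystem(ForwardModel):
    """Closed-form solver of the 2-parameter nonlinear system (output y2)."""

    dim_x = 2
    dim_y = 1
    dim_eps = 0
    differentiable = True

    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        x1, x2 = x[:, 0], x[:, 1]
        denom = 1.0 + x1 * x2
        if np.any(denom <= 0):
            i = int(np.argmax(denom <= 0))
            raise DomainError(
                f"degenerate denominator 1 + x1*x2 <= 0 at x = {x[i]}"
            )
        rad = (1.0 - x1) / denom
        if np.any(rad < 0):
            i = int(np.argmax(rad < 0))
            raise DomainError(f"negative radicand at x = {x[i]}")
        return np.sqrt(rad)[:, None]

    def jac_x(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x1, x2 = x[:, 0], x[:, 1]
        num = 1.0 - x1
        den = 1.0 + x1 * x2
        y = np.sqrt(num / den)
        # guard the y -> 0 edge (x1 -> 1): derivative diverges there
        y_safe = np.maximum(y, 1e-12)
        dy_dx1 = -(den + num * x2) / (2.0 * y_safe * den**2)
        dy_dx2 = -(num * x1) / (2.0 * y_safe * den**2)
        return np.stack([dy_dx1, dy_dx2], axis=-1)[:, None, :]


# ---------------------------------------------------------------------------
# Tiltmeter benchmark
# ---------------------------------------------------------------------------

@dataclass
class TiltmeterSpec:
    """Geometry of the wobbling-plate (tiltmeter) benchmark.

    A square plate pivots near the origin; its height above a surface point
    (p1, p2) is ``y = y0 + x1*(p1 + eps1) + x2*(p2 + eps2)`` where (x1, x2)
    are the plate slopes and (eps1, eps2) perturb the measurement location.
    """

    y0: float = 3.0
    positions: tuple[tuple[float, float], ...] = ((0.6, 0.6), (0.8, 0.6))

    def __post_init__(self) -> None:
        self.positions = tuple(tuple(float(c) for c in p) for p in self.positions)
        if not all(len(p) == 2 for p in self.positions):
            raise ValueError("each measurement position must be a (p1, p2) pair")


def eval_tiltmeter(
    spec: TiltmeterSpec, x: np.ndarray, eps: np.ndarray | None = None
) -> np.ndarray:
    """Plate heights at every measurement position for one parameter vector.

    ``eps`` holds one (eps1, eps2) pair per position, flattened; pass zeros
    (or None) for the deterministic instrument.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (2,):
        raise ValueError("tiltmeter expects a 2-vector of slopes (x1, x2)")
    npos = len(spec.positions)
    if eps is None:
        eps = np.zeros(2 * npos)
    eps = np.asarray(eps, dtype=float).reshape(-1)
    if eps.shape != (2 * npos,):
        raise ValueError(
            f"noise must supply one (eps1, eps2) pair per position: expected "
            f"{2 * npos} values, got {eps.size}"
        )
    out = np.empty(npos)
    for k, (p1, p2) in enumerate(spec.positions):
        e1, e2 = eps[2 * k], eps[2 * k + 1]
        out[k] = spec.y0 + x[0] * (p1 + e1) + x[1] * (p2 + e2)
    return out


class Tiltmeter(ForwardModel):
    """Batched tiltmeter model; stochastic when built with ``stochastic=True``."""

    differentiable = True

    def __init__(self, spec: TiltmeterSpec | None = None, stochastic: bool = False):
        super().__init__()
        self.spec = spec or TiltmeterSpec()
        self.dim_x = 2
        self.dim_y = len(self.spec.positions)
        self.dim_eps = 2 * self.dim_y if stochastic else 0

    @property
    def _pos(self) -> np.ndarray:
        return np.asarray(self.spec.positions)  # (dim_y, 2)

    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        pos = self._pos
        if self.dim_eps and eps is not None:
            e = eps.reshape(eps.shape[0], self.dim_y, 2)
        else:
            e = np.zeros((x.shape[0], self.dim_y, 2))
        # y[n, k] = y0 + sum_j x[n, j] * (pos[k, j] + e[n, k, j])
        return self.spec.y0 + np.einsum("nj,nkj->nk", x, pos[None, :, :] + e)

    def jac_x(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        pos = self._pos
        if self.dim_eps and eps is not None:
            e = np.asarray(eps, dtype=float).reshape(n, self.dim_y, 2)
        else:
            e = np.zeros((n, self.dim_y, 2))
        return np.broadcast_to(pos[None, :, :], (n, self.dim_y, 2)) + e

    def jac_eps(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        if not self.dim_eps:
            raise NotImplementedError("deterministic tiltmeter has no noise input")
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        jac = np.zeros((n, self.dim_y, self.dim_eps))
        for k in range(self.dim_y):
            jac[:, k, 2 * k] = x[:, 0]
            jac[:, k, 2 * k + 1] = x[:, 1]
        return jac


# ---------------------------------------------------------------------------
# Rosenbrock benchmark (standard 2-D form)
# ---------------------------------------------------------------------------

class Rosenbrock(ForwardModel):
    """Standard 2-D Rosenbrock valley ``y = (a - x1)^2 + b*(x2 - x1^2)^2``."""

    dim_x = 2
    dim_y = 1
    dim_eps = 0
    differentiable = True

    def __init__(self, a: float = 1.0, b: float = 100.0):
        super().__init__()
        self.a = float(a)
        self.b = float(b)

    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        x1, x2 = x[:, 0], x[:, 1]
        y = (self.a - x1) ** 2 + self.b * (x2 - x1**2) ** 2
        return y[:, None]

    def jac_x(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x1, x2 = x[:, 0], x[:, 1]
        d1 = -2.0 * (self.a - x1) - 4.0 * self.b * x1 * (x2 - x1**2)
        d2 = 2.0 * self.b * (x2 - x1**2)
        return np.stack([d1, d2], axis=-1)[:, None, :]


# ---------------------------------------------------------------------------
# Average-pooling (super-resolution) model
# ---------------------------------------------------------------------------

def eval_avg_pool(image: np.ndarray, window: int = 7) -> np.ndarray:
    """Average pooling with stride 1 and no padding.

    Every output cell is the mean over the ``window x window`` input patch
    anchored at that cell, so an H x W image maps to
    (H - window + 1) x (W - window + 1).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    h, w = image.shape
    if h < window or w < window:
        raise ValueError(
            f"image of shape {image.shape} is smaller than the "
            f"{window}x{window} pooling window"
        )
    patches = np.lib.stride_tricks.sliding_window_view(image, (window, window))
    return patches.mean(axis=(-2, -1))


class AvgPool(ForwardModel):
    """Average pooling as a forward model on flattened images."""

    dim_eps = 0
    differentiable = True

    def __init__(self, height: int = 28, width: int = 28, window: int = 7):
        super().__init__()
        if height < window or width < window:
            raise ValueError("image smaller than pooling window")
        self.height, self.width, self.window = height, width, window
        self.out_h = height - window + 1
        self.out_w = width - window + 1
        self.dim_x = height * width
        self.dim_y = self.out_h * self.out_w

    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        imgs = x.reshape(-1, self.height, self.width)
        out = np.stack([eval_avg_pool(im, self.window) for im in imgs])
        return out.reshape(len(imgs), self.dim_y)


# ---------------------------------------------------------------------------
# Differentiable surrogate
# ---------------------------------------------------------------------------

class SurrogateModel(ForwardModel):
    """Differentiable feed-forward surrogate of another forward model.

    Evaluations of the surrogate increment its own counter, not the
    mechanistic model's budget; the training draws already did that.
    """

    differentiable = True

    def __init__(self, net, x_mu, x_sd, y_mu, y_sd, dim_x, dim_y,
                 diagnostics=None):
        super().__init__()
        self.net = net
        self.x_mu, self.x_sd = x_mu, x_sd
        self.y_mu, self.y_sd = y_mu, y_sd
        self.dim_x, self.dim_y = dim_x, dim_y
        self.dim_eps = 0
        self.diagnostics = diagnostics or {}

    def _evaluate(self, x: np.ndarray, eps: np.ndarray | None) -> np.ndarray:
        out = self.net((x - self.x_mu) / self.x_sd)
        return self.y_mu + self.y_sd * out

    def jac_x(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        self.net((x - self.x_mu) / self.x_sd)
        jac = np.empty((n, self.dim_y, self.dim_x))
        for i in range(self.dim_y):
            onehot = np.zeros((n, self.dim_y))
            onehot[:, i] = self.y_sd[i] if np.ndim(self.y_sd) else self.y_sd
            jac[:, i, :] = self.net.backward(onehot) / self.x_sd
        return jac


def fit_surrogate(
    model: ForwardModel,
    prior,
    n_train: int = 2000,
    hidden: tuple = (64, 64, 64),
    n_epochs: int = 200,
    batch: int = 128,
    lr: float = 1e-3,
    holdout_frac: float = 0.2,
    min_train: int = 100,
    seed=None,
) -> SurrogateModel:
    """Train a differentiable fully-connected surrogate of ``model`` on
    prior draws (minimizing mean squared error), for use where the
    mechanistic model itself cannot provide gradients.

    The returned surrogate reports held-out relative RMSE over the prior in
    its ``diagnostics``.
    """
    from .nn import MLP, Adam  # deferred: keeps the model module lightweight

    if n_train < min_train:
        raise ValueError(f"n_train must be at least {min_train}")
    rng = np.random.default_rng(
        seed if not isinstance(seed, np.random.Generator) else None
    )
    if isinstance(seed, np.random.Generator):
        rng = seed
    x = prior.sample(n_train, rng)
    y = model.evaluate(x)
    n_hold = max(1, int(holdout_frac * n_train))
    x_tr, y_tr = x[:-n_hold], y[:-n_hold]
    x_te, y_te = x[-n_hold:], y[-n_hold:]

    x_mu, x_sd = x_tr.mean(axis=0), x_tr.std(axis=0) + 1e-12
    y_mu, y_sd = y_tr.mean(axis=0), y_tr.std(axis=0) + 1e-12
    xs, ys = (x_tr - x_mu) / x_sd, (y_tr - y_mu) / y_sd

    net = MLP([model.dim_x, *hidden, model.dim_y], rng, hidden_act="tanh")
    opt = Adam(net.parameters(), lr=lr, beta1=0.9)
    last_finite = None
    for _ in range(n_epochs):
        perm = rng.permutation(len(xs))
        for start in range(0, len(xs), batch):
            idx = perm[start:start + batch]
            pred = net(xs[idx])
            resid = pred - ys[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"surrogate training diverged; last finite loss was "
                    f"{last_finite}"
                )
            last_finite = loss
            net.zero_grad()
            net.backward(2.0 * resid / len(idx))
            opt.step(net.gradients())

    surr = SurrogateModel(
        net, x_mu, x_sd, y_mu, y_sd, model.dim_x, model.dim_y
    )
    pred_te = surr.evaluate(x_te)
    surr._n_simulations = 0  # diagnostics evaluation is not a simulation
    rel_rmse = float(
        np.sqrt(np.mean((pred_te - y_te) ** 2)) / (np.std(y_te) + 1e-12)
    )
    surr.diagnostics = {"heldout_relative_rmse": rel_rmse, "n_train": n_train}
    return surr


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

MODEL_REGISTRY: dict[str, type[ForwardModel]] = {
    "nonlinear_system": NonlinearSystem,
    "tiltmeter": Tiltmeter,
    "rosenbrock": Rosenbrock,
    "avg_pool": AvgPool,
}


def make_model(name: str, **params) -> ForwardModel:
    """Instantiate a registered benchmark model by name."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    if name == "tiltmeter":
        spec_kwargs = {k: params.pop(k) for k in ("y0", "positions") if k in params}
        spec = params.pop("spec", None) or (
            TiltmeterSpec(**spec_kwargs) if spec_kwargs else None
        )
        return cls(spec=spec, **params)
    return cls(**params)
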