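"""Priors, noise models and target-observation distributions.

Houses the parameter prior :math:`p_X`, the embedded-noise prior
:math:`p_E`, and the target observation distribution :math:`Q_Y` for all
benchmark experiments.  Targets are either analytic (a truncated normal with
an exact density) or empirical (a table of observation vectors, whose density
is later estimated with a Gaussian mixture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PriorSpec",
    "NoiseSpec",
    "TargetSpec",
    "sample_prior",
    "prior_logpdf",
    "make_target_nonlinear",
    "make_target_tiltmeter",
    "nonlinear_uniform_prior",
    "nonlinear_beta_prior",
    "tiltmeter_prior",
    "X2_HALF_WIDTH",
    "TILTMETER_TRUE_BOX",
]

# Half-width 4.5 * sqrt(0.1) of the second-parameter prior interval in the
# nonlinear-system benchmark, centred on 1.
X2_HALF_WIDTH = 4.5 * np.sqrt(0.1)

# "True" parameter box used to synthesize tiltmeter observations.
TILTMETER_TRUE_BOX = ((0.85, 1.6), (1.45, 1.85))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class PriorSpec:
    """Sampleable, log-density-evaluable prior over parameter vectors.

    Built through the classmethod constructors :meth:`uniform_box`,
    :meth:`scaled_beta` and :meth:`gaussian`.  Box-supported priors expose
    their bounds through :attr:`box`, which generators use to constrain
    their outputs to the prior support.
    """

    def __init__(self, kind: str, dim: int, frozen: list, box):
        self.kind = kind
        self.dim = dim
        self._dists = frozen  # per-dimension frozen scipy distributions
        self.box = box  # (low, high) arrays or None

    # -- constructors -------------------------------------------------------

    @classmethod
    def uniform_box(cls, low, high) -> "PriorSpec":
        low = np.atleast_1d(np.asarray(low, dtype=float))
        high = np.atleast_1d(np.asarray(high, dtype=float))
        if low.shape != high.shape:
            raise ValueError("low/high bound shapes differ")
        if np.any(low >= high):
            raise ValueError(f"require low < high per dimension, got {low}, {high}")
        dists = [stats.uniform(loc=a, scale=b - a) for a, b in zip(low, high)]
        return cls("uniform-box", len(low), dists, (low, high))

    @classmethod
    def scaled_beta(cls, alpha, beta, low, high) -> "PriorSpec":
        """Four-parameter beta: Beta(alpha, beta) rescaled to [low, high]."""
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        low = np.atleast_1d(np.asarray(low, dtype=float))
        high = np.atleast_1d(np.asarray(high, dtype=float))
        if not (alpha.shape == beta.shape == low.shape == high.shape):
            raise ValueError("parameter shapes differ")
        if np.any(alpha <= 0) or np.any(beta <= 0):
            raise ValueError("beta shape parameters must be positive")
        if np.any(low >= high):
            raise ValueError("require low < high per dimension")
        dists = [
            stats.beta(a, b, loc=lo, scale=hi - lo)
            for a, b, lo, hi in zip(alpha, beta, low, high)
        ]
        return cls("scaled-beta", len(low), dists, (low, high))

    @classmethod
    def gaussian(cls, mean, sd) -> "PriorSpec":
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        sd = np.atleast_1d(np.asarray(sd, dtype=float))
        if mean.shape != sd.shape:
            raise ValueError("mean/sd shapes differ")
        if np.any(sd <= 0):
            raise ValueError("standard deviations must be positive")
        dists = [stats.norm(m, s) for m, s in zip(mean, sd)]
        return cls("gaussian", len(mean), dists, None)

    # -- sampling and density ----------------------------------------------

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = _as_rng(seed)
        return np.column_stack(
            [d.rvs(size=n, random_state=rng) for d in self._dists]
        )

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError(
                f"expected vectors of dimension {self.dim}, got shape {x.shape}"
            )
        lp = np.zeros(x.shape[0])
        for j, d in enumerate(self._dists):
            with np.errstate(divide="ignore"):
                lp += d.logpdf(x[:, j])
        return lp

    def in_support(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.box is None:
            return np.ones(x.shape[0], dtype=bool)
        low, high = self.box
        return np.all((x >= low) & (x <= high), axis=1)


def sample_prior(prior: PriorSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` parameter vectors from the prior; reproducible given seed."""
    return prior.sample(n, seed)


def prior_logpdf(prior: PriorSpec, x: np.ndarray) -> np.ndarray:
    """Prior log-density; -inf outside the declared support."""
    return prior.logpdf(x)


@dataclass
class NoiseSpec:
    """Zero-mean gaussian prior over the simulator's embedded noise."""

    sd: np.ndarray

    def __post_init__(self) -> None:
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if np.any(self.sd <= 0):
            raise ValueError("noise standard deviations must be positive")

    @property
    def dim(self) -> int:
        return len(self.sd)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        return rng.normal(0.0, self.sd, size=(n, self.dim))

    def logpdf(self, eps: np.ndarray) -> np.ndarray:
        eps = np.atleast_2d(np.asarray(eps, dtype=float))
        return stats.norm(0.0, self.sd).logpdf(eps).sum(axis=1)


class TargetSpec:
    """Target observation distribution Q_Y.

    Either analytic — currently a univariate truncated normal, with exact
    pdf/logpdf — or empirical, given as an (n, dim_y) sample table.  Analytic
    targets can also carry a synthetic sample set drawn from the density.
    """

    def __init__(
        self,
        samples: np.ndarray | None = None,
        truncnorm_params: tuple[float, float, tuple[float, float]] | None = None,
    ):
        if samples is None and truncnorm_params is None:
            raise ValueError("target needs samples and/or an analytic density")
        self._tn = None
        self.interval = None
        if truncnorm_params is not None:
            mean, sd, (lo, hi) = truncnorm_params
            a, b = (lo - mean) / sd, (hi - mean) / sd
            self._tn = stats.truncnorm(a, b, loc=mean, scale=sd)
            self.mean, self.sd, self.interval = mean, sd, (lo, hi)
        if samples is not None:
            samples = np.atleast_2d(np.asarray(samples, dtype=float))
            if samples.ndim != 2:
                raise ValueError("sample table must be 2-D")
            if not np.all(np.isfinite(samples)):
                raise ValueError("target samples must all be finite")
        self.samples = samples

    @property
    def evaluable(self) -> bool:
        """True when an exact density is available (analytic form)."""
        return self._tn is not None

    @property
    def dim_y(self) -> int:
        if self.samples is not None:
            return self.samples.shape[1]
        return 1

    def logpdf(self, y: np.ndarray) -> np.ndarray:
        if self._tn is None:
            raise ValueError(
                "empirical target has no exact density; fit one with "
                "density_tools.fit_density"
            )
        y = np.asarray(y, dtype=float)
        if y.ndim == 2:
            y = y[:, 0]
        with np.errstate(divide="ignore"):
            return self._tn.logpdf(y)

    def pdf(self, y: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(y))

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Fresh draws: exact inverse-CDF draws for analytic targets,
        bootstrap rows for empirical ones."""
        rng = _as_rng(seed)
        if self._tn is not None:
            return self._tn.rvs(size=n, random_state=rng)[:, None]
        idx = rng.integers(0, len(self.samples), size=n)
        return self.samples[idx]


# ---------------------------------------------------------------------------
# Benchmark priors and targets
# ---------------------------------------------------------------------------

def nonlinear_uniform_prior() -> PriorSpec:
    """Uniform prior of the nonlinear-system benchmark:
    x1 ~ U(0.79, 0.99), x2 ~ U(1 - 4.5*sqrt(0.1), 1 + 4.5*sqrt(0.1))."""
    return PriorSpec.uniform_box(
        low=[0.79, 1.0 - X2_HALF_WIDTH], high=[0.99, 1.0 + X2_HALF_WIDTH]
    )


def nonlinear_beta_prior() -> PriorSpec:
    """Beta(2, 5) priors rescaled to the same intervals as the uniform case."""
    return PriorSpec.scaled_beta(
        alpha=[2.0, 2.0],
        beta=[5.0, 5.0],
        low=[0.79, 1.0 - X2_HALF_WIDTH],
        high=[0.99, 1.0 + X2_HALF_WIDTH],
    )


def tiltmeter_prior() -> PriorSpec:
    """Uniform prior over the plate slopes: x1, x2 ~ U(0, 2)."""
    return PriorSpec.uniform_box(low=[0.0, 0.0], high=[2.0, 2.0])


def make_target_nonlinear(n: int, seed=None) -> TargetSpec:
    """Target for the nonlinear-system benchmark: N(0.3, 0.025^2) truncated
    to (0, 0.6), returned with ``n`` exact inverse-CDF draws attached."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = TargetSpec(truncnorm_params=(0.3, 0.025, (0.0, 0.6)))
    spec_samples = spec.sample(n, seed)
    return TargetSpec(samples=spec_samples, truncnorm_params=(0.3, 0.025, (0.0, 0.6)))


def make_target_tiltmeter(stochastic: bool, n: int, seed=None) -> TargetSpec:
    """Empirical tiltmeter target: heights (y_A, y_B) simulated from the
    "true" slope box (U(0.85, 1.6), U(1.45, 1.85)); when ``stochastic``,
    measurement locations are perturbed with N(0, 0.075^2) noise."""
    from .models import Tiltmeter  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    (a1, b1), (a2, b2) = TILTMETER_TRUE_BOX
    x = np.column_stack(
        [rng.uniform(a1, b1, size=n), rng.uniform(a2, b2, size=n)]
    )
    model = Tiltmeter(stochastic=stochastic)
    if stochastic:
        eps = rng.normal(0.0, 0.075, size=(n, model.dim_eps))
        y = model.evaluate(x, eps)
    else:
        y = model.evaluate(x)
    return TargetSpec(samples=y)
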