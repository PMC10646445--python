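"""Rejection-sampling solvers for stochastic inverse problems.

``solve_algorithm1`` is classic data-consistent rejection: push a prior pool
through the model, estimate the push-forward density, accept each sample with
probability proportional to the ratio ``q_Y(y) / p_Y(y)``, normalized by the
observed ratio bound.  ``solve_algorithm2`` replaces the bound with an
algorithm parameter ``B`` and performs the rejection over several iterations,
refitting the push-forward density on the survivors each time so the ratio
(and hence the rejection pressure) shrinks as the surviving push-forward
approaches the target.  With one iteration and ``B`` set to the maximum
observed ratio, the iterative scheme reduces exactly to the classic one.

``solve_mcmc_boosted`` first samples a proposal pool from the density
proportional to ``q_Y(M(x)) p_X(x)`` with random-walk Metropolis — a member
of the equivalence class of proposals that share the prior's within-fiber
ratios, usually much closer to the solution — then applies the same
iterative rejection to correct the pool to the data-consistent solution.

Stochastic models are handled by treating (x, eps) jointly, drawing eps once
per pool entry from its prior, and dropping eps from the returned solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .density import estimate_jsd, fit_density, target_log_density
from .distributions import NoiseSpec, PriorSpec, TargetSpec, _as_rng
from .models import ForwardModel

__all__ = [
    "RejectionConfig",
    "MCMCConfig",
    "SIPSolution",
    "RejectionError",
    "solve_algorithm1",
    "solve_algorithm2",
    "mh_sample",
    "solve_mcmc_boosted",
]


class RejectionError(RuntimeError):
    """Raised when the surviving pool collapses below the configured minimum."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class RejectionConfig:
    """Settings for iterative rejection.

    ``B`` is the acceptance-scale constant; the string ``"max"`` uses the
    maximum observed density ratio (the classic bounding constant).  With
    ``n_iterations=1`` and ``B="max"`` the iteration is the classic
    algorithm.
    """

    B: float | str = 1.0
    n_iterations: int = 10
    n_initial: int = 50000
    min_survivors: int = 50
    n_components: int | str = "auto"
    max_components: int = 20
    floor_frac: float = 1e-3
    track_jsd: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B != "max" and float(self.B) <= 0:
            raise ValueError("B must be positive or 'max'")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings for the boosted proposal stage."""

    n_chains: int = 32
    step_scale: float | None = None  # default: 10% of prior scale per dim
    burn_frac: float = 0.25
    adapt: bool = True


@dataclass
class SIPSolution:
    """Accepted parameter samples, their push-forward, and diagnostics."""

    x: np.ndarray
    y: np.ndarray
    eps: np.ndarray | None = None
    accepted_indices: np.ndarray | None = None
    iteration_counts: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    n_simulations: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.x)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dx, dy = self.x.shape[1], self.y.shape[1]
        pd.DataFrame(self.x, columns=[f"x{i+1}" for i in range(dx)]).to_csv(
            outdir / "parameters.csv", index=False
        )
        pd.DataFrame(self.y, columns=[f"y{i+1}" for i in range(dy)]).to_csv(
            outdir / "pushforward.csv", index=False
        )
        diag = {
            "iteration_counts": [int(c) for c in self.iteration_counts],
            "seed": self.seed,
            "n_simulations": int(self.n_simulations),
            **_jsonable(self.diagnostics),
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return obj


def _build_pool(model, prior, noise, n, rng):
    x = prior.sample(n, rng)
    eps = noise.sample(n, rng) if noise is not None else None
    y = model.evaluate(x, eps)
    return x, eps, y


def _iterate(y_pool, log_q, cfg: RejectionConfig, rng, target_samples=None):
    """Shared rejection kernel: returns surviving indices into the pool."""
    alive = np.arange(len(y_pool))
    counts = [len(alive)]
    jsd_history = []
    for t in range(cfg.n_iterations):
        dens = fit_density(
            y_pool[alive],
            n_components=cfg.n_components,
            max_components=cfg.max_components,
            seed=rng,
        )
        p_hat = np.exp(dens.logpdf(y_pool[alive]))
        floor = cfg.floor_frac * float(np.median(p_hat))
        n_capped = int(np.sum(p_hat < floor))
        p_hat = np.maximum(p_hat, floor)
        r = np.exp(log_q(y_pool[alive])) / p_hat
        if cfg.B == "max":
            prob = r / r.max() if r.max() > 0 else np.zeros_like(r)
        else:
            prob = np.minimum(1.0, r / float(cfg.B))
        keep = rng.random(len(alive)) < prob
        alive = alive[keep]
        counts.append(len(alive))
        if len(alive) == 0:
            raise RejectionError(
                f"zero survivors at iteration {t + 1}; increase the pool size "
                "or use the iterative algorithm with smaller B",
                iteration=t + 1,
            )
        if len(alive) < cfg.min_survivors:
            raise RejectionError(
                f"only {len(alive)} survivors after iteration {t + 1} "
                f"(minimum {cfg.min_survivors}); increase n_initial or "
                "n_iterations",
                iteration=t + 1,
            )
        if cfg.track_jsd and target_samples is not None:
            jsd_history.append(
                estimate_jsd(target_samples, y_pool[alive], seed=rng).value
            )
        if n_capped:
            warnings.warn(
                f"iteration {t + 1}: density floor engaged on {n_capped} "
                "samples", RuntimeWarning,
            )
    return alive, counts, jsd_history


def _finalize(model, prior, x_pool, eps_pool, y_pool, alive, counts, jsd_hist,
              cfg, sims_before):
    return SIPSolution(
        x=x_pool[alive],
        y=y_pool[alive],
        eps=None if eps_pool is None else eps_pool[alive],
        accepted_indices=alive,
        iteration_counts=counts,
        diagnostics={
            "jsd_history": jsd_hist,
            "acceptance_rate": len(alive) / len(x_pool),
        },
        seed=cfg.seed,
        n_simulations=model.n_simulations - sims_before,
    )


def solve_algorithm2(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    cfg: RejectionConfig,
    noise: NoiseSpec | None = None,
) -> SIPSolution:
    """Iterative rejection: N_I rounds of (refit push-forward density on the
    survivors, retain each sample with probability min(1, ratio / B))."""
    rng = _as_rng(cfg.seed)
    sims0 = model.n_simulations
    x, eps, y = _build_pool(model, prior, noise, cfg.n_initial, rng)
    log_q = target_log_density(target, seed=rng)
    alive, counts, jsd_hist = _iterate(
        y, log_q, cfg, rng, target_samples=target.samples
    )
    return _finalize(model, prior, x, eps, y, alive, counts, jsd_hist, cfg, sims0)


def solve_algorithm1(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    n_initial: int,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    **kwargs,
) -> SIPSolution:
    """Classic rejection: single round, acceptance probability
    ``ratio / max(ratio)``.  Implemented as the one-iteration special case of
    the iterative kernel, so the two algorithms share one acceptance law."""
    cfg = RejectionConfig(
        B="max", n_iterations=1, n_initial=n_initial, seed=seed, **kwargs
    )
    return solve_algorithm2(model, prior, target, cfg, noise=noise)


# ---------------------------------------------------------------------------
# MCMC boosting
# ---------------------------------------------------------------------------

def mh_sample(
    log_density,
    n_chains: int,
    n_steps: int,
    step_scale,
    seed=None,
    x0: np.ndarray | None = None,
    burn_frac: float = 0.25,
    adapt: bool = True,
):
    """Random-walk Metropolis with gaussian proposals, vectorized over chains.

    ``log_density`` maps an (n_chains, d) batch to log densities (``-inf``
    allowed outside support).  The step scale is adapted toward a 20-40%
    acceptance rate during burn-in, then frozen.  Returns post-burn-in draws
    stacked over chains and the post-burn-in acceptance rate.
    """
    rng = _as_rng(seed)
    if x0 is None:
        raise ValueError("provide initial chain states x0 of shape (n_chains, d)")
    cur = np.array(x0, dtype=float)
    if cur.ndim == 1:
        cur = cur[None, :]
    d = cur.shape[1]
    step = np.broadcast_to(np.asarray(step_scale, dtype=float), (d,)).copy()
    cur_lp = np.asarray(log_density(cur), dtype=float)
    if not np.any(np.isfinite(cur_lp)):
        raise ValueError("log-density is -inf at every initial chain state")
    burn = int(burn_frac * n_steps)
    draws, acc_post, n_post = [], 0, 0
    acc_window = 0
    for t in range(n_steps):
        prop = cur + step * rng.normal(size=cur.shape)
        prop_lp = np.asarray(log_density(prop), dtype=float)
        accept = np.log(rng.random(len(cur))) < prop_lp - cur_lp
        cur[accept] = prop[accept]
        cur_lp[accept] = prop_lp[accept]
        acc_window += accept.mean()
        if t < burn:
            if adapt and (t + 1) % 25 == 0:
                rate = acc_window / 25
                step *= np.exp(0.7 * (rate - 0.3))
                acc_window = 0
        else:
            draws.append(cur.copy())
            acc_post += accept.sum()
            n_post += len(cur)
    rate = acc_post / max(n_post, 1)
    if rate < 0.01:
        warnings.warn(
            f"MCMC acceptance rate {rate:.3%} is below 1%; check step scale "
            "and support", RuntimeWarning,
        )
    return np.concatenate(draws, axis=0), float(rate)


def solve_mcmc_boosted(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    cfg: RejectionConfig,
    noise: NoiseSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> SIPSolution:
    """Rejection boosted with an MCMC proposal stage.

    Random-walk Metropolis targets ``q_Y(M(x)) p_X(x)`` (jointly with the
    noise prior for stochastic models), concentrating the proposal pool near
    the solution; the iterative rejection kernel then corrects the pool to
    the data-consistent distribution.  ``cfg.n_initial`` is interpreted as
    the total simulation budget for the MCMC stage.
    """
    mcmc = mcmc or MCMCConfig()
    rng = _as_rng(cfg.seed)
    sims0 = model.n_simulations
    log_q = target_log_density(target, seed=rng)

    n_chains = mcmc.n_chains
    if prior.box is not None:
        low, high = prior.box
        base_step = 0.1 * (high - low)
    else:
        base_step = np.ones(prior.dim)
    if noise is not None:
        step = np.concatenate([base_step, 0.5 * noise.sd])
    else:
        step = base_step
    if mcmc.step_scale is not None:
        step = np.broadcast_to(
            np.asarray(mcmc.step_scale, dtype=float), step.shape
        ).copy()
    else:
        step = step.copy()

    # chain state: x (and eps for stochastic models); y cached per state
    cur_x = prior.sample(n_chains, rng)
    cur_e = noise.sample(n_chains, rng) if noise is not None else None
    cur_y = model.evaluate(cur_x, cur_e)
    cur_lp = log_q(cur_y) + prior.logpdf(cur_x)
    if noise is not None:
        cur_lp = cur_lp + noise.logpdf(cur_e)

    n_steps = max(cfg.n_initial // n_chains - 1, 10)
    burn = int(mcmc.burn_frac * n_steps)
    d_x = model.dim_x
    pool_x, pool_e, pool_y = [], [], []
    acc_post = n_post = 0
    acc_window = 0.0
    for t in range(n_steps):
        prop_x = cur_x + step[:d_x] * rng.normal(size=cur_x.shape)
        prop_e = (
            cur_e + step[d_x:] * rng.normal(size=cur_e.shape)
            if noise is not None
            else None
        )
        ok = prior.in_support(prop_x)
        prop_y = np.full_like(cur_y, np.nan)
        if np.any(ok):
            prop_y[ok] = model.evaluate(
                prop_x[ok], None if prop_e is None else prop_e[ok]
            )
        prop_lp = np.full(n_chains, -np.inf)
        if np.any(ok):
            prop_lp[ok] = log_q(prop_y[ok]) + prior.logpdf(prop_x[ok])
            if noise is not None:
                prop_lp[ok] += noise.logpdf(prop_e[ok])
        accept = np.log(rng.random(n_chains)) < prop_lp - cur_lp
        cur_x[accept] = prop_x[accept]
        cur_y[accept] = prop_y[accept]
        cur_lp[accept] = prop_lp[accept]
        if noise is not None:
            cur_e[accept] = prop_e[accept]
        acc_window += accept.mean()
        if t < burn:
            if mcmc.adapt and (t + 1) % 25 == 0:
                step *= np.exp(0.7 * (acc_window / 25 - 0.3))
                acc_window = 0.0
        else:
            pool_x.append(cur_x.copy())
            pool_y.append(cur_y.copy())
            if noise is not None:
                pool_e.append(cur_e.copy())
            acc_post += accept.sum()
            n_post += n_chains

    x = np.concatenate(pool_x)
    y = np.concatenate(pool_y)
    eps = np.concatenate(pool_e) if noise is not None else None
    rate = acc_post / max(n_post, 1)
    if rate < 0.01:
        warnings.warn(
            f"MCMC acceptance rate {rate:.3%} is below 1%", RuntimeWarning
        )

    alive, counts, jsd_hist = _iterate(
        y, log_q, cfg, rng, target_samples=target.samples
    )
    sol = _finalize(model, prior, x, eps, y, alive, counts, jsd_hist, cfg, sims0)
    sol.diagnostics["mcmc_acceptance_rate"] = rate
    return sol
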