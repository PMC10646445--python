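"""Regularized GAN (r-GAN): constrained-optimization solver for stochastic
inverse problems.

The inverse problem is posed as

    minimize   D_f(Q_Xg || P_X)
    subject to supp(X_g) in supp(X),   D_f(Q_Yg || Q_Y) = 0,

with x_g = G(z) a neural sampler and y_g = M(x_g) its push-forward.  The
constrained problem is solved with the penalty method: the generator loss is
a weighted sum of the losses induced by two discriminators,

    L_G = w_Y * L_DY + w_X * L_DX,

where D_X separates generated parameters from prior draws (the objective)
and D_Y separates generated push-forward observations from target draws (the
constraint).  Training starts from a prior-pretrained generator (w_Y = 0,
pure GAN on prior samples — no simulations needed) and ramps the weights
from (w_X, w_Y) = (1, 0) to (0.1, 1.0).  The support constraint is enforced
exactly for box priors by a bounded output activation rescaled to the box.

Stochastic models add a trainable noise scale: eps_g = sigma * zeta with
zeta standard normal and sigma parameterized on log scale for positivity.
A third discriminator D_N regularizes generated noise toward the assumed
noise prior with weight w_N, while the push-forward constraint lets the data
pull sigma toward the true noise level.

Generator updates require gradients of M, so models must expose analytic
Jacobians (or be replaced by a differentiable surrogate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import estimate_jsd
from .distributions import NoiseSpec, PriorSpec, TargetSpec, _as_rng
from .models import ForwardModel
from .nn import MLP, Adam, d_softplus_neg, sigmoid, softplus
from .rejection import SIPSolution

__all__ = [
    "RGANConfig",
    "NoiseModel",
    "RGANState",
    "pretrain_prior",
    "train_rgan",
    "train_rgan_stochastic",
]


@dataclass
class RGANConfig:
    """r-GAN settings.

    The weight schedule runs from ``w_start`` (prior pretraining continues
    seamlessly: w_Y = 0) to ``w_end`` by linear interpolation over the first
    ``ramp_frac`` of the simulation-consuming steps, then stays fixed.
    """

    latent_dim: int = 5
    g_hidden: tuple = (64, 64)
    d_hidden: tuple = (64, 64)
    batch: int = 32
    pretrain_steps: int = 3000
    pretrain_batch: int = 128  # pretraining costs no simulations
    lr_g: float = 1e-3
    lr_d: float = 2e-3
    spectral_norm: bool = False
    w_start: tuple = (1.0, 0.0)  # (w_X, w_Y)
    w_end: tuple = (0.1, 1.0)
    ramp_frac: float = 0.3
    d_extra_steps: int = 4  # extra D_Y updates per step from the replay buffer
    n_snapshots: int = 8  # post-ramp generator snapshots ensembled at the end
    n_out: int = 10000
    n_stages: int = 4
    track_stage_jsd: bool = False
    constraint_jsd_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_start[1] != 0.0:
            raise ValueError("first schedule stage must have w_Y = 0")
        if not (self.w_end[0] < self.w_end[1]):
            raise ValueError("last schedule stage must have w_X << w_Y")
        if any(w < 0 for w in (*self.w_start, *self.w_end)):
            raise ValueError("schedule weights must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent dimension must be >= 1")


@dataclass
class NoiseModel:
    """Trainable noise scale with its prior and regularization weight.

    ``sigma`` is a single scale shared across noise dimensions (the usual
    case of one instrument noise level), initialized from the noise prior
    and trained on log scale so it stays positive.
    """

    prior: NoiseSpec
    w_N: float = 0.1
    sigma0: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0 is None:
            self.sigma0 = float(np.mean(self.prior.sd))
        if self.sigma0 <= 0:
            raise ValueError("initial sigma must be positive")


@dataclass
class RGANState:
    gnet: MLP
    d_x: MLP
    d_y: MLP | None = None
    d_n: MLP | None = None
    losses: dict = field(default_factory=dict)
    sigma_trajectory: np.ndarray | None = None
    stage_jsd: list = field(default_factory=list)
    schedule: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


class _BoxOut:
    def __init__(self, prior: PriorSpec):
        if prior.box is not None:
            low, high = prior.box
            self.c = 0.5 * (low + high)
            self.h = 0.5 * (high - low)
            self.bounded = True
        else:
            self.c = np.array([d.mean() for d in prior._dists])
            self.h = np.array([d.std() for d in prior._dists])
            self.bounded = False

    def forward(self, u):
        if self.bounded:
            t = np.tanh(u)
            return self.c + self.h * t, t
        return self.c + self.h * u, u

    def to_std(self, x):
        if self.bounded:
            return np.clip((x - self.c) / self.h, -1.0, 1.0)
        return (x - self.c) / self.h

    def grad_u(self, g_x, t):
        # g wrt the *unscaled* x; chain through x = c + h * tanh(u) (or h*u)
        if self.bounded:
            return g_x * self.h * (1.0 - t**2)
        return g_x * self.h

    def grad_u_from_std(self, g_std, t):
        # g wrt the standardized coordinate tanh(u) (or u)
        if self.bounded:
            return g_std * (1.0 - t**2)
        return g_std


def pretrain_prior(
    prior: PriorSpec,
    cfg: RGANConfig,
    rng=None,
    gnet: MLP | None = None,
    d_x: MLP | None = None,
    check_jsd: bool = True,
    jsd_threshold: float = 0.1,
):
    """Train the generator to reproduce the prior (w_Y = 0 stage).

    Pure GAN training of G against the prior discriminator D_X on prior
    draws; no simulator evaluations are involved.  Emits a warning if the
    generated spread collapses below 10% of the prior spread (mode collapse)
    or if the exit prior-vs-generated JSD exceeds ``jsd_threshold``.
    """
    rng = _as_rng(rng if rng is not None else cfg.seed)
    omap = _BoxOut(prior)
    dim_x = prior.dim
    if gnet is None:
        gnet = MLP(
            [cfg.latent_dim, *cfg.g_hidden, dim_x], rng, hidden_act="tanh"
        )
    if d_x is None:
        d_x = MLP(
            [dim_x, *cfg.d_hidden, 1], rng, hidden_act="lrelu",
            spectral_norm=cfg.spectral_norm,
        )
    opt_g = Adam(gnet.parameters(), lr=cfg.lr_g)
    opt_d = Adam(d_x.parameters(), lr=cfg.lr_d)
    B = cfg.pretrain_batch
    hist = {"d_x": [], "g": []}
    for _ in range(cfg.pretrain_steps):
        # discriminator updates, each on fresh prior draws and latents
        for _k in range(max(1, cfg.d_extra_steps // 2)):
            z = rng.normal(size=(B, cfg.latent_dim))
            _, t = omap.forward(gnet(z))
            xs_real = omap.to_std(prior.sample(B, rng))
            d_x.zero_grad()
            l_real = d_x(xs_real)
            d_x.backward((sigmoid(l_real) - 1.0) / B)
            l_fake = d_x(t)
            d_x.backward(sigmoid(l_fake) / B)
            opt_d.step(d_x.gradients())
        hist["d_x"].append(
            float(np.mean(softplus(-l_real)) + np.mean(softplus(l_fake)))
        )

        z = rng.normal(size=(B, cfg.latent_dim))
        _, t = omap.forward(gnet(z))
        d_x.zero_grad()
        l_fake = d_x(t)
        g_std = d_x.backward(d_softplus_neg(l_fake) / B)
        gnet.zero_grad()
        gnet.backward(omap.grad_u_from_std(g_std, t))
        opt_g.step(gnet.gradients())
        hist["g"].append(float(np.mean(softplus(-l_fake))))

    # diagnostics
    n_diag = 4000
    z = rng.normal(size=(n_diag, cfg.latent_dim))
    x_gen, _ = omap.forward(gnet(z))
    x_ref = prior.sample(n_diag, rng)
    spread_ratio = np.median(x_gen.std(axis=0) / (x_ref.std(axis=0) + 1e-12))
    diagnostics = {"spread_ratio": float(spread_ratio)}
    if spread_ratio < 0.1:
        warnings.warn(
            f"possible mode collapse during prior pretraining: generated "
            f"spread is {spread_ratio:.1%} of prior spread", RuntimeWarning,
        )
    if check_jsd:
        jsd = estimate_jsd(x_ref, x_gen, seed=rng)
        diagnostics["prior_jsd"] = jsd.to_dict()
        if jsd.value > jsd_threshold:
            warnings.warn(
                f"prior pretraining exit JSD {jsd.value:.3f} bits exceeds "
                f"threshold {jsd_threshold}", RuntimeWarning,
            )
    state = RGANState(gnet=gnet, d_x=d_x, losses=hist, diagnostics=diagnostics)
    return state


def _schedule_weights(step: int, n_steps: int, cfg: RGANConfig):
    ramp = max(1, int(cfg.ramp_frac * n_steps))
    f = min(1.0, step / ramp)
    wx = cfg.w_start[0] + f * (cfg.w_end[0] - cfg.w_start[0])
    wy = cfg.w_start[1] + f * (cfg.w_end[1] - cfg.w_start[1])
    return wx, wy


def _train_core(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    cfg: RGANConfig,
    budget: int,
    noise_model: NoiseModel | None,
):
    if not model.differentiable:
        raise ValueError(
            "r-GAN needs a differentiable model; train a surrogate first "
            "(models.fit_surrogate)"
        )
    tgt = target.samples
    if tgt is None or len(tgt) == 0:
        raise ValueError("target sample set must be non-empty")
    rng = _as_rng(cfg.seed)
    sims0 = model.n_simulations
    omap = _BoxOut(prior)
    B = cfg.batch
    n_out = min(cfg.n_out, max(budget // 5, 1000))
    n_steps = (budget - n_out) // B
    if n_steps < 10:
        raise ValueError("budget too small for r-GAN training")

    state = pretrain_prior(prior, cfg, rng=rng, check_jsd=False)
    gnet, d_x = state.gnet, state.d_x
    dim_x, dim_y = prior.dim, model.dim_y
    y_mu, y_sd = tgt.mean(axis=0), tgt.std(axis=0) + 1e-12
    d_y = MLP(
        [dim_y, *cfg.d_hidden, 1], rng, hidden_act="lrelu",
        spectral_norm=cfg.spectral_norm,
    )
    opt_g = Adam(gnet.parameters(), lr=cfg.lr_g)
    opt_dx = Adam(d_x.parameters(), lr=cfg.lr_d)
    opt_dy = Adam(d_y.parameters(), lr=cfg.lr_d)

    stochastic = noise_model is not None
    if stochastic:
        if model.dim_eps == 0:
            raise ValueError("noise model supplied for a deterministic model")
        d_n = MLP(
            [model.dim_eps, *cfg.d_hidden, 1], rng, hidden_act="lrelu",
            spectral_norm=cfg.spectral_norm,
        )
        opt_dn = Adam(d_n.parameters(), lr=cfg.lr_d)
        log_sigma = np.array([np.log(noise_model.sigma0)])
        opt_sigma = Adam([log_sigma], lr=cfg.lr_g)
        e_sd = noise_model.prior.sd
        sigma_traj = []
    else:
        d_n = None
        sigma_traj = None

    snapshots: list[dict] = []
    ramp_end = max(1, int(cfg.ramp_frac * n_steps))
    # snapshot only the last stretch, once the penalty weights have settled
    snap_start = max(ramp_end, int(0.6 * n_steps))
    if cfg.n_snapshots > 0:
        snap_every = max(1, (n_steps - snap_start) // cfg.n_snapshots)

    hist = {"d_x": [], "d_y": [], "g": []}
    if stochastic:
        hist["d_n"] = []
    schedule = []
    stage_jsd = []
    buf_y = []  # ring buffer of recent generated push-forwards (free JSD probes)
    stage_marks = {
        int(np.floor((k + 1) * n_steps / cfg.n_stages)) - 1
        for k in range(cfg.n_stages)
    }

    for step in range(n_steps):
        wx, wy = _schedule_weights(step, n_steps, cfg)
        z = rng.normal(size=(B, cfg.latent_dim))
        u = gnet(z)
        x_g, t = omap.forward(u)
        xs_g = t if omap.bounded else omap.to_std(x_g)
        if stochastic:
            sigma = float(np.exp(log_sigma[0]))
            if sigma < 1e-4 * noise_model.sigma0:
                raise RuntimeError(
                    "noise scale collapsed to the numerical floor; trajectory "
                    f"recorded over {len(sigma_traj)} steps"
                )
            zeta = rng.normal(size=(B, model.dim_eps))
            eps_g = sigma * zeta
            y_g = model.evaluate(x_g, eps_g)
        else:
            eps_g = None
            y_g = model.evaluate(x_g)
        ys_g = (y_g - y_mu) / y_sd

        # --- discriminators
        d_x.zero_grad()
        l_real = d_x(omap.to_std(prior.sample(B, rng)))
        d_x.backward((sigmoid(l_real) - 1.0) / B)
        l_fake = d_x(xs_g)
        d_x.backward(sigmoid(l_fake) / B)
        opt_dx.step(d_x.gradients())
        hist["d_x"].append(
            float(np.mean(softplus(-l_real)) + np.mean(softplus(l_fake)))
        )

        d_y.zero_grad()
        y_real = tgt[rng.integers(0, len(tgt), size=B)]
        l_real = d_y((y_real - y_mu) / y_sd)
        d_y.backward((sigmoid(l_real) - 1.0) / B)
        l_fake = d_y(ys_g)
        d_y.backward(sigmoid(l_fake) / B)
        opt_dy.step(d_y.gradients())
        hist["d_y"].append(
            float(np.mean(softplus(-l_real)) + np.mean(softplus(l_fake)))
        )
        # extra D_Y refinement on recently simulated push-forwards (replay;
        # consumes no simulation budget)
        for _ in range(cfg.d_extra_steps if buf_y else 0):
            recent = buf_y[-1] if len(buf_y) < 2 else np.concatenate(buf_y[-8:])
            yb = recent[rng.integers(0, len(recent), size=B)]
            d_y.zero_grad()
            lr_ = d_y((tgt[rng.integers(0, len(tgt), size=B)] - y_mu) / y_sd)
            d_y.backward((sigmoid(lr_) - 1.0) / B)
            lf_ = d_y((yb - y_mu) / y_sd)
            d_y.backward(sigmoid(lf_) / B)
            opt_dy.step(d_y.gradients())

        if stochastic:
            d_n.zero_grad()
            e_real = noise_model.prior.sample(B, rng) / e_sd
            l_real = d_n(e_real)
            d_n.backward((sigmoid(l_real) - 1.0) / B)
            l_fake = d_n(eps_g / e_sd)
            d_n.backward(sigmoid(l_fake) / B)
            opt_dn.step(d_n.gradients())
            hist["d_n"].append(
                float(np.mean(softplus(-l_real)) + np.mean(softplus(l_fake)))
            )

        # --- generator (and sigma): L_G = wY*L_DY + wX*L_DX (+ wN*L_DN)
        d_x.zero_grad()
        lx = d_x(xs_g)
        g_xstd = d_x.backward(wx * d_softplus_neg(lx) / B)

        d_y.zero_grad()
        ly = d_y(ys_g)
        g_ystd = d_y.backward(wy * d_softplus_neg(ly) / B)
        g_y = g_ystd / y_sd
        jac = model.jac_x(x_g, eps_g)
        g_x_from_y = np.einsum("ni,nij->nj", g_y, jac)

        gu = omap.grad_u_from_std(g_xstd, t) + omap.grad_u(g_x_from_y, t)
        gnet.zero_grad()
        gnet.backward(gu)
        opt_g.step(gnet.gradients())
        loss_g = float(
            wy * np.mean(softplus(-ly)) + wx * np.mean(softplus(-lx))
        )
        hist["g"].append(loss_g)
        if not np.isfinite(loss_g):
            raise RuntimeError(f"non-finite generator loss at step {step}")

        if stochastic:
            jac_e = model.jac_eps(x_g, eps_g)
            g_eps = np.einsum("ni,nij->nj", g_y, jac_e)  # wY path, via y
            d_n.zero_grad()
            ln = d_n(eps_g / e_sd)
            g_estd = d_n.backward(
                noise_model.w_N * d_softplus_neg(ln) / B
            )
            g_eps = g_eps + g_estd / e_sd
            g_sigma = float(np.sum(g_eps * zeta))
            opt_sigma.step([np.array([g_sigma * sigma])])  # d/d log sigma
            sigma_traj.append(float(np.exp(log_sigma[0])))

        if (
            cfg.n_snapshots > 0
            and step >= snap_start
            and (step - snap_start) % snap_every == snap_every - 1
        ):
            snapshots.append(gnet.state_dict())
            if len(snapshots) > cfg.n_snapshots:
                snapshots.pop(0)

        schedule.append((wx, wy))
        buf_y.append(y_g)
        if len(buf_y) > 40:
            buf_y.pop(0)
        if cfg.track_stage_jsd and step in stage_marks:
            recent = np.concatenate(buf_y)
            stage_jsd.append(
                {
                    "step": step,
                    "w": (wx, wy),
                    "jsd_y": estimate_jsd(tgt, recent, seed=rng).value,
                }
            )

    # --- final solution samples: ensemble over post-ramp generator
    # snapshots (averages training oscillation without shrinking spread)
    n_final = budget - n_steps * B
    if not snapshots:
        snapshots = [gnet.state_dict()]
    parts = np.array_split(np.arange(n_final), len(snapshots))
    chunks = []
    for state_k, idx in zip(snapshots, parts):
        gnet.load_state_dict(state_k)
        z = rng.normal(size=(len(idx), cfg.latent_dim))
        xk, _ = omap.forward(gnet(z))
        chunks.append(xk)
    x_fin = np.concatenate(chunks)
    if stochastic:
        sigma = float(np.exp(log_sigma[0]))
        eps_fin = sigma * rng.normal(size=(n_final, model.dim_eps))
        y_fin = model.evaluate(x_fin, eps_fin)
    else:
        eps_fin = None
        y_fin = model.evaluate(x_fin)

    jsd_y = estimate_jsd(tgt, y_fin, seed=rng)
    jsd_x = estimate_jsd(prior.sample(min(n_final, 10000), rng), x_fin, seed=rng)
    constraint_met = jsd_y.value < cfg.constraint_jsd_threshold
    if not constraint_met:
        warnings.warn(
            f"push-forward constraint not met: JSD(Q_Y||Q_Yg) = "
            f"{jsd_y.value:.3f} bits", RuntimeWarning,
        )
    state = RGANState(
        gnet=gnet,
        d_x=d_x,
        d_y=d_y,
        d_n=d_n,
        losses=hist,
        sigma_trajectory=np.asarray(sigma_traj) if stochastic else None,
        stage_jsd=stage_jsd,
        schedule=schedule,
        diagnostics={
            "jsd_y": jsd_y.to_dict(),
            "jsd_x": jsd_x.to_dict(),
            "constraint_met": bool(constraint_met),
        },
    )
    sol = SIPSolution(
        x=x_fin,
        y=y_fin,
        eps=eps_fin,
        diagnostics={
            "jsd_y": jsd_y.to_dict(),
            "jsd_x": jsd_x.to_dict(),
            "constraint_met": bool(constraint_met),
            **(
                {"sigma_final": float(np.exp(log_sigma[0]))}
                if stochastic
                else {}
            ),
        },
        seed=cfg.seed,
        n_simulations=model.n_simulations - sims0,
    )
    return state, sol


def train_rgan(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    cfg: RGANConfig,
    budget: int = 50000,
):
    """Penalty-method r-GAN solve for a deterministic differentiable model.

    Returns the trained state and a solution holding ``budget``-accounted
    generated parameters and their push-forward, with JSD diagnostics in
    both parameter and observation space.
    """
    return _train_core(model, prior, target, cfg, budget, noise_model=None)


def train_rgan_stochastic(
    model: ForwardModel,
    prior: PriorSpec,
    noise: NoiseModel,
    target: TargetSpec,
    cfg: RGANConfig,
    budget: int = 50000,
):
    """r-GAN for stochastic models with a trainable noise scale.

    Generated noise is ``sigma * zeta`` with a single trainable scale; the
    noise discriminator D_N keeps generated noise near the assumed prior
    (weight ``noise.w_N``) while the push-forward constraint lets the target
    data move sigma toward the true noise level.  The learned sigma
    trajectory is returned in the state.
    """
    return _train_core(model, prior, target, cfg, budget, noise_model=noise)
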