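"""Conditional-GAN amortized inversion.

A conditional generator ``x = G(y, z)`` is trained adversarially on pairs
``(x_i, y_i)`` with ``x_i`` drawn from the prior and ``y_i = M(x_i)`` (noise
drawn from its prior for stochastic models).  After training, inversion is
amortized: parameter samples for any target observation set are produced by
conditioning on target rows and resampling the latent ``z`` — no further
simulator evaluations.

For deterministic models the conditional distribution of x given y is
degenerate (supported on the fiber of y); the generator represents it
implicitly and no density evaluation is attempted.  Generator outputs pass
through a bounded activation rescaled to the prior box, so generated
parameters respect the prior support by construction for box priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import estimate_jsd
from .distributions import NoiseSpec, PriorSpec, TargetSpec, _as_rng
from .models import ForwardModel
from .nn import MLP, Adam, d_softplus_neg, sigmoid, softplus
from .rejection import SIPSolution

__all__ = [
    "CGANConfig",
    "GeneratorHandle",
    "make_training_pairs",
    "train_cgan",
    "infer_cgan",
    "solve_cgan",
]


@dataclass
class CGANConfig:
    latent_dim: int = 5
    g_hidden: tuple = (128, 128, 128)
    d_hidden: tuple = (128, 128, 128)
    n_steps: int = 10000
    batch: int = 128
    lr_g: float = 1e-3
    lr_d: float = 2e-3
    d_steps: int = 2  # discriminator updates per generator update
    n_snapshots: int = 8  # end-phase generator snapshots ensembled at inference
    spectral_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent dimension must be >= 1")
        if any(s <= 0 for s in (*self.g_hidden, *self.d_hidden, self.batch)):
            raise ValueError("layer and batch sizes must be positive")


class _BoxMap:
    """Map an unconstrained net output u to the prior box via tanh.

    The box-normalized coordinate (x - center)/half = tanh(u) doubles as the
    standardized discriminator input for x.
    """

    def __init__(self, low, high):
        self.c = 0.5 * (np.asarray(low) + np.asarray(high))
        self.h = 0.5 * (np.asarray(high) - np.asarray(low))

    def forward(self, u):
        t = np.tanh(u)
        return self.c + self.h * t, t

    def to_std(self, x):
        return np.clip((x - self.c) / self.h, -1.0, 1.0)

    def backward(self, g_std, t):
        return g_std * (1.0 - t**2)


class _LinearMap:
    """Affine output map for unbounded priors (moment standardization)."""

    def __init__(self, mu, sd):
        self.c = np.asarray(mu, dtype=float)
        self.h = np.asarray(sd, dtype=float)

    def forward(self, u):
        return self.c + self.h * u, u

    def to_std(self, x):
        return (x - self.c) / self.h

    def backward(self, g_std, t):
        return g_std


def _output_map(prior: PriorSpec):
    if prior.box is not None:
        low, high = prior.box
        return _BoxMap(low, high)
    mu = np.array([d.mean() for d in prior._dists])
    sd = np.array([d.std() for d in prior._dists])
    return _LinearMap(mu, sd)


@dataclass
class GeneratorHandle:
    """Trained conditional generator plus the scalers needed to use it."""

    gnet: MLP
    cfg: CGANConfig
    out_c: np.ndarray
    out_h: np.ndarray
    bounded: bool
    y_mu: np.ndarray
    y_sd: np.ndarray
    dim_x: int
    dim_y: int
    loss_history: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)

    def generate(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Generate parameters, ensembling over end-of-training generator
        snapshots when available (rows split across snapshots)."""
        y = np.atleast_2d(y)
        if not self.snapshots:
            return self._generate_one(y, z)
        parts = np.array_split(np.arange(len(y)), len(self.snapshots))
        out = np.empty((len(y), self.dim_x))
        current = self.gnet.state_dict()
        for state, idx in zip(self.snapshots, parts):
            if len(idx) == 0:
                continue
            self.gnet.load_state_dict(state)
            out[idx] = self._generate_one(y[idx], z[idx])
        self.gnet.load_state_dict(current)
        return out

    def _generate_one(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        y_std = (y - self.y_mu) / self.y_sd
        u = self.gnet(np.hstack([y_std, z]))
        if self.bounded:
            return self.out_c + self.out_h * np.tanh(u)
        return self.out_c + self.out_h * u

    def save(self, path) -> None:
        state = self.gnet.state_dict()
        snaps = {
            f"s{k}_{name}": arr
            for k, snap in enumerate(self.snapshots)
            for name, arr in snap.items()
        }
        np.savez(
            path,
            **state,
            **snaps,
            n_snapshots=np.array(len(self.snapshots)),
            out_c=self.out_c,
            out_h=self.out_h,
            bounded=np.array(self.bounded),
            y_mu=self.y_mu,
            y_sd=self.y_sd,
            dims=np.array([self.dim_x, self.dim_y, self.cfg.latent_dim]),
            g_hidden=np.array(self.cfg.g_hidden),
        )

    @classmethod
    def load(cls, path) -> "GeneratorHandle":
        data = np.load(path)
        dim_x, dim_y, latent = (int(v) for v in data["dims"])
        g_hidden = tuple(int(v) for v in data["g_hidden"])
        cfg = CGANConfig(latent_dim=latent, g_hidden=g_hidden)
        gnet = MLP(
            [dim_y + latent, *g_hidden, dim_x],
            np.random.default_rng(0),
            hidden_act="tanh",
        )
        gnet.load_state_dict(
            {
                k: data[k]
                for k in data.files
                if k[0] in "Wb" and k[1:].isdigit()
            }
        )
        n_snaps = int(data["n_snapshots"]) if "n_snapshots" in data.files else 0
        snapshots = [
            {
                k.split("_", 1)[1]: data[k]
                for k in data.files
                if k.startswith(f"s{j}_")
            }
            for j in range(n_snaps)
        ]
        return cls(
            snapshots=snapshots,
            gnet=gnet,
            cfg=cfg,
            out_c=data["out_c"],
            out_h=data["out_h"],
            bounded=bool(data["bounded"]),
            y_mu=data["y_mu"],
            y_sd=data["y_sd"],
            dim_x=dim_x,
            dim_y=dim_y,
        )


def make_training_pairs(
    model: ForwardModel,
    prior: PriorSpec,
    noise: NoiseSpec | None,
    n: int,
    seed=None,
):
    """Simulate aligned training pairs: x ~ prior, y = M(x[, eps])."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    x = prior.sample(n, rng)
    eps = noise.sample(n, rng) if noise is not None else None
    y = model.evaluate(x, eps)
    return x, y


def train_cgan(
    pairs: tuple[np.ndarray, np.ndarray],
    cfg: CGANConfig,
    prior: PriorSpec,
    holdout_frac: float = 0.1,
) -> GeneratorHandle:
    """Adversarial training of the conditional generator.

    The discriminator scores (x, y) pairs; both players use the
    non-saturating cross-entropy loss.  A held-out slice of the pairs gives
    a joint-distribution JSD diagnostic between real and generated pairs.
    """
    X, Y = (np.atleast_2d(np.asarray(a, dtype=float)) for a in pairs)
    if len(X) == 0 or len(X) != len(Y):
        raise ValueError("pairs must be non-empty and row-aligned")
    rng = _as_rng(cfg.seed)
    n_hold = int(holdout_frac * len(X))
    if n_hold >= 200:
        X_hold, Y_hold = X[-n_hold:], Y[-n_hold:]
        X, Y = X[:-n_hold], Y[:-n_hold]
    else:
        X_hold = Y_hold = None

    dim_x, dim_y = X.shape[1], Y.shape[1]
    omap = _output_map(prior)
    y_mu, y_sd = Y.mean(axis=0), Y.std(axis=0) + 1e-12
    Ys = (Y - y_mu) / y_sd
    Xs = omap.to_std(X)

    gnet = MLP(
        [dim_y + cfg.latent_dim, *cfg.g_hidden, dim_x], rng, hidden_act="tanh"
    )
    dnet = MLP(
        [dim_x + dim_y, *cfg.d_hidden, 1], rng, hidden_act="lrelu",
        spectral_norm=cfg.spectral_norm,
    )
    opt_g = Adam(gnet.parameters(), lr=cfg.lr_g)
    opt_d = Adam(dnet.parameters(), lr=cfg.lr_d)
    B = cfg.batch
    hist_d, hist_g = [], []

    snapshots: list[dict] = []
    snap_start = int(0.6 * cfg.n_steps)
    snap_every = max(1, (cfg.n_steps - snap_start) // max(cfg.n_snapshots, 1))

    for step in range(cfg.n_steps):
        # discriminator steps (each on a fresh data batch and fresh latents)
        loss_d = 0.0
        for _ in range(cfg.d_steps):
            idx_k = rng.integers(0, len(X), size=B)
            xs_r_k, ys_k = Xs[idx_k], Ys[idx_k]
            z_k = rng.normal(size=(B, cfg.latent_dim))
            u_k = gnet(np.hstack([ys_k, z_k]))
            xs_f_k = np.tanh(u_k) if isinstance(omap, _BoxMap) else u_k
            dnet.zero_grad()
            l_real = dnet(np.hstack([xs_r_k, ys_k]))
            dnet.backward((sigmoid(l_real) - 1.0) / B)
            l_fake = dnet(np.hstack([xs_f_k, ys_k]))
            dnet.backward(sigmoid(l_fake) / B)
            opt_d.step(dnet.gradients())
            loss_d = float(
                np.mean(softplus(-l_real)) + np.mean(softplus(l_fake))
            )

        # generator step (non-saturating), on its own fresh batch
        idx = rng.integers(0, len(X), size=B)
        ys = Ys[idx]
        z = rng.normal(size=(B, cfg.latent_dim))
        u = gnet(np.hstack([ys, z]))
        if isinstance(omap, _BoxMap):
            t = np.tanh(u)
            xs_fake = t
        else:
            t = u
            xs_fake = u
        dnet.zero_grad()
        l_fake = dnet(np.hstack([xs_fake, ys]))
        g_in = dnet.backward(d_softplus_neg(l_fake) / B)
        g_xstd = g_in[:, :dim_x]
        gu = g_xstd * (1.0 - t**2) if isinstance(omap, _BoxMap) else g_xstd
        gnet.zero_grad()
        gnet.backward(gu)
        opt_g.step(gnet.gradients())
        loss_g = float(np.mean(softplus(-l_fake)))
        if not (np.isfinite(loss_d) and np.isfinite(loss_g)):
            raise RuntimeError(
                f"non-finite GAN loss at step {step}: D={loss_d}, G={loss_g}"
            )
        hist_d.append(loss_d)
        hist_g.append(loss_g)
        if (
            cfg.n_snapshots > 0
            and step >= snap_start
            and (step - snap_start) % snap_every == snap_every - 1
        ):
            snapshots.append(gnet.state_dict())
            if len(snapshots) > cfg.n_snapshots:
                snapshots.pop(0)

    handle = GeneratorHandle(
        gnet=gnet,
        cfg=cfg,
        out_c=omap.c,
        out_h=omap.h,
        bounded=isinstance(omap, _BoxMap),
        y_mu=y_mu,
        y_sd=y_sd,
        dim_x=dim_x,
        dim_y=dim_y,
        loss_history={"d": hist_d, "g": hist_g},
        snapshots=snapshots,
    )
    if X_hold is not None:
        z = rng.normal(size=(len(Y_hold), cfg.latent_dim))
        x_gen = handle.generate(Y_hold, z)
        handle.diagnostics["joint_jsd"] = estimate_jsd(
            np.hstack([X_hold, Y_hold]),
            np.hstack([x_gen, Y_hold]),
            seed=rng,
        ).to_dict()
    return handle


def infer_cgan(
    gen: GeneratorHandle, target_samples: np.ndarray, n_z_per_y: int, seed=None
) -> np.ndarray:
    """Amortized inference: for each target row draw ``n_z_per_y`` latents and
    emit generated parameter vectors (no simulator evaluations)."""
    Y = np.atleast_2d(np.asarray(target_samples, dtype=float))
    if Y.shape[1] != gen.dim_y:
        raise ValueError(
            f"target dimensionality {Y.shape[1]} does not match generator "
            f"conditioning input {gen.dim_y}"
        )
    rng = _as_rng(seed)
    Y_rep = np.repeat(Y, n_z_per_y, axis=0)
    z = rng.normal(size=(len(Y_rep), gen.cfg.latent_dim))
    return gen.generate(Y_rep, z)


def solve_cgan(
    model: ForwardModel,
    prior: PriorSpec,
    target: TargetSpec,
    budget: int,
    cfg: CGANConfig | None = None,
    noise: NoiseSpec | None = None,
    n_out: int = 10000,
) -> tuple[SIPSolution, GeneratorHandle]:
    """End-to-end c-GAN solve: simulate pairs, train, infer on the target
    sample set, and push the inferred parameters forward for diagnostics.

    ``budget - n_out`` simulations go to training pairs; the remaining
    ``n_out`` evaluate the push-forward of the inferred parameters (with
    noise resampled from its prior for stochastic models).
    """
    cfg = cfg or CGANConfig()
    rng = _as_rng(cfg.seed)
    sims0 = model.n_simulations
    n_pairs = budget - n_out
    if n_pairs < 10 * cfg.batch:
        raise ValueError("budget too small for c-GAN training")
    pairs = make_training_pairs(model, prior, noise, n_pairs, rng)
    handle = train_cgan(pairs, cfg, prior)
    tgt = target.samples
    n_z = max(1, int(np.ceil(n_out / len(tgt))))
    x_gen = infer_cgan(handle, tgt, n_z, seed=rng)[:n_out]
    eps = noise.sample(len(x_gen), rng) if noise is not None else None
    y_gen = model.evaluate(x_gen, eps)
    sol = SIPSolution(
        x=x_gen,
        y=y_gen,
        eps=eps,
        diagnostics={"joint_jsd": handle.diagnostics.get("joint_jsd")},
        seed=cfg.seed,
        n_simulations=model.n_simulations - sims0,
    )
    return sol, handle
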