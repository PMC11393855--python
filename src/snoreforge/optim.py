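"""Continuous swarm optimizers: Firefly Algorithm (FA) and Capuchin
Search Algorithm (CSA), used to tune the random hidden layer of a
weighted ELM.

FA moves every firefly toward each brighter one with attractiveness
beta0*exp(-gamma r^2) plus a decaying random step; the brightest firefly
takes only the random step. CSA splits the population into leaders (first
half) and chain-following followers; leaders move by one of five
food-referenced mechanics (jump, leap, walk, swing, climb) selected by a
uniform draw, or are randomly relocated with probability Pr, with a
velocity term v <- rho*v + tau*z1*r1*(pbest - c) + tau*z2*r2*(F - c) and
the decaying modulation tau = 2*exp(-21 (t/T)^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elm import WELMClassifier
from .metrics import uar

__all__ = [
    "FireflyConfig", "CapuchinConfig", "firefly_distance",
    "firefly_attractiveness", "firefly_move", "fa_optimize",
    "csa_tau", "csa_theta", "csa_velocity", "csa_optimize", "optimize_welm",
]


@dataclass
class FireflyConfig:
    pop: int = 20
    beta0: float = 1.0
    gamma: float | None = None  # None -> 1 / mean pairwise init distance^2
    alpha: float = 0.2
    alpha_decay: float = 0.97
    iters: int = 100
    lb: float = -5.12
    ub: float = 5.12
    seed: int = 0


@dataclass
class CapuchinConfig:
    pop: int = 45
    iters: int = 100
    Pbf: float = 0.8
    Pe: float = 0.8
    Pr: float = 0.4
    z1: float = 2.0
    z2: float = 2.0
    rho: float = 0.7
    g: float = 9.81
    lb: float = -5.12
    ub: float = 5.12
    seed: int = 0


# ------------------------------------------------------------------ FA

def firefly_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cartesian (Euclidean) distance between two fireflies."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a - b))


def firefly_attractiveness(r: float, beta0: float, gamma: float) -> float:
    """beta(r) = beta0 * exp(-gamma r^2); beta0 at r = 0, decreasing in r."""
    return float(beta0 * np.exp(-gamma * r * r))


def firefly_move(pos_a: np.ndarray, pos_b: np.ndarray, beta0: float, gamma: float,
                 alpha: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Move firefly a toward the brighter firefly b plus a random step.

    The random term alpha*(rand - 0.5) is scaled by the domain width so
    the step size is invariant to the bounds chosen.
    """
    pos_a = np.asarray(pos_a, dtype=np.float64)
    pos_b = np.asarray(pos_b, dtype=np.float64)
    beta = firefly_attractiveness(firefly_distance(pos_a, pos_b), beta0, gamma)
    rand = rng.random(pos_a.size) - 0.5
    return pos_a + beta * (pos_b - pos_a) + alpha * scale * rand


def fa_optimize(objective, dim: int, cfg: FireflyConfig | None = None
                ) -> tuple[np.ndarray, float, list[float]]:
    """Firefly minimization; returns (best position, best fitness, trace)."""
    cfg = cfg or FireflyConfig()
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.ub - cfg.lb
    pos = rng.uniform(cfg.lb, cfg.ub, size=(cfg.pop, dim))
    fit = np.array([objective(p) for p in pos])

    gamma = cfg.gamma
    if gamma is None:
        diffs = pos[:, None, :] - pos[None, :, :]
        dists = np.sqrt((diffs**2).sum(axis=2))
        mean_d = dists[np.triu_indices(cfg.pop, 1)].mean() if cfg.pop > 1 else 1.0
        gamma = 1.0 / max(mean_d, 1e-12) ** 2

    best_i = int(np.argmin(fit))
    best_pos, best_fit = pos[best_i].copy(), float(fit[best_i])
    trace = [best_fit]
    alpha = cfg.alpha
    for _ in range(cfg.iters):
        for a in range(cfg.pop):
            moved = False
            for b in range(cfg.pop):
                if fit[b] < fit[a]:
                    pos[a] = np.clip(
                        firefly_move(pos[a], pos[b], cfg.beta0, gamma, alpha, scale, rng),
                        cfg.lb, cfg.ub)
                    moved = True
            if not moved:  # brightest firefly: random walk only
                pos[a] = np.clip(pos[a] + alpha * scale * (rng.random(dim) - 0.5),
                                 cfg.lb, cfg.ub)
            fit[a] = objective(pos[a])
            if fit[a] < best_fit:
                best_fit, best_pos = float(fit[a]), pos[a].copy()
        alpha *= cfg.alpha_decay
        trace.append(best_fit)
    return best_pos, best_fit, trace


# ----------------------------------------------------------------- CSA

def csa_tau(t: int, T: int) -> float:
    """Decaying life-parameter tau = 2 * exp(-21 (t/T)^2)."""
    return float(2.0 * np.exp(-21.0 * (t / T) ** 2))


def csa_theta(rng: np.random.Generator) -> float:
    """Jumping angle theta = (3 pi / 2) r, r uniform in [0, 1].

    The 3pi/2 range makes sin(2 theta) cover [-1, 1], so food-referenced
    moves can perturb a coordinate in either direction.
    """
    return 1.5 * np.pi * float(rng.random())


def csa_velocity(v: np.ndarray, pos: np.ndarray, pbest: np.ndarray, food: np.ndarray,
                 cfg: CapuchinConfig, tau: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """v <- rho*v + tau*z1*r1*(pbest - c) + tau*z2*r2*(F - c), r per coordinate."""
    d = v.size
    r1 = rng.random(d)
    r2 = rng.random(d)
    return cfg.rho * v + tau * cfg.z1 * r1 * (pbest - pos) + tau * cfg.z2 * r2 * (food - pos)


def _csa_leader_move(pos, v, v_prev, food, tau, eps, cfg, rng):
    # the jumping angle is drawn per dimension (the position update is
    # written per coordinate k), so food-referenced moves are isotropic
    s2t = np.sin(2.0 * np.array([csa_theta(rng) for _ in range(pos.size)]))
    if eps <= 0.2:  # tree jumping (covers the unassigned [0, 0.1) gap)
        return food + cfg.Pbf * (v**2) * s2t / cfg.g
    if eps <= 0.3:  # leaping on riverbanks
        return food + cfg.Pe * cfg.Pbf * (v**2) * s2t / cfg.g
    if eps < 0.5:  # normal ground walking (covers the [0.3, 0.4) gap)
        return pos + v
    if eps <= 0.75:  # swinging on trees
        return food + tau * cfg.Pbf * s2t
    return food + tau * cfg.Pbf * (v - v_prev)  # climbing


def csa_optimize(objective, dim: int, cfg: CapuchinConfig | None = None
                 ) -> tuple[np.ndarray, float, list[float]]:
    """Capuchin-search minimization; returns (best position, best fitness, trace)."""
    cfg = cfg or CapuchinConfig()
    rng = np.random.default_rng(cfg.seed)
    n_lead = cfg.pop // 2
    pos = rng.uniform(cfg.lb, cfg.ub, size=(cfg.pop, dim))
    vel = np.zeros((cfg.pop, dim))
    vel_prev = np.zeros((cfg.pop, dim))
    fit = np.array([objective(p) for p in pos])
    pbest = pos.copy()
    pbest_fit = fit.copy()
    best_i = int(np.argmin(fit))
    food, food_fit = pos[best_i].copy(), float(fit[best_i])
    trace = [food_fit]

    for t in range(1, cfg.iters + 1):
        tau = csa_tau(t, cfg.iters)
        for i in range(n_lead):
            vel_prev[i] = vel[i]
            vel[i] = csa_velocity(vel[i], pos[i], pbest[i], food, cfg, tau, rng)
            if rng.random() <= cfg.Pr:  # random relocation
                eps = rng.random(dim)
                pos[i] = tau * cfg.lb + eps * (cfg.ub - cfg.lb)
            else:
                eps = float(rng.random())
                pos[i] = _csa_leader_move(pos[i], vel[i], vel_prev[i], food,
                                          tau, eps, cfg, rng)
            pos[i] = np.clip(pos[i], cfg.lb, cfg.ub)
        for i in range(n_lead, cfg.pop):
            pos[i] = np.clip(0.5 * (pos[i - 1] + pos[i]), cfg.lb, cfg.ub)
        for i in range(cfg.pop):
            fit[i] = objective(pos[i])
            if fit[i] < pbest_fit[i]:
                pbest[i], pbest_fit[i] = pos[i].copy(), fit[i]
            if fit[i] < food_fit:
                food, food_fit = pos[i].copy(), float(fit[i])
        trace.append(food_fit)
    return food, food_fit, trace


# ------------------------------------------------- WELM hidden-layer tuning

def optimize_welm(X_train, y_train, X_val, y_val, *, optimizer: str = "fa",
                  n_hidden: int = 50, ridge: float = 0.01, pop: int = 12,
                  iters: int = 12, seed: int = 0) -> WELMClassifier:
    """Tune WELM input weights and biases by FA or CSA on validation UAR.

    The decision vector flattens the D x d input-weight matrix plus the D
    biases, bounded to [-1, 1]; fitness is 1 - UAR on the validation split
    of the WELM solved in closed form with those hidden parameters. The
    returned model is refit on the training split with the best vector.
    Features are expected pre-scaled (the pipeline z-scores per training
    fold before calling this).
    """
    Xt = np.asarray(X_train, dtype=np.float64)
    Xv = np.asarray(X_val, dtype=np.float64)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if not set(np.unique(y_val)) <= set(np.unique(y_train)):
        raise ValueError("validation split contains unseen classes")
    if np.unique(y_val).size < np.unique(y_train).size:
        raise ValueError("validation split is missing a class")
    d = Xt.shape[1]
    dim = n_hidden * d + n_hidden

    def build(vec: np.ndarray) -> WELMClassifier:
        W = vec[: n_hidden * d].reshape(n_hidden, d)
        b = vec[n_hidden * d :]
        model = WELMClassifier(n_hidden=n_hidden, ridge=ridge, random_state=seed)
        model.set_hidden(W, b)
        return model

    def objective(vec: np.ndarray) -> float:
        model = build(vec).fit(Xt, y_train)
        return 1.0 - uar(y_val, model.predict(Xv))

    if optimizer == "fa":
        cfg = FireflyConfig(pop=pop, iters=iters, lb=-1.0, ub=1.0, seed=seed)
        best, _, _ = fa_optimize(objective, dim, cfg)
    elif optimizer == "csa":
        cfg = CapuchinConfig(pop=max(pop, 4), iters=iters, lb=-1.0, ub=1.0, seed=seed)
        best, _, _ = csa_optimize(objective, dim, cfg)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    return build(best).fit(Xt, y_train)
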