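"""Binary wrapper feature selection by three swarm metaheuristics.

All three selectors minimize the same wrapper fitness

    f(p) = alpha * gamma_p + beta * |p| / N

where gamma_p is the balanced error (1 - UAR) of an internal weighted-ELM
classifier under stratified k-fold cross-validation on the masked
features, |p| the number of selected columns and N the total column
count. Defaults alpha = 0.8, beta = 0.01, threshold 0.5.

Golden eagle optimization (GEO) moves continuous agents along an attack
vector toward a remembered prey position plus a random cruise vector
orthogonal to it; positions are discretized by "bit = 1 iff position <=
theta". The salp swarm algorithm (SSA) tracks a food source with one
leader and chain-averaging followers; positions discretize by "bit = 1
iff position > 0.5". The refined SSA adds tent-chaotic-map population
initialization, stepped inertia weights in the follower update, and
simulated-annealing acceptance of food-source replacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .elm import WELMClassifier
from .metrics import uar

__all__ = [
    "FeatureMask", "FitnessConfig", "combine_objectives", "wrapper_fitness", "binarize_geo",
    "binarize_ssa", "repair_mask", "geo_attack_vector", "geo_cruise_vector",
    "geo_coefficients", "geo_step", "ssa_r1", "ssa_leader_update",
    "ssa_follower_update", "tent_map_sequence", "stepped_inertia", "sa_accept",
    "geo_select", "ssa_select", "refined_ssa_select",
    "GEOSelector", "SalpSelector",
]


@dataclass
class FeatureMask:
    """Binary inclusion vector over feature columns with its wrapper fitness."""

    bits: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.sum() < 1:
            raise ValueError("a feature mask must select at least one column")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


@dataclass
class FitnessConfig:
    """Wrapper-fitness settings: objective weights, CV folds and seed."""

    alpha: float = 0.8
    beta: float = 0.01
    wrapper_folds: int = 3
    seed: int = 0
    n_hidden: int = 50
    ridge: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")


def combine_objectives(gamma: float, n_selected: int, n_total: int,
                       alpha: float = 0.8, beta: float = 0.01) -> float:
    """The wrapper objective alpha * gamma + beta * |p| / N."""
    return alpha * gamma + beta * n_selected / n_total


def wrapper_fitness(bits: np.ndarray, X: np.ndarray, y: np.ndarray,
                    cfg: FitnessConfig) -> float:
    """f = alpha * (1 - UAR) + beta * |p|/N for one candidate mask.

    The wrapper classifier is a sigmoid WELM (fixed seed) evaluated by
    pooled stratified k-fold CV predictions; features are z-scored on
    each training fold. Deterministic for a fixed config seed.
    """
    bits = np.asarray(bits).astype(bool)
    if bits.sum() < 1:
        raise ValueError("mask selects no features")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("wrapper fitness undefined on a single-class table")
    Xm = np.asarray(X, dtype=np.float64)[:, bits]
    skf = StratifiedKFold(n_splits=cfg.wrapper_folds, shuffle=True,
                          random_state=cfg.seed)
    pred = np.empty(y.size, dtype=y.dtype)
    for tr, te in skf.split(Xm, y):
        scaler = StandardScaler().fit(Xm[tr])
        clf = WELMClassifier(n_hidden=cfg.n_hidden, ridge=cfg.ridge,
                             random_state=cfg.seed)
        clf.fit(scaler.transform(Xm[tr]), y[tr])
        pred[te] = clf.predict(scaler.transform(Xm[te]))
    gamma = 1.0 - uar(y, pred)
    return combine_objectives(gamma, int(bits.sum()), bits.size, cfg.alpha, cfg.beta)


def repair_mask(bits: np.ndarray, position: np.ndarray, threshold: float,
                *, below: bool) -> np.ndarray:
    """Guarantee a non-empty mask by flipping the coordinate nearest its threshold."""
    bits = np.asarray(bits, dtype=np.int8)
    if bits.sum() >= 1:
        return bits
    out = bits.copy()
    out[int(np.argmin(np.abs(np.asarray(position) - threshold)))] = 1
    return out


def binarize_geo(position: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """GEO dialect: bit = 1 iff position <= theta (as printed; non-empty repaired)."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    position = np.asarray(position, dtype=np.float64)
    bits = (position <= theta).astype(np.int8)
    return repair_mask(bits, position, theta, below=True)


def binarize_ssa(position: np.ndarray) -> np.ndarray:
    """SSA dialect: bit = 1 iff position > 0.5 (strict; non-empty repaired)."""
    position = np.asarray(position, dtype=np.float64)
    bits = (position > 0.5).astype(np.int8)
    return repair_mask(bits, position, 0.5, below=False)


# ----------------------------------------------------------------- GEO

def geo_attack_vector(prey_best: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Attack vector V = remembered prey position minus current position."""
    prey_best = np.asarray(prey_best, dtype=np.float64)
    current = np.asarray(current, dtype=np.float64)
    if prey_best.shape != current.shape:
        raise ValueError("dimension mismatch between prey and current position")
    return prey_best - current


def geo_cruise_vector(attack: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random vector in the hyperplane orthogonal to the attack vector.

    One coordinate q (with non-zero attack component) is solved so that
    V . W = 0 exactly; the remaining coordinates are uniform in [-1, 1].
    """
    attack = np.asarray(attack, dtype=np.float64)
    nz = np.flatnonzero(attack)
    if nz.size == 0:
        raise ValueError("cruise vector undefined for a zero attack vector")
    w = 2.0 * rng.random(attack.size) - 1.0
    q = int(rng.choice(nz))
    w[q] = 0.0
    w[q] = -np.dot(attack, w) / attack[q]
    return w


def geo_coefficients(i: int, I: int, cv0: float, cvI: float, cw0: float,
                     cwI: float) -> tuple[float, float]:
    """Linear attack/cruise weight schedules: c(i) = c0 + (i/I)(cI - c0)."""
    frac = i / I if I > 0 else 1.0
    return cv0 + frac * (cvI - cv0), cw0 + frac * (cwI - cw0)


def geo_step(attack: np.ndarray, cruise: np.ndarray | None, cv: float, cw: float,
             rng: np.random.Generator) -> np.ndarray:
    """Step = r1 o (cv V/|V|) + r2 o (cw W/|W|); a zero cruise drops its term."""
    attack = np.asarray(attack, dtype=np.float64)
    step = np.zeros_like(attack)
    na = np.linalg.norm(attack)
    if na > 0:
        step += rng.random(attack.size) * cv * attack / na
    if cruise is not None:
        cruise = np.asarray(cruise, dtype=np.float64)
        nc = np.linalg.norm(cruise)
        if nc > 0:
            step += rng.random(attack.size) * cw * cruise / nc
    return step


@dataclass
class GeoParams:
    pop: int = 15
    iters: int = 200
    theta: float = 0.5
    cv0: float = 0.5
    cvI: float = 2.0
    cw0: float = 1.0
    cwI: float = 0.5


def _multi_run(single_run, seed: int, runs: int) -> tuple[FeatureMask, list[float]]:
    """Independent restarts keeping the best-fitness mask (the multiple-runs
    protocol the swarm-selection literature reports); trace is the winner's."""
    best = None
    for r in range(runs):
        mask, trace = single_run(seed + 104729 * r)  # distinct streams per run
        if best is None or mask.fitness < best[0].fitness:
            best = (mask, trace)
    return best


def geo_select(X: np.ndarray, y: np.ndarray, cfg: FitnessConfig,
               params: GeoParams | None = None, seed: int = 0, runs: int = 1
               ) -> tuple[FeatureMask, list[float]]:
    """Binary golden-eagle wrapper selection.

    Returns the best mask found and the per-iteration best-fitness trace
    (non-increasing by the memory rule). ``runs > 1`` repeats the whole
    search independently and keeps the best-fitness mask.
    """
    params = params or GeoParams()
    if runs > 1:
        return _multi_run(lambda s: geo_select(X, y, cfg, params, s), seed, runs)
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 feature columns")
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = wrapper_fitness(bits, X, y, cfg)
        return cache[key]

    positions = rng.random((params.pop, d))
    memory = positions.copy()
    mem_fit = np.array([evaluate(binarize_geo(p, params.theta)) for p in positions])
    best_idx = int(np.argmin(mem_fit))
    best_bits = binarize_geo(memory[best_idx], params.theta)
    best_fit = float(mem_fit[best_idx])
    trace = [best_fit]

    for i in range(1, params.iters + 1):
        cv, cw = geo_coefficients(i, params.iters, params.cv0, params.cvI,
                                  params.cw0, params.cwI)
        prey = rng.permutation(params.pop)  # one-to-one random prey mapping
        for g in range(params.pop):
            attack = geo_attack_vector(memory[prey[g]], positions[g])
            if not np.any(attack):
                continue
            cruise = geo_cruise_vector(attack, rng) if d > 1 else None
            positions[g] = np.clip(positions[g] + geo_step(attack, cruise, cv, cw, rng),
                                   0.0, 1.0)
            bits = binarize_geo(positions[g], params.theta)
            fit = evaluate(bits)
            if fit < mem_fit[g]:
                memory[g] = positions[g]
                mem_fit[g] = fit
                if fit < best_fit:
                    best_fit, best_bits = fit, bits
        trace.append(best_fit)
    return FeatureMask(bits=best_bits, fitness=best_fit), trace


# ----------------------------------------------------------------- SSA

def ssa_r1(i: int, imax: int) -> float:
    """Adaptive factor r1 = 2 * exp(-(4 i / Imax)^2); 2 at i=0, 2e-16 at i=Imax."""
    return float(2.0 * np.exp(-((4.0 * i / imax) ** 2)))


def ssa_leader_update(food: np.ndarray, r1: float, lb: float, ub: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Leader moves around the food source, clamped to the bounds.

    Per coordinate: food +/- r1*((ub-lb)*r2 + lb), the sign chosen by a
    symmetric branch variable (r3 uniform in [0, 1], branch on r3 >= 0.5).
    """
    d = food.size
    r2 = rng.random(d)
    r3 = rng.random(d)
    offset = r1 * ((ub - lb) * r2 + lb)
    pos = np.where(r3 >= 0.5, food + offset, food - offset)
    return np.clip(pos, lb, ub)


def ssa_follower_update(pos_i: np.ndarray, pos_prev: np.ndarray) -> np.ndarray:
    """Follower moves to the midpoint of itself and its predecessor in the chain."""
    return 0.5 * (np.asarray(pos_i, dtype=np.float64)
                  + np.asarray(pos_prev, dtype=np.float64))


def tent_map_sequence(seed_value: float, n: int) -> np.ndarray:
    """n iterates of the Bernoulli-shift form of the tent map, d <- 2d mod 1.

    Degenerate seeds (0, 0.5, 1, or any dyadic rational which collapses to
    0) are perturbed by 1e-6 with a warning.
    """
    d = float(seed_value)
    if d in (0.0, 0.5, 1.0):
        warnings.warn("degenerate tent-map seed perturbed by 1e-6")
        d = d + 1e-6 if d < 1.0 else d - 1e-6
    out = np.empty(n)
    for j in range(n):
        d = (2.0 * d) % 1.0
        if d == 0.0:
            d = 1e-6
        out[j] = d
    return out


def stepped_inertia(t: int, tmax: int, lam: float, wmin: float, wmax: float) -> float:
    """w = wmax while t/tmax <= lambda (inclusive), wmin afterwards."""
    if not 0 <= t <= tmax:
        raise ValueError("t must lie in [0, tmax]")
    return wmax if t / tmax <= lam else wmin


def sa_accept(f_new: float, f_old: float, temperature: float,
              rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept improvement, else prob exp(-df/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if f_new < f_old:
        return True
    return bool(rng.random() < np.exp(-(f_new - f_old) / temperature))


@dataclass
class SsaParams:
    pop: int = 15
    iters: int = 200
    lb: float = 0.0
    ub: float = 1.0
    # refined-variant knobs
    wmin: float = 0.6
    wmax: float = 0.8
    lam: float = 0.2
    cooling: float = 0.95


def _ssa_loop(X, y, cfg, params, seed, *, refined: bool) -> tuple[FeatureMask, list[float]]:
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 feature columns")
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = wrapper_fitness(bits, X, y, cfg)
        return cache[key]

    if refined:
        positions = np.empty((params.pop, d))
        for p in range(params.pop):
            positions[p] = tent_map_sequence(rng.random(), d)
    else:
        positions = rng.uniform(params.lb, params.ub, size=(params.pop, d))

    fits = np.array([evaluate(binarize_ssa(p)) for p in positions])
    order = int(np.argmin(fits))
    food = positions[order].copy()
    food_fit = float(fits[order])
    best_bits = binarize_ssa(food)
    best_fit = food_fit
    trace = [best_fit]

    temperature = max(float(fits.max() - fits.min()), 1e-3)

    for i in range(1, params.iters + 1):
        r1 = ssa_r1(i, params.iters)
        positions[0] = ssa_leader_update(food, r1, params.lb, params.ub, rng)
        for j in range(1, params.pop):
            if refined:
                w = stepped_inertia(i, params.iters, params.lam, params.wmin, params.wmax)
                positions[j] = 0.5 * (positions[j] + w * positions[j - 1])
            else:
                positions[j] = ssa_follower_update(positions[j], positions[j - 1])
            positions[j] = np.clip(positions[j], params.lb, params.ub)
        fits = np.array([evaluate(binarize_ssa(p)) for p in positions])
        cand = int(np.argmin(fits))
        cand_fit = float(fits[cand])
        if refined:
            if sa_accept(cand_fit, food_fit, temperature, rng):
                food, food_fit = positions[cand].copy(), cand_fit
            temperature = max(temperature * params.cooling, 1e-12)
        elif cand_fit < food_fit:
            food, food_fit = positions[cand].copy(), cand_fit
        if cand_fit < best_fit:
            best_fit = cand_fit
            best_bits = binarize_ssa(positions[cand])
        trace.append(best_fit)
    return FeatureMask(bits=best_bits, fitness=best_fit), trace


def ssa_select(X, y, cfg: FitnessConfig, params: SsaParams | None = None,
               seed: int = 0, runs: int = 1) -> tuple[FeatureMask, list[float]]:
    """Plain salp-swarm wrapper selection."""
    params = params or SsaParams()
    if runs > 1:
        return _multi_run(lambda s: _ssa_loop(X, y, cfg, params, s, refined=False),
                          seed, runs)
    return _ssa_loop(X, y, cfg, params, seed, refined=False)


def refined_ssa_select(X, y, cfg: FitnessConfig, params: SsaParams | None = None,
                       seed: int = 0, runs: int = 1) -> tuple[FeatureMask, list[float]]:
    """Refined SSA: tent-map init, stepped inertia followers, SA food acceptance."""
    params = params or SsaParams()
    if runs > 1:
        return _multi_run(lambda s: _ssa_loop(X, y, cfg, params, s, refined=True),
                          seed, runs)
    return _ssa_loop(X, y, cfg, params, seed, refined=True)


# -------------------------------------------------- sklearn-style wrappers

class _SwarmSelectorBase(SelectorMixin, BaseEstimator):
    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def _run(self, X, y):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        mask, trace = self._run(X, np.asarray(y))
        self.mask_ = mask
        self.support_ = mask.bits.astype(bool)
        self.fitness_ = mask.fitness
        self.trace_ = trace
        return self


class GEOSelector(_SwarmSelectorBase):
    """Binary golden-eagle-optimization feature selector (sklearn transformer)."""

    def __init__(self, alpha: float = 0.8, beta: float = 0.01, pop: int = 15,
                 iters: int = 200, theta: float = 0.5, wrapper_folds: int = 3,
                 runs: int = 1, random_state: int = 0):
        self.alpha = alpha
        self.beta = beta
        self.pop = pop
        self.iters = iters
        self.theta = theta
        self.wrapper_folds = wrapper_folds
        self.runs = runs
        self.random_state = random_state

    def _run(self, X, y):
        cfg = FitnessConfig(alpha=self.alpha, beta=self.beta,
                            wrapper_folds=self.wrapper_folds, seed=self.random_state)
        params = GeoParams(pop=self.pop, iters=self.iters, theta=self.theta)
        return geo_select(X, y, cfg, params, seed=self.random_state, runs=self.runs)


class SalpSelector(_SwarmSelectorBase):
    """Salp-swarm feature selector; ``refined=True`` enables the tent-map /
    stepped-inertia / simulated-annealing variant."""

    def __init__(self, alpha: float = 0.8, beta: float = 0.01, pop: int = 15,
                 iters: int = 200, refined: bool = False, wmin: float = 0.6,
                 wmax: float = 0.8, lam: float = 0.2, wrapper_folds: int = 3,
                 runs: int = 1, random_state: int = 0):
        self.alpha = alpha
        self.beta = beta
        self.pop = pop
        self.iters = iters
        self.refined = refined
        self.wmin = wmin
        self.wmax = wmax
        self.lam = lam
        self.wrapper_folds = wrapper_folds
        self.runs = runs
        self.random_state = random_state

    def _run(self, X, y):
        cfg = FitnessConfig(alpha=self.alpha, beta=self.beta,
                            wrapper_folds=self.wrapper_folds, seed=self.random_state)
        params = SsaParams(pop=self.pop, iters=self.iters, wmin=self.wmin,
                           wmax=self.wmax, lam=self.lam)
        fn = refined_ssa_select if self.refined else ssa_select
        return fn(X, y, cfg, params, seed=self.random_state, runs=self.runs)
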