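"""Grasshopper Bio-Inspired Swarm Optimization (GBSO) feature selection.

A continuous swarm in [0, 1]^d is binarized (position >= 0.5 selects a
feature) and scored by a wrapper fitness: alpha * cross-validated k-NN
error + (1 - alpha) * fraction of features kept.  The social force
s(r) = f * exp(-r/l) - exp(-r) drives the position update; with the
defaults f = 0.5, l = 1.5 it is repulsive below r* = 3 ln 2 = 2.079 (the
comfort-zone boundary), attractive above, and peaks at 3 ln 3 = 3.296.
The decreasing coefficient G follows a fitness-adaptive schedule:
worse-than-average members decay linearly (exploration), better-than-
average members decay quadratically faster (exploitation).  A random
jump operator occasionally resets a member to a blend of its local best
and the global best.  The swarm's data model retains gravity/advection
fields for completeness, but only the social interaction acts in the
update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .signal_io import LabeledDataset


@dataclass
class Grasshopper:
    """One swarm member: position in [l_b, u_b]^d with elitist local best."""

    position: np.ndarray
    fitness: float = math.inf
    local_best_position: np.ndarray | None = None
    local_best_fitness: float = math.inf
    # Gravity and wind-advection components of the full grasshopper model;
    # documented in the data model but not used in the position update.
    gravity: np.ndarray | None = None
    advection: np.ndarray | None = None


@dataclass
class Swarm:
    members: list[Grasshopper]
    global_best_position: np.ndarray | None = None
    global_best_fitness: float = math.inf
    iteration: int = 0


@dataclass(frozen=True)
class GBSOConfig:
    """Swarm size, schedule, social-force and wrapper-fitness settings."""

    N: int = 30
    it_max: int = 100
    G_max: float = 1.0
    G_min: float = 1e-5
    f: float = 0.5          # attraction intensity
    l: float = 1.5          # attraction length scale
    jump_prob: float = 0.3
    mutation_prob: float = 0.25
    binarize_threshold: float = 0.5
    alpha: float = 0.99     # weight of wrapper error vs subset size
    wrapper_k: int = 5
    cv_folds: int = 5
    seed: int = 0
    l_b: float = 0.0
    u_b: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.G_min < self.G_max:
            raise ValueError("need 0 < G_min < G_max")
        if not 0 < self.f < 1:
            raise ValueError("attraction intensity f must lie in (0, 1)")
        if not self.l > 1:
            raise ValueError("length scale l must exceed 1 (comfort zone needs a root)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.N < 1 or self.it_max < 1:
            raise ValueError("N and it_max must be >= 1")


@dataclass
class SelectionResult:
    """Selected feature mask plus the optimisation trace."""

    mask: np.ndarray
    n_selected: int
    best_fitness: float
    fitness_history: list[float]
    best_position: np.ndarray


def social_force(r: np.ndarray | float, f: float = 0.5, l: float = 1.5):
    """s(r) = f*exp(-r/l) - exp(-r): negative = repulsion, positive = attraction."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be >= 0")
    out = f * np.exp(-r / l) - np.exp(-r)
    return float(out) if out.ndim == 0 else out


def comfort_zone_boundary(f: float = 0.5, l: float = 1.5) -> float:
    """Unique positive root of the social force: r* = l*ln(1/f)/(l-1)."""
    if not (0 < f < 1) or not l > 1:
        raise ValueError("need 0 < f < 1 and l > 1 for a positive root")
    return l * math.log(1.0 / f) / (l - 1.0)


def social_force_peak(f: float = 0.5, l: float = 1.5) -> float:
    """Maximizer of s(r): r = l*ln(l/f)/(l-1) (the band's upper operating end)."""
    if not (0 < f < 1) or not l > 1:
        raise ValueError("need 0 < f < 1 and l > 1")
    return l * math.log(l / f) / (l - 1.0)


def coefficient_schedule(
    it: int, it_max: int, G_max: float, G_min: float,
    fitness_i: float, avg_fitness: float,
) -> float:
    """Fitness-adaptive decreasing coefficient G_i.

    Worse-than-average members (fitness_i >= avg, minimisation) decay
    linearly from G_max to G_min; better members decay along the faster
    quadratic 2t - t^2, reaching the same endpoints.
    """
    if it_max < 1:
        raise ValueError("it_max must be >= 1")
    if not 0 <= it <= it_max:
        raise ValueError(f"iteration {it} outside [0, {it_max}]")
    t = it / it_max
    if fitness_i >= avg_fitness:
        return G_max - (G_max - G_min) * t
    return G_max - (G_max - G_min) * (2.0 * t - t * t)


def binarize_mask(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Feature i is selected iff position_i >= threshold (ties select)."""
    return np.asarray(position) >= threshold


def make_planted_features(
    n: int = 200, d: int = 20, n_informative: int = 4,
    shift: float = 3.0, seed: int = 0,
) -> tuple[LabeledDataset, np.ndarray]:
    """Benchmark dataset with planted informative features.

    Two balanced classes of standard-normal feature vectors; the first
    ``n_informative`` features of the positive class are shifted by
    ``shift`` standard deviations.  The default shift makes single
    features clearly insufficient (Bayes error of a 3-sigma separation)
    while any three together separate the classes essentially perfectly —
    the planted set is then the wrapper fitness's optimum rather than an
    arbitrary label.  Returns the dataset and the boolean planted mask.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    half = n // 2
    y = np.array([0] * half + [1] * (n - half))
    for f in range(n_informative):
        X[y == 1, f] += shift
    planted = np.zeros(d, dtype=bool)
    planted[:n_informative] = True
    ds = LabeledDataset([(X[i], ("neg", "pos")[y[i]]) for i in range(n)])
    return ds, planted


class _WrapperFitness:
    """Memoized k-NN wrapper fitness over a fixed dataset.

    Per-feature squared-difference matrices are precomputed once, so the
    masked pairwise distance matrix for any subset is a single tensor
    contraction; the k-NN vote and balanced accuracy are then evaluated
    fold-by-fold on precomputed stratified splits.
    """

    def __init__(self, dataset: LabeledDataset, cfg: GBSOConfig):
        X = dataset.feature_matrix()
        labels = dataset.labels
        classes = sorted(set(labels))
        y = np.array([classes.index(lab) for lab in labels])
        counts = np.bincount(y)
        if np.min(counts) < cfg.cv_folds:
            raise ValueError(
                f"each class needs >= cv_folds={cfg.cv_folds} instances, "
                f"got counts {dict(zip(classes, counts))}"
            )
        self.n, self.d = X.shape
        self.y = y
        self.n_classes = len(classes)
        self.k = cfg.wrapper_k
        self.alpha = cfg.alpha
        # per-feature squared differences: D2[i, j, f] = (X[i,f]-X[j,f])^2
        diff = X[:, None, :] - X[None, :, :]
        self.D2 = diff * diff
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=cfg.seed % (2**31))
        self.folds = list(skf.split(X, y))
        self._cache: dict[bytes, float] = {}

    def _balanced_accuracy(self, dist: np.ndarray) -> float:
        correct = np.zeros(self.n_classes)
        total = np.zeros(self.n_classes)
        for train_idx, test_idx in self.folds:
            sub = dist[np.ix_(test_idx, train_idx)]
            k = min(self.k, len(train_idx))
            nn = np.argpartition(sub, k - 1, axis=1)[:, :k]
            votes = self.y[train_idx][nn]                      # (n_test, k)
            for row, true in zip(votes, self.y[test_idx]):
                counts = np.bincount(row, minlength=self.n_classes)
                pred = int(np.argmax(counts))                  # ties -> lowest index
                total[true] += 1
                correct[true] += pred == true
        return float(np.mean(correct / np.maximum(total, 1)))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 1.0
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        dist = self.D2[:, :, mask].sum(axis=2)
        err = 1.0 - self._balanced_accuracy(dist)
        fit = self.alpha * err + (1.0 - self.alpha) * (mask.sum() / self.d)
        self._cache[key] = fit
        return fit


def subset_fitness(
    mask: np.ndarray, dataset: LabeledDataset, cfg: GBSOConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Wrapper fitness of one feature subset (lower is better).

    fitness = alpha * (1 - balanced k-NN CV accuracy) + (1-alpha) * |mask|/d;
    an empty mask scores the worst possible value 1.0.
    """
    return _WrapperFitness(dataset, cfg)(np.asarray(mask, dtype=bool))


def update_positions(swarm: Swarm, cfg: GBSOConfig, rng: np.random.Generator,
                     avg_fitness: float | None = None) -> Swarm:
    """One GBSO position update (social interaction + global best + jumps).

    x_j <- G_j * sum_{k != j} G_j * (u_b - l_b)/2 * s(d_hat_jk) *
           (x_k - x_j)/(d_jk + eps)  +  T_hat,
    with d_hat_jk = 2 + (d_jk mod 2) mapping raw distances into the
    responsive [2, 4) band of s.  The social term collapses the swarm
    onto the target within a few iterations (the update's known strong
    exploitation), so exploration rests on the random jump: with
    probability jump_prob a member moves to the blend
    beta * local_best + (1-beta) * T_hat (beta ~ U(0,1)) and each
    coordinate of the blend is then resampled uniformly in the bounds
    with probability mutation_prob, so jumps can cross the binarization
    threshold anywhere in the search space.  Positions are clamped to
    [l_b, u_b] afterwards.
    """
    if swarm.global_best_position is None:
        raise RuntimeError("swarm fitnesses must be evaluated before updating")
    for g in swarm.members:
        if not math.isfinite(g.fitness):
            raise RuntimeError("all member fitnesses must be evaluated first")
    if avg_fitness is None:
        avg_fitness = float(np.mean([g.fitness for g in swarm.members]))
    eps = 1e-10
    half_span = (cfg.u_b - cfg.l_b) / 2.0
    positions = np.array([g.position for g in swarm.members])
    new_positions = np.empty_like(positions)
    for j, g in enumerate(swarm.members):
        G_j = coefficient_schedule(swarm.iteration, cfg.it_max, cfg.G_max,
                                   cfg.G_min, g.fitness, avg_fitness)
        social = np.zeros_like(g.position)
        for k in range(len(swarm.members)):
            if k == j:
                continue
            delta = positions[k] - positions[j]
            d = float(np.linalg.norm(delta))
            d_hat = 2.0 + (d % 2.0)
            social += G_j * half_span * social_force(d_hat, cfg.f, cfg.l) * delta / (d + eps)
        new_positions[j] = G_j * social + swarm.global_best_position
    for j, g in enumerate(swarm.members):
        x = new_positions[j]
        if rng.uniform() < cfg.jump_prob:
            beta = rng.uniform()
            local = g.local_best_position if g.local_best_position is not None else x
            x = beta * local + (1.0 - beta) * swarm.global_best_position
            mutate = rng.uniform(size=x.size) < cfg.mutation_prob
            x = np.where(mutate, rng.uniform(cfg.l_b, cfg.u_b, size=x.size), x)
        g.position = np.clip(x, cfg.l_b, cfg.u_b)
    swarm.iteration += 1
    return swarm


def _polish_mask(mask: np.ndarray, fitness_fn) -> tuple[np.ndarray, float]:
    """Bidirectional single-feature local search around a mask.

    Flips one feature at a time (add or drop), keeping strict fitness
    improvements, until no single flip helps.  The swarm handles global
    exploration; this finishing pass handles the exact pruning the
    continuous update is poor at (memoization makes re-evaluations free).
    """
    mask = mask.copy()
    best = fitness_fn(mask)
    improved = True
    while improved:
        improved = False
        for i in range(mask.size):
            trial = mask.copy()
            trial[i] = ~trial[i]
            if not trial.any():
                continue
            f = fitness_fn(trial)
            if f < best - 1e-12:
                best, mask, improved = f, trial, True
    return mask, best


def gbso_select(dataset: LabeledDataset, cfg: GBSOConfig | None = None) -> SelectionResult:
    """Run the full GBSO loop and return the global best's feature mask.

    After the swarm loop the global best's mask is refined by a
    bidirectional single-feature local search (standard practice in
    wrapper feature selection); its final fitness is appended to the
    history, which therefore stays non-increasing.
    """
    cfg = cfg or GBSOConfig()
    X = dataset.feature_matrix()
    d = X.shape[1]
    if d == 0:
        raise ValueError("dataset has no features to select from")
    if len(set(dataset.labels)) < 2:
        raise ValueError("need at least 2 classes")
    fitness_fn = _WrapperFitness(dataset, cfg)
    rng = np.random.default_rng(cfg.seed)
    swarm = Swarm(members=[
        Grasshopper(position=rng.uniform(cfg.l_b, cfg.u_b, size=d))
        for _ in range(cfg.N)
    ])
    history: list[float] = []
    for it in range(cfg.it_max + 1):
        swarm.iteration = it
        for g in swarm.members:
            mask = binarize_mask(g.position, cfg.binarize_threshold)
            g.fitness = fitness_fn(mask)
            if g.fitness < g.local_best_fitness:
                g.local_best_fitness = g.fitness
                g.local_best_position = g.position.copy()
            if g.fitness < swarm.global_best_fitness:
                swarm.global_best_fitness = g.fitness
                swarm.global_best_position = g.position.copy()
        history.append(swarm.global_best_fitness)
        if it == cfg.it_max:
            break
        avg = float(np.mean([g.fitness for g in swarm.members]))
        update_positions(swarm, cfg, rng, avg_fitness=avg)
    mask = binarize_mask(swarm.global_best_position, cfg.binarize_threshold)
    if not mask.any():  # pathological: best position binarizes empty
        mask = np.zeros(d, dtype=bool)
        mask[int(np.argmax(swarm.global_best_position))] = True
    mask, best_fit = _polish_mask(mask, fitness_fn)
    history.append(min(best_fit, history[-1]))
    return SelectionResult(
        mask=mask, n_selected=int(mask.sum()),
        best_fitness=float(min(best_fit, swarm.global_best_fitness)),
        fitness_history=history,
        best_position=swarm.global_best_position.copy(),
    )
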