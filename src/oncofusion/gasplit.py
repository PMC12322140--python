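"""Genetic-algorithm train/test splitting with a class-balance penalty.

A split is encoded as a binary genome over the eligible (complete-vector)
patients, with 1 marking assignment to the test set and the number of test
bits fixed at ``N = round(test_fraction * n_eligible)``.  Two fitness
functions are maximized:

* *in-distribution*: the sum over test points of the cosine distance to
  their nearest neighboring test point, so selected points sit inside
  dense regions of the cohort (each has a close test neighbor only when
  the test set traces the bulk of the distribution) — minus the penalty;
* *out-of-distribution*: the sum of cosine distances over all pairs of
  test points, driving the test set toward mutually dissimilar outliers —
  minus the same penalty.

The penalty is ``alpha * sum_k |d_k - d_k,all|`` where ``d_k`` is the
positive fraction of target class k in the candidate test set and
``d_k,all`` the overall fraction, keeping both splits class-balanced.
The population evolves by tournament selection with elitism, one-point
crossover and inversion (segment-reversal) mutation; crossover children
are repaired back to exactly N test bits by random bit flips.  Patients
with incomplete vectors never enter the genome and are appended to the
training set.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._utils import child_rng

__all__ = [
    "SplitProblem",
    "GAParams",
    "SplitResult",
    "cosine_distance",
    "balance_penalty",
    "fitness_in",
    "fitness_out",
    "run_ga",
    "exhaustive_split_oracle",
    "problem_from_vectors",
]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − cosine similarity, in [0, 2]; a zero-norm vector is at distance 1
    from everything (documented convention)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("zero-norm vector in cosine distance; returning 1.0")
        return 1.0
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 2.0))


@dataclass
class SplitProblem:
    """GA state: vectors, binary targets, test fraction, penalty weight, mode.

    ``labels`` is an (n, C) array of {0, 1, NaN}; patients with a missing
    label for a class are excluded from that class's penalty term but remain
    splittable.  ``eligible`` marks complete-vector patients (the genome
    domain); ineligible patients are assigned to training.
    """

    X: np.ndarray
    patient_ids: list[str]
    labels: np.ndarray
    test_fraction: float = 0.20
    alpha: float | None = None          # None -> mode-scaled default
    mode: str = "in_distribution"
    eligible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("X must be finite (impute before splitting)")
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels misaligned with X")
        obs = self.labels[~np.isnan(self.labels)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("labels must be binary or NaN")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.mode not in ("in_distribution", "out_of_distribution"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.eligible is None:
            self.eligible = np.ones(self.X.shape[0], dtype=bool)
        self.eligible = np.asarray(self.eligible, dtype=bool)
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())

    @property
    def n_test(self) -> int:
        return int(round(self.test_fraction * self.n_eligible))

    def default_alpha(self) -> float:
        """alpha_in = N, alpha_out = N(N-1)/2: scales the penalty to the
        magnitude of the respective distance sum."""
        n = self.n_test
        return float(n) if self.mode == "in_distribution" else n * (n - 1) / 2.0

    def resolved_alpha(self) -> float:
        return self.default_alpha() if self.alpha is None else float(self.alpha)


@dataclass
class GAParams:
    """Evolutionary-search hyperparameters."""

    population_size: int = 10_000
    stagnation_limit: int = 50
    tournament_size: int = 3
    elite_count: int | None = None       # None -> 1% of population (>= 1)
    crossover_rate: float = 0.9
    mutation_rate: float | None = None   # None -> 1/n per individual
    max_generations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    best_fitness: float
    fitness_trace: list[float]
    mode: str = "in_distribution"
    n_generations: int = 0

    def to_dict(self) -> dict:
        return {"train": self.train_ids, "test": self.test_ids,
                "fitness": self.best_fitness, "mode": self.mode}


def balance_penalty(mask: np.ndarray, labels: np.ndarray, alpha: float) -> float:
    """alpha * sum_k |d_k − d_k,all| over the C target classes.

    Per class, only patients with an observed label enter either fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("test set must be non-empty")
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    total = 0.0
    for k in range(labels.shape[1]):
        lab = labels[:, k]
        obs = ~np.isnan(lab)
        if not obs.any():
            continue
        d_all = lab[obs].mean()
        test_obs = obs & mask
        d_test = lab[test_obs].mean() if test_obs.any() else 0.0
        total += abs(d_test - d_all)
    return float(alpha) * total


class _FitnessEngine:
    """Precomputed cosine-distance machinery over the eligible patients."""

    def __init__(self, problem: SplitProblem):
        self.problem = problem
        Xe = problem.X[problem.eligible]
        norms = np.linalg.norm(Xe, axis=1, keepdims=True)
        zero = norms[:, 0] == 0
        if zero.any():
            warnings.warn("zero-norm patient vectors; cosine distance 1 to everything")
        norms[norms == 0] = 1.0
        Xn = Xe / norms
        D = 1.0 - Xn @ Xn.T
        np.clip(D, 0.0, 2.0, out=D)
        np.fill_diagonal(D, 0.0)
        self.D = D
        self.n = Xe.shape[0]
        lab = problem.labels[problem.eligible]
        self.lab_obs = ~np.isnan(lab)            # (n, C)
        self.lab_pos = np.nan_to_num(lab) * self.lab_obs
        with np.errstate(invalid="ignore"):
            self.d_all = np.where(self.lab_obs.sum(0) > 0,
                                  self.lab_pos.sum(0) / np.maximum(self.lab_obs.sum(0), 1),
                                  np.nan)
        self.alpha = problem.resolved_alpha()
        self.in_mode = problem.mode == "in_distribution"

    def penalty_batch(self, P: np.ndarray) -> np.ndarray:
        """Penalty for each 0/1 genome row of P."""
        pen = np.zeros(P.shape[0])
        for k in range(self.lab_obs.shape[1]):
            if np.isnan(self.d_all[k]):
                continue
            n_obs = P @ self.lab_obs[:, k].astype(float)
            n_pos = P @ self.lab_pos[:, k]
            d_test = np.where(n_obs > 0, n_pos / np.maximum(n_obs, 1), 0.0)
            pen += np.abs(d_test - self.d_all[k])
        return self.alpha * pen

    def distance_term(self, masks: np.ndarray) -> np.ndarray:
        P = masks.astype(float)
        if self.in_mode:
            out = np.empty(masks.shape[0])
            for g, m in enumerate(masks):
                idx = np.flatnonzero(m)
                sub = self.D[np.ix_(idx, idx)]
                np.fill_diagonal(sub, np.inf)
                out[g] = sub.min(axis=1).sum()
            return out
        return ((P @ self.D) * P).sum(axis=1) / 2.0

    def fitness(self, masks: np.ndarray) -> np.ndarray:
        masks = np.atleast_2d(masks).astype(bool)
        return self.distance_term(masks) - self.penalty_batch(masks.astype(float))


def _check_mask(problem: SplitProblem, mask: np.ndarray, min_n: int = 2) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] == problem.X.shape[0]:
        mask = mask[problem.eligible]
    if mask.shape[0] != problem.n_eligible:
        raise ValueError("mask length must match eligible patients")
    if mask.sum() < min_n:
        raise ValueError(f"test set needs at least {min_n} patients")
    return mask


def fitness_in(mask: np.ndarray, problem: SplitProblem) -> float:
    """Sum of nearest-test-neighbor cosine distances minus the balance penalty."""
    prob = _with_mode(problem, "in_distribution")
    mask = _check_mask(prob, mask)
    return float(_FitnessEngine(prob).fitness(mask)[0])


def fitness_out(mask: np.ndarray, problem: SplitProblem) -> float:
    """Sum of all-pairs cosine distances minus the balance penalty."""
    prob = _with_mode(problem, "out_of_distribution")
    mask = _check_mask(prob, mask)
    return float(_FitnessEngine(prob).fitness(mask)[0])


def _with_mode(problem: SplitProblem, mode: str) -> SplitProblem:
    if problem.mode == mode:
        return problem
    return SplitProblem(X=problem.X, patient_ids=problem.patient_ids,
                        labels=problem.labels, test_fraction=problem.test_fraction,
                        alpha=problem.alpha, mode=mode, eligible=problem.eligible)


def _repair(masks: np.ndarray, N: int, rng: np.random.Generator) -> None:
    """Random bit flips restoring exactly N test bits per genome, in place."""
    counts = masks.sum(axis=1)
    for g in np.flatnonzero(counts != N):
        m = masks[g]
        ones = np.flatnonzero(m)
        zeros = np.flatnonzero(~m)
        if ones.size > N:
            drop = rng.choice(ones, size=ones.size - N, replace=False)
            m[drop] = False
        else:
            add = rng.choice(zeros, size=N - ones.size, replace=False)
            m[add] = True


def run_ga(problem: SplitProblem, params: GAParams | None = None) -> SplitResult:
    """Evolve a class-balanced split; returns train/test patient IDs.

    The best-so-far fitness trace is non-decreasing (elitism); termination
    after ``stagnation_limit`` generations without improvement or at the
    generation cap.  Fully reproducible under ``params.seed``.
    """
    params = params or GAParams()
    n = problem.n_eligible
    N = problem.n_test
    if n < math.ceil(1.0 / problem.test_fraction) or N < 2:
        raise ValueError(f"infeasible split: {n} eligible patients, N={N}")
    rng = child_rng(params.seed, "ga")
    engine = _FitnessEngine(problem)
    pop_size = params.population_size
    elite = params.elite_count if params.elite_count is not None \
        else max(1, pop_size // 100)
    mut_rate = params.mutation_rate if params.mutation_rate is not None else 1.0 / n

    # init: uniformly random N-subsets
    pop = np.zeros((pop_size, n), dtype=bool)
    for g in range(pop_size):
        pop[g, rng.choice(n, size=N, replace=False)] = True
    fit = engine.fitness(pop)

    trace: list[float] = []
    best_fit = -np.inf
    best_mask: np.ndarray | None = None
    stagnant = 0
    gen = 0
    for gen in range(1, params.max_generations + 1):
        order = np.argsort(fit)[::-1]
        if fit[order[0]] > best_fit:
            best_fit = float(fit[order[0]])
            best_mask = pop[order[0]].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if stagnant >= params.stagnation_limit:
            break

        children = np.empty_like(pop)
        children[:elite] = pop[order[:elite]]
        n_rest = pop_size - elite
        # tournament selection of parent pairs
        cand = rng.integers(pop_size, size=(2 * n_rest, params.tournament_size))
        winners = cand[np.arange(2 * n_rest), np.argmax(fit[cand], axis=1)]
        pa, pb = winners[:n_rest], winners[n_rest:]
        kids = pop[pa].copy()
        do_x = rng.random(n_rest) < params.crossover_rate
        cut = rng.integers(1, n, size=n_rest)
        for i in np.flatnonzero(do_x):
            kids[i, cut[i]:] = pop[pb[i], cut[i]:]
        # inversion mutation: reverse a random segment (preserves bit count)
        do_m = rng.random(n_rest) < mut_rate
        for i in np.flatnonzero(do_m):
            a, b = sorted(rng.choice(n, size=2, replace=False))
            kids[i, a:b + 1] = kids[i, a:b + 1][::-1]
        _repair(kids, N, rng)
        children[elite:] = kids
        pop = children
        fit = engine.fitness(pop)

    assert best_mask is not None
    eligible_ids = [pid for pid, e in zip(problem.patient_ids, problem.eligible) if e]
    ineligible_ids = [pid for pid, e in zip(problem.patient_ids, problem.eligible) if not e]
    test_ids = [pid for pid, b in zip(eligible_ids, best_mask) if b]
    train_ids = [pid for pid, b in zip(eligible_ids, best_mask) if not b]
    train_ids += ineligible_ids  # incomplete-vector patients train by rule
    return SplitResult(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                       best_fitness=best_fit, fitness_trace=trace,
                       mode=problem.mode, n_generations=gen)


def exhaustive_split_oracle(problem: SplitProblem, N: int) -> tuple[np.ndarray, float]:
    """Global optimum by enumeration of all C(n, N) masks (test oracle).

    Ties resolved to the lexicographically smallest mask (as a 0/1 vector).
    """
    n = problem.n_eligible
    if math.comb(n, N) > 10**6:
        raise ValueError("instance too large for exhaustive enumeration")
    engine = _FitnessEngine(problem)
    best_fit = -np.inf
    best_mask: np.ndarray | None = None
    for combo in itertools.combinations(range(n), N):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        f = float(engine.fitness(mask)[0])
        if f > best_fit or (f == best_fit and best_mask is not None
                            and tuple(mask) < tuple(best_mask)):
            best_fit = f
            best_mask = mask
    return best_mask, best_fit


def problem_from_vectors(vectors, labels: np.ndarray, *, test_fraction: float = 0.20,
                         alpha: float | None = None,
                         mode: str = "in_distribution") -> SplitProblem:
    """Build a :class:`SplitProblem` from a VectorSet; eligibility = completeness."""
    return SplitProblem(X=vectors.X, patient_ids=list(vectors.patient_ids),
                        labels=labels, test_fraction=test_fraction, alpha=alpha,
                        mode=mode, eligible=vectors.complete.copy())
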