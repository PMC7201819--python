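"""Modified immune evolutionary algorithm (MIEA) for fuzzy clustering.

A real-valued genetic algorithm searches the space of cluster-prototype sets:
each chromosome is the row-major concatenation of c centers in p dimensions
(length l = c*p), scored by the FCM objective through the fitness transform
f = 1/(J+1).  On top of the plain GA (roulette/rank selection, one-point
crossover, uniform-reset mutation) sit the immune operators:

* vaccine extraction — harvest a random fraction of the current elite's genes;
* vaccination — overwrite those gene positions in an offspring with the
  elite's values, with per-individual probability p_v;
* immune selection — keep the vaccinated individual only if its fitness did
  not degrade, which is what stops vaccination from destroying diversity
  gains, and elitism, which carries the best individual unchanged into the
  next generation so the elite objective is monotone.

The vaccine is refreshed whenever the elite improves, and otherwise with
per-generation probability p_u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .data import LabeledDataset
from .fcm import (
    _as_matrix,
    decode,
    encode,
    evaluate_chromosome,
    membership_update,
    squared_distances,
)

__all__ = [
    "Vaccine",
    "MIEAConfig",
    "ClusteringResult",
    "init_population",
    "select",
    "crossover",
    "mutate",
    "reverse_segment",
    "extract_vaccine",
    "vaccinate",
    "immune_select",
    "run_miea",
    "MIEAClustering",
]


@dataclass
class Vaccine:
    """Gene fragments harvested from an elite chromosome.

    ``positions`` are distinct indices into the chromosome, ``values`` the
    elite's genes at those positions, ``source_fitness`` the donor's fitness.
    """

    positions: np.ndarray
    values: np.ndarray
    source_fitness: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != np.unique(self.positions).size:
            raise ValueError("vaccine positions must be distinct")
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must align")


@dataclass
class MIEAConfig:
    """Run parameters of the immune evolutionary clustering loop.

    Defaults: crossover probability 0.95 and vaccination probability 0.3
    with fuzzifier 2 (the reference operating point); per-gene mutation
    probability 1e-2, the top of the conventional [1e-3, 1e-2] band —
    center chromosomes are short (l = c*p), so anything lower leaves most
    offspring without any new gene material and stalls refinement.
    ``tau`` is the stall tolerance on the elite objective: the loop stops
    once |dJ_elite| < tau for ``patience`` consecutive generations, or at
    ``max_gens``.  The default tau = 0 disables early stopping (elite
    improvements arrive in bursts with long gaps, so any positive default
    would routinely truncate runs mid-descent); set tau > 0 to opt in.
    """

    c: int = 2
    m: float = 2.0
    pop_size: int = 30
    p_c: float = 0.95
    p_m: float = 1e-2
    p_v: float = 0.3
    p_u: float = 0.5
    vaccine_fraction: float = 0.25
    tau: float = 0.0
    patience: int = 10
    max_gens: int = 100
    selection: str = "roulette"
    crossover_op: str = "one_point"
    mutation_op: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_c", "p_m", "p_v", "p_u"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0.0 < self.vaccine_fraction <= 1.0:
            raise ValueError("vaccine_fraction must be in (0, 1]")
        if self.tau < 0 or self.patience < 1 or self.max_gens < 1:
            raise ValueError("tau must be >= 0, patience and max_gens >= 1")
        if self.selection not in ("roulette", "rank"):
            raise ValueError("selection must be 'roulette' or 'rank'")
        if self.crossover_op not in ("one_point", "two_point", "uniform"):
            raise ValueError("crossover_op must be one_point|two_point|uniform")
        if self.mutation_op not in ("uniform", "segment_reversal"):
            raise ValueError("mutation_op must be uniform|segment_reversal")


@dataclass
class ClusteringResult:
    """Decoded outcome of a MIEA run."""

    best_chromosome: np.ndarray
    prototypes: np.ndarray
    membership: np.ndarray
    hard_labels: np.ndarray
    J_history: np.ndarray
    f_best: float
    generations_run: int
    seed: int | None
    generation_log: list[dict] = field(default_factory=list)


def _bounds(X: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.tile(X.min(axis=0), c)
    hi = np.tile(X.max(axis=0), c)
    return lo, hi


def init_population(X, c: int, pop_size: int, rng) -> np.ndarray:
    """pop_size chromosomes, each gene uniform within its feature's range."""
    Xm = _as_matrix(X)
    rng = np.random.default_rng(rng)
    lo, hi = _bounds(Xm, c)
    return rng.uniform(lo, hi, size=(pop_size, lo.size))


def select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    method: str,
    n_out: int,
    rng,
) -> np.ndarray:
    """Sample ``n_out`` chromosomes with replacement.

    ``roulette``: probability proportional to fitness (positive by
    construction of f = 1/(J+1)).  ``rank``: probability proportional to
    linear rank weight (worst gets 1, best gets len(pop)), invariant to
    monotone rescaling of fitness.
    """
    population = np.asarray(population)
    fitnesses = np.asarray(fitnesses, dtype=float)
    if population.shape[0] == 0:
        raise ValueError("empty population")
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    rng = np.random.default_rng(rng)
    if method == "roulette":
        probs = fitnesses / fitnesses.sum()
    elif method == "rank":
        ranks = np.empty(len(fitnesses))
        ranks[np.argsort(fitnesses, kind="stable")] = np.arange(
            1, len(fitnesses) + 1
        )
        probs = ranks / ranks.sum()
    else:
        raise ValueError(f"unknown selection method {method!r}")
    idx = rng.choice(len(population), size=n_out, replace=True, p=probs)
    return population[idx].copy()


def crossover(
    parent1: np.ndarray,
    parent2: np.ndarray,
    p_c: float,
    rng,
    op: str = "one_point",
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine two chromosomes with probability ``p_c``, else copy them.

    ``one_point`` swaps the tails after a uniform cut in [1, l-1];
    ``two_point`` swaps the segment between two cuts; ``uniform`` swaps each
    gene independently with probability 1/2.  Per-position gene multisets are
    conserved in all variants.
    """
    a = np.asarray(parent1, dtype=float).copy()
    b = np.asarray(parent2, dtype=float).copy()
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    rng = np.random.default_rng(rng)
    l = a.size
    if l < 2 or rng.random() >= p_c:
        return a, b
    if op == "one_point":
        cut = int(rng.integers(1, l))
        a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
    elif op == "two_point":
        i, j = sorted(rng.choice(l + 1, size=2, replace=False))
        a[i:j], b[i:j] = b[i:j].copy(), a[i:j].copy()
    elif op == "uniform":
        mask = rng.random(l) < 0.5
        a[mask], b[mask] = b[mask].copy(), a[mask].copy()
    else:
        raise ValueError(f"unknown crossover op {op!r}")
    return a, b


def mutate(
    chromosome: np.ndarray,
    p_m: float,
    lo: np.ndarray,
    hi: np.ndarray,
    rng,
    op: str = "uniform",
) -> np.ndarray:
    """Mutate a real-coded chromosome, staying within the feature bounds.

    ``uniform``: each gene is independently re-drawn uniformly within its
    feature's [lo, hi] with probability ``p_m`` — the real-coded realisation
    of gene "reversion", which for binary strings means bit inversion.
    ``segment_reversal``: with per-chromosome probability min(1, p_m * l),
    reverse a random gene slice instead (order-only perturbation).
    """
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("p_m must be in [0, 1]")
    a = np.asarray(chromosome, dtype=float).copy()
    rng = np.random.default_rng(rng)
    if op == "uniform":
        mask = rng.random(a.size) < p_m
        if mask.any():
            a[mask] = rng.uniform(lo[mask], hi[mask])
    elif op == "segment_reversal":
        if rng.random() < min(1.0, p_m * a.size):
            i, j = sorted(rng.choice(a.size + 1, size=2, replace=False))
            a[i:j] = a[i:j][::-1]
    else:
        raise ValueError(f"unknown mutation op {op!r}")
    return a


def reverse_segment(chromosome: np.ndarray, rng) -> np.ndarray:
    """Reverse a random gene slice (the optional inversion-style operator)."""
    a = np.asarray(chromosome, dtype=float).copy()
    rng = np.random.default_rng(rng)
    i, j = sorted(rng.choice(a.size + 1, size=2, replace=False))
    a[i:j] = a[i:j][::-1]
    return a


def extract_vaccine(
    elite: np.ndarray,
    elite_fitness: float,
    vaccine_fraction: float,
    rng,
) -> Vaccine:
    """Harvest ceil(vaccine_fraction * l) distinct gene positions from the elite."""
    if not 0.0 < vaccine_fraction <= 1.0:
        raise ValueError("vaccine_fraction must be in (0, 1]")
    elite = np.asarray(elite, dtype=float)
    rng = np.random.default_rng(rng)
    k = math.ceil(vaccine_fraction * elite.size)
    pos = np.sort(rng.choice(elite.size, size=k, replace=False))
    return Vaccine(pos, elite[pos].copy(), float(elite_fitness))


def _apply_vaccine(chromosome: np.ndarray, vaccine: Vaccine) -> np.ndarray:
    out = np.asarray(chromosome, dtype=float).copy()
    if vaccine.positions.size and vaccine.positions.max() >= out.size:
        raise ValueError("vaccine position out of range for this chromosome")
    out[vaccine.positions] = vaccine.values
    return out


def vaccinate(
    chromosome: np.ndarray, vaccine: Vaccine, p_v: float, rng
) -> np.ndarray:
    """With per-individual probability ``p_v`` inject the vaccine genes."""
    rng = np.random.default_rng(rng)
    if rng.random() < p_v:
        return _apply_vaccine(chromosome, vaccine)
    return np.asarray(chromosome, dtype=float).copy()


def immune_select(original, vaccinated, eval_fn) -> np.ndarray:
    """Greedy anti-degradation acceptance: keep the vaccinated individual iff
    its fitness is not worse than the original's."""
    f_orig = eval_fn(np.asarray(original, dtype=float))
    f_vacc = eval_fn(np.asarray(vaccinated, dtype=float))
    return (
        np.asarray(vaccinated, dtype=float)
        if f_vacc >= f_orig
        else np.asarray(original, dtype=float)
    )


class MIEAClustering(ClusterMixin, BaseEstimator):
    """Fuzzy clustering by the modified immune evolutionary algorithm.

    A population of center-encoding chromosomes evolves under selection,
    crossover and mutation; vaccination with elite gene fragments followed by
    immune (non-degradation) selection accelerates convergence, and elitism
    makes the best objective monotone over generations.  Compared with plain
    alternating-optimisation FCM this is a global search: it does not depend
    on a single initialisation.

    Parameters mirror :class:`MIEAConfig`; see that dataclass for defaults
    and meanings.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (c, p)
        Decoded elite prototypes.
    membership_ : ndarray of shape (c, n)
        Fuzzy partition of the training data under the elite prototypes.
    labels_ : ndarray of shape (n,)
        Argmax defuzzification of ``membership_``.
    objective_history_ : ndarray
        Elite J per generation (index 0 = initial population); non-increasing.
    fitness_ : float
        Elite fitness 1/(J+1).
    n_generations_ : int
        Generations actually run.
    generation_log_ : list of dict
        Per-generation records (gen, J_elite, f_elite, vaccinations).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        fuzzifier: float = 2.0,
        pop_size: int = 30,
        crossover_prob: float = 0.95,
        mutation_prob: float = 1e-2,
        vaccination_prob: float = 0.3,
        vaccine_update_prob: float = 0.5,
        vaccine_fraction: float = 0.25,
        tol: float = 0.0,
        patience: int = 10,
        max_gens: int = 100,
        selection: str = "roulette",
        crossover_op: str = "one_point",
        mutation_op: str = "uniform",
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.pop_size = pop_size
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.vaccination_prob = vaccination_prob
        self.vaccine_update_prob = vaccine_update_prob
        self.vaccine_fraction = vaccine_fraction
        self.tol = tol
        self.patience = patience
        self.max_gens = max_gens
        self.selection = selection
        self.crossover_op = crossover_op
        self.mutation_op = mutation_op
        self.random_state = random_state

    def _config(self) -> MIEAConfig:
        seed = self.random_state
        if seed is not None and not isinstance(seed, (int, np.integer)):
            raise ValueError("random_state must be an int or None")
        return MIEAConfig(
            c=self.n_clusters,
            m=self.fuzzifier,
            pop_size=self.pop_size,
            p_c=self.crossover_prob,
            p_m=self.mutation_prob,
            p_v=self.vaccination_prob,
            p_u=self.vaccine_update_prob,
            vaccine_fraction=self.vaccine_fraction,
            tau=self.tol,
            patience=self.patience,
            max_gens=self.max_gens,
            selection=self.selection,
            crossover_op=self.crossover_op,
            mutation_op=self.mutation_op,
            seed=None if seed is None else int(seed),
        )

    def fit(self, X, y=None):
        cfg = self._config()
        Xm = _as_matrix(X)
        if Xm.ndim != 2 or Xm.shape[0] < 2:
            raise ValueError("X must be 2-D with at least two samples")
        n = Xm.shape[0]
        if not 1 <= cfg.c <= n - 1:
            raise ValueError(f"need 1 <= c <= n-1, got c={cfg.c}, n={n}")
        rng = np.random.default_rng(cfg.seed)
        lo, hi = _bounds(Xm, cfg.c)

        def score(chrom: np.ndarray) -> tuple[float, float]:
            _, J, f = evaluate_chromosome(chrom, Xm, cfg.c, cfg.m)
            return J, f

        pop = init_population(Xm, cfg.c, cfg.pop_size, rng)
        J_pop = np.empty(cfg.pop_size)
        f_pop = np.empty(cfg.pop_size)
        for i, chrom in enumerate(pop):
            J_pop[i], f_pop[i] = score(chrom)

        best = int(np.argmin(J_pop))
        elite = pop[best].copy()
        elite_J, elite_f = float(J_pop[best]), float(f_pop[best])
        vaccine = extract_vaccine(elite, elite_f, cfg.vaccine_fraction, rng)

        J_history = [elite_J]
        log: list[dict] = []
        stall = 0
        gens = 0
        for gen in range(cfg.max_gens):
            gens = gen + 1
            parents = select(pop, f_pop, cfg.selection, cfg.pop_size, rng)
            offspring = []
            for i in range(0, cfg.pop_size - 1, 2):
                c1, c2 = crossover(
                    parents[i], parents[i + 1], cfg.p_c, rng, cfg.crossover_op
                )
                offspring += [c1, c2]
            if len(offspring) < cfg.pop_size:  # odd population size
                offspring.append(parents[-1].copy())
            offspring = [
                mutate(ch, cfg.p_m, lo, hi, rng, cfg.mutation_op)
                for ch in offspring
            ]

            pop = np.asarray(offspring)
            for i, chrom in enumerate(pop):
                J_pop[i], f_pop[i] = score(chrom)

            # vaccination + immune selection (anti-degradation acceptance)
            vaccinated = 0
            for i in range(cfg.pop_size):
                if rng.random() < cfg.p_v:
                    cand = _apply_vaccine(pop[i], vaccine)
                    J_c, f_c = score(cand)
                    if f_c >= f_pop[i]:
                        pop[i], J_pop[i], f_pop[i] = cand, J_c, f_c
                        vaccinated += 1

            # elitism: the current elite re-enters unmodified, replacing the worst
            worst = int(np.argmax(J_pop))
            pop[worst], J_pop[worst], f_pop[worst] = elite, elite_J, elite_f

            best = int(np.argmin(J_pop))
            improved = J_pop[best] < elite_J
            if improved:
                elite = pop[best].copy()
                elite_J, elite_f = float(J_pop[best]), float(f_pop[best])
                vaccine = extract_vaccine(elite, elite_f, cfg.vaccine_fraction, rng)
            elif rng.random() < cfg.p_u:
                vaccine = extract_vaccine(elite, elite_f, cfg.vaccine_fraction, rng)

            J_history.append(elite_J)
            log.append(
                {
                    "gen": gen,
                    "J_elite": elite_J,
                    "f_elite": elite_f,
                    "vaccinations": vaccinated,
                }
            )
            if cfg.tau > 0:
                stall = (
                    stall + 1 if abs(J_history[-2] - J_history[-1]) < cfg.tau else 0
                )
                if stall >= cfg.patience:
                    break

        V = decode(elite, cfg.c, Xm.shape[1])
        U = membership_update(squared_distances(Xm, V), cfg.m)
        self.best_chromosome_ = elite
        self.cluster_centers_ = V
        self.membership_ = U
        self.labels_ = U.argmax(axis=0)
        self.objective_history_ = np.asarray(J_history)
        self.objective_ = elite_J
        self.fitness_ = elite_f
        self.n_generations_ = gens
        self.generation_log_ = log
        self.n_features_in_ = Xm.shape[1]
        return self

    def predict(self, X):
        Xm = _as_matrix(X)
        U = membership_update(
            squared_distances(Xm, self.cluster_centers_), self.fuzzifier
        )
        return U.argmax(axis=0)


def run_miea(X, cfg: MIEAConfig) -> ClusteringResult:
    """Run the immune evolutionary clustering loop; thin functional wrapper
    over :class:`MIEAClustering`."""
    est = MIEAClustering(
        n_clusters=cfg.c,
        fuzzifier=cfg.m,
        pop_size=cfg.pop_size,
        crossover_prob=cfg.p_c,
        mutation_prob=cfg.p_m,
        vaccination_prob=cfg.p_v,
        vaccine_update_prob=cfg.p_u,
        vaccine_fraction=cfg.vaccine_fraction,
        tol=cfg.tau,
        patience=cfg.patience,
        max_gens=cfg.max_gens,
        selection=cfg.selection,
        crossover_op=cfg.crossover_op,
        mutation_op=cfg.mutation_op,
        random_state=cfg.seed,
    ).fit(X)
    return ClusteringResult(
        best_chromosome=est.best_chromosome_,
        prototypes=est.cluster_centers_,
        membership=est.membership_,
        hard_labels=est.labels_,
        J_history=est.objective_history_,
        f_best=est.fitness_,
        generations_run=est.n_generations_,
        seed=cfg.seed,
        generation_log=est.generation_log_,
    )
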