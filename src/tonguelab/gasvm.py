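"""Genetic-algorithm-tuned RBF support vector classification.

The soft-margin penalty ``c`` and RBF kernel parameter ``g`` (kernel
``K(x, y) = exp(-g ||x - y||^2)``) are searched on the log2 scale by a
generational genetic algorithm whose fitness is stratified k-fold
cross-validation accuracy on the training table.  GA settings follow the
study: population 20, 100 generations, 10-fold CV fitness; the operator
suite (tournament selection of size 2, uniform crossover, clipped Gaussian
mutation, elitism of the single best individual) uses standard defaults and
is fully configurable.

The quadratic-program solve itself is delegated to scikit-learn's ``SVC``
(a LIBSVM binding); the GA wrapper, the CV harness and all plumbing live
here.  :class:`GASVC` packages the search as a scikit-learn classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = ["SvmParams", "GaConfig", "GaTrace", "cv_fitness", "ga_optimize",
           "train_svm", "predict", "GASVC"]


@dataclass(frozen=True)
class SvmParams:
    """RBF C-SVM hyperparameters; both strictly positive."""

    c: float
    g: float

    def __post_init__(self):
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be strictly positive")


@dataclass
class GaConfig:
    population_size: int = 20
    generations: int = 100
    log2c_bounds: tuple = (-5.0, 15.0)
    log2g_bounds: tuple = (-15.0, 3.0)
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.5  # in log2 units
    tournament_size: int = 2
    elitism: int = 1
    cv_folds: int = 10
    seed: int = 0

    def validate(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GaTrace:
    """Per-generation record of the search."""

    generation: list = field(default_factory=list)
    best_fitness: list = field(default_factory=list)  # best-so-far
    mean_fitness: list = field(default_factory=list)
    best_c: list = field(default_factory=list)
    best_g: list = field(default_factory=list)
    n_evaluations: int = 0  # distinct chromosomes actually evaluated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "c": self.best_c,
                "g": self.best_g,
            }
        )


def _canonical_order(X, y):
    """Row order independent of input permutation (lexicographic)."""
    keys = np.column_stack([np.asarray(X, dtype=float), np.asarray(y, dtype=float)])
    return np.lexsort(keys.T[::-1])


def cv_fitness(X, y, params: SvmParams, folds: int = 10, seed: int = 0) -> float:
    """Mean held-out accuracy of an RBF C-SVM over stratified CV folds.

    Rows are first put in a canonical (lexicographic) order so the fitness
    is invariant to the row order of the training table; folds are then
    assigned by a seeded shuffle of that order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training table")
    order = _canonical_order(X, y)
    Xc, yc = X[order], y[order]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xc, yc):
        clf = SVC(C=params.c, gamma=params.g, kernel="rbf")
        clf.fit(Xc[tr], yc[tr])
        accs.append(float(np.mean(clf.predict(Xc[te]) == yc[te])))
    return float(np.mean(accs))


def ga_optimize(X, y, cfg: GaConfig | None = None, fitness_fn=None):
    """Search (c, g) by a generational GA; returns (best SvmParams, GaTrace).

    ``fitness_fn(params) -> float`` may be injected (e.g. for testing);
    by default it is :func:`cv_fitness` on (X, y).  Fitness evaluations are
    cached per chromosome, and the best chromosome ever evaluated is
    returned.  Elitism makes the best-so-far fitness non-decreasing.
    """
    cfg = cfg or GaConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([cfg.log2c_bounds[0], cfg.log2g_bounds[0]])
    hi = np.array([cfg.log2c_bounds[1], cfg.log2g_bounds[1]])

    cache: dict = {}

    def evaluate(chrom) -> float:
        key = (round(float(chrom[0]), 12), round(float(chrom[1]), 12))
        if key not in cache:
            params = SvmParams(2.0 ** key[0], 2.0 ** key[1])
            if fitness_fn is not None:
                cache[key] = float(fitness_fn(params))
            else:
                cache[key] = cv_fitness(X, y, params, folds=cfg.cv_folds, seed=cfg.seed)
        return cache[key]

    pop = rng.uniform(lo, hi, size=(cfg.population_size, 2))
    fit = np.array([evaluate(ind) for ind in pop])
    best_idx = int(np.argmax(fit))
    best_chrom, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace = GaTrace()

    def record(gen):
        trace.generation.append(gen)
        trace.best_fitness.append(best_fit)
        trace.mean_fitness.append(float(fit.mean()))
        trace.best_c.append(2.0 ** best_chrom[0])
        trace.best_g.append(2.0 ** best_chrom[1])

    record(0)
    for gen in range(1, cfg.generations + 1):
        new_pop = [pop[int(np.argmax(fit))].copy() for _ in range(cfg.elitism)]
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]].copy())
            a, b = parents
            if rng.random() < cfg.crossover_prob:  # uniform crossover on the two genes
                swap = rng.random(2) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                mutate = rng.random(2) < cfg.mutation_prob
                child[mutate] += rng.normal(0.0, cfg.mutation_sigma, size=int(mutate.sum()))
                np.clip(child, lo, hi, out=child)
                if len(new_pop) < cfg.population_size:
                    new_pop.append(child)
        pop = np.asarray(new_pop)
        fit = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_chrom = pop[gen_best].copy()
        record(gen)

    trace.n_evaluations = len(cache)
    return SvmParams(2.0 ** best_chrom[0], 2.0 ** best_chrom[1]), trace


def train_svm(X, y, params: SvmParams) -> SVC:
    """Fit an RBF C-SVM with the given hyperparameters."""
    return SVC(C=params.c, gamma=params.g, kernel="rbf").fit(
        np.asarray(X, dtype=float), np.asarray(y).astype(int)
    )


def predict(model: SVC, X):
    """Predicted labels and decision values; label = 1 iff decision > 0
    (for the usual 0/1 label encoding)."""
    check_is_fitted(model)
    X = np.asarray(X, dtype=float)
    return model.predict(X), model.decision_function(X)


class GASVC(ClassifierMixin, BaseEstimator):
    """RBF SVM with GA-selected hyperparameters, as a sklearn classifier.

    ``fit`` runs the genetic search (CV-accuracy fitness) on the training
    data and refits a single SVC with the best (c, g) found.

    Attributes (after fit)
    ----------------------
    best_params_ : SvmParams
    cv_accuracy_ : float, the best cross-validation fitness found
    trace_ : GaTrace
    svm_ : the refitted sklearn SVC
    """

    def __init__(
        self,
        population_size: int = 20,
        generations: int = 100,
        log2c_bounds: tuple = (-5.0, 15.0),
        log2g_bounds: tuple = (-15.0, 3.0),
        crossover_prob: float = 0.7,
        mutation_prob: float = 0.1,
        mutation_sigma: float = 0.5,
        tournament_size: int = 2,
        elitism: int = 1,
        cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.log2c_bounds = log2c_bounds
        self.log2g_bounds = log2g_bounds
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.mutation_sigma = mutation_sigma
        self.tournament_size = tournament_size
        self.elitism = elitism
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _ga_config(self) -> GaConfig:
        return GaConfig(
            population_size=self.population_size,
            generations=self.generations,
            log2c_bounds=tuple(self.log2c_bounds),
            log2g_bounds=tuple(self.log2g_bounds),
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            mutation_sigma=self.mutation_sigma,
            tournament_size=self.tournament_size,
            elitism=self.elitism,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.best_params_, self.trace_ = ga_optimize(X, y, self._ga_config())
        self.cv_accuracy_ = self.trace_.best_fitness[-1]
        self.svm_ = train_svm(X, y, self.best_params_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(np.asarray(X, dtype=float))
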