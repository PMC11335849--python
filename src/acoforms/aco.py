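"""Ant colony optimization for parallel test-form assembly.

Candidate solutions are triples (generally n-tuples) of disjoint forms,
each containing exactly one item per content domain.  A pheromone weight is
kept per (form, item) cell; every iteration a batch of "ants" samples
candidate triples with probabilities proportional to pheromone, each triple
is fully fitted and scored into a single pheromone value phi_overall
(see :mod:`acoforms.criteria`), and a strictly improving global best
deposits pheromone on its cells while all cells evaporate by a fixed
fraction.  The search stops once the best triple clears every criterion
threshold (all component pheromones >= 0.5), or after a patience window
without improvement, or at the iteration cap.

Exhaustive enumeration is hopeless — already a 30-item pool admits
C(30, 10) > 30 million single 10-item forms — hence the metaheuristic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .bank import ItemBank, ResponseData
from .criteria import CriterionProfile, TripleEvaluation, default_profile, evaluate_forms
from .thresholds import draw_uniform_triple

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyState",
    "AssemblyResult",
    "AntColonyAssembler",
    "sample_triple",
    "step",
    "run_aco",
    "random_search_baseline",
    "n_candidate_forms",
]

PHEROMONE_FLOOR = 1e-12


def n_candidate_forms(pool_size: int, form_length: int) -> int:
    """Number of distinct forms of given length from a pool: C(pool, length)."""
    return math.comb(pool_size, form_length)


@dataclass
class AssemblyState:
    """Mutable search state: pheromone, incumbent best, counters."""

    pheromone: np.ndarray  # n_forms x n_items, strictly positive
    rng: np.random.Generator
    best: TripleEvaluation | None = None
    iteration: int = 0
    stall_counter: int = 0
    n_evaluations: int = 0
    memo: dict = field(default_factory=dict)
    form_cache: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.pheromone <= 0):
            raise ValueError("pheromone entries must be positive")


@dataclass
class AssemblyResult:
    """Outcome of one assembly run."""

    forms: list[list[str]]
    evaluation: TripleEvaluation
    trace: list[dict]
    termination: str
    n_iterations: int
    n_evaluations: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "forms": [list(f) for f in self.forms],
            "evaluation": self.evaluation.to_dict(),
            "trace": self.trace,
            "termination": self.termination,
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }


def init_state(bank: ItemBank, n_forms: int, seed) -> AssemblyState:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return AssemblyState(pheromone=np.ones((n_forms, len(bank))), rng=rng)


def sample_triple(
    state: AssemblyState, bank: ItemBank, n_forms: int | None = None
) -> list[list[str]]:
    """Draw one coverage-respecting disjoint triple from the pheromone.

    Domain by domain, each form in turn draws one still-available item with
    probability proportional to its own pheromone row, so disjointness and
    one-item-per-domain coverage hold by construction.
    """
    n_forms = n_forms if n_forms is not None else state.pheromone.shape[0]
    index = {iid: j for j, iid in enumerate(bank.item_ids)}
    forms: list[list[str]] = [[] for _ in range(n_forms)]
    for dom in bank.domains:
        available = bank.domain_items(dom)
        if len(available) < n_forms:
            raise ValueError(f"domain {dom!r} cannot supply {n_forms} disjoint items")
        for f in range(n_forms):
            w = np.array([state.pheromone[f, index[iid]] for iid in available])
            probs = w / w.sum()
            pick = state.rng.choice(len(available), p=probs)
            forms[f].append(available.pop(pick))
    return forms


def _canonical(sets: list[list[str]]) -> tuple:
    return tuple(sorted(tuple(sorted(s)) for s in sets))


def _evaluate_memo(
    state: AssemblyState,
    responses: ResponseData,
    triple: list[list[str]],
    profile: CriterionProfile,
    **fit_kwargs,
) -> TripleEvaluation:
    key = _canonical(triple)
    state.n_evaluations += 1
    if key not in state.memo:
        state.memo[key] = evaluate_forms(
            responses,
            [list(s) for s in key],
            profile,
            form_cache=state.form_cache,
            **fit_kwargs,
        )
    return state.memo[key]


def step(
    state: AssemblyState,
    bank: ItemBank,
    responses: ResponseData,
    profile: CriterionProfile,
    n_ants: int = 50,
    evaporation: float = 0.05,
    deposit_scale: float = 1.0,
    **fit_kwargs,
) -> AssemblyState:
    """One ACO iteration: sample, evaluate, deposit on improvement, evaporate."""
    index = {iid: j for j, iid in enumerate(bank.item_ids)}
    best_ant: TripleEvaluation | None = None
    for _ in range(n_ants):
        triple = sample_triple(state, bank, profile.n_forms)
        ev = _evaluate_memo(state, responses, triple, profile, **fit_kwargs)
        if best_ant is None or ev.phi_overall > best_ant.phi_overall:
            best_ant = ev
    improved = state.best is None or best_ant.phi_overall > state.best.phi_overall
    if improved:
        state.best = best_ant
        state.stall_counter = 0
        for f, items in enumerate(best_ant.item_sets):
            for iid in items:
                state.pheromone[f, index[iid]] += deposit_scale * best_ant.phi_overall
        logger.info(
            "iteration %d: new best phi_overall=%.4f components=%s",
            state.iteration + 1,
            best_ant.phi_overall,
            {k: round(v, 4) for k, v in best_ant.components.items()},
        )
    else:
        state.stall_counter += 1
    state.pheromone *= 1.0 - evaporation
    np.maximum(state.pheromone, PHEROMONE_FLOOR, out=state.pheromone)
    state.iteration += 1
    return state


def _all_criteria_met(ev: TripleEvaluation) -> bool:
    return (not ev.failed) and all(v >= 0.5 for v in ev.components.values())


def run_aco(
    bank: ItemBank,
    responses: ResponseData,
    profile: CriterionProfile | None = None,
    n_ants: int = 50,
    evaporation: float = 0.05,
    deposit_scale: float = 1.0,
    max_iter: int = 300,
    patience: int = 30,
    seed: int = 0,
    **fit_kwargs,
) -> AssemblyResult:
    """Full assembly run; deterministic under ``seed``.

    Stops when the incumbent clears every criterion threshold (all
    component pheromones >= 0.5), when ``patience`` iterations pass without
    improvement, or at ``max_iter`` (an initial ant batch always runs, so
    ``max_iter=0`` returns the best of that batch).
    """
    profile = profile if profile is not None else default_profile()
    bank.check_coverage(profile.n_forms)
    if n_ants < 1 or not (0.0 <= evaporation < 1.0) or patience < 0 or max_iter < 0:
        raise ValueError("invalid hyperparameters")
    if profile.has_dtf and responses.group is None:
        raise ValueError("profile includes DTF criteria but responses have no groups")
    state = init_state(bank, profile.n_forms, seed)
    trace: list[dict] = []
    termination = "max_iter"
    while True:
        step(
            state,
            bank,
            responses,
            profile,
            n_ants=n_ants,
            evaporation=evaporation,
            deposit_scale=deposit_scale,
            **fit_kwargs,
        )
        entry = {
            "iteration": state.iteration,
            "phi_overall": state.best.phi_overall,
            "stall": state.stall_counter,
        }
        entry.update({f"phi_{k}": v for k, v in state.best.components.items()})
        trace.append(entry)
        if _all_criteria_met(state.best):
            termination = "all_criteria_met"
            break
        if state.stall_counter >= patience > 0:
            termination = "patience"
            break
        if state.iteration >= max_iter:
            termination = "max_iter"
            break
    return AssemblyResult(
        forms=[list(s) for s in state.best.item_sets],
        evaluation=state.best,
        trace=trace,
        termination=termination,
        n_iterations=state.iteration,
        n_evaluations=state.n_evaluations,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def random_search_baseline(
    bank: ItemBank,
    responses: ResponseData,
    profile: CriterionProfile | None = None,
    n_evals: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> TripleEvaluation:
    """Best of ``n_evals`` uniform coverage-respecting draws.

    Control condition for search efficacy at an equal evaluation budget
    (one evaluation = one drawn triple, as in the ACO accounting).
    """
    profile = profile if profile is not None else default_profile()
    bank.check_coverage(profile.n_forms)
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    rng = np.random.default_rng(seed)
    memo: dict = {}
    form_cache: dict = {}
    best: TripleEvaluation | None = None
    for _ in range(n_evals):
        triple = draw_uniform_triple(bank, profile.n_forms, rng)
        key = _canonical(triple)
        if key not in memo:
            memo[key] = evaluate_forms(
                responses,
                [list(s) for s in key],
                profile,
                form_cache=form_cache,
                **fit_kwargs,
            )
        ev = memo[key]
        if best is None or ev.phi_overall > best.phi_overall:
            best = ev
    return best


class AntColonyAssembler(BaseEstimator):
    """Scikit-learn-style front end to the assembly search.

    ``fit`` runs the ACO on a :class:`ResponseData` and exposes ``forms_``
    (the assembled parallel forms), ``best_evaluation_``, ``trace_`` and
    ``result_``.
    """

    def __init__(
        self,
        bank: ItemBank = None,
        profile: CriterionProfile | None = None,
        n_ants: int = 50,
        evaporation: float = 0.05,
        deposit_scale: float = 1.0,
        max_iter: int = 300,
        patience: int = 30,
        seed: int = 0,
    ):
        self.bank = bank
        self.profile = profile
        self.n_ants = n_ants
        self.evaporation = evaporation
        self.deposit_scale = deposit_scale
        self.max_iter = max_iter
        self.patience = patience
        self.seed = seed

    def fit(self, X: ResponseData, y=None):
        if self.bank is None:
            raise ValueError("a bank must be supplied at construction")
        result = run_aco(
            self.bank,
            X,
            self.profile,
            n_ants=self.n_ants,
            evaporation=self.evaporation,
            deposit_scale=self.deposit_scale,
            max_iter=self.max_iter,
            patience=self.patience,
            seed=self.seed,
        )
        self.result_ = result
        self.forms_ = result.forms
        self.best_evaluation_ = result.evaluation
        self.trace_ = result.trace
        return self
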