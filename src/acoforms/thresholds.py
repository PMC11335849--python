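"""Data-driven calibration of criterion thresholds and slopes.

Rather than importing fixed cutoff conventions, thresholds are calibrated
against what the item pool can actually deliver: many random
coverage-respecting parallel triples are drawn, each is fully fitted and
scored, and the threshold of every criterion is set at the favorable-tail
percentile of its empirical distribution — the 5th percentile for
smaller-is-better criteria (RMSEA, TCC/TIF sqsum, sDTF, uDTF) and the 95th
for larger-is-better ones (CFI, reliability).  By construction roughly 5%
of random triples beat each single threshold, so a triple beating all of
them at once is genuinely hard to find at random, which is exactly the
niche the pheromone search exploits.

The same machinery reports criterion correlations across the random draws
(to spot redundant criteria worth merging in the profile weights) and slope
diagnostics (which share of random triples would receive a pheromone above
given cut levels for each candidate slope).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bank import ItemBank, ResponseData
from .criteria import CriterionProfile, default_profile, evaluate_forms, logit_phi

logger = logging.getLogger(__name__)

__all__ = [
    "CriterionDistributions",
    "draw_uniform_triple",
    "sample_random_triples",
    "empirical_thresholds",
    "criterion_correlations",
    "slope_diagnostics",
    "plot_criterion_distributions",
    "ThresholdCalibrator",
]

#: distribution keys and their optimization direction
CRITERION_DIRECTIONS = {
    "cfi": "maximize",
    "rmsea": "minimize",
    "reliability": "maximize",
    "tcc_sqsum": "minimize",
    "tif_sqsum": "minimize",
    "sdtf": "minimize",
    "udtf": "minimize",
}

_RAW_KEYS = {  # TripleEvaluation.raw key per distribution key
    "cfi": "cfi_min",
    "rmsea": "rmsea_max",
    "reliability": "rel_min",
    "tcc_sqsum": "tcc_sqsum",
    "tif_sqsum": "tif_sqsum",
    "sdtf": "sdtf_max",
    "udtf": "udtf_max",
}


@dataclass
class CriterionDistributions:
    """Criterion values across random parallel-triple replications.

    Failed replications hold NaN; ``sdtf`` stores the magnitude of the
    decisive signed DTF.
    """

    values: dict[str, np.ndarray]
    n_reps: int
    n_failed: int = 0
    grid_spec: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) != 1:
            raise ValueError("all criterion vectors must have the same length")
        if lengths.pop() != self.n_reps or self.n_reps < 1:
            raise ValueError("vectors must hold one value per replication (>= 1)")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def draw_uniform_triple(
    bank: ItemBank, n_forms: int, rng: np.random.Generator
) -> list[list[str]]:
    """One uniform coverage-respecting draw of ``n_forms`` disjoint forms."""
    forms: list[list[str]] = [[] for _ in range(n_forms)]
    for dom in bank.domains:
        pool = bank.domain_items(dom)
        picks = rng.choice(len(pool), size=n_forms, replace=False)
        for f, j in enumerate(picks):
            forms[f].append(pool[j])
    return forms


def sample_random_triples(
    bank: ItemBank,
    responses: ResponseData,
    n_reps: int,
    profile: CriterionProfile | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> CriterionDistributions:
    """Draw and fully score ``n_reps`` random parallel triples.

    Records, per replication, the decisive raw criteria (worst-form CFI,
    RMSEA, reliability, |sDTF|, uDTF and the cross-form TCC/TIF square
    sums).  Deterministic under ``seed``; failed fits are logged and kept
    as NaN.
    """
    profile = profile if profile is not None else default_profile()
    bank.check_coverage(profile.n_forms)
    rng = np.random.default_rng(seed)
    keys = [k for k in CRITERION_DIRECTIONS if k in profile.criteria]
    values = {k: np.full(n_reps, np.nan) for k in keys}
    n_failed = 0
    for r in range(n_reps):
        triple = draw_uniform_triple(bank, profile.n_forms, rng)
        ev = evaluate_forms(responses, triple, profile, **fit_kwargs)
        if ev.failed:
            n_failed += 1
            logger.warning("replication %d failed: %s", r, ev.failure_reason)
            continue
        for k in keys:
            v = ev.raw[_RAW_KEYS[k]]
            values[k][r] = abs(v) if k == "sdtf" else v
    if n_failed:
        logger.info("%d of %d replications failed and were dropped", n_failed, n_reps)
    return CriterionDistributions(
        values=values,
        n_reps=n_reps,
        n_failed=n_failed,
        grid_spec=profile.grid_spec,
        meta={"seed": seed, "n_items": len(bank)},
    )


def empirical_thresholds(
    dists: CriterionDistributions,
    percentile_map: dict[str, float] | None = None,
    template: CriterionProfile | None = None,
) -> CriterionProfile:
    """Percentile thresholds from the random-triple distributions.

    Default percentiles: 95th for maximize criteria, 5th for minimize
    (the favorable 5% tail in both cases); linear-interpolation percentile.
    Directions, slopes and weights come from the template profile.
    """
    template = template if template is not None else default_profile()
    if dists.n_reps - dists.n_failed < 20:
        warnings.warn(
            "fewer than 20 successful replications; thresholds will be noisy"
        )
    thresholds = {}
    for name, vec in dists.values.items():
        if name not in template.criteria:
            continue
        clean = vec[~np.isnan(vec)]
        if clean.size == 0:
            raise ValueError(f"criterion {name!r} has no successful replications")
        if percentile_map and name in percentile_map:
            pct = percentile_map[name]
        else:
            pct = 95.0 if CRITERION_DIRECTIONS[name] == "maximize" else 5.0
        thresholds[name] = float(np.percentile(clean, pct))
    prof = template.with_thresholds(thresholds)
    prof.grid_spec = dists.grid_spec or template.grid_spec
    return prof


def criterion_correlations(dists: CriterionDistributions) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between the criteria."""
    return dists.frame().corr(method="pearson", min_periods=2)


def slope_diagnostics(
    values: np.ndarray,
    threshold: float,
    candidate_slopes,
    direction: str,
    phi_cuts=(0.25, 0.5),
) -> pd.DataFrame:
    """Share of random models whose pheromone clears given cut levels.

    For each candidate slope, every distribution value is pushed through the
    logistic transform at the fixed threshold; the table reports the
    fraction of models with phi above each cut.  Steeper slopes concentrate
    reward near the threshold; flatter slopes keep borderline models in
    play.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    rows = []
    for slope in candidate_slopes:
        phi = logit_phi(values, threshold, float(slope), direction)
        row = {"slope": float(slope)}
        for cut in phi_cuts:
            row[f"frac_phi_above_{cut}"] = float(np.mean(phi > cut))
        rows.append(row)
    return pd.DataFrame(rows)


class ThresholdCalibrator(BaseEstimator):
    """Estimator wrapper around the random-sampling threshold calibration.

    Parameters mirror :func:`sample_random_triples`; ``fit`` draws and
    scores the random triples and exposes ``distributions_``,
    ``correlations_`` and the calibrated ``profile_``.
    """

    def __init__(
        self,
        bank: ItemBank = None,
        n_reps: int = 200,
        template: CriterionProfile | None = None,
        percentile_map: dict | None = None,
        seed: int = 0,
    ):
        self.bank = bank
        self.n_reps = n_reps
        self.template = template
        self.percentile_map = percentile_map
        self.seed = seed

    def fit(self, X: ResponseData, y=None):
        if self.bank is None:
            raise ValueError("a bank must be supplied at construction")
        template = self.template if self.template is not None else default_profile()
        self.distributions_ = sample_random_triples(
            self.bank, X, self.n_reps, template, seed=self.seed
        )
        self.correlations_ = criterion_correlations(self.distributions_)
        self.profile_ = empirical_thresholds(
            self.distributions_, self.percentile_map, template
        )
        return self


def plot_criterion_distributions(
    dists: CriterionDistributions,
    path,
    template: CriterionProfile | None = None,
    bins: int = 40,
) -> None:
    """Optional diagnostic: per-criterion histograms with percentile cutoffs.

    Writes one figure with a panel per criterion; the vertical line marks
    the favorable-tail percentile used as the threshold.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profile = empirical_thresholds(
        dists, template=template if template is not None else default_profile()
    )
    names = [n for n in dists.values if n in profile.criteria]
    ncol = 3
    nrow = -(-len(names) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, name in zip(axes.flat, names):
        clean = dists.values[name]
        clean = clean[~np.isnan(clean)]
        ax.hist(clean, bins=bins, color="steelblue", alpha=0.8)
        ax.axvline(profile.criteria[name].threshold, color="red")
        ax.set_title(name)
    for ax in axes.flat[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
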