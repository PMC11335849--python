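"""Logistic criterion transforms and their aggregation into a pheromone value.

Every raw assembly criterion (model fit, reliability, curve matching,
differential test functioning) is pushed through a logistic ("logit")
transform centred at a threshold so that all criteria live on a common
(0, 1) scale:

    maximize:  phi = 1 / (1 + exp(slope * (threshold - x)))
    minimize:  phi = 1 - 1 / (1 + exp(slope * (threshold - x)))

phi is exactly 0.5 when the raw value sits at the threshold, and the slope
controls how sharply quality drops off around it.  Component pheromones are
built from the decisive (worst-form) raw values:

    phi_fit  = (3 * phi_cfi + phi_rmsea) / 4        on CFI_min, RMSEA_max
    phi_rel  = logit(rel_min)
    phi_diff = logit(TCC_sqsum),  phi_prec = logit(TIF_sqsum)
    phi_dtf  = (phi_sdtf + phi_udtf) / 2            on |sDTF|_max, uDTF_max

and the overall pheromone is their (by default equal-) weighted mean.  The
shipped default profile carries thresholds .97 / .02 / .63 / 202 / 62 /
0.13 / 0.29 with slopes 100 / 100 / 100 / 0.025 / 0.08 / 25 / 25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .bank import ResponseData
from .dtf import DtfResult, dtf_result, fit_multigroup_2pl
from .irt import (
    CalibratedForm,
    CurveSet,
    ThetaGrid,
    TwoParameterLogistic,
    curve_set,
    curve_sqsum,
    eap_reliability,
    eap_scores,
    grid_from_spec,
)
from .model_fit import FitIndices, fit_indices

__all__ = [
    "CriterionSpec",
    "CriterionProfile",
    "FormEvaluation",
    "TripleEvaluation",
    "default_profile",
    "logit_phi",
    "phi_fit",
    "phi_rel",
    "phi_diff",
    "phi_prec",
    "phi_dtf",
    "phi_overall",
    "evaluate_triple",
    "evaluate_forms",
]


@dataclass(frozen=True)
class CriterionSpec:
    """One criterion's logistic transform: direction, inflection, steepness."""

    name: str
    direction: str  # "maximize" | "minimize"
    threshold: float
    slope: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"{self.name}: direction must be maximize or minimize")
        if self.slope <= 0:
            raise ValueError(f"{self.name}: slope must be positive")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be nonnegative")

    def phi(self, x: float) -> float:
        return logit_phi(x, self.threshold, self.slope, self.direction)


_COMPONENTS = ("fit", "reliability", "difficulty", "precision", "dtf")


@dataclass
class CriterionProfile:
    """All constants of the optimization function, plus the curve grid spec.

    ``criteria`` maps raw-criterion names (cfi, rmsea, reliability,
    tcc_sqsum, tif_sqsum, sdtf, udtf) to :class:`CriterionSpec`;
    ``component_weights`` weights the five component pheromones in the
    overall mean.  ``grid_spec`` records the theta grid the curve-sqsum
    thresholds were calibrated on — evaluating with a different grid is an
    error because those thresholds are grid-relative.
    """

    criteria: dict[str, CriterionSpec]
    component_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in _COMPONENTS}
    )
    n_forms: int = 3
    grid_spec: dict | None = None

    def __post_init__(self) -> None:
        if sum(self.component_weights.values()) <= 0:
            raise ValueError("component weights must sum to a positive value")
        if self.n_forms < 2:
            raise ValueError("at least two parallel forms are required")
        needs_grid = {"tcc_sqsum", "tif_sqsum"} & set(self.criteria)
        if needs_grid and self.grid_spec is None:
            raise ValueError(
                "grid_spec is required when curve-matching criteria are present"
            )

    @property
    def has_dtf(self) -> bool:
        return "sdtf" in self.criteria or "udtf" in self.criteria

    def grid(self) -> ThetaGrid:
        return grid_from_spec(self.grid_spec)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "criteria": {
                name: {
                    "direction": c.direction,
                    "threshold": c.threshold,
                    "slope": c.slope,
                    "weight": c.weight,
                }
                for name, c in self.criteria.items()
            },
            "component_weights": dict(self.component_weights),
            "n_forms": self.n_forms,
            "grid_spec": self.grid_spec,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionProfile":
        crits = {
            name: CriterionSpec(name=name, **spec) for name, spec in d["criteria"].items()
        }
        return cls(
            criteria=crits,
            component_weights=dict(d.get("component_weights", {c: 1.0 for c in _COMPONENTS})),
            n_forms=int(d.get("n_forms", 3)),
            grid_spec=d.get("grid_spec"),
        )

    def with_thresholds(self, thresholds: dict[str, float]) -> "CriterionProfile":
        crits = dict(self.criteria)
        for name, thr in thresholds.items():
            if name not in crits:
                raise KeyError(f"unknown criterion {name!r}")
            crits[name] = replace(crits[name], threshold=float(thr))
        return CriterionProfile(
            criteria=crits,
            component_weights=dict(self.component_weights),
            n_forms=self.n_forms,
            grid_spec=self.grid_spec,
        )


def default_profile(n_forms: int = 3, grid_spec: dict | None = None, with_dtf: bool = True) -> CriterionProfile:
    """The shipped default profile (thresholds/slopes listed in the module docstring)."""
    crits = {
        "cfi": CriterionSpec("cfi", "maximize", 0.97, 100.0, weight=3.0),
        "rmsea": CriterionSpec("rmsea", "minimize", 0.02, 100.0, weight=1.0),
        "reliability": CriterionSpec("reliability", "maximize", 0.63, 100.0),
        "tcc_sqsum": CriterionSpec("tcc_sqsum", "minimize", 202.0, 0.025),
        "tif_sqsum": CriterionSpec("tif_sqsum", "minimize", 62.0, 0.08),
    }
    weights = {"fit": 1.0, "reliability": 1.0, "difficulty": 1.0, "precision": 1.0}
    if with_dtf:
        crits["sdtf"] = CriterionSpec("sdtf", "minimize", 0.13, 25.0)
        crits["udtf"] = CriterionSpec("udtf", "minimize", 0.29, 25.0)
        weights["dtf"] = 1.0
    if grid_spec is None:
        grid_spec = {"n_nodes": 61, "lo": -6.0, "hi": 6.0}
    return CriterionProfile(criteria=crits, component_weights=weights, n_forms=n_forms, grid_spec=grid_spec)


# ---------------------------------------------------------------------------
# the logistic transform and component pheromones

def logit_phi(x: float, threshold: float, slope: float, direction: str) -> float:
    """Map a raw criterion value into (0, 1); exactly 0.5 at the threshold."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    z = slope * (np.asarray(x, dtype=float) - threshold)
    if direction == "maximize":
        out = expit(z)
    elif direction == "minimize":
        out = expit(-z)
    else:
        raise ValueError("direction must be 'maximize' or 'minimize'")
    return float(out) if np.isscalar(x) else out


def phi_fit(cfi_min: float, rmsea_max: float, profile: CriterionProfile) -> float:
    """Weighted model-fit pheromone from the worst CFI and worst RMSEA."""
    c, r = profile.criteria["cfi"], profile.criteria["rmsea"]
    return (c.weight * c.phi(cfi_min) + r.weight * r.phi(rmsea_max)) / (c.weight + r.weight)


def phi_rel(rel_min: float, profile: CriterionProfile) -> float:
    return profile.criteria["reliability"].phi(rel_min)


def phi_diff(tcc_sqsum: float, profile: CriterionProfile) -> float:
    return profile.criteria["tcc_sqsum"].phi(tcc_sqsum)


def phi_prec(tif_sqsum: float, profile: CriterionProfile) -> float:
    return profile.criteria["tif_sqsum"].phi(tif_sqsum)


def phi_dtf(sdtf_max: float, udtf_max: float, profile: CriterionProfile) -> float:
    """DTF pheromone from the worst |sDTF| and worst uDTF across forms."""
    s, u = profile.criteria["sdtf"], profile.criteria["udtf"]
    return (s.weight * s.phi(abs(sdtf_max)) + u.weight * u.phi(udtf_max)) / (
        s.weight + u.weight
    )


def phi_overall(components: dict[str, float], weights: dict[str, float] | None = None) -> float:
    """Weighted mean of the component pheromones (default equal weights)."""
    if weights is None:
        weights = {name: 1.0 for name in components}
    missing = set(weights) - set(components)
    if missing:
        raise KeyError(f"weights name unknown components: {sorted(missing)}")
    num = sum(weights[name] * components[name] for name in weights)
    den = sum(weights.values())
    if den <= 0:
        raise ValueError("weights must sum to a positive value")
    return num / den


# ---------------------------------------------------------------------------
# triple evaluation

@dataclass
class FormEvaluation:
    """Everything the criteria need from one fitted form."""

    form: CalibratedForm | None
    fit: FitIndices | None = None
    reliability: float = np.nan
    dtf: DtfResult | None = None
    failed: bool = False
    failure_reason: str | None = None


@dataclass
class TripleEvaluation:
    """Raw decisive criteria, component pheromones and the overall value."""

    item_sets: list[list[str]]
    raw: dict[str, float]
    components: dict[str, float]
    phi_overall: float
    phi_detail: dict[str, float] = field(default_factory=dict)
    per_form: list[dict] = field(default_factory=list)
    failed: bool = False
    failure_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "item_sets": [list(s) for s in self.item_sets],
            "raw": {k: float(v) for k, v in self.raw.items()},
            "components": {k: float(v) for k, v in self.components.items()},
            "phi_overall": float(self.phi_overall),
            "phi_detail": {k: float(v) for k, v in self.phi_detail.items()},
            "per_form": self.per_form,
            "failed": self.failed,
            "failure_reason": self.failure_reason,
        }


def _failed_triple(item_sets, reason: str) -> TripleEvaluation:
    return TripleEvaluation(
        item_sets=[list(s) for s in item_sets],
        raw={},
        components={},
        phi_overall=0.0,
        failed=True,
        failure_reason=reason,
    )


def evaluate_triple(
    form_evals: list[FormEvaluation],
    tcc_curves: CurveSet | None,
    tif_curves: CurveSet | None,
    profile: CriterionProfile,
    item_sets: list[list[str]] | None = None,
) -> TripleEvaluation:
    """Compose the overall pheromone from per-form and cross-form criteria.

    Decisive rules: the worst form decides each per-form criterion
    (min CFI, max RMSEA, min reliability, max |sDTF|, max uDTF); curve
    criteria are already cross-form.  Any failed form collapses the triple
    to phi_overall = 0.
    """
    if item_sets is None:
        item_sets = [
            list(fe.form.item_ids) if fe.form is not None else [] for fe in form_evals
        ]
    if len(form_evals) != profile.n_forms:
        raise ValueError(
            f"profile declares {profile.n_forms} forms, got {len(form_evals)}"
        )
    bad = [fe for fe in form_evals if fe.failed or fe.form is None or not fe.form.converged]
    if bad:
        return _failed_triple(item_sets, bad[0].failure_reason or "form estimation failed")

    raw = {
        "cfi_min": min(fe.fit.cfi for fe in form_evals),
        "rmsea_max": max(fe.fit.rmsea for fe in form_evals),
        "rel_min": min(fe.reliability for fe in form_evals),
        "tcc_sqsum": curve_sqsum(tcc_curves),
        "tif_sqsum": curve_sqsum(tif_curves),
    }
    detail = {
        "phi_cfi": profile.criteria["cfi"].phi(raw["cfi_min"]),
        "phi_rmsea": profile.criteria["rmsea"].phi(raw["rmsea_max"]),
    }
    components = {
        "fit": phi_fit(raw["cfi_min"], raw["rmsea_max"], profile),
        "reliability": phi_rel(raw["rel_min"], profile),
        "difficulty": phi_diff(raw["tcc_sqsum"], profile),
        "precision": phi_prec(raw["tif_sqsum"], profile),
    }
    if profile.has_dtf:
        if any(fe.dtf is None for fe in form_evals):
            return _failed_triple(item_sets, "profile requires DTF but none was computed")
        sdtf_vals = [fe.dtf.sdtf for fe in form_evals]
        raw["sdtf_max"] = max(sdtf_vals, key=abs)
        raw["udtf_max"] = max(fe.dtf.udtf for fe in form_evals)
        detail["phi_sdtf"] = profile.criteria["sdtf"].phi(abs(raw["sdtf_max"]))
        detail["phi_udtf"] = profile.criteria["udtf"].phi(raw["udtf_max"])
        components["dtf"] = phi_dtf(raw["sdtf_max"], raw["udtf_max"], profile)
    overall = phi_overall(components, profile.component_weights)
    per_form = []
    for fe in form_evals:
        rec = {
            "item_ids": list(fe.form.item_ids),
            "m2": float(fe.fit.m2),
            "df": int(fe.fit.df),
            "rmsea": float(fe.fit.rmsea),
            "cfi": float(fe.fit.cfi),
            "n": int(fe.fit.n_persons),
            "reliability": float(fe.reliability),
        }
        if fe.dtf is not None:
            rec.update(
                sdtf=float(fe.dtf.sdtf),
                udtf=float(fe.dtf.udtf),
                reference_level=fe.dtf.reference_level,
            )
        per_form.append(rec)
    return TripleEvaluation(
        item_sets=item_sets,
        raw=raw,
        components=components,
        phi_overall=overall,
        phi_detail=detail,
        per_form=per_form,
    )


def _evaluate_one_form(
    responses: ResponseData,
    items: list[str],
    profile: CriterionProfile,
    grid: ThetaGrid,
    anchor_items: list[str] | None,
    **fit_kwargs,
) -> FormEvaluation:
    sub = responses.subset(list(items))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = TwoParameterLogistic(grid=grid, **fit_kwargs).fit(
                sub, item_ids=list(items)
            )
            form = est.form_()
            if not form.converged:
                return FormEvaluation(
                    form=form, failed=True, failure_reason="non-convergence"
                )
            fit = fit_indices(form, sub.responses, grid)
            scores, sds = eap_scores(form, sub, grid)
            rel = eap_reliability(scores, sds)
            dtf = None
            if profile.has_dtf:
                cal = fit_multigroup_2pl(
                    sub,
                    grid=grid,
                    anchor_items=anchor_items,
                    start=(form.a_hat, form.b_hat),  # warm start from the pooled fit
                    **fit_kwargs,
                )
                if not (cal.reference.converged and cal.focal.converged):
                    return FormEvaluation(
                        form=form, failed=True, failure_reason="group non-convergence"
                    )
                dtf = dtf_result(cal, grid)
    except (ValueError, KeyError) as exc:
        return FormEvaluation(form=None, failed=True, failure_reason=str(exc))
    return FormEvaluation(form=form, fit=fit, reliability=rel, dtf=dtf)


def evaluate_forms(
    responses: ResponseData,
    item_sets: list[list[str]],
    profile: CriterionProfile,
    anchor_items: list[str] | None = None,
    form_cache: dict | None = None,
    **fit_kwargs,
) -> TripleEvaluation:
    """Fit and score a candidate set of parallel forms end to end.

    For each form: pooled 2PL fit, M2-based CFI/RMSEA, EAP reliability and
    (when the profile carries DTF criteria) a two-group calibration with
    sDTF/uDTF.  Estimation failures are absorbed into phi_overall = 0.
    ``form_cache`` (keyed by the sorted item tuple) lets a search loop reuse
    per-form results across candidate triples.
    """
    grid = profile.grid()
    ids = set()
    for s in item_sets:
        overlap = ids & set(s)
        if overlap:
            raise ValueError(f"forms overlap on items {sorted(overlap)}")
        ids |= set(s)
    form_evals: list[FormEvaluation] = []
    for items in item_sets:
        key = tuple(sorted(items))
        if form_cache is not None and key in form_cache:
            fe = form_cache[key]
        else:
            fe = _evaluate_one_form(
                responses, list(items), profile, grid, anchor_items, **fit_kwargs
            )
            if form_cache is not None:
                form_cache[key] = fe
        form_evals.append(fe)
    if any(fe.failed or fe.form is None for fe in form_evals):
        reason = next(
            (fe.failure_reason for fe in form_evals if fe.failure_reason),
            "form estimation failed",
        )
        return _failed_triple(item_sets, reason)
    forms = [fe.form for fe in form_evals]
    tcc_curves = curve_set(forms, grid, "tcc")
    tif_curves = curve_set(forms, grid, "tif")
    return evaluate_triple(form_evals, tcc_curves, tif_curves, profile, item_sets=item_sets)
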