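"""Differential test functioning (DTF) between two examinee groups.

Item parameters are calibrated separately in a reference and a focal group
and the gap between the two test characteristic curves is integrated over
the focal ability distribution:

    sDTF = integral [ TCC_ref(theta) - TCC_focal(theta) ] f(theta) dtheta
    uDTF = integral | TCC_ref(theta) - TCC_focal(theta) | f(theta) dtheta

Both are in raw score points (0 .. n_items).  sDTF signals a net scoring
bias; uDTF also picks up bias that cancels across the ability range, so
uDTF >= |sDTF| always.

Identification: by default both groups' latent distributions are fixed to
N(0, 1) with all item parameters free.  This confounds true group-mean
differences (impact) with DTF, but makes the measure the observable
expected-score gap, which is the operational quantity for fairness-driven
test assembly.  An anchored variant (focal mean/SD estimated, user-named
anchor items fixed to the reference estimates) is available via
``anchor_items``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import ResponseData
from .irt import CalibratedForm, ThetaGrid, TwoParameterLogistic, default_grid, tcc

__all__ = ["GroupCalibration", "DtfResult", "fit_multigroup_2pl", "sdtf", "udtf", "dtf_result"]


@dataclass
class GroupCalibration:
    """Per-group 2PL calibrations of the same form."""

    reference: CalibratedForm
    focal: CalibratedForm
    focal_mean: float = 0.0
    focal_sd: float = 1.0
    reference_level: object = None
    focal_level: object = None

    def __post_init__(self) -> None:
        if list(self.reference.item_ids) != list(self.focal.item_ids):
            raise ValueError("reference and focal forms must share item_ids")
        if self.focal_sd <= 0:
            raise ValueError("focal_sd must be positive")


@dataclass
class DtfResult:
    """Signed and unsigned DTF in raw score points."""

    sdtf: float
    udtf: float
    reference_level: object = None

    def __post_init__(self) -> None:
        if self.udtf < 0 or self.udtf < abs(self.sdtf) - 1e-9:
            raise ValueError("requires udtf >= |sdtf| >= 0")


def fit_multigroup_2pl(
    responses: ResponseData,
    grid: ThetaGrid | None = None,
    anchor_items: list[str] | None = None,
    reference_level=None,
    start=None,
    **fit_kwargs,
) -> GroupCalibration:
    """Calibrate a form separately in the reference and focal groups.

    The first level of ``responses.group_levels`` (or ``reference_level``)
    is the reference.  Without anchors, both groups use a fixed N(0, 1)
    prior.  With ``anchor_items``, the named items' focal parameters are
    fixed to the reference estimates and the focal latent mean/SD are
    estimated.
    """
    grid = grid if grid is not None else default_grid()
    if responses.group is None:
        raise ValueError("responses carry no group labels")
    levels = list(responses.group_levels)
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, found {levels}")
    if reference_level is not None:
        if reference_level not in levels:
            raise ValueError(f"{reference_level!r} is not a group level")
        levels = [reference_level] + [l for l in levels if l != reference_level]
    ref_lvl, foc_lvl = levels
    mats = {lvl: responses.responses[responses.group == lvl] for lvl in levels}

    for lvl, mat in mats.items():
        props = mat.mean(axis=0) if len(mat) else np.array([])
        bad = np.where((props == 0) | (props == 1))[0]
        if len(mat) == 0 or bad.size:
            names = [responses.item_ids[j] for j in bad]
            raise ValueError(
                f"group {lvl!r} lacks both response categories on items {names or 'all'}"
            )

    ref_est = TwoParameterLogistic(grid=grid, **fit_kwargs).fit(
        mats[ref_lvl], item_ids=responses.item_ids, start=start
    )
    fixed = None
    estimate_prior = False
    if anchor_items:
        idx = {iid: j for j, iid in enumerate(responses.item_ids)}
        missing = [a for a in anchor_items if a not in idx]
        if missing:
            raise KeyError(f"anchor items not on this form: {missing}")
        fixed = {idx[a]: (ref_est.a_[idx[a]], ref_est.b_[idx[a]]) for a in anchor_items}
        estimate_prior = True
    foc_est = TwoParameterLogistic(
        grid=grid, estimate_prior=estimate_prior, **fit_kwargs
    ).fit(mats[foc_lvl], item_ids=responses.item_ids, fixed=fixed, start=start)

    return GroupCalibration(
        reference=ref_est.form_(),
        focal=foc_est.form_(),
        focal_mean=foc_est.prior_mean_,
        focal_sd=foc_est.prior_sd_,
        reference_level=ref_lvl,
        focal_level=foc_lvl,
    )


def _tcc_gap(cal: GroupCalibration, grid: ThetaGrid):
    gap = tcc(cal.reference, grid) - tcc(cal.focal, grid)
    w = grid.normal_weights(cal.focal_mean, cal.focal_sd)
    return gap, w


def sdtf(cal: GroupCalibration, grid: ThetaGrid | None = None) -> float:
    """Signed DTF: focal-density-weighted mean of TCC_ref - TCC_focal."""
    grid = grid if grid is not None else default_grid()
    gap, w = _tcc_gap(cal, grid)
    return float(gap @ w)


def udtf(cal: GroupCalibration, grid: ThetaGrid | None = None) -> float:
    """Unsigned DTF: focal-density-weighted mean of |TCC_ref - TCC_focal|."""
    grid = grid if grid is not None else default_grid()
    gap, w = _tcc_gap(cal, grid)
    return float(np.abs(gap) @ w)


def dtf_result(cal: GroupCalibration, grid: ThetaGrid | None = None) -> DtfResult:
    grid = grid if grid is not None else default_grid()
    return DtfResult(
        sdtf=sdtf(cal, grid), udtf=udtf(cal, grid), reference_level=cal.reference_level
    )
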