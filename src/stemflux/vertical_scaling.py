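"""Vertical variation of stem CO2 efflux along trees.

EA measured at several heights per tree is modelled with a linear mixed
model,

    EA ~ intercept + b * log(height) + buttress + above_branch + (1 | tree),

where the position classes (stem reference; buttress; above the first major
branching point) carry additive offsets and the tree-level random intercept
absorbs between-tree baseline differences.  Fitting is by REML.  The fitted
model is then applied to every cylinder of a QSM (at its midpoint height,
with its position class) to predict a per-cylinder efflux rate for
stand-level upscaling; predictions are population-level (random intercept
zero) because upscaling covers unsampled trees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .surface_area import Cylinder, QSMTree, TreeRecord

POSITIONS = ("stem", "buttress", "above_branch")


@dataclass(frozen=True)
class PositionRules:
    """Rules mapping QSM geometry to position classes.

    major_branch_ratio : a child cylinder whose radius is at least this
        fraction of its parent's marks the first major branching point.
    buttress_top_height : trunk below this height counts as buttress on
        buttressed trees (m).
    min_height_floor : lower bound on height entering log() (m).
    """

    major_branch_ratio: float = 0.5
    buttress_top_height: float = 3.0
    min_height_floor: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.major_branch_ratio <= 1):
            raise ValueError("major_branch_ratio must be in (0, 1]")
        if self.buttress_top_height <= 0 or self.min_height_floor <= 0:
            raise ValueError("heights must be positive")


@dataclass
class VerticalModelFit:
    """Fitted vertical EA model (units mg C m^-2 h^-1 unless noted).

    Fixed effects absent from the data are ``None`` (absent, not zero);
    standard errors are ``nan`` for synthetic truth objects that were never
    fit to data.
    """

    intercept: float
    log_height_slope: float | None
    buttress_effect: float | None
    above_branch_effect: float | None
    random_intercept_sd: float = 0.0
    residual_sd: float = 0.0
    n_obs: int = 0
    n_trees: int = 0
    intercept_se: float = float("nan")
    log_height_slope_se: float = float("nan")
    buttress_effect_se: float = float("nan")
    above_branch_effect_se: float = float("nan")
    aic: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be >= 0")

    def position_effect(self, position: str) -> float:
        if position == "stem":
            return 0.0
        eff = {"buttress": self.buttress_effect,
               "above_branch": self.above_branch_effect}.get(position)
        if eff is None:
            raise ValueError(f"no effect estimated for position {position!r}")
        return eff

    def confidence_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """t-based CIs for the fixed effects, df = n_trees - 1 (between-tree
        information governs small-sample behaviour with a random intercept)."""
        df = max(self.n_trees - 1, 1)
        tcrit = stats.t.ppf(0.5 + level / 2.0, df)
        out = {}
        for name in ("intercept", "log_height_slope",
                     "buttress_effect", "above_branch_effect"):
            est = getattr(self, name)
            se = getattr(self, f"{name}_se")
            if est is not None and np.isfinite(se):
                out[name] = (est - tcrit * se, est + tcrit * se)
        return out


def _trunk_path(tree: QSMTree) -> list[Cylinder]:
    """Follow the trunk from the root: at each node the largest-radius child
    continues the trunk."""
    children: dict[int, list[Cylinder]] = {}
    for c in tree.cylinders:
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c)
    path = [tree.root]
    seen = {tree.root.cyl_id}
    while True:
        kids = children.get(path[-1].cyl_id, [])
        kids = [k for k in kids if k.cyl_id not in seen]
        if not kids:
            return path
        nxt = max(kids, key=lambda c: c.radius_m)
        path.append(nxt)
        seen.add(nxt.cyl_id)


def first_major_branch_height(tree: QSMTree, rules: PositionRules) -> float:
    """Base height of the lowest major branching point, or +inf if none.

    A branching point is major when, among the children of a trunk cylinder,
    a non-continuation child has radius >= major_branch_ratio times the
    parent's radius.
    """
    children: dict[int, list[Cylinder]] = {}
    for c in tree.cylinders:
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c)
    best = math.inf
    for cyl in _trunk_path(tree):
        kids = sorted(children.get(cyl.cyl_id, []),
                      key=lambda c: c.radius_m, reverse=True)
        if len(kids) < 2:
            continue
        # kids[0] continues the trunk; any other major child defines a split
        for k in kids[1:]:
            if k.radius_m >= rules.major_branch_ratio * cyl.radius_m:
                best = min(best, k.base_height_m)
                break
    return best


def classify_cylinders(tree: QSMTree, record: TreeRecord,
                       rules: PositionRules = PositionRules()) -> QSMTree:
    """Assign each cylinder exactly one position class.

    Trunk cylinders below ``buttress_top_height`` on buttressed trees are
    ``buttress``; cylinders based at or above the first major branching
    point (branches included) are ``above_branch``; everything else is
    ``stem``.  Returns a new QSMTree; the input is not modified.
    """
    branch_h = first_major_branch_height(tree, rules)
    trunk_ids = {c.cyl_id for c in _trunk_path(tree)}
    out = []
    for c in tree.cylinders:
        if (record.buttressed and c.cyl_id in trunk_ids
                and c.base_height_m < rules.buttress_top_height):
            pos = "buttress"
        elif c.base_height_m >= branch_h:
            pos = "above_branch"
        else:
            pos = "stem"
        out.append(replace(c, position=pos))
    return QSMTree(tag=tree.tag, cylinders=out, sa_sd=tree.sa_sd)


def fit_vertical_model(obs: pd.DataFrame,
                       rules: PositionRules = PositionRules(),
                       ea_col: str = "ea") -> VerticalModelFit:
    """Fit the vertical EA mixed model by REML.

    ``obs`` columns: tree_tag, height_m, position (stem | buttress |
    above_branch) and the EA column.  Position classes absent from the data
    get ``None`` effects; a height covariate with no variation leaves the
    slope ``None`` (unidentifiable) and fits an intercept-only model.
    """
    if obs["tree_tag"].nunique() < 2:
        raise ValueError("need observations from at least 2 trees")
    if (obs["height_m"] <= 0).any():
        raise ValueError("heights must be positive")
    unknown = set(obs["position"]) - set(POSITIONS)
    if unknown:
        raise ValueError(f"unknown position classes: {unknown}")

    log_h = np.log(np.maximum(obs["height_m"].to_numpy(float),
                              rules.min_height_floor))
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    slope_identifiable = np.ptp(log_h) > 1e-12
    if slope_identifiable:
        cols.append(log_h)
        names.append("log_height_slope")
    present = [p for p in ("buttress", "above_branch") if (obs["position"] == p).any()]
    for p in present:
        cols.append((obs["position"] == p).to_numpy(float))
        names.append(f"{p}_effect")
    exog = np.column_stack(cols)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(obs[ea_col].to_numpy(float), exog,
                           groups=obs["tree_tag"].to_numpy())
        res = model.fit(reml=True)

    est = dict(zip(names, res.params[: len(names)]))
    se = dict(zip(names, res.bse[: len(names)]))
    return VerticalModelFit(
        intercept=float(est["intercept"]),
        log_height_slope=float(est["log_height_slope"]) if slope_identifiable else None,
        buttress_effect=float(est["buttress_effect"]) if "buttress_effect" in est else None,
        above_branch_effect=(float(est["above_branch_effect"])
                             if "above_branch_effect" in est else None),
        random_intercept_sd=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(max(res.scale, 0.0))),
        n_obs=len(obs), n_trees=obs["tree_tag"].nunique(),
        intercept_se=float(se["intercept"]),
        log_height_slope_se=float(se.get("log_height_slope", np.nan)),
        buttress_effect_se=float(se.get("buttress_effect", np.nan)),
        above_branch_effect_se=float(se.get("above_branch_effect", np.nan)),
        aic=float(res.aic) if res.aic is not None else float("nan"),
        converged=bool(res.converged),
    )


def predict_cylinder_ea(fit: VerticalModelFit, cylinder: Cylinder,
                        rules: PositionRules = PositionRules()) -> float:
    """Population-level EA prediction (mg C m^-2 h^-1) for one cylinder.

    Height is the cylinder midpoint (base + length/2), floored at
    ``min_height_floor`` so log() stays finite at the tree base; negative
    predictions are floored at 0.
    """
    if cylinder.position is None:
        raise ValueError("cylinder has no position; run classify_cylinders first")
    h = max(cylinder.base_height_m + cylinder.length_m / 2.0,
            rules.min_height_floor)
    slope = fit.log_height_slope if fit.log_height_slope is not None else 0.0
    pred = fit.intercept + slope * math.log(h) + fit.position_effect(cylinder.position)
    return max(pred, 0.0)


def predict_tree_ea(fit: VerticalModelFit, tree: QSMTree, record: TreeRecord,
                    rules: PositionRules = PositionRules(),
                    truncation_diameter_m: float = 0.0) -> pd.DataFrame:
    """Per-cylinder EA predictions and areas for one tree.

    Returns columns cyl_id, position, height_m, area_m2,
    ea_mgc_m2_h, ea_mgc_h (rate times area); cylinders below the truncation
    diameter are excluded.
    """
    classified = classify_cylinders(tree, record, rules)
    rows = []
    for c in classified.cylinders:
        if 2.0 * c.radius_m < truncation_diameter_m:
            continue
        rate = predict_cylinder_ea(fit, c, rules)
        rows.append({
            "cyl_id": c.cyl_id, "position": c.position,
            "height_m": c.base_height_m + c.length_m / 2.0,
            "area_m2": c.lateral_area,
            "ea_mgc_m2_h": rate, "ea_mgc_h": rate * c.lateral_area,
        })
    return pd.DataFrame(rows)
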