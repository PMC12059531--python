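"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of a 1-ha old-growth tropical forest
plot campaign: a census of ~400 stems (DBH 10-210 cm, a truncated power-law
size distribution, ~1/6 buttressed), QSM cylinder models for a scanned
subset, closed-chamber concentration series inverted exactly from known
fluxes, vertical EA profiles on 13 climbed trees (4-7 heights each, stem /
buttress / above-branch classes), and hourly diel EA series on 18 trees
with battery-limited 11-22 h continuous runs and heterogeneous per-tree
amplitude and phase.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flux_core import GAS_CONSTANT, ChamberSpec, ConcentrationSeries
from .surface_area import (DEFAULT_HEIGHT_CORRECTION, DEFAULT_SITE_HEIGHT_MODEL,
                           Cylinder, HeightModel, QSMTree, TreeRecord,
                           allometric_surface_area as _chambers_sa,
                           qsm_surface_area)
from .vertical_scaling import PositionRules, VerticalModelFit


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class DielPatternSpec:
    """Per-tree diel cycle specification.

    Baseline EA per tree is lognormal around ``baseline_mean``; each tree's
    cycle is baseline * (1 + amplitude * cos(2 pi (hour - phase)/24)), with
    amplitude and phase drawn per tree so some trees peak and others dip in
    the afternoon.  An optional common depression (smooth bump centred in
    ``depression_window``) multiplies all trees' fluxes, emulating a shared
    afternoon drawdown.  Observations come in ``n_runs`` continuous runs of
    11-22 h within a 48-h campaign, mimicking battery-limited logging.
    """

    baseline_mean: float = 59.30          # mg C m^-2 h^-1, campaign mean
    baseline_log_sd: float = 0.5
    amplitude_range: tuple[float, float] = (0.05, 0.35)
    noise_frac: float = 0.12              # residual SD as fraction of baseline
    depression_window: tuple[int, int] | None = None
    depression_depth: float = 0.0         # fractional flux reduction at centre
    hours_total: int = 48
    run_length_range: tuple[int, int] = (11, 22)
    n_runs: int = 2

    @classmethod
    def null(cls, **kw) -> "DielPatternSpec":
        """Flat cycles: no diel signal at all (type-I error studies)."""
        return cls(amplitude_range=(0.0, 0.0), depression_depth=0.0, **kw)

    @classmethod
    def common_depression(cls, window: tuple[int, int] = (15, 19),
                          depth: float = 0.5, **kw) -> "DielPatternSpec":
        """Heterogeneous per-tree cycles sharing an afternoon depression.

        Individual amplitudes and phases stay random (mixed peaks and dips,
        as observed in the field), so only the shared depression departs
        consistently from the daily mean across the cohort.
        """
        return cls(depression_window=window, depression_depth=depth, **kw)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic plot.

    Defaults reproduce the campaign's scale: 397 census stems, 66
    buttressed, 190 scanned, 13 vertical-profile trees, 18 diel trees, a
    site height model h = 14.779 ln(DBH) - 24.546, and a vertical truth
    with no height trend but positive buttress and above-branch offsets
    around a 95.77 mg C m^-2 h^-1 breast-height rate.
    """

    n_trees: int = 397
    dbh_range: tuple[float, float] = (10.0, 210.0)
    dbh_power: float = 2.2                # P(DBH>50) ~ 0.12, matching census
    buttress_fraction: float = 66.0 / 397.0
    height_model: HeightModel = field(
        default_factory=lambda: DEFAULT_SITE_HEIGHT_MODEL)
    height_noise_sd: float = 4.0          # m; gives R^2 ~ 0.75-0.8
    min_height: float = 5.0
    n_qsm_trees: int = 190
    sa_sd_fraction: float = 0.05          # QSM-refit spread as fraction of SA
    # observed TLS area structure: total ~1.669x the diameter-only allometry
    # (tall-site correction), ~40% of it in sub-2-cm cylinders
    crown_area_ratio: float = DEFAULT_HEIGHT_CORRECTION
    crown_area_log_sd: float = 0.1
    fine_area_fraction: tuple[float, float] = (0.35, 0.45)
    vertical_truth: VerticalModelFit = field(default_factory=lambda: VerticalModelFit(
        intercept=95.77, log_height_slope=0.0,
        buttress_effect=40.0, above_branch_effect=30.0,
        random_intercept_sd=10.0, residual_sd=5.0))
    n_vertical_trees: int = 13
    vertical_heights_range: tuple[int, int] = (4, 7)
    n_diel_trees: int = 18
    diel: DielPatternSpec = field(default_factory=DielPatternSpec)
    chamber_noise_sd: float = 0.5         # umol mol^-1 on CO2 samples
    seed: int = 0


# ---------------------------------------------------------------------------
# census

def generate_census(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Census table: tag, dbh_cm, height_m, species, buttressed.

    DBH follows a truncated power-law (inverse-CDF sampling); heights are
    the site model prediction plus Gaussian noise, floored at
    ``min_height``.
    """
    rng = _rng(config.seed if rng is None else rng)
    lo, hi = config.dbh_range
    a = config.dbh_power
    u = rng.uniform(size=config.n_trees)
    dbh = (lo ** (1 - a) + u * (hi ** (1 - a) - lo ** (1 - a))) ** (1 / (1 - a))
    height = np.maximum(
        config.height_model.predict(dbh) + config.height_noise_sd
        * rng.standard_normal(config.n_trees),
        config.min_height)
    buttressed = rng.uniform(size=config.n_trees) < config.buttress_fraction
    return pd.DataFrame({
        "tag": [f"T{i:04d}" for i in range(config.n_trees)],
        "dbh_cm": dbh, "height_m": height,
        "species": "synthetic", "buttressed": buttressed,
    })


def census_records(census: pd.DataFrame) -> dict[str, TreeRecord]:
    """Census DataFrame -> {tag: TreeRecord}."""
    return {row.tag: TreeRecord(tag=row.tag, dbh=row.dbh_cm, height=row.height_m,
                                species=row.species, buttressed=bool(row.buttressed))
            for row in census.itertuples()}


# ---------------------------------------------------------------------------
# QSM cylinders

def generate_qsm(record: TreeRecord, config: SyntheticConfig,
                 rng: np.random.Generator | None = None,
                 pole: bool = False) -> QSMTree:
    """A cylinder model whose area structure emulates scanned tropical trees.

    The bole is built geometrically (tapered 1-m segments from DBH to tree
    top, with a basal flare on buttressed trees).  Branch and twig area are
    then calibrated so that the tree reproduces the observed TLS
    relationships: total cylinder area about ``crown_area_ratio`` times the
    diameter-only allometric prediction, with ``fine_area_fraction`` of the
    total in sub-2-cm cylinders (so the 2-cm truncation removes a realistic
    share).  Cylinder counts are far below a real QSM's; the twig cylinders
    are area-equivalent bundles, not individual twigs.

    ``pole=True`` builds a bare untapered trunk (no branches): its surface
    area is exactly pi * D * H, a closed-form check on the geometry.
    """
    rng = _rng(config.seed if rng is None else rng)
    height = record.height if record.height else config.height_model.predict(record.dbh)
    height = max(height, config.min_height)
    r_dbh = record.dbh / 200.0  # cm diameter -> m radius
    n_seg = max(int(round(height)), 3)
    seg = height / n_seg

    def trunk_radius(h: float) -> float:
        if pole:
            return r_dbh
        r = r_dbh * (1.0 - 0.7 * (h / height) ** 1.5)
        if record.buttressed and h < 2.5:
            r *= 1.0 + 0.5 * (1.0 - h / 2.5)  # basal flare
        return max(r, 0.005)

    cyls: list[Cylinder] = []
    next_id = 0
    for i in range(n_seg):
        base = i * seg
        cyls.append(Cylinder(cyl_id=next_id, parent_id=None if i == 0 else next_id - 1,
                             branch_order=0, radius_m=trunk_radius(base + seg / 2),
                             length_m=seg, base_height_m=base))
        next_id += 1
    if pole:
        tree = QSMTree(tag=record.tag, cylinders=cyls, sa_sd=0.0)
        return replace(tree, sa_sd=config.sa_sd_fraction * qsm_surface_area(tree))

    trunk_area = sum(c.lateral_area for c in cyls)
    target_total = (config.crown_area_ratio * _chambers_sa(record.dbh)
                    * math.exp(rng.normal(0.0, config.crown_area_log_sd)))
    fine_frac = rng.uniform(*config.fine_area_fraction)
    target_fine = fine_frac * target_total
    target_branch = max(target_total - target_fine - trunk_area,
                        0.05 * trunk_area)

    # first major branch at 55-80% of height; its cylinders carry the
    # coarse (>= 2 cm) branch area
    branch_frac = rng.uniform(0.55, 0.80)
    attach = cyls[min(int(branch_frac * n_seg), n_seg - 1)]
    parent_id, base_h = attach.cyl_id, attach.base_height_m
    n_branch = 4
    r_branch = max(0.6 * attach.radius_m, 0.011)
    lengths = target_branch / (2.0 * math.pi * r_branch * n_branch)
    branch_ids = []
    for j in range(n_branch):
        cyls.append(Cylinder(cyl_id=next_id, parent_id=parent_id, branch_order=1,
                             radius_m=r_branch * (1.0 - 0.1 * j),
                             length_m=float(lengths * (1.0 + 0.1 * j)),
                             base_height_m=base_h))
        branch_ids.append(next_id)
        parent_id = next_id
        base_h += 0.5 * lengths
        next_id += 1

    # sub-2-cm twig bundles spread along the branch
    n_fine = 6
    for k in range(n_fine):
        r = float(rng.uniform(0.006, 0.0095))
        length = target_fine / n_fine / (2.0 * math.pi * r)
        parent = branch_ids[k % len(branch_ids)]
        p = next(c for c in cyls if c.cyl_id == parent)
        cyls.append(Cylinder(cyl_id=next_id, parent_id=parent, branch_order=2,
                             radius_m=r, length_m=length,
                             base_height_m=p.base_height_m + 0.3))
        next_id += 1

    tree = QSMTree(tag=record.tag, cylinders=cyls, sa_sd=0.0)
    sa = qsm_surface_area(tree, 0.0)
    return replace(tree, sa_sd=config.sa_sd_fraction * sa)


def generate_plot(config: SyntheticConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[pd.DataFrame, list[QSMTree]]:
    """Census plus QSMs for the scanned subset (largest-first, as big trees
    segment most reliably)."""
    rng = _rng(config.seed if rng is None else rng)
    census = generate_census(config, rng)
    records = census_records(census)
    scanned = census.sort_values("dbh_cm", ascending=False).head(config.n_qsm_trees)
    trees = [generate_qsm(records[tag], config, rng) for tag in scanned["tag"]]
    return census, trees


# ---------------------------------------------------------------------------
# chamber concentration series

def invert_flux_to_slope(true_flux: float, chamber: ChamberSpec,
                         p0_kpa: float = 101.325, w0_mmol_mol: float = 10.0,
                         t0_c: float = 25.0) -> float:
    """Exact algebraic inversion of the chamber flux equation: the CO2 slope
    (umol mol^-1 s^-1) that yields ``true_flux`` under the given state."""
    return (true_flux * GAS_CONSTANT * chamber.collar_area_cm2 * (t0_c + 273.15)
            / (10.0 * chamber.system_volume_cm3 * p0_kpa
               * (1.0 - w0_mmol_mol / 1000.0)))


def generate_chamber_series(true_flux: float, chamber: ChamberSpec,
                            noise_sd: float = 0.5,
                            rng: np.random.Generator | int | None = None,
                            c0: float = 420.0, p0_kpa: float = 101.325,
                            w0_mmol_mol: float = 10.0, t0_c: float = 25.0,
                            dt_s: float = 1.0) -> ConcentrationSeries:
    """Concentration series whose noiseless slope recovers ``true_flux``
    exactly (round-trip identity)."""
    if true_flux < 0:
        raise ValueError("true_flux must be >= 0")
    rng = _rng(rng)
    slope = invert_flux_to_slope(true_flux, chamber, p0_kpa, w0_mmol_mol, t0_c)
    t = np.arange(0.0, chamber.closure_duration_s + dt_s / 2, dt_s)
    co2 = c0 + slope * t + noise_sd * rng.standard_normal(t.size)
    return ConcentrationSeries(t, np.maximum(co2, 0.0),
                               h2o_mmol_mol=w0_mmol_mol,
                               pressure_kpa=p0_kpa, temp_c=t0_c)


def analytic_slope_se(chamber: ChamberSpec, noise_sd: float,
                      dt_s: float = 1.0) -> float:
    """OLS slope standard error for i.i.d. Gaussian noise on the
    post-dead-band samples: noise_sd / sqrt(sum (t - tbar)^2)."""
    t = np.arange(0.0, chamber.closure_duration_s + dt_s / 2, dt_s)
    t = t[t >= chamber.dead_band_s]
    return noise_sd / math.sqrt(float(np.sum((t - t.mean()) ** 2)))


def generate_chamber_closures(true_fluxes: dict[str, float], chamber: ChamberSpec,
                              noise_sd: float = 0.5,
                              rng: np.random.Generator | int | None = None
                              ) -> pd.DataFrame:
    """Long-format closure table (one series per tree) for
    :func:`stemflux.flux_core.process_closures`."""
    rng = _rng(rng)
    frames = []
    for i, (tag, flux) in enumerate(true_fluxes.items()):
        s = generate_chamber_series(flux, chamber, noise_sd, rng)
        frames.append(pd.DataFrame({
            "closure_id": f"c{i:04d}", "tree_tag": tag, "time_s": s.time_s,
            "co2_umol_mol": s.co2_umol_mol, "h2o_mmol_mol": s.h2o_mmol_mol,
            "pressure_kpa": s.pressure_kpa, "temp_c": s.temp_c,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# vertical EA observations

def select_vertical_trees(census: pd.DataFrame, config: SyntheticConfig) -> list[str]:
    """Pick the climbed trees: large stems, buttressed ones first so the
    buttress class is represented (as in the field campaign)."""
    big = census[census["dbh_cm"] >= 40.0]
    if len(big) < config.n_vertical_trees:
        big = census
    ordered = big.sort_values(["buttressed", "dbh_cm"], ascending=[False, False])
    return ordered["tag"].head(config.n_vertical_trees).tolist()


def generate_vertical_observations(records: list[TreeRecord],
                                   truth: VerticalModelFit,
                                   config: SyntheticConfig,
                                   rng: np.random.Generator | int | None = None,
                                   rules: PositionRules = PositionRules()
                                   ) -> pd.DataFrame:
    """Vertical profiles: 4-7 heights per tree, ~5 or ~10 m apart.

    The lowest observation on a buttressed tree sits on the buttress; every
    second tree gets a topmost above-branch observation, so all three
    position classes are present at the campaign's design size.  EA is the
    truth surface plus a tree random intercept and residual noise.
    """
    rng = _rng(config.seed if rng is None else rng)
    lo_n, hi_n = config.vertical_heights_range
    rows = []
    for i, rec in enumerate(records):
        b_tree = truth.random_intercept_sd * rng.standard_normal()
        n_h = int(rng.integers(lo_n, hi_n + 1))
        top = 0.85 * (rec.height or 40.0)
        spacing = 5.0 if top <= 35.0 else 10.0
        heights = 1.1 + spacing * np.arange(n_h) \
            + rng.uniform(-1.0, 1.0, n_h)
        heights = np.clip(heights, 0.3, top)
        heights = np.sort(heights)
        for j, h in enumerate(heights):
            if rec.buttressed and j == 0:
                pos = "buttress"
                h = float(min(h, rules.buttress_top_height - 0.5))
            elif i % 2 == 0 and j == n_h - 1:
                pos = "above_branch"
            else:
                pos = "stem"
            slope = truth.log_height_slope or 0.0
            ea = (truth.intercept + slope * math.log(max(h, rules.min_height_floor))
                  + truth.position_effect(pos) + b_tree
                  + truth.residual_sd * rng.standard_normal())
            rows.append({"tree_tag": rec.tag, "height_m": h, "position": pos,
                         "ea": ea, "temp_c": 25.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diel EA observations

def _depression_factor(hour: np.ndarray, spec: DielPatternSpec) -> np.ndarray:
    if spec.depression_window is None or spec.depression_depth == 0.0:
        return np.ones_like(hour)
    lo, hi = spec.depression_window
    centre = (lo + hi) / 2.0
    width_sd = max((hi - lo) / 2.0, 1.0) * 0.72  # bump ~ covers the window
    d = np.minimum(np.abs(hour - centre), 24.0 - np.abs(hour - centre))
    return 1.0 - spec.depression_depth * np.exp(-0.5 * (d / width_sd) ** 2)


def generate_diel_observations(config: SyntheticConfig,
                               rng: np.random.Generator | int | None = None
                               ) -> pd.DataFrame:
    """Hourly diel EA with gaps: tree_tag, hour (0-24), time_h, ea."""
    rng = _rng(config.seed if rng is None else rng)
    spec = config.diel
    rows = []
    for i in range(config.n_diel_trees):
        tag = f"D{i:02d}"
        baseline = spec.baseline_mean * math.exp(
            spec.baseline_log_sd * rng.standard_normal()
            - spec.baseline_log_sd ** 2 / 2.0)
        amp = rng.uniform(*spec.amplitude_range)
        phase = rng.uniform(0.0, 24.0)
        times: list[int] = []
        cursor = int(rng.integers(0, 6))
        for _ in range(spec.n_runs):
            run = int(rng.integers(spec.run_length_range[0],
                                   spec.run_length_range[1] + 1))
            times.extend(range(cursor, min(cursor + run, spec.hours_total)))
            cursor += run + int(rng.integers(2, 8))  # battery-swap gap
        t = np.array(sorted(set(times)), dtype=float)
        hod = t % 24.0
        cycle = 1.0 + amp * np.cos(2.0 * np.pi * (hod - phase) / 24.0)
        ea = (baseline * cycle * _depression_factor(hod, spec)
              + spec.noise_frac * baseline * rng.standard_normal(t.size))
        for tt, hh, e in zip(t, hod, ea):
            rows.append({"tree_tag": tag, "time_h": tt, "hour": hh, "ea": float(e)})
    return pd.DataFrame(rows)
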