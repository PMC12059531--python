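"""CSV interfaces for the pipeline's tabular inputs and outputs.

All formats are plain long-format CSV:

* chamber series — closure_id, tree_tag, time_s, co2_umol_mol,
  h2o_mmol_mol, pressure_kpa, temp_c
* census — tag, dbh_cm, height_m, species, buttressed
* cylinders — tree_tag, cyl_id, parent_id, branch_order, radius_m,
  length_m, base_height_m (one long table; per-tree sa_sd in a companion
  table tree_tag, sa_sd_m2)
* vertical observations — tree_tag, height_m, position, ea, temp_c
* diel observations — tree_tag, time_h, hour, ea
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .surface_area import Cylinder, QSMTree
from .synthetic_data import (SyntheticConfig, census_records,
                             generate_census, generate_diel_observations,
                             generate_plot, generate_vertical_observations,
                             select_vertical_trees)

CYLINDER_COLUMNS = ["tree_tag", "cyl_id", "parent_id", "branch_order",
                    "radius_m", "length_m", "base_height_m"]


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["buttressed"] = df["buttressed"].astype(bool)
    return df


def write_cylinders(trees: list[QSMTree], path, sd_path=None) -> None:
    pd.concat([t.to_frame() for t in trees], ignore_index=True).to_csv(
        path, index=False)
    if sd_path is not None:
        pd.DataFrame({"tree_tag": [t.tag for t in trees],
                      "sa_sd_m2": [t.sa_sd for t in trees]}).to_csv(
            sd_path, index=False)


def read_cylinders(path, sd_path=None) -> list[QSMTree]:
    """Long cylinder CSV (and optional per-tree sd CSV) -> QSMTree list."""
    df = pd.read_csv(path)
    sds = {}
    if sd_path is not None:
        sd_df = pd.read_csv(sd_path)
        sds = dict(zip(sd_df["tree_tag"], sd_df["sa_sd_m2"]))
    trees = []
    for tag, grp in df.groupby("tree_tag", sort=False):
        cyls = [Cylinder(cyl_id=int(r.cyl_id),
                         parent_id=None if pd.isna(r.parent_id) else int(r.parent_id),
                         branch_order=int(r.branch_order),
                         radius_m=float(r.radius_m), length_m=float(r.length_m),
                         base_height_m=float(r.base_height_m))
                for r in grp.itertuples()]
        trees.append(QSMTree(tag=str(tag), cylinders=cyls,
                             sa_sd=float(sds.get(tag, 0.0))))
    return trees


def write_synthetic_dataset(out_dir, config: SyntheticConfig | None = None,
                            seed: int | None = None) -> dict:
    """Write every CSV the pipeline reads, plus a ground-truth JSON.

    Returns the ground-truth dictionary.  ``seed`` overrides the config
    seed when given.
    """
    from dataclasses import replace
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    census, trees = generate_plot(config, rng)
    census.to_csv(out / "census.csv", index=False)
    write_cylinders(trees, out / "cylinders.csv", out / "cylinder_sd.csv")

    records = census_records(census)
    vertical_tags = select_vertical_trees(census, config)
    vert = generate_vertical_observations([records[t] for t in vertical_tags],
                                          config.vertical_truth, config, rng)
    vert.to_csv(out / "vertical_observations.csv", index=False)

    diel = generate_diel_observations(config, rng)
    diel.to_csv(out / "diel_observations.csv", index=False)

    truth = {
        "seed": config.seed,
        "n_trees": config.n_trees,
        "n_qsm_trees": len(trees),
        "vertical_truth": {k: v for k, v in asdict(config.vertical_truth).items()
                           if isinstance(v, (int, float)) and np.isfinite(v)},
        "diel": asdict(config.diel),
        "height_model": asdict(config.height_model),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
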