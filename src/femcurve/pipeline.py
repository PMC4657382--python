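"""End-to-end orchestration: simulate -> standardize -> measure -> clearance
-> cohort statistics, as one reproducible, seeded run.

A run simulates a cohort table (demographics + true geometric parameters per
femur), builds the femur meshes for each row, pushes every femur through the
measurement pipeline, optionally checks nail-surrogate clearance, and then
runs the statistical battery over the measured table.  Per-femur failures are
isolated: one bad mesh is reported and skipped, the cohort continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centerline import extract_centerline, inscribed_diameter_profile, isthmus
from .circle_geometry import fit_circle_3d
from .cohort_stats import compare_groups, ks_normality, pearson_matrix, stepwise_regression
from .curvature_metrics import measure_femur
from .errors import ConfigError
from .synthetic_femur import FemurParams, make_cohort_table, make_femur_meshes
from .torus_clearance import check_clearance, torus_spec_for_centerline

log = logging.getLogger("femcurve.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (simulation mode)."""

    n_femurs: int = 8
    seed: int | None = None
    out_dir: str | None = None
    n_slices: int = 60
    trim_fraction: float = 0.10
    mesh_resolution: tuple = (96, 160)
    clearance: bool = False
    clearance_samples: int = 8000
    p_enter: float = 0.05
    p_remove: float = 0.10
    stats: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.n_femurs < 1:
            raise ConfigError("n_femurs must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is required when simulation is enabled")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "mesh_resolution" in raw:
            raw["mesh_resolution"] = tuple(raw["mesh_resolution"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mesh_resolution"] = list(self.mesh_resolution)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analytic parameters (output location and log level do
        not change the science and are excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _params_from_row(row, config: RunConfig) -> FemurParams:
    rfc = float(np.clip(row["rfc_mm"], 450.0, 2200.0))
    length = float(np.clip(row["length_mm"], 330.0, 520.0))
    banking = float(np.clip(row["banking_deg"], 50.0, 145.0))
    isthmus_d = float(np.clip(row["isthmus_mm"], 6.0, 16.5))
    return FemurParams.for_study(
        R_curvature=rfc,
        banking=banking,
        isthmus_diameter=isthmus_d,
        length_total=length,
        side=row["side"],
        mesh_resolution=config.mesh_resolution,
    )


def _measure_one(row, config: RunConfig) -> dict:
    params = _params_from_row(row, config)
    cortex, canal, truth = make_femur_meshes(params)
    rec = measure_femur(
        cortex,
        canal,
        {"subject_id": row["subject_id"], "side": row["side"]},
        n_slices=config.n_slices,
        trim_fraction=config.trim_fraction,
    )
    out = rec.to_dict()
    out["true_rfc_mm"] = truth.R_curvature
    out["true_banking_deg"] = truth.banking
    out["true_isthmus_mm"] = truth.isthmus_diameter
    out["true_length_mm"] = truth.femoral_length
    if config.clearance:
        from .pose_standardization import standardize

        pose, (canal_std,) = standardize(cortex, (canal,))
        cl = extract_centerline(
            canal_std, n_slices=config.n_slices, trim_fraction=config.trim_fraction
        )
        cl = inscribed_diameter_profile(canal_std, cl)
        _, dia = isthmus(cl)
        circ = fit_circle_3d(cl.points)
        spec = torus_spec_for_centerline(circ, cl, dia)
        rep = check_clearance(spec, canal_std, n_samples=config.clearance_samples)
        out["clearance_mm"] = rep.min_clearance
        out["clearance_intersects"] = rep.intersects
    return out


def _summary(measured: pd.DataFrame, config: RunConfig) -> dict:
    """Cohort summary: per-gender means +/- SD with t-tests, paired left/right
    differences, the correlation matrix, and (when n allows) the stepwise
    models for RFC and banking."""
    out: dict = {}
    cols = ["femoral_length", "rfc", "banking", "isthmus_diameter"]
    by_gender = {}
    for g, name in ((0.0, "male"), (1.0, "female")):
        sub = measured[measured["gender"] == g]
        by_gender[name] = {
            c: {"mean": float(sub[c].mean()), "sd": float(sub[c].std())}
            for c in cols
        } | {"n": int(len(sub))}
    out["by_gender"] = by_gender
    males = measured[measured["gender"] == 0.0]
    females = measured[measured["gender"] == 1.0]
    if len(males) >= 2 and len(females) >= 2:
        out["gender_tests"] = {
            c: dataclasses.asdict(
                compare_groups(males[c], females[c], "independent_t")
            )
            for c in cols
        }
    left = measured[measured["side"] == "left"].sort_values("subject_id")
    right = measured[measured["side"] == "right"].sort_values("subject_id")
    if len(left) == len(right) and len(left) >= 2:
        out["laterality_tests"] = {
            c: dataclasses.asdict(
                compare_groups(
                    left[c].to_numpy(), right[c].to_numpy(), "paired_t"
                )
            )
            for c in cols
        }
        out["laterality_diff_mean"] = {
            c: float((left[c].to_numpy() - right[c].to_numpy()).mean())
            for c in cols
        }
    corr_vars = ["age_y", "height_m", "weight_kg"] + cols
    cm = pearson_matrix(measured, corr_vars)
    out["pearson_r"] = cm.r.round(6).to_dict()
    if len(measured) >= 8:
        out["normality_p"] = {
            c: float(
                ks_normality(measured[c].to_numpy(), seed=config.seed).p_value
            )
            for c in cols
            if measured[c].std() > 0
        }
    candidates = [
        "femoral_length", "banking", "laterality", "gender",
        "age_y", "height_m", "weight_kg",
    ]
    if len(measured) >= len(candidates) + 10:
        m = stepwise_regression(
            measured, "rfc", candidates,
            p_enter=config.p_enter, p_remove=config.p_remove,
        )
        out["stepwise_rfc"] = {
            "terms": m.terms,
            "coefficients": m.coefficients,
            "r_squared": m.r_squared,
            "steps": m.steps,
        }
    return out


def run_pipeline(config: RunConfig):
    """Execute a full simulated-cohort run.

    Returns (measured table, per-femur records list, summary dict); when
    ``config.out_dir`` is set, also writes ``cohort.csv``, ``records.json``
    and ``summary.json`` (all tagged with the config hash and seed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    n_subjects = max(int(math.ceil(config.n_femurs / 2)), 10)
    cohort = make_cohort_table(n_subjects, seed=config.seed)
    cohort = cohort.iloc[: config.n_femurs]

    records = []
    failures = []
    for _, row in cohort.iterrows():
        tag = f"{int(row['subject_id'])}/{row['side']}"
        try:
            rec = _measure_one(row, config)
        except Exception as exc:  # noqa: BLE001 - per-femur isolation
            log.warning("femur %s failed: %r", tag, exc)
            failures.append({"femur": tag, "error": repr(exc)})
            continue
        for k in ("laterality", "gender", "age_y", "height_m", "weight_kg"):
            rec[k] = float(row[k])
        records.append(rec)
    if not records:
        raise ConfigError("all femurs failed; nothing to summarize")

    measured = pd.DataFrame(records)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # outputs stay byte-identical across dirs
    summary = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": config.config_hash,
        "n_measured": len(records),
        "failures": failures,
    }
    if config.stats:
        summary["statistics"] = _summary(measured, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        measured.to_csv(out / "cohort.csv", index=False, float_format="%.6f")
        with open(out / "records.json", "w") as fh:
            json.dump(
                {"config_hash": config.config_hash, "records": records},
                fh, indent=2, sort_keys=True,
            )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return measured, records, summary
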