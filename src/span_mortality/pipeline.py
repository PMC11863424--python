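"""Config-driven orchestration of the full SPAN mortality analysis.

One call runs: simulate (or load) a cohort -> score the diet quality
components -> apply exclusions, Winsorize, build joint tertiles -> fit the
27-cell and continuous Cox models -> dose grid, minimal-dose ladder,
absolute risks and additive-interaction indices -> write all output tables
plus a run manifest for deterministic re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_prep, dose_response, interaction, simulate, survival
from .diet_score import DQS_COMPONENTS, default_scales, load_scales, score_dqs_table

logger = logging.getLogger("span_mortality")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

DEFAULT_COVARIATES = ("age", "sex", "confounder")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    mode: str = "synthetic"  # synthetic | csv
    cohort_csv: str | None = None
    synthetic: simulate.SyntheticCohortConfig = field(
        default_factory=simulate.SyntheticCohortConfig
    )
    scale_file: str | None = None  # None -> shipped default scales
    rescore_ffq: bool = True  # synthetic mode: generate + rescore FFQ columns
    exclusions: dict = field(
        default_factory=lambda: {"death_in_first_year": True}
    )
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    targets: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError(f"mode must be 'synthetic' or 'csv', got {self.mode!r}")
        if self.mode == "csv" and not self.cohort_csv:
            raise ValueError("csv mode requires cohort_csv")
        if any(not 0 < t < 100 for t in self.targets):
            raise ValueError("targets must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if k in ("covariates", "targets") else v
                     for k, v in raw.items()})
        if syn:
            if "exposure_correlation" in syn:
                syn["exposure_correlation"] = tuple(
                    tuple(r) for r in syn["exposure_correlation"]
                )
            cfg.synthetic = simulate.SyntheticCohortConfig(**syn)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["exposure_correlation"] = [
            list(map(float, r)) for r in
            np.asarray(d["synthetic"]["exposure_correlation"], dtype=float)
        ]
        d["covariates"] = list(self.covariates)
        d["targets"] = list(map(float, self.targets))
        return d


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    input_hash: str
    stage_counts: dict
    tertile_cuts: dict
    anchor: dict
    outputs: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.mode == "csv":
        return simulate.read_cohort(config.cohort_csv)
    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    return simulate.generate_cohort(syn, with_ffq=config.rescore_ffq)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the full analysis; returns the manifest (also written to disk).

    Outputs written to ``config.out_dir``: ``cell_hr.csv`` (27-row joint
    tertile HR table), ``absolute_risk.csv``, ``dose_grid.csv``,
    ``minimal_dose_ladder.csv``, ``interaction.csv``,
    ``exclusion_ledger.json``, ``continuous_fit.json``, ``manifest.json``.
    Any stage error aborts the run and removes partial outputs.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_counts: dict = {}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    try:
        # --- input ---------------------------------------------------
        cohort = _load_cohort(config)
        input_hash = _hash_frame(cohort)
        stage_counts["input"] = {"n": len(cohort),
                                 "events": int(cohort["event"].sum())}
        logger.info("input: %d rows, %d events", len(cohort),
                    int(cohort["event"].sum()))

        # --- diet scoring --------------------------------------------
        scales = (load_scales(config.scale_file) if config.scale_file
                  else default_scales())
        has_ffq = all(c in cohort.columns for c in DQS_COMPONENTS)
        if has_ffq:
            scored = score_dqs_table(cohort[list(DQS_COMPONENTS)], scales)
            cohort = cohort.copy()
            cohort["dqs"] = scored["dqs"]
            logger.info("dqs rescored from FFQ components")
        elif "dqs" not in cohort.columns:
            raise ValueError("cohort has neither FFQ components nor a dqs column")

        # --- preparation ---------------------------------------------
        cohort, ledger = cohort_prep.apply_exclusions(
            cohort, config.exclusions, covariate_cols=list(config.covariates)
        )
        stage_counts["exclusions"] = ledger
        stage_counts["analysis"] = {"n": len(cohort),
                                    "events": int(cohort["event"].sum())}
        cohort = cohort.copy()
        winsor = {}
        for e in survival.EXPOSURES:
            w = cohort_prep.winsorize(cohort[e].to_numpy())
            cohort[e] = w.values
            winsor[e] = (w.lo_value, w.hi_value)
        cuts = {e: cohort_prep.tertile_cuts(cohort[e].to_numpy(), name=e)
                for e in survival.EXPOSURES}
        cohort = cohort_prep.assign_joint_categories(
            cohort, cuts["sleep"], cuts["mvpa"], cuts["dqs"]
        )
        logger.info("prepared: %d rows after exclusions %s", len(cohort), ledger)

        # --- models --------------------------------------------------
        joint_fit = survival.fit_joint_tertile_model(
            cohort, covariate_cols=config.covariates
        )
        cont_fit = survival.fit_continuous_model(
            cohort, covariate_cols=config.covariates
        )
        logger.info("fits done: joint ll=%.1f, continuous ll=%.1f",
                    joint_fit.log_likelihood, cont_fit.log_likelihood)

        # --- outputs -------------------------------------------------
        anchor = dose_response.anchor_from_percentile(cohort, 5.0)
        cells = survival.cell_hr_table(joint_fit)
        emit("cell_hr.csv", lambda p: cells.to_csv(p, index=False))
        risks = survival.absolute_risk(cohort, "cell_index")
        emit("absolute_risk.csv", lambda p: risks.to_csv(p, index=False))
        grid = dose_response.build_grid(cont_fit, anchor)
        emit("dose_grid.csv", lambda p: grid.to_frame().to_csv(p, index=False))
        ladder = dose_response.minimal_dose_ladder(
            cont_fit, anchor, targets=config.targets
        )
        emit("minimal_dose_ladder.csv", lambda p: ladder.to_csv(p, index=False))
        rrs, cov = interaction.joint_dichotomous_rrs(
            cohort, covariate_cols=config.covariates
        )
        inter = interaction.reri3(
            rrs["rr100"], rrs["rr010"], rrs["rr001"], rrs["rr111"],
            covariance=cov,
        )
        emit("interaction.csv",
             lambda p: inter.to_frame().to_csv(p, index=False))
        emit("exclusion_ledger.json",
             lambda p: Path(p).write_text(json.dumps(ledger, indent=1)))
        emit("continuous_fit.json", cont_fit.to_json)

        manifest = RunManifest(
            config_hash=_hash_obj(config.to_dict()),
            package_version=_package_version(),
            seed=config.seed,
            input_hash=input_hash,
            stage_counts=stage_counts,
            tertile_cuts={e: [cuts[e].cut_lo, cuts[e].cut_hi]
                          for e in survival.EXPOSURES},
            anchor=anchor.as_dict() | {"kind": anchor.kind},
            outputs=[p.name for p in written] + ["manifest.json", "run.log"],
        )
        emit("manifest.json", manifest.to_json)
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("span-mortality")
    except PackageNotFoundError:
        return "0+unknown"
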