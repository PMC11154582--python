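"""One-shot orchestration of the full analysis and its reproduction report.

:func:`run_reproduction` executes the whole pipeline on the bundled
126-compound table — chemometrics, the headline three-predictor fit, LOO and
leave-30%-out validation, the Williams applicability domain, and categorical
predictions for every compound — writing diff-able CSV/TSV/JSON artefacts
plus a machine-readable comparison of the recomputed statistics against the
published values with pass/fail at stated tolerances.  Every output carries
the configuration hash and seed so identical config + seed reproduce
byte-identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, dataset, rules
from .domain import williams_assessment
from .model import EQ4_PREDICTORS, LogBBModel, enumerate_candidates
from .validation import leave_group_out_cv

logger = logging.getLogger("bbbqsar")

__all__ = ["PipelineConfig", "run_reproduction", "run_stage", "PUBLISHED_VALUES"]

#: Published reference statistics used by the reproduction comparison.
PUBLISHED_VALUES = {
    "r2": 0.9342,
    "r2_adj": 0.9326,
    "r2_pred": 0.9296,
    "press": 1.76752,
    "ss_total": 25.1199,
    "mse": 0.01355,
    "f_stat": 578.0,
    "coef_const": -0.0004,
    "coef_log_kw_iam": 0.0081,
    "coef_mw": 0.0044,
    "coef_hb_total": -0.2030,
    "h_star": 0.095,
    "mean_mw": 323.47,
    "hydrazide_pred_min": -1.241,
    "hydrazide_pred_max": -1.014,
    "active_pred_min": 0.342,
    "active_pred_max": 0.558,
}

#: Absolute tolerances of the reproduction comparison (R2-family at the 4th
#: decimal, F at 0.5, everything else at printed-precision rounding).
_TOLERANCES = {
    "r2": 1e-4, "r2_adj": 1e-4, "r2_pred": 1e-4,
    "press": 5e-6, "ss_total": 5e-5, "mse": 5e-6,
    "f_stat": 0.5,
    "coef_const": 5e-5, "coef_log_kw_iam": 5e-5, "coef_mw": 5e-5,
    "coef_hb_total": 5e-5,
    "h_star": 5e-4, "mean_mw": 5e-3,
    "hydrazide_pred_min": 5e-4, "hydrazide_pred_max": 5e-4,
    "active_pred_min": 5e-4, "active_pred_max": 5e-4,
}

HYDRAZIDE_IDS = (53, 56, 57, 58, 59, 60)
CNS_ACTIVE_IDS = (83, 89, 103, 109, 114, 116)


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults reproduce the published analysis."""

    compound_table: Optional[str] = None   # None -> packaged fixture
    predictors: Sequence[str] | str = EQ4_PREDICTORS  # or "auto"
    response: str = "log_bb"
    cv_fraction: float = 0.30
    cv_scheme: str = "grouped-folds"
    cv_repeats: Optional[int] = None
    residual_band: float = 3.0
    category_upper: float = 0.3
    category_lower: float = -1.0
    similarity_convention: str = chemometrics.DEFAULT_CONVENTION
    linkage: str = chemometrics.DEFAULT_LINKAGE
    seed: int = 0
    output_dir: str = "bbbqsar_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides take precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["predictors"] = list(payload["predictors"])
        # hash covers analysis-relevant settings only, not where files land
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash()}\tseed={config.seed}\n"


def _write_table(frame: pd.DataFrame, path: Path, config: PipelineConfig,
                 sep: str = ",", index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        frame.to_csv(fh, sep=sep, index=index)


def _write_json(payload: dict, path: Path, config: PipelineConfig) -> None:
    payload = {"config_hash": config.config_hash(), "seed": config.seed, **payload}
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _load_frame(config: PipelineConfig) -> pd.DataFrame:
    if config.compound_table is None:
        return dataset.load_fixture_frame()
    records = dataset.read_compound_table(config.compound_table)
    frame = dataset.records_to_frame(records)
    frame["hb_total"] = frame["hbd"] + frame["hba"]
    return frame


def run_reproduction(config: Optional[PipelineConfig] = None) -> dict:
    """Run the full analysis and emit the reproduction report bundle.

    Returns a dict with the in-memory results (``results``, ``cv``, ``ad``,
    ``candidates``, ``comparison``) and writes the artefact files under
    ``config.output_dir``.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = _load_frame(config)
    logger.info("loaded %d compounds", len(frame))

    # --- chemometrics ------------------------------------------------------
    panel = dataset.descriptor_panel(frame)
    pca = chemometrics.run_pca(panel)
    sim = chemometrics.similarity_matrix(panel, config.similarity_convention)
    clustering = chemometrics.cluster_variables(
        sim, config.linkage, convention=config.similarity_convention
    )
    _write_table(pca.loadings.round(6), out / "pca_loadings.csv", config, index=True)
    _write_table(sim.round(4), out / "similarity_matrix.csv", config, index=True)
    merges = pd.DataFrame(
        [
            {"step": i + 1, "members": " ".join(sorted(a | b)),
             "similarity": round(s, 4)}
            for i, (a, b, s) in enumerate(clustering.merge_sequence)
        ]
    )
    _write_table(merges, out / "cluster_merges.tsv", config, sep="\t")

    # --- model -------------------------------------------------------------
    if config.predictors == "auto":
        candidates = enumerate_candidates(frame, config.response)
        results = candidates[0].results
        predictors = candidates[0].predictors
    else:
        candidates = None
        predictors = tuple(config.predictors)
        results = LogBBModel.from_dataframe(frame, predictors, config.response).fit()
    logger.info("fitted %s: R2=%.4f", " + ".join(predictors), results.r2)
    _write_json(results.to_dict(), out / "model.json", config)
    row = results.statistics_row().to_frame().T
    _write_table(row, out / "table3_row.tsv", config, sep="\t")

    # --- validation --------------------------------------------------------
    cv = leave_group_out_cv(
        results,
        fraction=config.cv_fraction,
        scheme=config.cv_scheme,
        repeats=config.cv_repeats,
        seed=config.seed,
    )
    _write_json(
        {
            "scheme": cv.scheme,
            "holdout_fraction": cv.holdout_fraction,
            "holdout_size": cv.holdout_size,
            "repeats": cv.repeats,
            "press_cv": cv.press_cv,
            "q2_cv": cv.q2_cv,
            "press_over_ss": cv.press_over_ss,
            "folds": [members for members, _ in cv.per_fold],
        },
        out / "cv.json",
        config,
    )

    # --- applicability domain ---------------------------------------------
    ad = williams_assessment(results, residual_band=config.residual_band,
                             index=frame["compound_id"])
    with open(out / "williams.tsv", "w") as fh:
        fh.write(_stamp(config))
        fh.write(f"# h_star={ad.h_star:.6g}\n")
        ad.table.to_csv(fh, sep="\t")

    # --- predictions for every compound ------------------------------------
    preds = rules.batch_predict(results, frame)
    _write_table(preds, out / "predictions.csv", config)

    # --- comparison against the published statistics ------------------------
    published_form = results.predict(frame, coef_precision=4)
    by_id = pd.Series(published_form, index=frame["compound_id"])
    computed = {
        "r2": results.r2,
        "r2_adj": results.r2_adj,
        "r2_pred": results.r2_pred,
        "press": results.press,
        "ss_total": results.ss_total,
        "mse": results.mse,
        "f_stat": results.f_stat,
        "h_star": ad.h_star,
        "mean_mw": float(frame["mw"].mean()),
        "hydrazide_pred_min": float(by_id.loc[list(HYDRAZIDE_IDS)].min()),
        "hydrazide_pred_max": float(by_id.loc[list(HYDRAZIDE_IDS)].max()),
        "active_pred_min": float(by_id.loc[list(CNS_ACTIVE_IDS)].min()),
        "active_pred_max": float(by_id.loc[list(CNS_ACTIVE_IDS)].max()),
    }
    for name in ("const", *predictors):
        key = f"coef_{name}"
        if key in PUBLISHED_VALUES:
            computed[key] = float(results.params[name])
    comparison = {}
    for key, reference in PUBLISHED_VALUES.items():
        if key not in computed:
            continue
        tol = _TOLERANCES[key]
        value = computed[key]
        comparison[key] = {
            "computed": value,
            "published": reference,
            "tolerance": tol,
            "pass": bool(abs(value - reference) <= tol),
        }
    _write_json({"comparison": comparison}, out / "comparison.json", config)
    n_pass = sum(entry["pass"] for entry in comparison.values())
    logger.info("reproduction comparison: %d/%d within tolerance",
                n_pass, len(comparison))

    return {
        "frame": frame,
        "pca": pca,
        "clustering": clustering,
        "results": results,
        "candidates": candidates,
        "cv": cv,
        "ad": ad,
        "predictions": preds,
        "comparison": comparison,
        "output_dir": out,
    }


def run_stage(stage: str, config: Optional[PipelineConfig] = None, **kwargs) -> dict:
    """Run a single named pipeline stage (see the CLI for the stage list)."""
    from . import cli  # stage table lives next to the subcommands

    config = config or PipelineConfig()
    runner = cli.STAGE_RUNNERS.get(stage)
    if runner is None:
        raise ValueError(
            f"unknown stage {stage!r}; choose from {sorted(cli.STAGE_RUNNERS)}"
        )
    return runner(config, **kwargs)
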