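"""End-to-end orchestration of the validation pipeline.

Stages run in the analysis order: cohort descriptives and local
independence, MGRM calibration and structure comparison, item
diagnostics, DIF screening, latent profile enumeration, and the
dose-response link from resilience classes to QoL.  Each stage writes
its artifacts (CSV/JSON) before the final report, so stages compose or
re-run standalone, and every stage records the seed it used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    QoLLinkSpec,
    SyntheticCohort,
    default_true_params,
    generate_cohort,
    read_cohort_csv,
    stage_seeds,
    total_score_moments,
    write_cohort_csv,
)
from .diagnostics import (
    item_diagnostics_table,
    item_moments,
    ordered_thresholds_report,
    q3_residual_correlations,
)
from .dif import monte_carlo_thresholds, purify
from .mgrm import (
    ConvergenceError,
    EstimationOptions,
    ItemResponseMatrix,
    ScaleStructure,
    compare_structures,
    fit,
)
from .profiles import enumerate_classes
from .qol import fit_gam_logistic, logistic_dose_response, table1_descriptives

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_input", "load_config"]


class PipelineError(RuntimeError):
    """Stage-named failure; ``stage`` says where the pipeline halted."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``responses_csv`` (with optional ``covariates_csv``)
    or ``simulate`` may be set.  Stage toggles switch individual stages
    off; options mirror the corresponding module defaults.
    """

    responses_csv: str | None = None
    covariates_csv: str | None = None
    simulate: dict | None = None
    output_dir: str = "caremirt_output"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "descriptives": True, "mgrm": True, "diagnostics": True,
        "dif": True, "lpa": True, "doseresponse": True,
    })
    factor_assignment: list = field(default_factory=lambda: [0] * 5 + [1] * 5)
    estimator: str = "em"
    quad_nodes: int = 21
    max_cycles: int = 500
    compare_bifactor: bool = False
    dif_group_col: str = "sex"
    dif_n_sims: int = 500
    dif_alpha: float = 0.05
    lpa_k_max: int = 5
    lpa_n_starts: int = 50
    lpa_indicators: str = "items"
    qol_cutoff: float | None = None
    dose_class_source: str = "lpa"

    def __post_init__(self):
        has_files = self.responses_csv is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError(
                "config must set exactly one of responses_csv / simulate"
            )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def validate_input(responses_csv, covariates_csv=None) -> list[dict]:
    """Schema checks on input CSVs; returns a machine-readable error list."""
    errors: list[dict] = []
    frame = pd.read_csv(responses_csv)
    item_cols = [c for c in frame.columns if c.startswith("item")]
    if not item_cols:
        errors.append({"file": str(responses_csv), "error": "no item columns found"})
        return errors
    for col in item_cols:
        vals = frame[col]
        bad = ~vals.isin([1, 2, 3, 4, 5])
        if bad.any():
            row = int(np.where(bad)[0][0])
            errors.append(
                {
                    "file": str(responses_csv), "row": row, "column": col,
                    "error": f"response {vals.iloc[row]!r} outside 1..5",
                }
            )
    if covariates_csv is not None:
        cov = pd.read_csv(covariates_csv)
        if "id" in frame.columns and "id" in cov.columns:
            if not frame["id"].equals(cov["id"]):
                errors.append(
                    {
                        "file": str(covariates_csv),
                        "error": "id column does not align with responses file",
                    }
                )
        elif len(cov) != len(frame):
            errors.append(
                {"file": str(covariates_csv), "error": "row count mismatch"}
            )
    return errors


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def _load_cohort(config: PipelineConfig) -> SyntheticCohort:
    if config.simulate is not None:
        sim = dict(config.simulate)
        link = QoLLinkSpec(**sim.pop("qol_link")) if "qol_link" in sim else None
        rho = sim.pop("latent_correlation", 0.5)
        cc_kwargs = {
            "n_persons": sim.pop("n_persons", 382),
            "seed": sim.pop("seed", config.seed),
            "true_params": default_true_params(rho),
        }
        if link is None:
            params = cc_kwargs["true_params"]
            mean, sd = total_score_moments(params)
            link = QoLLinkSpec(center=mean, scale=sd)
        cc_kwargs["qol_link"] = link
        cohort_config = CohortConfig(**cc_kwargs)
        return generate_cohort(cohort_config)
    errors = validate_input(config.responses_csv, config.covariates_csv)
    if errors:
        raise PipelineError("validate", json.dumps(errors))
    return read_cohort_csv(config.responses_csv)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the validation report.

    All artifacts are written under ``config.output_dir`` before the
    report (``report.json``); any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "stages": {},
    }

    cohort = _load_cohort(config)
    write_cohort_csv(cohort, out / "cohort.csv", out / "cohort_truth.csv")
    data = cohort.responses

    if config.stages.get("descriptives", True):
        desc = table1_descriptives(cohort.covariates, strata="cancer_type"
                                   if "cancer_type" in cohort.covariates.columns else None)
        desc.to_csv(out / "descriptives.csv", index=False)
        moments = item_moments(data)
        moments.to_csv(out / "item_moments.csv", index=False)
        report["stages"]["descriptives"] = {
            "n_persons": int(cohort.n_persons),
            "path": "descriptives.csv",
        }

    params = ability = indices = None
    if config.stages.get("mgrm", True):
        structure = ScaleStructure.between_item(config.factor_assignment)
        options = EstimationOptions(
            estimator=config.estimator, quad_nodes=config.quad_nodes,
            max_cycles=config.max_cycles, seed=seeds["responses"],
        )
        try:
            params, ability, indices = fit(data, structure, options)
        except ConvergenceError as exc:
            raise PipelineError("mgrm", str(exc)) from exc
        pd.DataFrame(params.a, columns=[f"a{f + 1}" for f in range(params.n_factors)]).assign(
            item=data.item_ids
        ).to_csv(out / "mgrm_slopes.csv", index=False)
        pd.DataFrame(
            params.d, columns=[f"d{k + 2}" for k in range(params.d.shape[1])]
        ).assign(item=data.item_ids).to_csv(out / "mgrm_intercepts.csv", index=False)
        stage = {
            "fit_indices": indices.as_dict(),
            "latent_correlation": float(params.latent_cov[0, 1]),
        }
        if config.compare_bifactor:
            cmp = compare_structures(data, config.factor_assignment, options)
            stage["structure_comparison"] = {
                "aic_between": cmp.fit_between.aic,
                "aic_bifactor": cmp.fit_bifactor.aic,
                "lr_pvalue": cmp.lr_pvalue,
                "negative_specific_slopes": int(cmp.negative_specific_slopes.sum()),
                "recommended": cmp.recommended,
            }
        report["stages"]["mgrm"] = stage

    if config.stages.get("diagnostics", True):
        if params is None:
            raise PipelineError("diagnostics", "requires the mgrm stage")
        diag = item_diagnostics_table(params, list(data.item_ids))
        diag.to_frame().to_csv(out / "item_diagnostics.csv", index=False)
        ordered = ordered_thresholds_report(params)
        q3 = q3_residual_correlations(params, ability, data)
        pd.DataFrame(q3.values, index=data.item_ids, columns=data.item_ids).to_csv(
            out / "q3_residuals.csv"
        )
        report["stages"]["diagnostics"] = {
            "min_mdisc": float(diag.mdisc.min()),
            "all_thresholds_ordered": bool(ordered["ordered"].all()),
            "q3_flagged_pairs": len(q3.flagged_pairs),
            "q3_flagged_proportion": q3.flagged_proportion,
        }

    if config.stages.get("dif", True):
        if params is None:
            raise PipelineError("dif", "requires the mgrm stage")
        group_col = config.dif_group_col
        if group_col not in cohort.covariates.columns:
            raise PipelineError("dif", f"group covariate {group_col!r} not present")
        group = cohort.covariates[group_col].astype(str).to_numpy()
        thresholds = None
        if config.dif_n_sims >= 100:
            sizes = pd.Series(group).value_counts()
            thresholds = monte_carlo_thresholds(
                params, (int(sizes.iloc[0]), int(sizes.iloc[1])),
                n_sims=config.dif_n_sims, alpha=config.dif_alpha,
                seed=seeds["dif"],
            )
            with open(out / "dif_thresholds.json", "w") as fh:
                json.dump(thresholds.as_dict(), fh, indent=2, sort_keys=True)
        result = purify(
            data, params, group, criterion="lr",
            alpha=config.dif_alpha, thresholds=thresholds,
        )
        result.table.to_csv(out / "dif_table.csv", index=False)
        report["stages"]["dif"] = {
            "group": group_col,
            "flagged_items": result.flagged_items("any"),
            "iterations": getattr(result, "iterations", 0),
            "monte_carlo": thresholds is not None,
        }

    if config.stages.get("lpa", True):
        if config.lpa_indicators == "items":
            indicators = data.values.astype(float)
        else:
            if ability is None:
                raise PipelineError("lpa", "theta indicators require the mgrm stage")
            indicators = ability.theta
        table, recommended, sols = enumerate_classes(
            indicators, range(1, config.lpa_k_max + 1),
            n_starts=config.lpa_n_starts, seed=seeds["classes"],
        )
        table.to_csv(out / "lpa_solutions.csv", index=False)
        best = sols[recommended]
        pd.DataFrame(
            {"id": np.arange(1, cohort.n_persons + 1), "class": best.assignments() + 1}
        ).to_csv(out / "lpa_assignments.csv", index=False)
        report["stages"]["lpa"] = {
            "recommended_k": int(recommended),
            "entropy": None if np.isnan(best.entropy) else float(best.entropy),
            "path": "lpa_solutions.csv",
        }
        lpa_classes = best.assignments()
    else:
        lpa_classes = None

    if config.stages.get("doseresponse", True):
        total = data.total_scores()
        y = cohort.qol_binary
        if lpa_classes is None or len(np.unique(lpa_classes)) < 2:
            raise PipelineError(
                "doseresponse", "needs at least two latent resilience classes"
            )
        covars = cohort.covariates.drop(
            columns=[c for c in ("cancer_type",) if c in cohort.covariates.columns]
        )
        try:
            dose = logistic_dose_response(lpa_classes + 1, total, covars, y)
            gam = fit_gam_logistic(total.astype(float), y)
        except ValueError as exc:
            raise PipelineError("doseresponse", str(exc)) from exc
        dose.table.to_csv(out / "dose_response.csv", index=False)
        report["stages"]["doseresponse"] = {
            "per_sd_or": float(dose.per_sd_row()["or"]),
            "per_sd_ci": [
                float(dose.per_sd_row()["ci_low"]),
                float(dose.per_sd_row()["ci_high"]),
            ],
            "monotone_class_ors": dose.monotone_class_ors,
            "gam_edf_smooth": gam.edf_smooth,
            "gam_nonlinearity_p": gam.lr_pvalue,
            "covariates_adjusted": dose.covariates_used,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report
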