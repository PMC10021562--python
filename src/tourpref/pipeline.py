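"""End-to-end orchestration: design -> simulate/ingest -> fit -> WTA -> survey
regressions -> reports.

`run_pipeline` executes the enabled stages in order, writes one JSON/CSV
artifact per stage into the output directory, and stamps every artifact with
the configuration hash and seed so a rerun with the same config is verifiably
identical.  Any stage failure raises `StageError` naming the stage; artifacts
written before the failure are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import preference_metrics as pm
from . import risk_correlates as rc
from .choice_models import fit_mmnl, fit_mnl
from .experimental_design import ChoiceDesign, default_attributes, load_attributes
from .io_ import load_choice_data, recode_money_continuous, write_choice_data, write_survey
from .synthetic_data import default_generator_config, generate_choices, generate_survey, recovery_experiment

logger = logging.getLogger("tourpref")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Stage toggles, paths and estimation options for one pipeline run."""

    output_dir: str = "tourpref_output"
    seed: int = 0
    n_respondents: int | None = None
    design_config: str | None = None  # attribute YAML; packaged default when None
    choice_data: str | None = None  # ingest instead of simulating when set
    survey_data: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "design": True,
            "simulate": True,
            "fit_mnl": True,
            "fit_mmnl": False,
            "wta": True,
            "correlates": True,
            "recovery": False,
        }
    )
    mmnl_draws: int = 1000
    wta_draws: int = 10_000
    recovery_replicates: int = 50
    tolerance: float = 1e-6

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(doc: dict, config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed, **doc}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return a manifest of artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    manifest: dict[str, str] = {}

    attributes = (
        load_attributes(config.design_config) if config.design_config else default_attributes()
    )

    def stage(name: str):
        enabled = config.stages.get(name, False)
        if enabled:
            logger.info("stage %s: start", name)
        return enabled

    t0 = time.time()
    try:
        design = None
        if stage("design"):
            from .synthetic_data import default_design

            design = default_design(seed=config.seed + 1)
            design.metadata.update(config_hash=config.config_hash(), seed=config.seed)
            design.to_json(out / "design.json")
            design.questionnaire().to_csv(out / "questionnaire.csv", index=False)
            manifest["design"] = str(out / "design.json")
            logger.info("stage design: d_error=%.4f", design.metadata.get("d_error", float("nan")))
    except Exception as err:  # noqa: BLE001
        raise StageError("design", err) from err

    try:
        dataset = None
        if config.choice_data:
            dataset = load_choice_data(config.choice_data, attributes=attributes)
            logger.info("ingested %d respondents", dataset.n_respondents)
        elif stage("simulate"):
            if design is None:
                design = ChoiceDesign.from_json(out / "design.json")
            gen = default_generator_config(
                seed=config.seed, design=design, n_respondents=config.n_respondents
            )
            dataset = generate_choices(gen)
            write_choice_data(dataset, out / "choices.csv")
            manifest["choices"] = str(out / "choices.csv")
            survey = generate_survey(gen)
            write_survey(survey, out / "survey.csv")
            manifest["survey"] = str(out / "survey.csv")
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError("simulate", err) from err

    mnl_result = None
    try:
        if stage("fit_mnl") and dataset is not None:
            mnl_result = fit_mnl(dataset, tolerance=config.tolerance)
            doc = _stamp(mnl_result.to_dict(), config)
            (out / "mnl.json").write_text(json.dumps(doc, indent=2))
            manifest["mnl"] = str(out / "mnl.json")
            logger.info("stage fit_mnl: LL=%.2f converged=%s", mnl_result.loglik, mnl_result.converged)
    except Exception as err:  # noqa: BLE001
        raise StageError("fit_mnl", err) from err

    try:
        if stage("fit_mmnl") and dataset is not None:
            mmnl_result = fit_mmnl(dataset, n_draws=config.mmnl_draws, seed=config.seed)
            doc = _stamp(mmnl_result.to_dict(), config)
            (out / "mmnl.json").write_text(json.dumps(doc, indent=2))
            manifest["mmnl"] = str(out / "mmnl.json")
            logger.info("stage fit_mmnl: LL=%.2f", mmnl_result.loglik)
    except Exception as err:  # noqa: BLE001
        raise StageError("fit_mmnl", err) from err

    try:
        if stage("wta") and dataset is not None:
            cont = recode_money_continuous(dataset, attributes)
            cont_result = fit_mnl(cont, tolerance=config.tolerance)
            condom = next(a for a in attributes if a.name == "condom_use")
            contrasts = [
                pm.level_contrast(condom, condom.levels[0], condom.levels[-1]),
                pm.Contrast("relationship in general: neither -> engage", {"opt_out": -1.0}),
            ]
            table = pm.wta_table(
                cont_result, contrasts, n_sim_draws=config.wta_draws, seed=config.seed
            )
            doc = _stamp({k: v.to_dict() for k, v in table.items()}, config)
            (out / "wta.json").write_text(json.dumps(doc, indent=2))
            manifest["wta"] = str(out / "wta.json")
    except Exception as err:  # noqa: BLE001
        raise StageError("wta", err) from err

    try:
        if stage("correlates"):
            if config.survey_data:
                import pandas as pd

                survey = pd.read_csv(config.survey_data)
            elif "survey" not in manifest:
                raise ValueError("correlates stage needs survey data (simulate or survey_data)")
            tables = rc.build_table3(survey)
            rc.table3_to_json(tables, out / "correlates.json")
            rc.format_table3(tables).to_csv(out / "correlates.csv")
            manifest["correlates"] = str(out / "correlates.json")
            logger.info("stage correlates: %d models", len(tables))
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError("correlates", err) from err

    try:
        if stage("recovery"):
            gen = default_generator_config(
                seed=config.seed,
                design=design if design is not None else None,
                n_respondents=config.n_respondents,
            )
            report = recovery_experiment(gen, n_replicates=config.recovery_replicates)
            doc = _stamp(
                {
                    "n_replicates": report.n_replicates,
                    "n_converged": report.n_converged,
                    "stats": report.stats.reset_index(names="coefficient").to_dict(orient="records"),
                },
                config,
            )
            (out / "recovery.json").write_text(json.dumps(doc, indent=2))
            manifest["recovery"] = str(out / "recovery.json")
    except Exception as err:  # noqa: BLE001
        raise StageError("recovery", err) from err

    logger.info("pipeline complete in %.1fs", time.time() - t0)
    logger.removeHandler(fh)
    fh.close()
    manifest["run_log"] = str(out / "run.log")
    return manifest
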