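"""End-to-end orchestration: simulate → pmf2k → fit → validate → decompose → report.

:func:`run_pipeline` runs the full analysis from a
:class:`PipelineConfig` and writes every artifact class:

1. synthetic study inputs (or ingestion of user-supplied manifest +
   descriptor table),
2. the adsorption-record table from Boltzmann integration of the PMFs,
3. logK-vs-ΔG and logK-vs-E_ad correlation summaries,
4. fitted + validated pp-LFER models (JSON) per endpoint,
5. Williams-plot coordinate exports,
6. the per-term contribution report with enthalpy/entropy and
   water/gaseous decompositions,

plus a machine-readable run log (versions, seeds, config hash).  All
randomness flows from explicit seeds, so a rerun with the same config
produces byte-identical JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import (
    aggregate_table1_report,
    decompose_entropy,
    decompose_water,
    term_contributions,
)
from .fixtures import literature_models
from .lfer import (
    MissingDescriptorError,
    PPLFERModel,
    AQUEOUS_DESCRIPTORS,
    fit_pplfer,
    read_descriptor_table,
    split_train_validation,
    validate,
    williams_domain,
)
from .pmf import (
    DECADIC_LOG,
    ThermoConstants,
    get_adsorbent,
    profile_to_record,
    read_pmf_profile,
    records_to_frame,
    regress_logk_on_deltag,
    AdsorptionRecord,
)
from .synthetic import GeneratorConfig, simulate_study, write_study

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "StructuralError",
    "run_pipeline",
    "compare_with_literature",
]

log = logging.getLogger("nanosorb.pipeline")

#: Stage order is a stable contract; the run log records it.
STAGES = ("simulate", "pmf2k", "correlate", "fit", "decompose", "report")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class StructuralError(ValueError):
    """Artifacts cannot be combined (non-comparable endpoints, shapes)."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (flat, explicit seeds)."""

    output_dir: str | Path = "nanosorb_run"
    seed: int = 0
    n_compounds: int = 41
    temperature: float = 300.0  # K
    adsorbent: str = "BP"
    split_fraction: float = 0.8
    k: int = 5
    repetitions: int = 5000
    endpoints: tuple[str, ...] = (
        "logK_gaseous",
        "logK_aqueous",
        "absEad_gaseous",
        "absEad_aqueous",
    )
    manifest: str | None = None  # PMF batch manifest CSV; None → simulate
    descriptor_table: str | None = None  # descriptors+endpoints CSV; None → simulate
    logk_decimals: int = 1
    stat_decimals: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["endpoints"] = list(self.endpoints)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _validate_config(config: PipelineConfig) -> None:
    for attr in ("manifest", "descriptor_table"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr} path does not exist: {p}")
    if (config.manifest is None) != (config.descriptor_table is None):
        raise ValueError("provide both manifest and descriptor_table, or neither")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage in order; returns artifact name → path.

    Any stage failure aborts with the stage name attached
    (:class:`PipelineStageError`).
    """
    _validate_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    constants = ThermoConstants(temperature=config.temperature)
    adsorbent = get_adsorbent(config.adsorbent)

    # -- simulate (or load) --------------------------------------------------
    stage = "simulate"
    try:
        if config.manifest is None:
            log.info("stage %s: generating synthetic study (n=%d, seed=%d)",
                     stage, config.n_compounds, config.seed)
            gen = GeneratorConfig(
                n_compounds=config.n_compounds, temperature=config.temperature
            )
            study = simulate_study(gen, seed=config.seed)
            paths = write_study(study, outdir / "inputs")
            artifacts.update(paths)
            table = study.dataset.table
            manifest = pd.read_csv(paths["manifest"])
        else:
            log.info("stage %s: loading supplied inputs", stage)
            table = read_descriptor_table(config.descriptor_table)
            manifest = pd.read_csv(config.manifest)
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise PipelineStageError(stage, exc) from exc

    # -- pmf2k ---------------------------------------------------------------
    stage = "pmf2k"
    try:
        records: list[AdsorptionRecord] = []
        for _, row in manifest.iterrows():
            prof = read_pmf_profile(
                row["path"],
                adsorbate_id=row["adsorbate_id"],
                phase=row["phase"],
                adsorbent_id=row.get("adsorbent_id", config.adsorbent),
            )
            records.append(profile_to_record(prof, adsorbent, constants))
        rec_frame = records_to_frame(records)
        rec_path = outdir / "adsorption_records.csv"
        rec_frame.to_csv(rec_path, index=False)
        artifacts["records"] = str(rec_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- correlate -----------------------------------------------------------
    stage = "correlate"
    try:
        correlations = {}
        for phase in ("gaseous", "aqueous"):
            sub = [r for r in records if r.phase == phase]
            if len(sub) >= 3:
                reg = regress_logk_on_deltag(sub)
                correlations[f"logK_vs_deltaG_{phase}"] = {
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r": reg.r, "n": reg.n,
                }
            # logK (from PMF) against the externally supplied DFT energies
            col = f"absEad_{phase}"
            if col in table.columns:
                merged = rec_frame[rec_frame["phase"] == phase].set_index("adsorbate_id")
                e_ad = -table.loc[merged.index, col]
                r = float(np.corrcoef(e_ad, merged["logK"])[0, 1])
                slope, intercept = np.polyfit(e_ad, merged["logK"], 1)
                correlations[f"logK_vs_Ead_{phase}"] = {
                    "slope": float(slope), "intercept": float(intercept),
                    "r": r, "n": len(merged),
                }
        corr_path = outdir / "correlations.json"
        _dump_json(correlations, corr_path)
        artifacts["correlations"] = str(corr_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- fit + validate + Williams -------------------------------------------
    stage = "fit"
    models: dict[str, PPLFERModel] = {}
    train_sets: dict[str, pd.DataFrame] = {}
    try:
        model_dir = outdir / "models"
        model_dir.mkdir(exist_ok=True)
        train, valid = split_train_validation(
            table, seed=config.seed, train_fraction=config.split_fraction
        )
        for endpoint in config.endpoints:
            if endpoint not in table.columns:
                raise MissingDescriptorError(
                    f"endpoint column {endpoint!r} missing from descriptor table"
                )
            model = fit_pplfer(train, endpoint)
            report = validate(
                train, valid, endpoint,
                k=config.k, repetitions=config.repetitions, seed=config.seed,
            )
            models[endpoint] = model
            train_sets[endpoint] = train
            payload = model.to_dict()
            payload["validation"] = report.to_dict()
            payload["config_hash"] = config.config_hash()
            _dump_json(payload, model_dir / f"{endpoint}.json")
            ad = williams_domain(model, train, valid)
            coords = pd.concat(
                [ad.train.assign(set="train"), ad.others.assign(set="validation")]
            )
            coords.insert(0, "leverage_threshold", ad.leverage_threshold)
            wpath = outdir / f"williams_{endpoint}.csv"
            coords.to_csv(wpath, index_label="compound_id")
            artifacts[f"model_{endpoint}"] = str(model_dir / f"{endpoint}.json")
            artifacts[f"williams_{endpoint}"] = str(wpath)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- decompose -----------------------------------------------------------
    stage = "decompose"
    try:
        report = _contribution_report(table, models, train, constants)
        contrib_path = outdir / "contributions_table.csv"
        report.table.to_csv(contrib_path)
        artifacts["contributions"] = str(contrib_path)
        payload = {"table": json.loads(report.table.to_json()),
                   "config_hash": config.config_hash()}
        if report.diagnostics is not None:
            payload["diagnostics"] = json.loads(report.diagnostics.to_json())
        _dump_json(payload, outdir / "contributions_table.json")
        artifacts["contributions_json"] = str(outdir / "contributions_table.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # -- report (run log) ----------------------------------------------------
    stage = "report"
    try:
        import scipy
        import statsmodels

        run_log = {
            "package": {"nanosorb": __version__},
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stages": list(STAGES),
            "artifacts": dict(sorted(artifacts.items())),
            "seed": config.seed,
        }
        log_path = outdir / "run_log.json"
        _dump_json(run_log, log_path)
        artifacts["run_log"] = str(log_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    return artifacts


def _contribution_report(table, models, train, constants):
    """Build the six-column contribution report on the training set.

    Direct |Ead| and logK columns are self-normalized; the four
    decomposition columns (TΔS, enthalpic |Ead|, ΔG_H2O, ΔG_gaseous)
    are referenced against the direct aqueous-logK prediction with the
    decadic factor ±1/(2.303RT), so paired columns approximately sum to
    the direct logK column.
    """
    needed = {"logK_aqueous", "absEad_aqueous"}
    if not needed <= set(models):
        raise StructuralError(
            f"contribution report needs fitted models for {sorted(needed)}"
        )
    logk_model = models["logK_aqueous"]
    scale = 1.0 / (DECADIC_LOG * constants.rt)

    # thermodynamic decompositions on the training compounds
    thermo = pd.DataFrame(index=train.index)
    thermo["delta_g_aqueous"] = train["deltaG_aqueous"]
    thermo["delta_g_gaseous"] = train["deltaG_gaseous"]
    thermo["e_ad_aqueous"] = -train["absEad_aqueous"]
    thermo = decompose_entropy(thermo)
    thermo = decompose_water(thermo)
    aux = train.copy()
    aux["t_delta_s"] = thermo["t_delta_s"]
    aux["delta_g_h2o"] = thermo["delta_g_h2o"]

    def fit_aux(endpoint):
        return fit_pplfer(aux, endpoint, descriptor_set=AQUEOUS_DESCRIPTORS,
                          phase="aqueous")

    columns = [
        term_contributions(models["absEad_aqueous"], train, name="absEad"),
        term_contributions(logk_model, train, name="logK"),
        term_contributions(
            fit_aux("t_delta_s"), train, name="TdS",
            denominator_model=logk_model, scale=scale,
        ),
        term_contributions(
            models["absEad_aqueous"], train, name="Ead_enthalpic",
            denominator_model=logk_model, scale=scale,
        ),
        term_contributions(
            fit_aux("delta_g_h2o"), train, name="dG_H2O",
            denominator_model=logk_model, scale=-scale,
        ),
        term_contributions(
            fit_aux("deltaG_gaseous"), train, name="dG_gaseous",
            denominator_model=logk_model, scale=-scale,
        ),
    ]
    return aggregate_table1_report(columns)


def compare_with_literature(
    model: PPLFERModel, fixtures: list[dict] | None = None
) -> pd.DataFrame:
    """Tabulate a fitted logK model against the packaged literature models.

    Rows are the Abraham-form fixture models of the same phase (plus the
    fitted model itself, labelled ``this fit``); columns carry n_train,
    the recorded R²_train, the coefficients, and coefficient-wise
    differences (fit − fixture) over shared terms.
    """
    if not model.endpoint.startswith("logK"):
        raise StructuralError(
            f"literature comparison is defined for logK endpoints, "
            f"got {model.endpoint!r}"
        )
    fixtures = fixtures if fixtures is not None else literature_models()
    rows = []
    own = {
        "label": "this fit", "nanomaterial": "", "phase": model.phase,
        "n_train": model.n_train, "r2_train": model.r2_train,
        "intercept": model.intercept,
    }
    for d, c in model.coefficients.items():
        own[d] = c
    rows.append(own)
    for fx in fixtures:
        if not fx.get("abraham", False) or fx["phase"] != model.phase:
            continue
        row = {
            "label": fx["label"], "nanomaterial": fx["nanomaterial"],
            "phase": fx["phase"], "n_train": fx["n_train"],
            "r2_train": fx["r2_train"], "intercept": fx["intercept"],
        }
        row.update(fx["coefficients"])
        row["d_intercept"] = model.intercept - fx["intercept"]
        for d in model.descriptor_set:
            if d in fx["coefficients"]:
                row[f"d_{d}"] = model.coefficients[d] - fx["coefficients"][d]
        rows.append(row)
    if len(rows) == 1:
        raise StructuralError(
            f"no comparable literature model for phase {model.phase!r}"
        )
    return pd.DataFrame(rows).set_index("label")
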