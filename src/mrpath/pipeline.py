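"""Config-driven orchestration of the full analysis plan.

A YAML config names the per-trait summary files, instrument thresholds, the
univariable analyses, the multivariable models, mediation pairs and a power
grid; :func:`run_pipeline` executes read → harmonise → select → univariable
MR (all sensitivity methods) → MR-PRESSO/leave-one-out with the joint
outlier rule → MVMR → mediation → power, writes TSV tables plus one JSON
report, and logs every stage to stderr.  Reruns with the same config and
seeds produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, instruments, mediation, mvmr, power, sensitivity, summary_io
from .model import MRModel, MVMRModel

log = logging.getLogger("mrpath")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[mrpath:%(stage)s] %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run every configured stage; returns the report dict (also written to disk)."""
    _setup_logging()
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(output_dir or config.get("output_dir", "mrpath_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _round_floats(config), "stages": {}}

    stage = "read"
    try:
        if not config.get("traits"):
            raise ValueError("no traits configured")
        tables: dict[str, pd.DataFrame] = {}
        for trait, spec in config["traits"].items():
            tables[trait] = summary_io.read_summary_stats(
                spec["path"], trait_id=trait, column_map=spec.get("column_map")
            )
            _log(stage, f"{trait}: {len(tables[trait])} variants from {spec['path']}")
        outcome_id = config["outcome"]
        ld = None
        if config.get("ld_matrix"):
            ld = summary_io.read_ld_matrix(config["ld_matrix"])
            _log(stage, f"LD matrix: {len(ld.variant_ids)} variants")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "select"
    instrument_sets: dict[str, instruments.InstrumentSet] = {}
    try:
        for trait, spec in config.get("instruments", {}).items():
            iset = instruments.select_instruments(
                tables[trait],
                p_threshold=float(spec.get("p_threshold", 5e-8)),
                ld=ld,
                ld_r2_threshold=float(spec.get("ld_r2_threshold", 0.2)),
                retain_correlated=bool(spec.get("retain_correlated", False)),
                exposure_id=trait,
            )
            instrument_sets[trait] = iset
            _log(
                stage,
                f"{trait}: {len(iset.variant_ids)} instruments "
                f"(R2={iset.r2_total:.4g}, F={iset.f_statistic:.1f})",
            )
        report["stages"]["instruments"] = {
            t: json.loads(s.to_json()) for t, s in instrument_sets.items()
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "univariable"
    uni_rows = []
    uni_main: dict[str, estimators.MREstimate] = {}
    decisions = {}
    try:
        for trait in config.get("univariable", []):
            iset = instrument_sets[trait]
            exp_sub = tables[trait][tables[trait]["variant_id"].isin(iset.variant_ids)]
            model = MRModel.from_tables(
                exp_sub, tables[outcome_id],
                ld=_restrict_ld(ld, exp_sub, tables[outcome_id]),
            )
            res = model.fit_all(seed=seed, n_boot=int(config.get("n_boot", 2000)))
            res.insert(0, "exposure_label", trait)
            uni_rows.append(res)
            main = model.fit("ivw_random")
            if model.data.n_variants >= 4 and not iset.correlated_retained:
                dec = model.outlier_decision(
                    n_simulations=int(config.get("presso", {}).get("n_simulations", 2000)),
                    influence_threshold=float(
                        config.get("presso", {}).get("influence_threshold", 1.0)
                    ),
                    seed=seed,
                )
                decisions[trait] = dec.to_dict()
                main = dec.main_estimate
                if dec.removed:
                    _log(stage, f"{trait}: removed outlier(s) {dec.removed}")
            uni_main[trait] = main
            _log(stage, f"{trait}: IVW OR {main.or_scale[0]:.3f}")
        if uni_rows:
            uni_table = pd.concat(uni_rows, ignore_index=True)
            uni_table.to_csv(out_dir / "univariable_mr.tsv", sep="\t", index=False,
                             float_format="%.6g")
            report["stages"]["univariable"] = _round_floats(
                uni_table.to_dict(orient="records")
            )
        report["stages"]["outlier_decisions"] = _round_floats(decisions)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "mvmr"
    mvmr_results: dict[str, mvmr.MVMRResult] = {}
    try:
        mv_rows = []
        for model_spec in config.get("mvmr_models", []):
            label = model_spec.get("label") or " + ".join(model_spec["exposures"])
            exps = model_spec["exposures"]
            model = MVMRModel.from_tables(
                [instrument_sets[e] for e in exps],
                [tables[e] for e in exps],
                tables[outcome_id],
                ld=ld,
                model_label=label,
                exposure_ids=exps,
            )
            for method in ("ivw", "egger"):
                res = model.fit(method)
                mvmr_results[(label, method)] = res
                frame = res.to_frame()
                frame.insert(1, "variant_count", res.n_snps)
                mv_rows.append(frame)
            _log(stage, f"{label}: {res.n_snps} variants")
        if mv_rows:
            mv_table = pd.concat(mv_rows, ignore_index=True)
            mv_table.to_csv(out_dir / "mvmr.tsv", sep="\t", index=False,
                            float_format="%.6g")
            report["stages"]["mvmr"] = _round_floats(mv_table.to_dict(orient="records"))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "mediation"
    try:
        med_rows = []
        for pair in config.get("mediation", []):
            expo, medi = pair["exposure"], pair["mediator"]
            total = uni_main[expo]
            direct = None
            for (label, method), res in mvmr_results.items():
                if method == "ivw" and expo in res.exposure_ids and medi in res.exposure_ids:
                    direct = res.estimate_for(expo)
                    break
            if direct is None:
                raise ValueError(
                    f"no MVMR model with exposures ({expo}, {medi}) for mediation"
                )
            med = mediation.proportion_mediated(
                total, direct, mediator_id=medi,
                n_draws=int(config.get("mediation_draws", 100000)), seed=seed,
            )
            med_rows.append(med.to_dict())
            _log(stage, med.summary())
        if med_rows:
            med_table = pd.DataFrame(med_rows)
            med_table.to_csv(out_dir / "mediation.tsv", sep="\t", index=False,
                             float_format="%.6g")
            report["stages"]["mediation"] = _round_floats(med_rows)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "power"
    try:
        pw = config.get("power")
        if pw:
            rows = []
            for trait, iset in instrument_sets.items():
                res = power.mr_power(
                    r2=iset.r2_total,
                    n_outcome=float(pw["n_outcome"]),
                    case_fraction=float(pw["case_fraction"]),
                    effect=float(pw.get("effect", np.log(0.6))),
                    alpha=float(pw.get("alpha", 0.05)),
                )
                d = res.to_dict()
                d["exposure"] = trait
                rows.append(d)
                _log(stage, f"{trait}: power {res.power:.3f} at OR "
                            f"{np.exp(res.effect):.2f}")
            pw_table = pd.DataFrame(rows)
            pw_table.to_csv(out_dir / "power.tsv", sep="\t", index=False,
                            float_format="%.6g")
            report["stages"]["power"] = _round_floats(rows)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    _log("report", f"wrote {report_path}")
    return report


def _restrict_ld(ld, exposure_table, outcome_table):
    if ld is None:
        return None
    shared = [
        v for v in ld.variant_ids
        if v in set(exposure_table["variant_id"]) and v in set(outcome_table["variant_id"])
    ]
    return ld.subset(shared)
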