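"""End-to-end orchestration with a single config and a run manifest.

The pipeline wires the stages in dependency order — simulate/ingest module
counts, reconstruct and rank by Z score, select candidates, quantify qPCR
screens, build and evaluate classifiers — writing every stage's outputs as
plain tabular files plus a JSON manifest capturing the full config, seeds,
parameter decisions and output digests, so a run can be reproduced and
audited from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import counting, enrichment, modeling, qpcr, simulate
from .scaffold import make_scaffold


class ConfigError(ValueError):
    """Configuration does not validate."""


class DataError(ValueError):
    """Upstream data missing or malformed."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "k": 4,
    "depth": 1_000_000,
    "n_high": 10,
    "n_low": 10,
    "planted_pairs": 5,
    "enrichment_factor": 5.0,
    "direction": "high_vs_low",
    "K": 10_000,
    "n_select": 4,
    "block_rows": 256,
    "max_fixed_mismatches": 0,
    "frequency_denominator": "matched",
    "threshold_multiple": 6.0,
    "cv_threshold": 6.0,
    "ref_Cq": 20.0,
    "ref_E": 1.9,
    "estimator": "ExtraTreesClassifier",
    "cohort_preset": "strong",
    "min_features": 1,
}

_STAGES = ("simulate", "zscan", "select", "qpcr", "model")


def validate_config(config: dict) -> dict:
    """Merge over defaults; reject unknown keys and out-of-range values."""
    unknown = set(config) - set(DEFAULTS) - {"stages"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **config}
    if not 1 <= merged["k"] <= 8:
        raise ConfigError("k must be in [1, 8]")
    if merged["direction"] not in (enrichment.HIGH_VS_LOW, enrichment.LOW_VS_HIGH):
        raise ConfigError(f"bad direction {merged['direction']!r}")
    stages = merged.get("stages", list(_STAGES))
    bad = set(stages) - set(_STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    merged["stages"] = stages
    return merged


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage outputs land under ``out_dir`` as TSV/JSON files. Fails fast with
    the failing stage named. An empty stage list produces a manifest only.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "config": {k: v for k, v in cfg.items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages_run": [],
        "outputs": {},
        "decisions": {
            "sd_convention": "sample (ddof=1)",
            "frequency_denominator": cfg["frequency_denominator"],
            "separation_metric": "min(num) - max(den)",
            "tie_break": "z desc, iA asc, iB asc",
            "ref_Cq": cfg["ref_Cq"],
            "ref_E": cfg["ref_E"],
        },
    }

    profiles = None
    stage = ""
    try:
        if "simulate" in cfg["stages"]:
            stage = "simulate"
            planted = simulate.default_planted(
                cfg["k"], cfg["planted_pairs"], cfg["enrichment_factor"],
                "high", seed=seed,
            )
            sim_cfg = simulate.SimulationConfig(
                seed=seed, k=cfg["k"], n_high=cfg["n_high"], n_low=cfg["n_low"],
                depth=cfg["depth"], planted=planted,
            )
            profiles, tables, truth = simulate.simulate_profiles(sim_cfg)
            counts_dir = out / "counts"
            counts_dir.mkdir(exist_ok=True)
            sheet = []
            for (ta, tb), prof in zip(tables, profiles):
                ta.write_tsv(counts_dir / f"{ta.sample_id}_A.tsv")
                tb.write_tsv(counts_dir / f"{tb.sample_id}_B.tsv")
                sheet.append({"sample_id": prof.sample_id, "group": prof.group})
            pd.DataFrame(sheet).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
            truth.write(out / "ground_truth.json")
            manifest["stages_run"].append(stage)

        if "zscan" in cfg["stages"]:
            stage = "zscan"
            if profiles is None:
                profiles = load_profiles(out, cfg["k"])
            result = enrichment.contrast_zscores(
                profiles, cfg["direction"], K=cfg["K"], block_rows=cfg["block_rows"],
            )
            manifest["stages_run"].append(stage)
            if "select" in cfg["stages"]:
                result = enrichment.select_candidates(result, profiles, cfg["n_select"])
                manifest["stages_run"].append("select")
            scaffold = make_scaffold(cfg["k"])
            frame = result.to_frame(scaffold)
            frame.to_csv(out / "ranked_hits.tsv", sep="\t", index=False,
                         float_format="%.12g")
            if result.selected:
                sel = pd.DataFrame(
                    [{"iA": h.iA, "iB": h.iB, "z": h.z, "separation": h.separation}
                     for h in result.selected]
                )
                sel.to_csv(out / "selected.tsv", sep="\t", index=False,
                           float_format="%.12g")
            manifest["zscan"] = {
                **result.parameters, "n_zero_sd": result.n_zero_sd,
            }

        if "qpcr" in cfg["stages"]:
            stage = "qpcr"
            rng = np.random.default_rng(seed + 1)
            truths = []
            for s in range(8):
                for apt in simulate.RTP_FEATURES:
                    for repwell in range(2):
                        truths.append(simulate.QpcrTruth(
                            f"w{s}_{apt}_{repwell}", f"S{s:02d}", apt, "run1",
                            float(rng.uniform(1.75, 2.0)),
                            float(rng.uniform(18, 28)),
                        ))
            curves = simulate.simulate_qpcr(truths, noise_sigma=0.01, seed=seed + 2)
            rows = []
            for c in curves:
                for cyc, f in zip(c.cycles, c.fluorescence):
                    rows.append({"run_id": c.run_id, "well_id": c.well_id,
                                 "sample_id": c.sample_id,
                                 "aptamarker": c.aptamarker_name,
                                 "cycle": int(cyc), "fluorescence": f})
            curve_df = pd.DataFrame(rows)
            wells, norms, rtp = qpcr.quantify_plate(
                curve_df, cfg["threshold_multiple"], cfg["cv_threshold"],
                cfg["ref_Cq"], cfg["ref_E"],
            )
            wells.to_csv(out / "qpcr_wells.tsv", sep="\t", index=False)
            norms.to_csv(out / "qpcr_runs.tsv", sep="\t", index=False)
            rtp.to_csv(out / "rtp_matrix.tsv", sep="\t")
            manifest["stages_run"].append(stage)

        if "model" in cfg["stages"]:
            stage = "model"
            maker = (simulate.strong_cohort_config
                     if cfg["cohort_preset"] == "strong"
                     else simulate.null_cohort_config)
            table, truth = simulate.simulate_cohort(maker(seed=seed))
            scaled, _ = modeling.zero_mean_scale(table)
            reports = modeling.sequential_feature_exclusion(
                scaled, cfg["estimator"], seed=seed,
                min_features=cfg["min_features"],
            )
            modeling.reports_to_frame(reports).to_csv(
                out / "model_reports.tsv", sep="\t", index=False,
                float_format="%.6g")
            imp = pd.DataFrame([reports[0].feature_importances]).T
            imp.columns = ["importance"]
            imp.index.name = "feature"
            imp.to_csv(out / "feature_importances.tsv", sep="\t",
                       float_format="%.6g")
            manifest["stages_run"].append(stage)
    except (ConfigError, DataError):
        raise
    except FileNotFoundError as exc:
        raise DataError(f"stage {stage!r}: missing upstream output: {exc}") from exc
    except ValueError as exc:
        raise DataError(f"stage {stage!r}: {exc}") from exc

    for p in sorted(out.rglob("*.tsv")) + sorted(out.glob("*.json")):
        if p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_profiles(run_dir: str | Path, k: int) -> list[enrichment.SampleLibraryProfile]:
    """Rebuild sample profiles from a run directory's count files and sheet."""
    run_dir = Path(run_dir)
    sheet_path = run_dir / "sample_sheet.tsv"
    if not sheet_path.exists():
        raise DataError(f"no sample sheet at {sheet_path}")
    sheet = pd.read_csv(sheet_path, sep="\t")
    profiles = []
    for _, row in sheet.iterrows():
        sid, group = str(row["sample_id"]), str(row["group"])
        ta = counting.ModuleCountTable.from_tsv(
            run_dir / "counts" / f"{sid}_A.tsv", sid, "A", k)
        tb = counting.ModuleCountTable.from_tsv(
            run_dir / "counts" / f"{sid}_B.tsv", sid, "B", k)
        profiles.append(enrichment.SampleLibraryProfile(
            sid, group,
            counting.to_frequencies(ta), counting.to_frequencies(tb)))
    return profiles
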