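"""End-to-end orchestration: simulate -> compress -> resolve -> clean ->
preprocess -> ASCA -> PLS-DA -> correspond.

One config (YAML-friendly nested dict) drives the whole study; a master
seed deterministically derives every stage's random stream, so a rerun
with the same config produces byte-identical numeric outputs. Each stage
writes its tables under the results directory and appends its row/column
audit to the manifest.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import asca as asca_mod
from . import correspondence as corr_mod
from . import features as feat_mod
from . import mcr as mcr_mod
from . import plsda as plsda_mod
from .assembly import build_augmented, segment_regions, trim_injection
from .ms_io import save_arrays, write_feature_table, write_mzml
from .roi import ROIParams, build_union_axis, extract_rois
from .synthetic import (
    DetectionConfig,
    NoiseModel,
    default_study_components,
    emit_fp_feature_table,
    generate_design,
    simulate_study,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run"]

logger = logging.getLogger("roimcr")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "ionization_mode": "+",
    "design": {
        "n_reps_per_cell": 3,
        "include_blanks": True,
        "include_qc": True,
        "n_blanks": 3,
        "n_qc": 8,
    },
    "simulate": {
        "n_analytes": 40,
        "n_background": 40,
        "scan_interval": 0.4,
        "run_length": 1800.0,
        "noise": "default",  # or a dict of NoiseModel fields
    },
    "roi": {
        "mass_tolerance": 0.005,
        "intensity_threshold": 500.0,
        "min_consecutive_scans": 30,
        "max_gap": 0,
    },
    "injection_cutoff_s": 330.0,
    "regions": {"strategy": "tic-valley", "n_regions": 12, "boundaries": None},
    "mcr": {"n_components": "auto", "target_lof": 7.3, "tol": 1e-3, "max_iter": 50},
    "cleaning": {
        "blank_fold": 3.0,
        "max_replicate_cv": 1.0,
        "min_consistent_fraction": 0.5,
        "min_presence_fraction": 0.4,
        "min_width_s": 2.0,
        "max_width_s": 60.0,
        "min_top_to_edge": 5.0,
        "min_unimodal_fraction": 0.7,
    },
    "fp": {
        "min_intensity": 500.0,
        "min_scan_span": 5,
        "reject_tailing_tau": 8.0,
        "false_positive_rate": 0.1,
    },
    "preprocess": {"log_first": False, "epsilon": None},
    "asca": {"enabled": True, "n_perm": 1000, "n_boot": 200, "alpha": 0.05},
    "plsda": {"enabled": True, "k": 5, "n_perm": 200, "schemes": ["type", "early_late"]},
    "correspondence": {"mz_tol": 0.005, "rt_tol_min": 0.3, "base_peak_frac": 0.05},
    "io": {"write_mzml": False},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if key not in base:
            raise ValueError(f"unknown config key: {path + key}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults, check ranges, normalize units.

    An empty config yields the full default parameter set (0.005 Da mass
    tolerances, 0.3 min RT tolerance, 330 s injection cutoff, 30
    consecutive scans, 1000/200 permutations, 5-fold CV, alpha 0.05).
    The RT matching tolerance is entered in minutes and additionally
    stored in seconds (``rt_tol_s``) for internal use.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if cfg["roi"]["mass_tolerance"] <= 0:
        raise ValueError("roi.mass_tolerance must be > 0")
    if cfg["correspondence"]["mz_tol"] < 0:
        raise ValueError("correspondence.mz_tol must be >= 0")
    if cfg["correspondence"]["rt_tol_min"] < 0:
        raise ValueError("correspondence.rt_tol_min must be >= 0")
    if cfg["injection_cutoff_s"] < 0:
        raise ValueError("injection_cutoff_s must be >= 0")
    if cfg["asca"]["n_perm"] < 1 or cfg["plsda"]["n_perm"] < 1:
        raise ValueError("permutation counts must be >= 1")
    if not (0 < cfg["asca"]["alpha"] < 1):
        raise ValueError("asca.alpha must be in (0, 1)")
    cfg["correspondence"]["rt_tol_s"] = cfg["correspondence"]["rt_tol_min"] * 60.0
    return cfg


def _spawn_seeds(master: int, names: list) -> dict:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: c for n, c in zip(names, children)}


def _mass_entries_from_features(table) -> list:
    return [
        corr_mod.MassEntry(str(fid), float(row["mz"]), float(row["rt"]), source="fp-feature")
        for fid, row in table.data.iterrows()
    ]


def run(config: dict | None, outdir, design=None) -> dict:
    """Run the full study; returns the result bundle and writes outputs.

    Any stage error aborts with the stage name and cause. ``design``
    overrides the generated design (e.g. a design with outliers removed).
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg["seed"], ["components", "simulate", "fp", "asca", "plsda"])
    manifest: dict = {"config": _jsonable(cfg), "stages": [], "seed": cfg["seed"]}
    bundle: dict = {"config": cfg}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s done in %.1f s", name, time.time() - t0)
            return result

        return deco

    # -- simulate ----------------------------------------------------------
    @stage("simulate")
    def _sim():
        d = design or generate_design(**cfg["design"])
        comps = default_study_components(
            cfg["simulate"]["n_analytes"],
            cfg["simulate"]["n_background"],
            seed=seeds["components"],
            run_length=cfg["simulate"]["run_length"],
        )
        noise = (
            NoiseModel()
            if cfg["simulate"]["noise"] == "default"
            else NoiseModel(**cfg["simulate"]["noise"])
        )
        scansets, truth = simulate_study(
            d,
            comps,
            noise,
            scan_interval=cfg["simulate"]["scan_interval"],
            run_length=cfg["simulate"]["run_length"],
            seed=seeds["simulate"],
        )
        return d, comps, scansets, truth

    design_obj, components, scansets, truth = _sim
    design_obj.to_csv(outdir / "design.csv")
    truth.to_files(outdir / "truth")
    if cfg["io"]["write_mzml"]:
        (outdir / "mzml").mkdir(exist_ok=True)
        for sid, ss in scansets.items():
            write_mzml(ss, outdir / "mzml" / f"{sid}.mzML")
    manifest["stages"].append({"stage": "simulate", "samples": len(scansets), "components": len(components)})

    # -- ROI compression ---------------------------------------------------
    @stage("extract")
    def _extract():
        params = ROIParams(**cfg["roi"])
        roi_sets = {}
        trimmed = {}
        for sid, ss in scansets.items():
            ts = trim_injection(ss, cfg["injection_cutoff_s"])
            trimmed[sid] = ts
            roi_sets[sid] = extract_rois(ts, params)
        return trimmed, roi_sets

    trimmed, roi_sets = _extract
    n_rois = {sid: len(r) for sid, r in roi_sets.items()}
    manifest["stages"].append({"stage": "extract", "rois_per_sample_median": float(np.median(list(n_rois.values())))})

    # -- augmented matrix + regions ---------------------------------------
    @stage("assemble")
    def _assemble():
        union_mz, mapping = build_union_axis(roi_sets, cfg["roi"]["mass_tolerance"])
        aug = build_augmented(roi_sets, union_mz, mapping, trimmed, design_obj.sample_ids)
        regions = segment_regions(
            aug,
            cfg["regions"]["strategy"],
            cfg["regions"]["n_regions"],
            cfg["regions"]["boundaries"],
        )
        return union_mz, aug, regions

    union_mz, aug, regions = _assemble
    pd.DataFrame({"mz": union_mz}).to_csv(outdir / "union_axis.csv", index=False)
    manifest["stages"].append(
        {
            "stage": "assemble",
            "rows": int(aug.data.shape[0]),
            "union_rois": int(aug.data.shape[1]),
            "K": aug.K,
            "regions": len(regions),
        }
    )

    # -- MCR/ALS -----------------------------------------------------------
    @stage("decompose")
    def _decompose():
        models = mcr_mod.decompose_regions(
            regions,
            cfg["mcr"]["n_components"],
            target_lof=cfg["mcr"]["target_lof"],
            tol=cfg["mcr"]["tol"],
            max_iter=cfg["mcr"]["max_iter"],
        )
        cam = mcr_mod.assemble_area_matrix(models, design_obj)
        return models, cam

    models, cam = _decompose
    fit_rows = [
        {"region": m.region_id, "n_components": m.n_components, "lof": m.lof, "r2": m.r2, "converged": m.converged}
        for m in models
    ]
    pd.DataFrame(fit_rows).to_csv(outdir / "mcr_fit.csv", index=False)
    for m in models:
        save_arrays(
            {
                "region": m.region_id,
                "n_components": m.n_components,
                "lof": m.lof,
                "r2": m.r2,
                "sample_ids": list(m.block_index),
            },
            {"C": m.C, "S": m.S, "col_mz": m.col_mz},
            outdir / f"mcr_model_r{m.region_id:02d}",
        )
    manifest["stages"].append(
        {
            "stage": "decompose",
            "n_models": len(models),
            "total_components": int(cam.areas.shape[1]),
            "max_lof": float(max(m.lof for m in models)),
            "min_r2": float(min(m.r2 for m in models)),
        }
    )

    # -- cleaning ----------------------------------------------------------
    @stage("clean")
    def _clean():
        rules = mcr_mod.ShapeRules(
            min_width_s=cfg["cleaning"]["min_width_s"],
            max_width_s=cfg["cleaning"]["max_width_s"],
            min_top_to_edge=cfg["cleaning"]["min_top_to_edge"],
            min_unimodal_fraction=cfg["cleaning"]["min_unimodal_fraction"],
        )
        return mcr_mod.clean_components(
            cam,
            models,
            design_obj,
            blank_fold=cfg["cleaning"]["blank_fold"],
            shape_rules=rules,
            max_replicate_cv=cfg["cleaning"]["max_replicate_cv"],
            min_consistent_fraction=cfg["cleaning"]["min_consistent_fraction"],
            min_presence_fraction=cfg["cleaning"]["min_presence_fraction"],
        )

    cam_clean, clean_log = _clean
    clean_log.to_csv(outdir / "cleaning_log.csv", index=False)
    cam_clean.meta.to_csv(outdir / "components.csv")
    cam_clean.areas.to_csv(outdir / "component_areas.csv")
    from .evaluation import component_recovery

    recovery = component_recovery(cam_clean, truth, rt_min=cfg["injection_cutoff_s"])
    manifest["stages"].append(
        {
            "stage": "clean",
            "components_before": int(cam.areas.shape[1]),
            "components_after": int(cam_clean.areas.shape[1]),
            "recovery_precision": recovery["precision"],
            "recovery_recall": recovery["recall"],
        }
    )

    # -- FP branch ---------------------------------------------------------
    @stage("fp_table")
    def _fp():
        det = DetectionConfig(
            min_intensity=cfg["fp"]["min_intensity"],
            min_scan_span=cfg["fp"]["min_scan_span"],
            scan_interval=cfg["simulate"]["scan_interval"],
            reject_tailing_tau=cfg["fp"]["reject_tailing_tau"],
            false_positive_rate=cfg["fp"]["false_positive_rate"],
        )
        table = emit_fp_feature_table(truth, det, seed=seeds["fp"].generate_state(1)[0] % (2**31))
        audit = feat_mod.ReductionAudit()
        audit.record("fp_export", len(table.data), len(table.data), len(table.data), len(table.data))
        reduced = feat_mod.drop_injection_features(table, cfg["injection_cutoff_s"], audit)
        reduced = feat_mod.blank_subtract(reduced, design_obj, cfg["cleaning"]["blank_fold"], audit)
        return table, reduced, audit

    fp_raw, fp_reduced, audit = _fp
    write_feature_table(fp_raw, outdir / "fp_features_raw.csv")
    write_feature_table(fp_reduced, outdir / "fp_features_reduced.csv")
    audit.to_frame().to_csv(outdir / "reduction_audit.csv", index=False)
    manifest["stages"].append(
        {"stage": "fp_table", "features_raw": fp_raw.n_features, "features_reduced": fp_reduced.n_features}
    )

    # -- preprocessing (both workflows, 42 core samples) -------------------
    @stage("preprocess")
    def _preprocess():
        study_ids = [s.sample_id for s in design_obj.study_samples]
        mcr_matrix = feat_mod.AreaMatrix(
            cam_clean.areas.loc[study_ids].copy(), cam_clean.meta.copy(), provenance="mcr"
        )
        fp_matrix = feat_mod.feature_table_to_matrix(fp_reduced, provenance="fp")
        fp_matrix.values = fp_matrix.values.loc[[s for s in study_ids if s in fp_matrix.values.index]]
        pp = cfg["preprocess"]
        return (
            feat_mod.preprocess_areas(mcr_matrix, pp["log_first"], pp["epsilon"]),
            feat_mod.preprocess_areas(fp_matrix, pp["log_first"], pp["epsilon"]),
        )

    X_mcr, X_fp = _preprocess
    manifest["stages"].append(
        {
            "stage": "preprocess",
            "mcr_matrix": list(X_mcr.values.shape),
            "fp_matrix": list(X_fp.values.shape),
        }
    )

    # -- ASCA --------------------------------------------------------------
    asca_results = {}
    sig_vars = {}
    if cfg["asca"]["enabled"]:

        @stage("asca")
        def _asca():
            out = {}
            sig = {}
            seeds_a = seeds["asca"].spawn(2 * 4)
            for w, (tag, X) in enumerate((("mcr", X_mcr), ("fp", X_fp))):
                res = asca_mod.asca_fit(X.values, design_obj)
                for e_i, eff in enumerate(asca_mod.EFFECTS):
                    res.effects[eff]["p_value"] = asca_mod.permutation_test(
                        X.values,
                        design_obj,
                        eff,
                        n_perm=cfg["asca"]["n_perm"],
                        seed=seeds_a[w * 4 + e_i],
                    )
                boot = {}
                for e_i, eff in enumerate(("type", "time")):
                    boot[eff] = asca_mod.bootstrap_loadings(
                        X.values,
                        design_obj,
                        eff,
                        n_boot=cfg["asca"]["n_boot"],
                        alpha=cfg["asca"]["alpha"],
                        seed=seeds_a[w * 4 + 3],
                    )
                out[tag] = res
                sig[tag] = {eff: b.index[b["significant"]].tolist() for eff, b in boot.items()}
                res.summary().to_csv(outdir / f"asca_{tag}.csv", index=False)
                for eff, b in boot.items():
                    b.to_csv(outdir / f"asca_{tag}_loadings_{eff}.csv")
            return out, sig

        asca_results, sig_vars = _asca
        manifest["stages"].append(
            {
                "stage": "asca",
                "percents_mcr": {k: round(v, 3) for k, v in asca_results["mcr"].percents().items()},
                "percents_fp": {k: round(v, 3) for k, v in asca_results["fp"].percents().items()},
            }
        )

    # -- PLS-DA ------------------------------------------------------------
    plsda_results = {}
    vip_sets = {}
    if cfg["plsda"]["enabled"]:

        @stage("plsda")
        def _plsda():
            out = {}
            vips = {}
            rows = []
            seeds_p = seeds["plsda"].spawn(2 * len(cfg["plsda"]["schemes"]))
            i = 0
            for tag, X in (("mcr", X_mcr), ("fp", X_fp)):
                samples = list(X.values.index)
                schemes = plsda_mod.label_schemes(design_obj, samples)
                for scheme in cfg["plsda"]["schemes"]:
                    labels = schemes[scheme]
                    perm = plsda_mod.permutation_validate(
                        X.values,
                        labels,
                        k=cfg["plsda"]["k"],
                        n_perm=cfg["plsda"]["n_perm"],
                        seed=seeds_p[i],
                    )
                    cv = perm["cv"]
                    model = plsda_mod.plsda_fit(X.values, labels, cv["n_lv"])
                    vip = plsda_mod.vip_scores(model)
                    out[(tag, scheme)] = {"cv": cv, "perm_p": perm["p_value"], "model": model, "vip": vip}
                    vips[(tag, scheme)] = vip.index[vip > 1.0].tolist()
                    vip.to_csv(outdir / f"vip_{tag}_{scheme}.csv")
                    rows.append(
                        {
                            "workflow": tag,
                            "scheme": scheme,
                            "n_lv": cv["n_lv"],
                            "cv_class_error": cv["class_error"],
                            "r2y": model.r2y,
                            "r2x": model.r2x,
                            "perm_p": perm["p_value"],
                            "n_vip_gt1": len(vips[(tag, scheme)]),
                            **{f"sens_{c}": s for c, s in cv["sensitivity"].items()},
                        }
                    )
                    i += 1
            pd.DataFrame(rows).to_csv(outdir / "plsda_summary.csv", index=False)
            return out, vips

        plsda_results, vip_sets = _plsda
        manifest["stages"].append(
            {
                "stage": "plsda",
                "class_errors": {
                    f"{t}_{s}": round(r["cv"]["class_error"], 4) for (t, s), r in plsda_results.items()
                },
            }
        )

    # -- correspondence ----------------------------------------------------
    @stage("correspond")
    def _correspond():
        cc = cfg["correspondence"]
        roi_entries = [
            corr_mod.MassEntry(f"u{k}", float(mz), source="roi") for k, mz in enumerate(union_mz)
        ]
        fp_raw_entries = _mass_entries_from_features(fp_raw)
        fp_red_entries = _mass_entries_from_features(fp_reduced)
        comp_entries = []
        for cid in cam_clean.areas.columns:
            mzs, spec = cam_clean.spectra[cid]
            comp_entries.extend(
                corr_mod.unfold_component(
                    cid, mzs, spec, float(cam_clean.meta.loc[cid, "apex_rt"]), cc["base_peak_frac"]
                )
            )
        stages_dict = {
            "rois_vs_features": (roi_entries, fp_raw_entries, "mass"),
            "components_vs_reduced": (comp_entries, fp_red_entries, "mass_rt"),
        }
        if sig_vars:
            sig_comp = []
            for cid in sig_vars["mcr"].get("type", []) + sig_vars["mcr"].get("time", []):
                if cid in cam_clean.spectra:
                    mzs, spec = cam_clean.spectra[cid]
                    sig_comp.extend(
                        corr_mod.unfold_component(
                            cid, mzs, spec, float(cam_clean.meta.loc[cid, "apex_rt"]), cc["base_peak_frac"]
                        )
                    )
            sig_feat_ids = set(sig_vars["fp"].get("type", []) + sig_vars["fp"].get("time", []))
            sig_feat = [e for e in fp_red_entries if e.entry_id in sig_feat_ids]
            if sig_comp and sig_feat:
                stages_dict["asca_prioritized"] = (sig_comp, sig_feat, "mass_rt")
        if vip_sets:
            vip_comp_ids = set().union(*(v for (t, _s), v in vip_sets.items() if t == "mcr"))
            vip_feat_ids = set().union(*(v for (t, _s), v in vip_sets.items() if t == "fp"))
            vip_comp = []
            for cid in sorted(vip_comp_ids):
                if cid in cam_clean.spectra:
                    mzs, spec = cam_clean.spectra[cid]
                    vip_comp.extend(
                        corr_mod.unfold_component(
                            cid, mzs, spec, float(cam_clean.meta.loc[cid, "apex_rt"]), cc["base_peak_frac"]
                        )
                    )
            vip_feat = [e for e in fp_red_entries if e.entry_id in vip_feat_ids]
            if vip_comp and vip_feat:
                stages_dict["vip_prioritized"] = (vip_comp, vip_feat, "mass_rt")
        return corr_mod.stage_report(stages_dict, cc["mz_tol"], cc["rt_tol_min"])

    corr_table = _correspond
    corr_table.to_csv(outdir / "correspondence.csv", index=False)
    manifest["stages"].append({"stage": "correspond", "n_stages": int(len(corr_table))})

    manifest["elapsed_s"] = None  # timings live in the log, not the manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished in %.1f s", time.time() - t_start)

    bundle.update(
        {
            "design": design_obj,
            "truth": truth,
            "scansets": scansets,
            "roi_sets": roi_sets,
            "union_mz": union_mz,
            "aug": aug,
            "regions": regions,
            "models": models,
            "cam": cam,
            "cam_clean": cam_clean,
            "clean_log": clean_log,
            "recovery": recovery,
            "fp_raw": fp_raw,
            "fp_reduced": fp_reduced,
            "X_mcr": X_mcr,
            "X_fp": X_fp,
            "asca": asca_results,
            "asca_significant": sig_vars,
            "plsda": plsda_results,
            "vip_sets": vip_sets,
            "correspondence": corr_table,
            "manifest": manifest,
        }
    )
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
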