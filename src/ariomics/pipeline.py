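"""End-to-end orchestration from one config plus the in-package worked example.

``run_pipeline`` executes the enabled stages in dependency order (simulate ->
diffsig / trace / lipid / raman / clinical), seeds every random procedure
from one global seed, writes its tables under the configured output
directory and returns a machine-readable run report.

``load_table1_fixture`` returns the packaged six-comparison log2
fold-change matrix of the thirteen proteins consistently modulated across
all three resistant lines in both culture formats — the desk-scale worked
example for the consistency filter.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .diffsig import differential_table, intersect_contexts, score_selection, select_consistent
from .isotope import correct_mid, enrichment_metrics, parse_formula
from .lipids import lipid_diff_matrix
from .raman import band_ratios, compare_groups, run_map_pipeline
from .survival import km_curve, logrank_test, stratify_kmeans
from .synthetic import SimDesign, gen_cohort, gen_lipidome, gen_proteome, gen_raman_map, gen_tracing_samples

__all__ = ["DEFAULTS", "load_config", "run_pipeline", "load_table1_fixture", "make_table1_decoys"]

_TABLE1_SHA256 = "457f8040e4d64f99b4a324c5276a3109cbdbda8f5bbba6382eba788f929862e6"

# All thresholds default to the study's printed values.
DEFAULTS: dict = {
    "seed": 0,
    "outdir": "results/pipeline",
    "stages": ["simulate", "diffsig", "trace", "lipid", "raman", "clinical"],
    "diffsig": {"fc": 1.5, "p": 0.05, "k_of_n": None, "require_sign": True,
                "permutation": False, "use_q": False},
    "trace": {"formula": "C3H4O3", "true_mid": None, "n_reps": 3,
              "noise_cv": 0.05, "mode": "all-elements", "purity": 1.0},
    "lipid": {"fc": 1.2, "p": 0.05, "min_groups": 1, "mode": "logFC",
              "ko_effect": 2.0},
    "raman": {"floor": 60000.0, "sd_k": 1.0, "anchor": 2933.0,
              "crop": [2800.0, 3020.0], "group_delta": 0.3,
              "n_maps_per_group": 4, "nx": 8, "ny": 8},
    "clinical": {"k": 3, "restarts": 10, "n": 300,
                 "hazard_ratios": [1.0, 1.4, 2.0], "censor_rate": 0.3},
    "proteome": {"n_features": 2000, "frac_signature": 0.05, "reps_per_group": 4,
                 "effect_log2_range": [1.0, 2.0], "noise_sd_log": 0.3},
}


class ConfigError(ValueError):
    """Run configuration violates the schema."""


def _merge(defaults: dict, override: dict) -> dict:
    out = dict(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML run config against the defaults schema."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    unknown = set(cfg["stages"]) - set(DEFAULTS["stages"])
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    if not cfg["stages"]:
        raise ConfigError("no stage enabled")
    return cfg


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 13 x 6 log2FC matrix of the consistent resistance panel."""
    ref = resources.files("ariomics").joinpath("data/table1_log2fc.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            f"panel fixture corrupted: sha256 {digest} != expected {_TABLE1_SHA256}"
        )
    df = pd.read_csv(ref.open("r"), sep="\t", index_col="gene")
    return df.drop(columns="protein")


def make_table1_decoys(n: int = 20, seed: int = 0) -> pd.DataFrame:
    """Decoy rows that each fail the |log2FC| >= log2(1.5) rule in >=1 column."""
    rng = np.random.default_rng(seed)
    cols = load_table1_fixture().columns
    rows = {}
    thr = np.log2(1.5)
    for i in range(n):
        vals = rng.uniform(0.7, 3.0, size=len(cols)) * rng.choice([-1, 1], size=len(cols))
        n_fail = int(rng.integers(1, len(cols) + 1))
        fail_at = rng.choice(len(cols), size=n_fail, replace=False)
        vals[fail_at] = rng.uniform(-0.95, 0.95, size=n_fail) * thr
        rows[f"DECOY{i:02d}"] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def table1_selection(n_decoys: int = 20, seed: int = 0) -> list:
    """Worked example: consistency filter on the fixture plus failing decoys.

    All significance flags are set to pass (the fixture publishes fold
    changes of already-significant proteins), so the filter reduces to the
    fold-change/sign consistency rule in all six comparisons.
    """
    fixture = pd.concat([load_table1_fixture(), make_table1_decoys(n_decoys, seed)])
    tidy = fixture.rename_axis("feature").reset_index().melt(
        id_vars="feature", var_name="comparison", value_name="log2fc"
    )
    parts = tidy["comparison"].str.split("_", expand=True)
    tidy["format"], tidy["group"] = parts[1], parts[2]
    tidy["p"] = 0.01
    tidy["q"] = 0.01
    tidy["sign"] = np.sign(tidy["log2fc"]).astype(int)
    return select_consistent(tidy, fc_threshold=1.5, p_threshold=0.05,
                             k_of_n=6, require_sign=True)


def _seed_for(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the one global seed."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    child = np.random.SeedSequence(seed, spawn_key=(tag,))
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the enabled stages; return (and write) a machine-readable report."""
    cfg = _merge(DEFAULTS, config or {})
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"version": __version__, "seed": seed, "stages": {}}
    stages = cfg["stages"]

    # --- simulate -----------------------------------------------------------
    prot = dict(cfg["proteome"])
    prot["effect_log2_range"] = tuple(prot["effect_log2_range"])
    design = SimDesign(seed=_seed_for(seed, "proteome"), **prot)
    proteomes, prot_truth = gen_proteome(design)
    trace_cfg = cfg["trace"]
    formula = parse_formula(trace_cfg["formula"])
    true_mid = trace_cfg["true_mid"]
    if true_mid is None:
        true_mid = np.zeros(formula.n_carbon + 1)
        true_mid[0], true_mid[-1] = 0.4, 0.6  # partially labelled pool
    records = gen_tracing_samples(
        formula, np.asarray(true_mid, dtype=float), trace_cfg["n_reps"],
        trace_cfg["noise_cv"], seed=_seed_for(seed, "trace"), mode=trace_cfg["mode"],
    )
    lipid_mat, species, lipid_truth = gen_lipidome(
        ko_effect=cfg["lipid"]["ko_effect"], seed=_seed_for(seed, "lipidome")
    )
    raman_cfg = cfg["raman"]
    study = gen_raman_map(
        nx=raman_cfg["nx"], ny=raman_cfg["ny"], group_delta=raman_cfg["group_delta"],
        n_maps_per_group=raman_cfg["n_maps_per_group"], seed=_seed_for(seed, "raman"),
    )
    clin = cfg["clinical"]
    cohort, cohort_truth = gen_cohort(
        n=clin["n"], hazard_ratio_per_group=tuple(clin["hazard_ratios"]),
        censor_rate=clin["censor_rate"], seed=_seed_for(seed, "cohort"),
    )
    if "simulate" in stages:
        for fmt, mat in proteomes.items():
            io.write_omics_matrix(mat, out / f"proteome_{fmt}.tsv", out / f"design_{fmt}.tsv")
        prot_truth.to_csv(out / "proteome_truth.tsv", sep="\t")
        io.write_isotopologues(records, out / "isotopologues.tsv")
        io.write_omics_matrix(lipid_mat, out / "lipidome.tsv", out / "lipidome_design.tsv")
        for map_id, rmap in study.maps.items():
            io.write_raman_map(rmap, out / f"raman_{map_id}.tsv", out / f"raman_{map_id}_coords.tsv")
        io.write_cohort(cohort, out / "cohort.tsv")
        report["stages"]["simulate"] = {
            "generators": ["proteome", "tracing", "lipidome", "raman", "cohort"],
            "n_features": design.n_features,
            "n_raman_maps": len(study.maps),
            "n_patients": len(cohort),
        }

    # --- differential signature ---------------------------------------------
    if "diffsig" in stages:
        ds = cfg["diffsig"]
        selections, results = {}, []
        for fmt, mat in proteomes.items():
            res = differential_table(
                mat, permutation=ds["permutation"], seed=_seed_for(seed, f"perm-{fmt}")
            )
            results.append(res)
            selections[fmt] = select_consistent(
                res, fc_threshold=ds["fc"], p_threshold=ds["p"],
                k_of_n=ds["k_of_n"], require_sign=ds["require_sign"],
                p_column="q" if ds["use_q"] else "p",
            )
        res_all = pd.concat(results, ignore_index=True)
        res_all.to_csv(out / "differential_table.tsv", sep="\t", index=False)
        panel = intersect_contexts(selections, res=res_all, require_sign=ds["require_sign"])
        panel.table.to_csv(out / "signature_panel.tsv", sep="\t")
        scores = score_selection(panel.features, prot_truth)
        worked = table1_selection(seed=_seed_for(seed, "decoys"))
        report["stages"]["diffsig"] = {
            "panel_size": len(panel),
            "sensitivity": scores["sensitivity"],
            "observed_fdr": scores["observed_fdr"],
            "table1_worked_example_count": len(worked),
            "params": ds,
        }

    # --- isotope tracing ------------------------------------------------------
    if "trace" in stages:
        rows = []
        for rec in records:
            x, total = correct_mid(rec, mode=trace_cfg["mode"])
            metrics = enrichment_metrics(x)
            rows.append({
                "compound": rec.compound, "sample": rec.sample, "total": total,
                "labelled_fraction": metrics["labelled_fraction"],
                "fractional_enrichment": metrics["fractional_enrichment"],
                **{f"M{i}": v for i, v in enumerate(x)},
            })
        pd.DataFrame(rows).to_csv(out / "corrected_mids.tsv", sep="\t", index=False)
        report["stages"]["trace"] = {
            "n_records": len(records), "formula": trace_cfg["formula"],
            "mode": trace_cfg["mode"],
        }

    # --- lipidomics -----------------------------------------------------------
    if "lipid" in stages:
        lp = cfg["lipid"]
        matrix, ann = lipid_diff_matrix(
            lipid_mat, species, mode=lp["mode"], fc_threshold=lp["fc"],
            p_threshold=lp["p"], min_groups=lp["min_groups"],
        )
        matrix.to_csv(out / "lipid_heatmap.tsv", sep="\t")
        ann.to_csv(out / "lipid_annotations.tsv", sep="\t")
        report["stages"]["lipid"] = {
            "n_retained": len(matrix),
            "n_high_unsat": int((ann["saturation"] == "high_unsat").sum()),
            "params": lp,
        }

    # --- raman ----------------------------------------------------------------
    if "raman" in stages:
        ratios, reports = {}, {}
        for map_id, rmap in study.maps.items():
            ratios[map_id], reports[map_id] = run_map_pipeline(
                rmap, crop=tuple(raman_cfg["crop"]),
                intensity_floor=raman_cfg["floor"], sd_k=raman_cfg["sd_k"],
                anchor=raman_cfg["anchor"],
            )
        comparison = compare_groups(ratios, study.grouping)
        comparison.to_csv(out / "raman_group_comparison.tsv", sep="\t", index=False)
        pd.DataFrame(reports).T.to_csv(out / "raman_qc_report.tsv", sep="\t")
        report["stages"]["raman"] = {
            "n_maps": len(study.maps),
            "p_lipid_ratio": float(comparison.loc[comparison["ratio"] == "r_lipid", "p"].iloc[0]),
        }

    # --- clinical -------------------------------------------------------------
    if "clinical" in stages:
        strata = stratify_kmeans(
            cohort, k=clin["k"], restarts=clin["restarts"],
            seed=_seed_for(seed, "kmeans"),
        )
        strata.labels.rename_axis("patient").to_csv(out / "strata.tsv", sep="\t")
        curves = []
        from .survival import CohortTable
        for label in strata.strata:
            sub = CohortTable(cohort.data[strata.labels == label])
            curve = km_curve(sub)
            curve["stratum"] = label
            curves.append(curve)
        pd.concat(curves).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        lr = logrank_test(strata, cohort)
        with open(out / "logrank.json", "w") as fh:
            json.dump(lr, fh, indent=2)
        report["stages"]["clinical"] = {"logrank": lr, "k": clin["k"]}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
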