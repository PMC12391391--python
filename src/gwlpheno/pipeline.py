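"""End-to-end orchestration: config, stage graph, tidy outputs, manifest.

Stages and their dependency order:

    simulate -> gate -> respond
                gate -> similarity
    simulate -> fitdose
    simulate -> biomarker
    simulate -> phospho

``run_pipeline`` executes the requested subset in order, reading each
stage's inputs from the output directory, so stages can also be re-run
individually on previously written tables. Every run writes a manifest
(config hash, seed, package/library versions, outputs) and is
byte-reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, biomarker, cellfeatures, doseresp, phospho, response, similarity, synth
from .doseresp import FourPL

log = logging.getLogger(__name__)

STAGES = ("simulate", "gate", "respond", "similarity", "fitdose", "biomarker",
          "phospho")

_DEFAULTS: dict = {
    # grid extends well past the most resistant line's midpoint so every
    # ED50 is bracketed
    "doses_um": [0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0],
    "n_cells": 2000,
    "peak_cv": 0.10,
    "intensity_gain": 1000.0,
    # synthetic "cell lines": midpoint of the ploidy-shift transfer curve (µM)
    # spans sensitive -> resistant, mirroring a heterogeneous panel
    "cell_lines": {"SYN-A": 0.2, "SYN-B": 0.5, "SYN-C": 1.5},
    "gates": {},
    "subsample_n": 500,
    "umap": {"n_neighbors": 15, "min_dist": 0.1},
    "colony": {"slope": 2.0, "lower": 0.0, "upper": 1.0, "replicates": 3,
               "noise_cv": 0.10},
    "panel": {"n_lines": 12, "gradient": 0.399, "intercept": 0.406,
              "noise_sd": 0.05},
    "flag_fraction": 0.05,
    "phospho": {"n_sites": 1500, "replicates": 3, "frac_down": 0.08,
                "frac_up": 0.03, "effect_log2": 3.0, "pro_plus1_hit": 0.6,
                "pro_plus1_bg": 0.2, "n_datasets": 3},
    "thresholds": {"p_max": 0.05, "fdr_max": 0.1},
    "cohort_groups": [["GRP1", 40, 40], ["GRP2", 40, 40], ["GRP3", 30, 0]],
    "cohort_shifts": {"GRP2": {"gwl": 0.5, "b55a": -0.3}},
}


@dataclass
class RunConfig:
    """Validated run configuration. Unspecified keys take package defaults."""

    seed: int = 0
    outdir: str = "results"
    params: dict = field(default_factory=dict)
    reference_condition: str | None = None  # defaults to highest-dose control line

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "outdir", "reference_condition"}
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "results")),
            reference_condition=raw.get("reference_condition"),
            params={k: v for k, v in raw.items() if k not in known},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        doses = self.get("doses_um")
        if any(d < 0 for d in doses) or list(doses) != sorted(doses):
            raise ValueError("config field 'doses_um' must be ascending and non-negative")

    def get(self, key: str):
        if key in self.params:
            v = self.params[key]
            if isinstance(_DEFAULTS.get(key), dict) and isinstance(v, dict):
                return {**_DEFAULTS[key], **v}
            return v
        return _DEFAULTS[key]

    def canonical(self) -> str:
        return json.dumps(
            {"seed": self.seed, "reference_condition": self.reference_condition,
             "params": self.params}, sort_keys=True, default=str)


def _seeds(config: RunConfig) -> dict:
    """One independent, stable child seed per randomised stage."""
    ss = np.random.SeedSequence(config.seed)
    names = ("simulate", "similarity", "fitdose")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write(df: pd.DataFrame, path: Path, outputs: list, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    outputs.append(str(path))


# ---------------------------------------------------------------- stages

def _stage_simulate(config: RunConfig, out: Path, outputs: list) -> None:
    seed = _seeds(config)["simulate"]
    rng_seed = np.random.SeedSequence(seed)
    doses = [float(d) for d in config.get("doses_um")]
    lines = config.get("cell_lines")
    n_cells = int(config.get("n_cells"))
    gain = float(config.get("intensity_gain"))
    cv = float(config.get("peak_cv"))

    # per-cell feature tables across the dose grid, one family per line
    pop_dir = out / "synthetic" / "populations"
    pop_dir.mkdir(parents=True, exist_ok=True)
    child = iter(rng_seed.spawn(len(lines) * len(doses) + 64))
    frames = []
    for line, midpoint in lines.items():
        # negative slope: effect rises with dose from lower to upper
        effect = FourPL(slope=-2.0, lower=0.0, upper=0.9, midpoint=float(midpoint))
        for dose in doses:
            spec = synth.PopulationSpec(
                n_cells=n_cells, dose=dose, effect_curve=effect,
                p21_fraction=FourPL(-2.0, 0.05, 0.4, float(midpoint)),
                multinucleation_fraction=FourPL(-2.0, 0.02, 0.3, float(midpoint)),
                intensity_gain=gain, peak_cv=cv,
                seed=int(next(child).generate_state(1)[0] % (2**31)),
                condition=f"{line}@{dose:g}uM",
            )
            table, truth = synth.gen_cell_population(spec)
            table.insert(0, "line", line)
            frames.append(table)
            truth.save(pop_dir / f"{line}_{dose:g}uM.truth.json")
    _write(pd.concat(frames, ignore_index=True), pop_dir / "cells.csv", outputs)

    # colony-formation curves per line (ED50 = the line's transfer midpoint)
    colony = config.get("colony")
    col_frames = []
    for line, midpoint in lines.items():
        curve = FourPL(colony["slope"], colony["lower"], colony["upper"],
                       float(midpoint))
        tab, truth = synth.gen_dose_response(
            curve, doses, int(colony["replicates"]), float(colony["noise_cv"]),
            seed=int(next(child).generate_state(1)[0] % (2**31)))
        tab.insert(0, "line", line)
        col_frames.append(tab)
        truth.save(out / "synthetic" / f"colonies_{line}.truth.json")
    _write(pd.concat(col_frames, ignore_index=True),
           out / "synthetic" / "colonies.csv", outputs)

    # expression panel following the ratio model
    panel_cfg = config.get("panel")
    panel, truth = synth.gen_expression_panel(
        int(panel_cfg["n_lines"]), float(panel_cfg["gradient"]),
        float(panel_cfg["intercept"]), float(panel_cfg["noise_sd"]),
        seed=int(next(child).generate_state(1)[0] % (2**31)))
    _write(panel, out / "synthetic" / "expression_panel.csv", outputs)
    truth.save(out / "synthetic" / "expression_panel.truth.json")

    # phosphosite matrices (several, for the intersection analysis)
    ph = config.get("phospho")
    for i in range(int(ph["n_datasets"])):
        mat, design, truth = synth.gen_phospho_dataset(
            n_sites=int(ph["n_sites"]), replicates=int(ph["replicates"]),
            frac_down=float(ph["frac_down"]), frac_up=float(ph["frac_up"]),
            effect_log2=float(ph["effect_log2"]),
            pro_plus1_hit=float(ph["pro_plus1_hit"]),
            pro_plus1_bg=float(ph["pro_plus1_bg"]),
            seed=int(next(child).generate_state(1)[0] % (2**31)))
        mat.to_csv(out / "synthetic" / f"phospho_{i+1}.csv")
        outputs.append(str(out / "synthetic" / f"phospho_{i+1}.csv"))
        (out / "synthetic" / f"phospho_{i+1}.design.json").write_text(
            json.dumps(design, indent=1))
        truth.save(out / "synthetic" / f"phospho_{i+1}.truth.json")

    # tumour/normal cohort
    groups = [tuple(g) for g in config.get("cohort_groups")]
    cohort, truth = synth.gen_cohort_expression(
        groups, config.get("cohort_shifts"),
        seed=int(next(child).generate_state(1)[0] % (2**31)))
    _write(cohort, out / "synthetic" / "cohort.csv", outputs)
    truth.save(out / "synthetic" / "cohort.truth.json")


def _load_cells(out: Path) -> pd.DataFrame:
    path = out / "synthetic" / "populations" / "cells.csv"
    if not path.exists():
        raise FileNotFoundError(f"{path} missing: run the simulate stage first")
    return pd.read_csv(path)


def _stage_gate(config: RunConfig, out: Path, outputs: list) -> None:
    cells = _load_cells(out)
    gates = cellfeatures.GateConfig(**config.get("gates"))
    summaries = []
    labelled_frames = []
    for line, sub in cells.groupby("line", sort=True):
        ref = sub[sub["dose_um"] == sub["dose_um"].min()]
        for dose, pop in sub.groupby("dose_um", sort=True):
            norm = cellfeatures.normalize_population(pop, ref)
            labelled = cellfeatures.classify_cells(norm, gates)
            labelled_frames.append(labelled)
            s = cellfeatures.summarise_population(labelled)
            summaries.append({"line": line, "dose_um": dose, **s.as_dict()})
    _write(pd.concat(labelled_frames, ignore_index=True),
           out / "gated" / "cells_labelled.csv", outputs)
    _write(pd.DataFrame(summaries), out / "gated" / "population_summary.csv",
           outputs)


def _stage_respond(config: RunConfig, out: Path, outputs: list) -> None:
    path = out / "gated" / "population_summary.csv"
    if not path.exists():
        raise FileNotFoundError(f"{path} missing: run the gate stage first")
    summary = pd.read_csv(path)
    prop_cols = ["pct_2n", "pct_s", "pct_4n", "pct_8n"]
    rows, aucs = [], []
    for line, sub in summary.groupby("line", sort=True):
        sub = sub.sort_values("dose_um")
        control = sub.iloc[0][prop_cols].to_numpy(dtype=float)
        d = [response.euclidean_response(control, r[prop_cols].to_numpy(dtype=float))
             for _, r in sub.iterrows()]
        auc = response.profile_auc(sub["dose_um"].to_numpy(), d)
        rows.extend({"line": line, "dose_um": ds, "euclidean_d": dd}
                    for ds, dd in zip(sub["dose_um"], d))
        aucs.append({"line": line, "auc": auc})
    _write(pd.DataFrame(rows), out / "response" / "euclidean_profiles.csv", outputs)
    _write(pd.DataFrame(aucs), out / "response" / "auc.csv", outputs)


def _stage_similarity(config: RunConfig, out: Path, outputs: list) -> None:
    gated = out / "gated" / "cells_labelled.csv"
    if not gated.exists():
        raise FileNotFoundError(f"{gated} missing: run the gate stage first")
    cells = pd.read_csv(gated)
    seed = _seeds(config)["similarity"]
    n = int(config.get("subsample_n"))
    lines = sorted(cells["line"].unique())
    top_dose = cells["dose_um"].max()

    reference = config.reference_condition or f"{lines[0]}@{top_dose:g}uM"
    conditions = {}
    for line in lines:
        sub = cells[(cells["line"] == line) & (cells["dose_um"] == top_dose)]
        name = f"{line}@{top_dose:g}uM"
        conditions[name] = similarity.subsample_cells(sub, n, seed=seed + len(conditions))
    if reference not in conditions:
        raise ValueError(f"config reference_condition {reference!r} not among "
                         f"simulated conditions {sorted(conditions)}")
    um = config.get("umap")
    emb = similarity.embed_conditions(conditions, seed=seed,
                                      n_neighbors=int(um["n_neighbors"]),
                                      min_dist=float(um["min_dist"]))
    coords_rows = []
    for name, pts in emb.coords.items():
        for x, y in pts:
            coords_rows.append({"condition": name, "umap_x": x, "umap_y": y})
    _write(pd.DataFrame(coords_rows), out / "similarity" / "embedding.csv", outputs)
    scores = similarity.similarity_profile(emb, reference, seed=seed)
    _write(pd.DataFrame([{"condition": s.condition, "wasserstein": s.distance,
                          "n": s.n, "seed": seed} for s in scores]),
           out / "similarity" / "wasserstein.csv", outputs)


def _stage_fitdose(config: RunConfig, out: Path, outputs: list) -> None:
    path = out / "synthetic" / "colonies.csv"
    if not path.exists():
        raise FileNotFoundError(f"{path} missing: run the simulate stage first")
    colonies = pd.read_csv(path)
    fit_rows, ed_rows = [], []
    for line, sub in colonies.groupby("line", sort=True):
        fits = doseresp.fit_replicates(sub)
        for rep, f in zip(sorted(sub["replicate"].unique()), fits):
            fit_rows.append({"line": line, "replicate": rep, "slope": f.slope,
                             "lower": f.lower, "upper": f.upper,
                             "ed50_um": f.midpoint, "sse": f.sse,
                             "converged": f.converged,
                             "se_ed50": f.se.get("midpoint", np.nan)})
        mean, sd = doseresp.ed50_with_replicates(fits)
        ed_rows.append({"line": line, "ed50_mean_um": mean, "ed50_sd_um": sd})
    _write(pd.DataFrame(fit_rows), out / "doseresp" / "fourpl_fits.csv", outputs)
    _write(pd.DataFrame(ed_rows), out / "doseresp" / "ed50.csv", outputs)


def _stage_biomarker(config: RunConfig, out: Path, outputs: list) -> None:
    panel_path = out / "synthetic" / "expression_panel.csv"
    if not panel_path.exists():
        raise FileNotFoundError(f"{panel_path} missing: run the simulate stage first")
    panel = pd.read_csv(panel_path)
    model = biomarker.fit_ratio_model(panel)
    _write(pd.DataFrame([{"gradient": model.gradient, "intercept": model.intercept,
                          "r_squared": model.r_squared, "pearson_r": model.pearson_r,
                          "p": model.p, "n": model.n}]),
           out / "biomarker" / "ratio_model.csv", outputs)
    pred = biomarker.predict_ed50(model, panel)
    flags = biomarker.rank_and_flag(pred, float(config.get("flag_fraction")))
    _write(panel.assign(pred_ed50_um=pred, flagged=flags),
           out / "biomarker" / "predictions.csv", outputs)

    cohort = pd.read_csv(out / "synthetic" / "cohort.csv")
    shifts = biomarker.cohort_median_shift(cohort)
    _write(shifts, out / "biomarker" / "cohort_median_shift.csv", outputs)


def _stage_phospho(config: RunConfig, out: Path, outputs: list) -> None:
    ph = config.get("phospho")
    th = config.get("thresholds")
    hit_sets = {}
    for i in range(int(ph["n_datasets"])):
        mat_path = out / "synthetic" / f"phospho_{i+1}.csv"
        if not mat_path.exists():
            raise FileNotFoundError(f"{mat_path} missing: run the simulate stage first")
        matrix = pd.read_csv(mat_path, index_col="site")
        design = json.loads((out / "synthetic" / f"phospho_{i+1}.design.json")
                            .read_text())
        processed = phospho.normalize_phospho(matrix)
        stats_df = phospho.moderated_test(processed, design)
        classified = phospho.classify_hits(stats_df, float(th["p_max"]),
                                           float(th["fdr_max"]))
        _write(classified.reset_index(), out / "phospho" / f"site_stats_{i+1}.csv",
               outputs)
        hit_sets[f"dataset_{i+1}"] = set(
            classified.index[classified["hit_class"] != "not significant"])
        freqs, enrich = phospho.motif_frequencies(
            classified["window"].tolist(), classified["hit_class"].tolist())
        _write(enrich, out / "phospho" / f"plus1_enrichment_{i+1}.csv", outputs)
    inter = phospho.intersect_hits(hit_sets)
    region_rows = [{"region": "&".join(k), "exclusive_size": v}
                   for k, v in sorted(inter.regions.items())]
    region_rows.append({"region": "shared_fraction",
                        "exclusive_size": inter.shared_fraction})
    _write(pd.DataFrame(region_rows), out / "phospho" / "intersection.csv", outputs)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "gate": _stage_gate,
    "respond": _stage_respond,
    "similarity": _stage_similarity,
    "fitdose": _stage_fitdose,
    "biomarker": _stage_biomarker,
    "phospho": _stage_phospho,
}

# direct prerequisites inside a single run
_DEPS = {
    "gate": ("simulate",),
    "respond": ("gate",),
    "similarity": ("gate",),
    "fitdose": ("simulate",),
    "biomarker": ("simulate",),
    "phospho": ("simulate",),
}


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order; write a manifest.

    A stage failure halts its dependents only; independent branches still
    run. Returns the manifest dict.
    """
    config.validate()
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in requested]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    failed: dict[str, str] = {}
    completed: list[str] = []
    for stage in ordered:
        blocked = [d for d in _DEPS.get(stage, ()) if d in failed]
        if blocked:
            failed[stage] = f"skipped: dependency {blocked[0]} failed"
            log.error("stage %s skipped (dependency failed)", stage)
            continue
        try:
            _STAGE_FN[stage](config, out, outputs)
            completed.append(stage)
            log.info("stage %s done", stage)
        except Exception as exc:  # halt dependents, keep independent branches
            failed[stage] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", stage, exc)

    rel_outputs = [str(Path(p).relative_to(out)) if Path(p).is_relative_to(out)
                   else str(p) for p in outputs]
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "stages_completed": completed,
        "stages_failed": failed,
        "outputs": rel_outputs,
        "versions": {
            "gwlpheno": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failed:
        raise RuntimeError(f"stage failures: {failed}")
    return manifest
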