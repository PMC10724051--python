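"""Pipeline orchestration: simulate -> fit -> cluster -> harmonize -> compare.

Every stage boundary is a CSV (or JSON for scalar summaries), so stages can
be re-run, swapped or inspected independently.  A manifest records the
configuration snapshot, per-file checksums, stage wall-clock and warnings,
making every downstream table traceable to a seeded run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bentline import BentLineModel, classify_cp_position
from .biomarkers import ReferenceZScorer
from .clustering import TrajectoryClusterer
from .comparisons import compare_groups, recode_covariates, results_frame
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_tables"]

log = logging.getLogger("cogtraj")

STAGES = ("simulate", "fit", "cluster", "biomarkers", "compare")

DEFAULT_VARIABLES = {
    "age_baseline": ("continuous", "kruskal_wallis"),
    "bmi": ("continuous", "kruskal_wallis"),
    "cesd": ("continuous", "kruskal_wallis"),
    "libra": ("continuous", "kruskal_wallis"),
    "female": ("categorical", None),
    "apoe4": ("categorical", None),
    "family_history": ("categorical", None),
    "college": ("categorical", None),
    "hypertension": ("categorical", None),
    "diabetes": ("categorical", None),
    "high_cholesterol": ("categorical", None),
    "depressed": ("categorical", None),
    "bmi_cat": ("categorical", None),
    "whr_cat": ("categorical", None),
    "rx_cat": ("categorical", None),
    "srh_cat": ("categorical", None),
    "memory_cat": ("categorical", None),
    "libra_cat": ("categorical", None),
}


@dataclass
class RunConfig:
    """Seed-controlled configuration for a pipeline run."""

    stages: tuple = STAGES
    seed: int = 0
    out_dir: str = "cogtraj_run"
    generator: GeneratorConfig | None = None
    n_participants: int = 150
    chains: int = 2
    iterations: int = 1500
    warmup: int | None = None
    kmax: int = 10
    n_init: int = 25
    dvr_cutoff: float = 1.16
    z_cutoff: float = 1.5
    gmm: bool = False
    fdr_q: float = 0.05
    inputs: dict = field(default_factory=dict)  # stage -> input csv overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if gen is not None:
            from .synthetic import _config_from_dict

            cfg.generator = _config_from_dict(gen)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_tables(paths: dict) -> list[dict]:
    """Schema/range checks per table; returns a list of violation records."""
    report = []

    def bad(file, rule, row=None, column=None):
        report.append({"file": str(file), "rule": rule, "row": row, "column": column})

    if "cohort_long" in paths:
        p = Path(paths["cohort_long"])
        df = pd.read_csv(p)
        need = {"participant_id", "visit_age_years", "pacc3_z"}
        for c in sorted(need - set(df.columns)):
            bad(p, "missing column", column=c)
        if need <= set(df.columns):
            for pid, grp in df.groupby("participant_id"):
                if len(grp) < 3:
                    bad(p, "fewer than three cognitive visits (inclusion rule)", row=pid)
                ages = grp["visit_age_years"].to_numpy()
                if not np.all(np.diff(ages) > 0):
                    idx = int(grp.index[np.argmin(np.diff(ages) > 0) + 1])
                    bad(p, "visit ages not strictly increasing", row=idx)
            if not np.isfinite(df["pacc3_z"]).all():
                bad(p, "non-finite composite score", column="pacc3_z")
    if "covariates" in paths:
        p = Path(paths["covariates"])
        df = pd.read_csv(p)
        for col, lo, hi in (("srh", 1, 5), ("memory_rating", 1, 7)):
            if col in df.columns:
                out = ~df[col].dropna().between(lo, hi)
                if out.any():
                    bad(p, f"{col} outside Likert range {lo}-{hi}", row=int(out.idxmax()), column=col)
        for col in ("rx_count", "comorbidity_tally"):
            if col in df.columns and (df[col].dropna() < 0).any():
                bad(p, "negative count", column=col)
    if "biomarkers" in paths:
        p = Path(paths["biomarkers"])
        df = pd.read_csv(p)
        if {"gm", "wm", "csf", "ticv"} <= set(df.columns):
            ok = df[["gm", "wm", "csf", "ticv"]].dropna()
            resid = (ok["ticv"] - ok[["gm", "wm", "csf"]].sum(axis=1)).abs()
            if (resid > 1e-6).any():
                bad(p, "ticv != gm + wm + csf", row=int(resid.idxmax()))
        if "dvr" in df.columns and (df["dvr"].dropna() <= 0).any():
            bad(p, "non-positive DVR", column="dvr")
    return report


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "files": {},
        "warnings": [],
        "config": {
            k: v
            for k, v in vars(config).items()
            if k not in ("generator", "inputs")
        },
    }
    seeds = {s: int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
             for i, s in enumerate(STAGES)}

    def record(stage, t0, files):
        entry = {"stage": stage, "seconds": round(time.perf_counter() - t0, 3),
                 "outputs": {}}
        for name, p in files.items():
            p = Path(p)
            entry["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}
            manifest["files"][name] = entry["outputs"][name]
        manifest["stages"].append(entry)
        log.info("stage=%s done in %.2fs outputs=%s", stage, entry["seconds"],
                 list(files))

    def need(name):
        if name in config.inputs:
            p = Path(config.inputs[name])
        elif name in manifest["files"]:
            p = Path(manifest["files"][name]["path"])
        else:
            p = out / f"{name}.csv"
        if not p.exists():
            raise FileNotFoundError(f"required input {name!r} not found at {p}")
        return p

    try:
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            gen = config.generator or GeneratorConfig.default(
                n_participants=config.n_participants
            )
            cohort = generate_cohort(gen, seed=seeds["simulate"])
            files = cohort.write_csvs(out)
            gen.to_yaml(out / "generator_config.yaml")
            files["generator_config"] = out / "generator_config.yaml"
            record("simulate", t0, files)

        if "fit" in config.stages:
            t0 = time.perf_counter()
            long_df = pd.read_csv(need("cohort_long"))
            problems = validate_tables({"cohort_long": need("cohort_long")})
            if problems:
                raise ValueError(f"schema violations in cohort_long: {problems[:3]}")
            model = BentLineModel(
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=seeds["fit"],
            ).fit(long_df)
            pp = model.person_params_.reset_index()
            cp, props = classify_cp_position(model.person_params_, long_df)
            pp["cp_position"] = cp.values
            pp.to_csv(out / "person_params.csv", index=False)
            fe = {
                "fixed_effects": model.fixed_effects_.round(6).to_dict(orient="index"),
                "diagnostics": model.diagnostics_,
                "cp_position_proportions": props,
                "converged": model.converged_,
            }
            (out / "fixed_effects.json").write_text(json.dumps(fe, indent=2))
            if not model.converged_:
                manifest["warnings"].append("bent-line fit convergence flagged")
            record("fit", t0, {"person_params": out / "person_params.csv",
                               "fixed_effects": out / "fixed_effects.json"})

        if "cluster" in config.stages:
            t0 = time.perf_counter()
            pp = pd.read_csv(need("person_params"))
            clus = TrajectoryClusterer(
                kmax=config.kmax, n_init=config.n_init, random_state=seeds["cluster"]
            ).fit(pp)
            clus.results_frame().to_csv(out / "clusters.csv", index=False)
            clus.ch_by_k_.to_csv(out / "ch_by_k.csv", index=False)
            pca = pd.DataFrame(
                clus.pca_scores_, columns=[f"pc{i+1}" for i in range(clus.pca_scores_.shape[1])]
            )
            pca.insert(0, "participant_id", clus.participants_)
            pca.to_csv(out / "pca.csv", index=False)
            record("cluster", t0, {"clusters": out / "clusters.csv",
                                   "ch_by_k": out / "ch_by_k.csv",
                                   "pca": out / "pca.csv"})

        if "biomarkers" in config.stages:
            t0 = time.perf_counter()
            panel = pd.read_csv(need("biomarkers"))
            scorer = ReferenceZScorer(
                dvr_cutoff=config.dvr_cutoff,
                z_cutoff=config.z_cutoff,
                gmm=config.gmm,
                seed=seeds["biomarkers"],
            ).fit(panel)
            zdf = scorer.transform(panel)
            zdf.to_csv(out / "biomarker_z.csv", index=False)
            (out / "reference_stats.json").write_text(
                json.dumps(
                    {
                        m: {k: v for k, v in vars(s).items() if v is not None}
                        for m, s in scorer.stats_.items()
                    },
                    indent=2,
                )
            )
            record("biomarkers", t0, {"biomarker_z": out / "biomarker_z.csv",
                                      "reference_stats": out / "reference_stats.json"})

        if "compare" in config.stages:
            t0 = time.perf_counter()
            cov = pd.read_csv(need("covariates"))
            clusters = pd.read_csv(need("clusters"))
            df = recode_covariates(cov).merge(
                clusters[["participant_id", "severity_label"]], on="participant_id"
            )
            variables = {k: v for k, v in DEFAULT_VARIABLES.items() if k in df.columns}
            results = compare_groups(
                df,
                "severity_label",
                variables,
                q=config.fdr_q,
                seed=seeds["compare"],
                adjust_covariates=("age_baseline", "sex"),
            )
            results_frame(results).to_csv(out / "comparisons.csv", index=False)
            adj = [
                r.adjusted.assign(variable=r.variable)
                for r in results
                if r.adjusted is not None
            ]
            if adj:
                pd.concat(adj).to_csv(out / "adjusted_means.csv", index=False)
                record("compare", t0, {"comparisons": out / "comparisons.csv",
                                       "adjusted_means": out / "adjusted_means.csv"})
            else:
                record("compare", t0, {"comparisons": out / "comparisons.csv"})
    except Exception as exc:
        manifest["failed"] = {"error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
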