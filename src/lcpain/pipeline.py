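"""End-to-end analysis pipeline: score -> MCAR check -> impute -> trajectory
model -> pooled regressions -> mediation -> report bundle.

Every stage writes its outputs to the run directory and downstream stages
always read those files back, so a warm (cached) rerun is byte-identical
to a cold run by construction.  All randomness derives from one master
seed through named per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indices import default_cutpoints, derive_cutpoints, load_cutpoints, score_cohort
from .lctm import TrajectorySpec, assign_classes, fit_lctm, fit_table, select_model
from .mediation import MediationSpec, mediate, moderated_mediate, pool_mediation
from .missing_data import impute_chained, little_mcar_test, pool_rubin
from .regression import DesignSpec, RegressionResult, add_interaction, \
    fit_multinomial, fit_negative_binomial

__all__ = ["PipelineConfig", "run_pipeline", "pool_regression"]

log = logging.getLogger("lcpain.pipeline")


@dataclass
class PipelineConfig:
    cohort_csv: str
    out_dir: str
    seed: int = 0
    cutpoint_mode: str = "fixed_table"       # fixed_table | sample_quartile | path
    lctm_k_range: tuple[int, int] = (1, 3)
    lctm_random_effects: tuple[str, ...] = ("none",)
    lctm_transform: str = "identity"
    lctm_standardized: bool = True
    lctm_n_starts: int = 5
    m_imputations: int = 5
    imputation_cycles: int = 5
    confounders: tuple[str, ...] = ("conf_1", "conf_2", "conf_3", "conf_4", "conf_5")
    mediation_exposure: str = "sed_total"
    mediation_n_boot: int = 200
    mediation_moderator: str = "sed_childhood_raw"
    min_class_share: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("lctm_k_range", "lctm_random_effects", "confounders"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _hash_inputs(cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(cfg), sort_keys=True, default=list).encode())
    h.update(Path(cfg.cohort_csv).read_bytes())
    h.update(__version__.encode())
    return h.hexdigest()


class _Stage:
    """Disk-backed stage cache: skip recompute when the run hash matches."""

    def __init__(self, out_dir: Path, run_hash: str):
        self.cache_dir = out_dir / ".cache"
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.run_hash = run_hash

    def fresh(self, name: str, files: Sequence[Path]) -> bool:
        manifest = self.cache_dir / f"{name}.json"
        if not manifest.exists():
            return False
        try:
            meta = json.loads(manifest.read_text())
        except json.JSONDecodeError:
            return False
        return meta.get("hash") == self.run_hash and all(f.exists() for f in files)

    def mark(self, name: str, files: Sequence[Path]) -> None:
        (self.cache_dir / f"{name}.json").write_text(
            json.dumps({"hash": self.run_hash, "files": [str(f) for f in files]})
        )


def pool_regression(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Rubin-pool per-term coefficients across imputation-specific fits;
    exponentiated estimates (OR/IRR) and CIs on the exponentiated scale."""
    if len(results) == 1:
        t = results[0].table.copy()
        return t[["level", "term", "coef", "se", "exp_coef", "ci_low", "ci_high", "p"]]
    base = results[0].table[["level", "term"]]
    rows = []
    from scipy import stats as st
    for _, (level, term) in base.iterrows():
        coefs, variances = [], []
        for r in results:
            row = r.term(term, level)
            coefs.append(row["coef"])
            variances.append(row["se"] ** 2)
        pe = pool_rubin(coefs, variances)
        z = pe.estimate / pe.se if pe.se > 0 else np.nan
        p = (2.0 * st.norm.sf(abs(z)) if np.isinf(pe.df)
             else 2.0 * st.t.sf(abs(z), pe.df))
        rows.append({
            "level": level, "term": term, "coef": pe.estimate, "se": pe.se,
            "exp_coef": np.exp(pe.estimate),
            "ci_low": np.exp(pe.ci_low), "ci_high": np.exp(pe.ci_high), "p": p,
        })
    return pd.DataFrame(rows)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns the paths of the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_hash = _hash_inputs(cfg)
    stage = _Stage(out, run_hash)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(("lctm", "impute", "mediation"), ss.spawn(3))}

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        cohort = _read_csv(Path(cfg.cohort_csv))
        if "id" not in cohort.columns:
            raise ValueError("cohort CSV must carry an 'id' column")
        missing_conf = [c for c in cfg.confounders if c not in cohort.columns]
        if missing_conf:
            raise ValueError(f"schema violation: confounder columns missing "
                             f"{missing_conf}")

        # ---- stage 1: index scoring -----------------------------------
        scores_path = out / "scores.csv"
        if not stage.fresh("scores", [scores_path]):
            log.info("stage scores: scoring cohort (%d rows)", len(cohort))
            if cfg.cutpoint_mode == "fixed_table":
                cuts = default_cutpoints()
            elif cfg.cutpoint_mode == "sample_quartile":
                cuts = derive_cutpoints(cohort, "sample_quartile")
            else:
                cuts = load_cutpoints(cfg.cutpoint_mode)
            scores = score_cohort(cohort, cuts)
            scores.insert(0, "id", cohort["id"].to_numpy())
            scores.to_csv(scores_path, index=False)
            stage.mark("scores", [scores_path])
        scores = _read_csv(scores_path)
        outputs["scores"] = scores_path

        # ---- stage 2: missingness pattern ------------------------------
        mcar_path = out / "mcar.json"
        if not stage.fresh("mcar", [mcar_path]):
            log.info("stage mcar: Little's test on %d confounders",
                     len(cfg.confounders))
            res = little_mcar_test(cohort[list(cfg.confounders)])
            mcar_path.write_text(json.dumps(
                {"d2": res.d2, "df": res.df, "p": res.p,
                 "n_patterns": res.n_patterns}, indent=2))
            stage.mark("mcar", [mcar_path])
        outputs["mcar"] = mcar_path

        # ---- stage 3: multiple imputation ------------------------------
        imp_dir = out / "imputed"
        imp_files = [imp_dir / f"imputed_{i:02d}.csv"
                     for i in range(1, cfg.m_imputations + 1)]
        if not stage.fresh("impute", imp_files):
            log.info("stage impute: m=%d chains, %d cycles",
                     cfg.m_imputations, cfg.imputation_cycles)
            methods = {c: "continuous" for c in cfg.confounders}
            imp = impute_chained(cohort[["id", *cfg.confounders]], methods,
                                 m=cfg.m_imputations, seed=seeds["impute"],
                                 cycles=cfg.imputation_cycles)
            imp.write(imp_dir)
            stage.mark("impute", imp_files)
        imputed = [_read_csv(f) for f in imp_files]
        outputs["imputed"] = imp_dir

        # ---- stage 4: latent-class trajectories ------------------------
        sel_path = out / "trajectory_selection.csv"
        cls_path = out / "trajectory_classes.csv"
        if not stage.fresh("lctm", [sel_path, cls_path]):
            log.info("stage lctm: K in %s", list(cfg.lctm_k_range))
            value_cols = ([f"sed_{p}_std" for p in ("childhood", "midus1", "midus2")]
                          if cfg.lctm_standardized else
                          [f"sed_{p}_raw" for p in ("childhood", "midus1", "midus2")])
            long = pd.concat([
                pd.DataFrame({"id": scores["id"], "time": t,
                              "score": scores[col]})
                for t, col in enumerate(value_cols)
            ], ignore_index=True).dropna(subset=["score"])
            fits = []
            for k in range(cfg.lctm_k_range[0], cfg.lctm_k_range[1] + 1):
                for re_kind in cfg.lctm_random_effects:
                    spec = TrajectorySpec(
                        n_classes=k, random_effects=re_kind,
                        transform=cfg.lctm_transform,
                        standardized=cfg.lctm_standardized,
                        n_starts=cfg.lctm_n_starts, seed=seeds["lctm"],
                    )
                    fits.append(fit_lctm(long, spec))
            fit_table(fits).to_csv(sel_path, index=False)
            best = select_model(fits, min_share=cfg.min_class_share)
            assign = assign_classes(best)
            pd.DataFrame({"id": assign.ids, "trajectory_class": assign.labels}
                         ).to_csv(cls_path, index=False)
            stage.mark("lctm", [sel_path, cls_path])
        classes = _read_csv(cls_path)
        outputs["trajectory_selection"] = sel_path
        outputs["trajectory_classes"] = cls_path

        # ---- stage 5: pooled regressions -------------------------------
        reg_paths = {name: out / f"{name}.csv"
                     for name in ("sed_cp", "sed_al", "al_cp")}
        if not stage.fresh("regression", list(reg_paths.values())):
            log.info("stage regression: pooled over m=%d imputations",
                     len(imputed))
            frames = []
            for imp_df in imputed:
                df = scores.merge(imp_df, on="id").merge(classes, on="id")
                df["traj_2"] = (df["trajectory_class"] == 2).astype(float)
                df["traj_3"] = (df["trajectory_class"] == 3).astype(float)
                frames.append(df)
            conf = tuple(cfg.confounders)

            sed_cp = [fit_multinomial(df, DesignSpec(
                outcome="cp_interference_cat", exposures=("sed_midus2_raw",),
                confounders=conf, reference="no_pain")) for df in frames]
            pool_regression(sed_cp).to_csv(reg_paths["sed_cp"], index=False)

            sed_al = [fit_negative_binomial(df, DesignSpec(
                outcome="al_score", exposures=("sed_total",),
                confounders=conf)) for df in frames]
            pool_regression(sed_al).to_csv(reg_paths["sed_al"], index=False)

            spec = DesignSpec(outcome="cp_sites_cat",
                              exposures=("al_score", "sed_childhood_raw"),
                              confounders=conf, reference="no_pain")
            spec = add_interaction(spec, "al_score", "sed_childhood_raw")
            al_cp = [fit_multinomial(df, spec) for df in frames]
            pool_regression(al_cp).to_csv(reg_paths["al_cp"], index=False)
            stage.mark("regression", list(reg_paths.values()))
        outputs.update(reg_paths)

        # ---- stage 6: mediation ----------------------------------------
        med_path = out / "mediation.csv"
        if not stage.fresh("mediation", [med_path]):
            log.info("stage mediation: n_boot=%d", cfg.mediation_n_boot)
            med_frames = []
            for imp_df in imputed:
                df = scores.merge(imp_df, on="id")
                df = df[df["cp_interference_cat"].isin(["no_pain", "high"])].copy()
                df["cp_high"] = (df["cp_interference_cat"] == "high").astype(float)
                med_frames.append(df)
            spec = MediationSpec(
                exposure=cfg.mediation_exposure, mediator="al_score",
                outcome="cp_high", confounders=tuple(cfg.confounders),
                n_boot=cfg.mediation_n_boot, seed=seeds["mediation"],
            )
            results = [mediate(df, spec) for df in med_frames]
            pooled = (pool_mediation(results) if len(results) > 1 else results[0])
            report = pooled.to_frame()
            report.insert(0, "analysis", "sed_al_cp_high")
            report.to_csv(med_path, index=False)
            stage.mark("mediation", [med_path])
        outputs["mediation"] = med_path

        # ---- run log ----------------------------------------------------
        log_path = out / "run_manifest.json"
        log_path.write_text(json.dumps({
            "package_version": __version__,
            "python": platform.python_version(),
            "master_seed": cfg.seed,
            "stage_seeds": seeds,
            "run_hash": run_hash,
            "config": asdict(cfg),
        }, indent=2, default=list))
        outputs["manifest"] = log_path

        for name, path in outputs.items():
            if not Path(path).exists():
                raise RuntimeError(f"stage {name}: expected output missing")
        return outputs
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
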