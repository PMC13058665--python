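"""End-to-end analysis pipeline.

Stages, in order: cohort (generate synthetic data or ingest CSVs) ->
questionnaire scores -> behavioural measures (learning accuracies, effort
modulation) -> per-participant model fits -> AIC-weight model comparison ->
parameter recovery and posterior-predictive check -> statistical battery
(outlier-filtered one-tailed t, ANOVAs, Spearman / partial Spearman with BH
correction, Pearson-Filon). Each stage derives its own seed from the master
seed by a fixed offset so stages can be re-run in isolation; a manifest
records the config snapshot, seeds, output checksums and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import fitting, io, models, questionnaires, stats, task

logger = logging.getLogger("rebl.pipeline")

SYMPTOM_COLUMNS = {
    "bdi": "bdi_total",
    "teps_a": "teps_a",
    "teps_c": "teps_c",
    "shaps": "shaps_total",
    "stai": "stai_total",
}

#: covariate rule: anhedonia scales are controlled for depression with the
#: anhedonia items removed; anxiety is controlled for full-scale depression.
COVARIATE_RULE = {
    "bdi": (),
    "teps_a": ("bdi_reduced",),
    "teps_c": ("bdi_reduced",),
    "shaps": ("bdi_reduced",),
    "stai": ("bdi_total",),
}

BEHAVIOUR_MEASURES = (
    "reward_accuracy", "effort_accuracy", "effort_modulation",
    "alpha_reward", "alpha_effort", "tau_reward", "tau_effort",
    "liking", "wanting", "effort_willingness",
)

DEFAULT_CONFIG: dict = {
    "synthetic": {},           # GeneratorConfig overrides; or use "inputs"
    "inputs": None,            # {"participants": path, "trials": path, "ratings": path}
    "task": {},                # TaskConfig overrides
    "models": ["f_alpha_tau", "cf_alpha_tau"],
    "best_model": models.BEST_MODEL,
    "fit": {"n_starts": 10},
    "recovery": {"enabled": True, "n_agents": 50, "block": task.REWARD},
    "ppc": {"enabled": True, "bin_size": 5, "n_sims_per_fit": 3},
    "stats": {"alpha": 0.05, "outlier_k": 2.0, "power_rho": 0.3, "power": 0.8},
}

STAGE_OFFSETS = {"cohort": 1, "fits": 2, "recovery": 3, "ppc": 4, "stats": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) * 1009 + STAGE_OFFSETS[stage] * 9176) % (2**31 - 1)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        user = yaml.safe_load(text) or {}
    config = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if key not in config:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(config.get(key), dict) and isinstance(value, dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


class _StageFiles:
    """Track files written by a stage; delete them if the stage fails."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: list[Path] = []

    def write(self, df: pd.DataFrame, name: str) -> Path:
        path = io.write_csv(df, self.out_dir / name)
        self.files.append(path)
        return path

    def write_json(self, obj, name: str) -> Path:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        self.files.append(path)
        return path

    def cleanup(self) -> None:
        for f in self.files:
            f.unlink(missing_ok=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path_or_dict, out_dir, seed: int = 0) -> dict:
    """Run all stages and return the manifest (also written to the output dir)."""
    config = load_config(config_path_or_dict)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        ctx = _run_stages(config, out, seed, outputs)
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest = {
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGE_OFFSETS},
        "config": _config_snapshot(config),
        "cohort_id": ctx.get("cohort_id"),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "versions": _versions(),
        "log": log_path.name,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_snapshot(config: dict) -> dict:
    return json.loads(json.dumps(config, default=_json_default, sort_keys=True))


def _versions() -> dict:
    import pingouin
    import scipy
    import statsmodels

    from . import __version__

    return {
        "rebl": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "pingouin": pingouin.__version__,
    }


def _run_stages(config: dict, out: Path, seed: int, outputs: dict) -> dict:
    ctx: dict = {}
    for stage_fn in (_stage_cohort, _stage_scores, _stage_behaviour, _stage_fits,
                     _stage_comparison, _stage_validation, _stage_stats):
        files = _StageFiles(out)
        name = stage_fn.__name__.removeprefix("_stage_")
        logger.info("stage %s: start", name)
        try:
            stage_fn(config, seed, ctx, files)
        except Exception:
            logger.exception("stage %s: failed, removing partial outputs", name)
            files.cleanup()
            raise
        for f in files.files:
            outputs[f.name] = f
        logger.info("stage %s: done (%d files)", name, len(files.files))
    return ctx


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_cohort(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    task_cfg = task.build_task_config(config["task"], seed=seed)
    if config.get("inputs"):
        paths = config["inputs"]
        participants = io.read_csv(paths["participants"], "participants")
        trials = io.read_csv(paths["trials"], "trials")
        ratings = io.read_csv(paths["ratings"], "ratings")
        sessions = io.frame_to_sessions(trials, task_cfg)
        ctx["cohort"] = None
        ctx["cohort_id"] = None
        ctx["ground_truth"] = None
    else:
        overrides = dict(config["synthetic"])
        effects = overrides.pop("effects", None)
        if isinstance(effects, dict) and effects and isinstance(next(iter(effects)), str):
            effects = cohort_mod.effects_from_json(json.dumps(effects))
        kwargs = dict(overrides)
        if effects is not None:
            kwargs["effects"] = effects
        gen_cfg = cohort_mod.GeneratorConfig(
            task=task_cfg, seed=stage_seed(seed, "cohort"), **kwargs
        )
        dataset = cohort_mod.generate_cohort(gen_cfg)
        participants = dataset.participants
        ratings = dataset.ratings
        sessions = dataset.sessions
        trials = io.sessions_to_frame(sessions)
        ctx["cohort"] = dataset
        ctx["cohort_id"] = dataset.cohort_id
        ctx["ground_truth"] = dataset.ground_truth
        files.write(dataset.ground_truth, "ground_truth.csv")
    files.write(participants, "participants.csv")
    files.write(trials, "trials.csv")
    files.write(ratings, "ratings.csv")
    ctx["participants"] = participants
    ctx["ratings"] = ratings
    ctx["sessions"] = sessions


def _stage_scores(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    scores = questionnaires.score_participants(ctx["participants"])
    files.write(scores, "scores.csv")
    ctx["scores"] = scores


def _stage_behaviour(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    rows = []
    for session in ctx["sessions"]:
        r_acc, _ = task.learning_accuracy(session, task.REWARD)
        e_acc, _ = task.learning_accuracy(session, task.EFFORT)
        em = stats.effort_modulation(session)
        rows.append(
            {
                "participant_id": session.participant_id,
                "block_order": session.config.block_order,
                "reward_accuracy": r_acc,
                "effort_accuracy": e_acc,
                "speed_high": em.speed_high,
                "speed_low": em.speed_low,
                "effort_modulation": em.diff,
                "modulation_undefined": em.diff is None,
            }
        )
    behaviour = pd.DataFrame(rows)
    files.write(behaviour, "behaviour.csv")
    ctx["behaviour"] = behaviour


def _stage_fits(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    n_starts = int(config["fit"]["n_starts"])
    fit_seed = stage_seed(seed, "fits")
    rows = []
    for i, session in enumerate(ctx["sessions"]):
        for spec_name in config["models"]:
            for block in task.BLOCKS:
                fit = fitting.fit_block(
                    session, block, spec_name, n_starts=n_starts,
                    rng=fitting._stable_seed(fit_seed, i, spec_name, block),
                )
                rows.append(fit.to_row())
    fits = pd.DataFrame(rows)
    files.write(fits, "fits.csv")
    ctx["fits"] = fits


def _stage_comparison(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    fits = ctx["fits"]
    tables = []
    for block, grp in fits.groupby("block"):
        sums = grp.groupby("spec")["aic"].sum()
        weights = fitting.aic_weights(sums.to_numpy())
        winners = (
            grp.loc[grp.groupby("participant_id")["aic"].idxmin(), "spec"]
            .value_counts().reindex(sums.index, fill_value=0)
        )
        tables.append(
            pd.DataFrame(
                {
                    "block": block,
                    "spec": sums.index,
                    "sum_aic": sums.to_numpy(),
                    "delta_aic": sums.to_numpy() - sums.min(),
                    "weight": weights,
                    "n_participants_best": winners.to_numpy(),
                }
            )
        )
    comparison = pd.concat(tables, ignore_index=True)
    files.write(comparison, "model_comparison.csv")
    ctx["comparison"] = comparison


def _stage_validation(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    best = config["best_model"]
    fits = ctx["fits"]
    best_fits = fits[fits["spec"] == best]
    if best_fits.empty:
        raise ValueError(f"best model {best!r} is not among the fitted models")
    task_cfg = ctx["sessions"][0].config
    if config["recovery"].get("enabled", True):
        block = config["recovery"].get("block", task.REWARD)
        sub = best_fits[best_fits["block"] == block]
        n_agents = min(int(config["recovery"].get("n_agents", 50)), len(sub))
        spec = models.get_model(best)
        gen = [
            models.ParameterVector.from_free(
                [row[n] for n in spec.free_names], spec
            )
            for _, row in sub.head(n_agents).iterrows()
        ]
        report = fitting.parameter_recovery(
            spec, gen, task_cfg, block=block,
            n_starts=int(config["fit"]["n_starts"]),
            seed=stage_seed(seed, "recovery"),
        )
        files.write(report.to_frame(), "recovery_report.csv")
        ctx["recovery"] = report
    if config["ppc"].get("enabled", True):
        sessions_by_id = {s.participant_id: s for s in ctx["sessions"]}
        fit_objs, sess_objs = [], []
        spec = models.get_model(best)
        for block in task.BLOCKS:
            for _, row in best_fits[best_fits["block"] == block].iterrows():
                fit_objs.append(
                    fitting.FitResult(
                        participant_id=row["participant_id"], block=block, spec_name=best,
                        params=models.ParameterVector.from_free(
                            [row[n] for n in spec.free_names], spec
                        ),
                        negloglik=row["negloglik"], k=int(row["k"]), aic=row["aic"],
                        n_starts_converged=int(row["n_starts_converged"]),
                    )
                )
                sess_objs.append(sessions_by_id[row["participant_id"]])
        ppc = fitting.posterior_predictive(
            fit_objs, sess_objs,
            bin_size=int(config["ppc"].get("bin_size", 5)),
            seed=stage_seed(seed, "ppc"),
            n_sims_per_fit=int(config["ppc"].get("n_sims_per_fit", 3)),
        )
        files.write(ppc, "ppc.csv")
        ctx["ppc"] = ppc


def _measure_table(ctx: dict, best: str) -> pd.DataFrame:
    """One row per participant: scores + behavioural measures + fitted parameters."""
    scores = ctx["scores"]
    behaviour = ctx["behaviour"]
    fits = ctx["fits"]
    best_fits = fits[fits["spec"] == best]
    wide = best_fits.pivot(index="participant_id", columns="block",
                           values=["alpha", "tau"])
    wide.columns = [f"{p}_{b}" for p, b in wide.columns]
    ratings = ctx["ratings"]
    pre_high = ratings[(ratings["time"] == "pre") & (ratings["stimulus"] == "high")]
    rate_wide = pre_high.pivot(index="participant_id", columns="rating_type",
                               values="rating")
    df = (
        scores.set_index("participant_id")
        .join(behaviour.set_index("participant_id"))
        .join(wide)
        .join(rate_wide)
        .reset_index()
    )
    return df


def _stage_stats(config: dict, seed: int, ctx: dict, files: _StageFiles) -> None:
    scfg = config["stats"]
    alpha = float(scfg.get("alpha", 0.05))
    k = float(scfg.get("outlier_k", 2.0))
    best = config["best_model"]
    table = _measure_table(ctx, best)
    report: dict = {"cohort_id": ctx.get("cohort_id"), "n_participants": len(table)}

    # effort modulation: single-pass outlier screen then one-tailed t
    diffs = table["effort_modulation"].dropna().to_numpy(dtype=float)
    retained, removed_idx = stats.filter_outliers(diffs, k=k)
    t, df_, p = stats.one_sample_t_one_tailed(retained, 0.0)
    report["effort_modulation"] = {
        "n_defined": int(diffs.size),
        "n_removed": int(removed_idx.size),
        "n_retained": int(retained.size),
        "mean_diff": float(retained.mean()),
        "t": t, "df": df_, "p": p, "one_sided": True,
    }
    keep_ids = np.ones(len(table), dtype=bool)
    defined_idx = table.index[table["effort_modulation"].notna()].to_numpy()
    keep_ids[defined_idx[removed_idx]] = False
    table_em = table[keep_ids & table["effort_modulation"].notna()]

    # correlation battery with BH within symptom families
    corr_rows = []
    for symptom, col in SYMPTOM_COLUMNS.items():
        for measure in BEHAVIOUR_MEASURES:
            sub = table_em if measure == "effort_modulation" else table
            cols = list(dict.fromkeys([measure, col, "bdi_reduced", "bdi_total", "block_order"]))
            sub = sub[cols].dropna()
            if sub[measure].nunique() < 2 or sub[col].nunique() < 2:
                continue
            res = stats.spearman_partial(
                sub[measure], sub[col], pair=f"{measure}~{symptom}"
            )
            corr_rows.append({**_corr_row(res), "family": symptom})
            covs = list(COVARIATE_RULE[symptom])
            if measure == "effort_modulation":
                covs = covs + ["block_order"]
            if covs:
                cov_arrays = [
                    sub[c] if c != "block_order"
                    else (sub[c] == task.REWARD_FIRST).astype(float)
                    for c in covs
                ]
                res_p = stats.spearman_partial(
                    sub[measure], sub[col], covariates=cov_arrays,
                    pair=f"{measure}~{symptom}", covariate_names=tuple(covs),
                )
                corr_rows.append({**_corr_row(res_p), "family": symptom})
    corr = pd.DataFrame(corr_rows)
    corr["p_bh"] = np.nan
    corr["reject_bh"] = False
    for (family, covs), idx in corr.groupby(["family", "covariates"]).groups.items():
        p_adj, reject = stats.bh_adjust(corr.loc[idx, "p"].to_numpy(), q=alpha)
        corr.loc[idx, "p_bh"] = p_adj
        corr.loc[idx, "reject_bh"] = reject
    files.write(corr, "correlations.csv")
    report["correlations"] = corr.to_dict(orient="records")

    # dependent-correlation comparison: is liking more strongly tied to
    # consummatory anhedonia than to depression? TEPS-C is reverse coded
    # (max+min - score) so both correlations point the same way.
    pf_sub = table[["liking", "bdi_total", "teps_c"]].dropna()
    rev_teps_c = 56 - pf_sub["teps_c"]  # item-level 7 - response, summed
    r_jk = stats.spearman_partial(pf_sub["liking"], pf_sub["bdi_total"]).rho
    r_jh = stats.spearman_partial(pf_sub["liking"], rev_teps_c).rho
    r_kh = stats.spearman_partial(pf_sub["bdi_total"], rev_teps_c).rho
    try:
        pf = stats.pearson_filon_z(r_jk, r_jh, r_kh, len(pf_sub))
        report["pearson_filon"] = {
            "comparison": "liking~bdi vs liking~reversed_teps_c",
            "r_jk": pf.r_jk, "r_jh": pf.r_jh, "r_kh": pf.r_kh,
            "n": pf.n, "z": pf.z, "p": pf.p,
        }
    except ValueError as exc:
        report["pearson_filon"] = {"error": str(exc)}

    # rating ANOVA on high-minus-low difference scores
    ratings = ctx["ratings"]
    wide = ratings.pivot_table(index=["participant_id", "rating_type", "time"],
                               columns="stimulus", values="rating").reset_index()
    wide["diff"] = wide["high"] - wide["low"]
    rating_table = stats.rating_anova(wide[["participant_id", "rating_type", "time", "diff"]])
    report["rating_anova"] = rating_table.to_dict(orient="records")

    # block type x block order mixed ANOVA on accuracies
    acc_long = ctx["behaviour"].melt(
        id_vars=["participant_id", "block_order"],
        value_vars=["reward_accuracy", "effort_accuracy"],
        var_name="block", value_name="accuracy",
    )
    acc_long["block"] = acc_long["block"].str.removesuffix("_accuracy")
    try:
        order_table = stats.block_order_anova(acc_long)
        report["block_order_anova"] = order_table.to_dict(orient="records")
    except ValueError as exc:
        report["block_order_anova"] = {"error": str(exc)}

    # a priori sample size for the planned correlation test
    report["power"] = {
        "rho": scfg.get("power_rho", 0.3),
        "power": scfg.get("power", 0.8),
        "alpha": alpha,
        "min_n_exact": stats.power_min_n(scfg.get("power_rho", 0.3),
                                         scfg.get("power", 0.8), alpha),
    }
    files.write_json(report, "stats_report.json")
    ctx["stats_report"] = report


def _corr_row(res: stats.CorrelationResult) -> dict:
    return {
        "pair": res.pair,
        "covariates": "+".join(res.covariates),
        "method": res.method,
        "rho": res.rho,
        "p": res.p,
        "n": res.n,
    }
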