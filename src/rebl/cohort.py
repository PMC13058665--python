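"""Synthetic cohort generation with planted symptom-behaviour effects.

The generator emulates the statistical structure the study design assumes:
155 young people spanning low (72), mild/moderate (65) and severe (18)
depression strata; item-level questionnaire responses; pre/post visual
analogue ratings of the reward stimuli (liking, wanting, willingness to
exert effort; 0-100); and a full two-block learning session per participant
with per-trial press speeds.

Structure: a latent severity factor induces the inter-correlations among
the symptom scales (configurable loadings); planted monotone effects link
symptom latents to agent parameters (softmax temperature per block), to the
reward-modulation of press speed, and to rating levels. Questionnaire items
are generated top-down -- a target total is drawn from the latent, then
distributed across items -- because only totals enter the downstream
analyses. Every draw is reproducible from the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import models, questionnaires, task
from .models import ParameterVector, get_model
from .task import EFFORT, EFFORT_FIRST, REWARD, REWARD_FIRST, SessionData, TaskConfig

SYMPTOM_LATENTS = ("bdi", "teps_a", "teps_c", "shaps", "stai")

RATING_TYPES = ("liking", "wanting", "effort_willingness")

#: default loadings of each symptom scale on the shared severity factor;
#: TEPS loads negatively (lower scores = more anhedonia).
DEFAULT_LOADINGS = {
    "bdi": 0.90,
    "teps_a": -0.55,
    "teps_c": -0.55,
    "shaps": 0.60,
    "stai": 0.70,
}

#: default planted effects, (target, symptom latent) -> correlation of the
#: behavioural latent with the symptom latent. Directions mirror the
#: hypothesised pattern: more consummatory anhedonia (lower TEPS-C, higher
#: SHAPS) -> higher temperature; more anticipatory anhedonia (lower TEPS-A)
#: -> weaker effort modulation and lower reward ratings; more depression ->
#: lower liking. Magnitudes sit near |rho| ~ 0.2, the scale of behavioural
#: correlations realistically detectable at N = 155.
DEFAULT_EFFECTS = {
    ("tau_reward", "teps_c"): -0.20,
    ("tau_effort", "shaps"): 0.20,
    ("effort_modulation", "teps_a"): 0.20,
    ("liking", "teps_a"): 0.30,
    ("liking", "bdi"): -0.15,
    ("wanting", "teps_a"): 0.30,
    ("effort_willingness", "teps_a"): 0.20,
}

BEHAVIOUR_TARGETS = ("tau_reward", "tau_effort", "effort_modulation",
                     "liking", "wanting", "effort_willingness")


class InfeasibleEffectMapError(ValueError):
    """The requested effect map implies a non-positive-semidefinite covariance."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 155
    strata_counts: tuple[int, int, int] = (72, 65, 18)  # low, mild/moderate, severe
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    # agent parameters (counterfactual alpha+tau model)
    alpha_mean: float = 0.44
    alpha_spread: float = 0.7  # SD on the logit scale
    tau_reward_mean: float = 2.05
    tau_effort_mean: float = 1.55
    tau_log_sd: float = 0.40
    # press speeds, presses per second
    speed_baseline_mean: float = 4.0
    speed_baseline_sd: float = 0.8
    modulation_mean: float = 0.10
    modulation_sd: float = 0.25
    speed_noise_sd: float = 0.40
    speed_floor: float = 0.5  # physiologic floor
    # ratings (0-100 visual analogue scale)
    rating_high_mean: float = 70.0
    rating_low_mean: float = 45.0
    rating_effect_scale: float = 12.0
    rating_noise_sd: float = 8.0
    rating_retest_sd: float = 5.0
    task: TaskConfig = field(default_factory=TaskConfig)
    model: str = models.BEST_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if any(c < 0 for c in self.strata_counts) or sum(self.strata_counts) <= 0:
            raise ValueError("strata_counts must be nonnegative with positive sum")
        for (target, symptom), r in self.effects.items():
            if target not in BEHAVIOUR_TARGETS:
                raise ValueError(f"unknown effect target {target!r}")
            if symptom not in SYMPTOM_LATENTS:
                raise ValueError(f"unknown symptom latent {symptom!r}")
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted correlation for {target}~{symptom} must be in (-1, 1)")


@dataclass
class CohortDataset:
    participants: pd.DataFrame
    ratings: pd.DataFrame
    sessions: list[SessionData]
    ground_truth: pd.DataFrame | None
    config: GeneratorConfig

    @property
    def cohort_id(self) -> str:
        ids = ",".join(self.participants["participant_id"].astype(str))
        return hashlib.sha1(f"{self.config.seed}|{ids}".encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# item-level generation
# ---------------------------------------------------------------------------


def distribute_total(total: int, n_items: int, lo: int, hi: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Distribute an integer total across items, each within [lo, hi]."""
    if not n_items * lo <= total <= n_items * hi:
        raise ValueError(f"total {total} infeasible for {n_items} items in [{lo}, {hi}]")
    items = np.full(n_items, lo, dtype=np.int64)
    remaining = total - n_items * lo
    while remaining > 0:
        open_idx = np.flatnonzero(items < hi)
        # add up to the remaining amount in random unit increments
        picks = rng.choice(open_idx, size=min(remaining, open_idx.size), replace=False)
        items[picks] += 1
        remaining -= picks.size
    return items


def _latent_to_total(latent: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Monotone map from a standard-normal latent to an integer total in [lo, hi]."""
    u = sps.norm.cdf(latent)
    return np.clip(np.rint(lo + u * (hi - lo)), lo, hi).astype(np.int64)


def _bdi_totals(severity_latent: np.ndarray, strata_counts: tuple[int, int, int]) -> np.ndarray:
    """Map severity percentiles to BDI totals through the severity bands.

    Piecewise-linear through 0-13 / 14-28 / 29-63 with breakpoints at the
    configured strata proportions, so the expected stratum mix matches.
    """
    total_n = sum(strata_counts)
    p1 = strata_counts[0] / total_n
    p2 = (strata_counts[0] + strata_counts[1]) / total_n
    u = sps.norm.cdf(severity_latent)
    out = np.empty(u.shape)
    low = u <= p1
    mid = (u > p1) & (u <= p2)
    high = u > p2
    out[low] = 13.0 * u[low] / p1 if p1 > 0 else 0.0
    if p2 > p1:
        out[mid] = 14.0 + 14.0 * (u[mid] - p1) / (p2 - p1)
    if p2 < 1:
        out[high] = 29.0 + 34.0 * (u[high] - p2) / (1 - p2)
    return np.clip(np.rint(out), 0, 63).astype(np.int64)


# ---------------------------------------------------------------------------
# latent construction
# ---------------------------------------------------------------------------


def _symptom_latents(config: GeneratorConfig, rng: np.random.Generator
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    n = config.n_participants
    severity = rng.standard_normal(n)
    lat = {}
    for name in SYMPTOM_LATENTS:
        lam = config.loadings[name]
        if not -1.0 <= lam <= 1.0:
            raise ValueError(f"loading for {name} must be in [-1, 1]")
        lat[name] = lam * severity + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    return severity, pd.DataFrame(lat)


def _latent_corr(config: GeneratorConfig) -> pd.DataFrame:
    """Implied correlation matrix of the symptom latents (shared-factor model)."""
    lams = np.array([config.loadings[s] for s in SYMPTOM_LATENTS])
    C = np.outer(lams, lams)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=SYMPTOM_LATENTS, columns=SYMPTOM_LATENTS)


def _behaviour_latents(config: GeneratorConfig, symptom_lat: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """One unit-variance latent per behavioural target, tied to its symptom drivers."""
    n = len(symptom_lat)
    corr = _latent_corr(config)
    out = {}
    for target in BEHAVIOUR_TARGETS:
        drivers = {s: r for (t, s), r in config.effects.items() if t == target}
        if not drivers:
            out[target] = rng.standard_normal(n)
            continue
        names = list(drivers)
        r = np.array([drivers[s] for s in names])
        sub = corr.loc[names, names].to_numpy()
        signal_var = float(r @ sub @ r)
        if signal_var > 1.0 + 1e-12:
            raise InfeasibleEffectMapError(
                f"planted effects for {target!r} imply latent variance {signal_var:.3f} > 1; "
                "the implied correlation matrix is not positive semidefinite"
            )
        signal = sum(w * symptom_lat[s].to_numpy() for s, w in drivers.items())
        out[target] = signal + np.sqrt(max(0.0, 1.0 - signal_var)) * rng.standard_normal(n)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_cohort(config: GeneratorConfig | None = None) -> CohortDataset:
    """Generate a complete synthetic cohort (questionnaires, ratings, sessions)."""
    config = config or GeneratorConfig()
    n = config.n_participants
    pids = [f"p{i:04d}" for i in range(n)]

    severity, sym_lat = _symptom_latents(config, _rng(config, 1))
    beh_lat = _behaviour_latents(config, sym_lat, _rng(config, 2))

    # --- questionnaire totals and items ---------------------------------
    rng_items = _rng(config, 3)
    bdi_totals = _bdi_totals(sym_lat["bdi"].to_numpy(), config.strata_counts)
    teps_a_totals = _latent_to_total(sym_lat["teps_a"].to_numpy(), 10, 60)
    teps_c_totals = _latent_to_total(sym_lat["teps_c"].to_numpy(), 8, 48)
    shaps_totals = _latent_to_total(sym_lat["shaps"].to_numpy(), 0, 14)
    stai_totals = _latent_to_total(sym_lat["stai"].to_numpy(), 20, 80)

    part_rows = []
    for i, pid in enumerate(pids):
        row: dict = {"participant_id": pid}
        bdi_items = distribute_total(int(bdi_totals[i]), 21, 0, 3, rng_items)
        row.update(zip(questionnaires.BDI_COLUMNS, (int(v) for v in bdi_items)))
        teps_items = np.empty(18, dtype=np.int64)
        a_vals = distribute_total(int(teps_a_totals[i]), 10, 1, 6, rng_items)
        c_vals = distribute_total(int(teps_c_totals[i]), 8, 1, 6, rng_items)
        for j, item in enumerate(questionnaires.TEPS_ANTICIPATORY_ITEMS):
            teps_items[item - 1] = a_vals[j]
        for j, item in enumerate(questionnaires.TEPS_CONSUMMATORY_ITEMS):
            teps_items[item - 1] = c_vals[j]
        row.update(zip(questionnaires.TEPS_COLUMNS, (int(v) for v in teps_items)))
        shaps_items = np.where(
            np.isin(np.arange(14), rng_items.choice(14, int(shaps_totals[i]), replace=False)),
            rng_items.integers(1, 3, 14),  # disagree levels
            rng_items.integers(3, 5, 14),  # agree levels
        )
        row.update(zip(questionnaires.SHAPS_COLUMNS, (int(v) for v in shaps_items)))
        anx = distribute_total(int(stai_totals[i]), 20, 1, 4, rng_items)
        stai_items = anx.copy()
        for item in questionnaires.STAI_REVERSE_ITEMS:
            stai_items[item - 1] = 5 - anx[item - 1]
        row.update(zip(questionnaires.STAI_COLUMNS, (int(v) for v in stai_items)))
        row["age"] = int(rng_items.integers(16, 26))
        row["sex"] = str(rng_items.choice(["female", "male"], p=[0.75, 0.25]))
        part_rows.append(row)
    participants = pd.DataFrame(part_rows)

    # --- agent parameters -------------------------------------------------
    rng_par = _rng(config, 4)
    logit = np.log(config.alpha_mean / (1 - config.alpha_mean))
    alpha_r = 1 / (1 + np.exp(-(logit + config.alpha_spread * rng_par.standard_normal(n))))
    alpha_e = 1 / (1 + np.exp(-(logit + config.alpha_spread * rng_par.standard_normal(n))))
    sd = config.tau_log_sd
    tau_r = np.exp(np.log(config.tau_reward_mean) - sd**2 / 2 + sd * beh_lat["tau_reward"])
    tau_e = np.exp(np.log(config.tau_effort_mean) - sd**2 / 2 + sd * beh_lat["tau_effort"])
    tau_r = np.clip(tau_r, 0.05, 15.0)
    tau_e = np.clip(tau_e, 0.05, 15.0)
    baseline = np.maximum(
        config.speed_baseline_mean + config.speed_baseline_sd * rng_par.standard_normal(n), 1.0
    )
    modulation = config.modulation_mean + config.modulation_sd * beh_lat["effort_modulation"]

    # --- sessions ----------------------------------------------------------
    rng_task = _rng(config, 5)
    spec = get_model(config.model)
    sessions: list[SessionData] = []
    orders = []
    for i, pid in enumerate(pids):
        order = REWARD_FIRST if rng_task.random() < 0.5 else EFFORT_FIRST
        orders.append(order)
        cfg = task.TaskConfig(
            reward_block_contingency=config.task.reward_block_contingency,
            effort_block_contingency=config.task.effort_block_contingency,
            high_effort_presses=config.task.high_effort_presses,
            low_effort_presses=config.task.low_effort_presses,
            trials_per_block=config.task.trials_per_block,
            n_practice=config.task.n_practice,
            block_order=order,
            seed=config.seed,
        )
        block_params = {
            REWARD: ParameterVector(alpha=float(alpha_r[i]), tau=float(tau_r[i])),
            EFFORT: ParameterVector(alpha=float(alpha_e[i]), tau=float(tau_e[i])),
        }
        policies = {b: models.QLearningPolicy(p, spec, rng_task) for b, p in block_params.items()}
        session = task.run_session(lambda b, h: policies[b](b, h), cfg, rng_task, pid)
        speeds = []
        for t in session.trials:
            mu = baseline[i] + (modulation[i] if t.reward_level == "high" else 0.0)
            speeds.append(max(config.speed_floor, mu + config.speed_noise_sd * rng_task.standard_normal()))
        sessions.append(task.with_press_speeds(session, speeds))

    # --- ratings -----------------------------------------------------------
    rng_rate = _rng(config, 6)
    rate_rows = []
    for i, pid in enumerate(pids):
        for rtype in RATING_TYPES:
            high_pre = (config.rating_high_mean
                        + config.rating_effect_scale * beh_lat.loc[i, rtype]
                        + config.rating_noise_sd * rng_rate.standard_normal())
            low_pre = config.rating_low_mean + 10.0 * rng_rate.standard_normal()
            for stimulus, pre in (("high", high_pre), ("low", low_pre)):
                post = pre + config.rating_retest_sd * rng_rate.standard_normal()
                for time, value in (("pre", pre), ("post", post)):
                    rate_rows.append(
                        {
                            "participant_id": pid,
                            "rating_type": rtype,
                            "stimulus": stimulus,
                            "time": time,
                            "rating": float(np.clip(np.rint(value), 0, 100)),
                        }
                    )
    ratings = pd.DataFrame(rate_rows)

    ground_truth = pd.DataFrame(
        {
            "participant_id": pids,
            "severity": severity,
            "stratum": [questionnaires.bdi_severity(int(t)) for t in bdi_totals],
            "block_order": orders,
            "alpha_reward": alpha_r,
            "alpha_effort": alpha_e,
            "tau_reward": tau_r,
            "tau_effort": tau_e,
            "speed_baseline": baseline,
            "modulation": modulation,
            **{f"latent_{t}": beh_lat[t].to_numpy() for t in BEHAVIOUR_TARGETS},
        }
    )
    return CohortDataset(participants, ratings, sessions, ground_truth, config)


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------


def planted_effect_audit(dataset: CohortDataset, pipeline_output: dict,
                         tolerance: float = 0.2) -> pd.DataFrame:
    """Compare planted effect signs/magnitudes against pipeline estimates.

    ``pipeline_output`` must carry the ``cohort_id`` of the dataset it was
    computed from and a ``correlations`` table (records with ``pair``,
    ``covariates`` and ``rho``); zero-order rows (empty covariates) are
    matched against the planted map by their ``target~symptom`` pair name.
    """
    if dataset.ground_truth is None:
        raise ValueError("dataset has no ground truth; audit requires a synthetic cohort")
    if pipeline_output.get("cohort_id") != dataset.cohort_id:
        raise ValueError(
            "cohort identifier mismatch: the pipeline output was computed from a "
            "different dataset"
        )
    corr = pd.DataFrame(pipeline_output["correlations"],
                        columns=["pair", "covariates", "rho"]
                        if not pipeline_output["correlations"] else None)
    if corr.empty:
        by_pair = {}
    else:
        corr = corr[corr["covariates"].fillna("").astype(str) == ""]
        by_pair = corr.set_index("pair")["rho"].to_dict()
    latent_corr = _latent_corr(dataset.config)
    rows = []
    for (target, symptom), planted in dataset.config.effects.items():
        pair = f"{target}~{symptom}"
        # marginal correlation implied by all drivers of this target, not
        # just the named one: corr(T, L_s) = sum_k r_k Corr(L_k, L_s)
        drivers = {s: r for (t, s), r in dataset.config.effects.items() if t == target}
        implied = float(sum(r * latent_corr.loc[s, symptom] for s, r in drivers.items()))
        est = by_pair.get(pair)
        if est is None:
            rows.append({"pair": pair, "planted_r": planted, "implied_r": implied,
                         "estimated_rho": np.nan, "sign_match": False,
                         "within_tolerance": False, "status": "missing"})
            continue
        sign_ok = (implied == 0 and abs(est) <= tolerance) or (np.sign(est) == np.sign(implied))
        rows.append(
            {
                "pair": pair,
                "planted_r": planted,
                "implied_r": implied,
                "estimated_rho": float(est),
                "sign_match": bool(sign_ok),
                "within_tolerance": bool(abs(est - implied) <= tolerance),
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)


def effects_to_json(effects: dict) -> str:
    """Serialise an effect map for configs / manifests."""
    return json.dumps({f"{t}~{s}": r for (t, s), r in effects.items()}, sort_keys=True)


def effects_from_json(text: str) -> dict:
    out = {}
    for key, r in json.loads(text).items():
        target, symptom = key.split("~", 1)
        out[(target, symptom)] = float(r)
    return out
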