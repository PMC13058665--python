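"""CSV schemas and schema-validated readers for the pipeline tables.

All tables are UTF-8 CSV with a header row. ``trials.csv`` has one row per
experimental trial with 0-based ``trial_index`` and ``choice`` coded 1 for
the advantageous shape.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import questionnaires
from .task import (
    ADVANTAGEOUS,
    BLOCK_ORDERS,
    BLOCKS,
    DISADVANTAGEOUS,
    SessionData,
    TaskConfig,
    TrialRecord,
)

TRIALS_COLUMNS = [
    "participant_id", "block", "block_order", "trial_index", "choice", "outcome",
    "reward_level", "effort_level", "required_presses", "press_speed",
]


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "block": t.block,
                    "block_order": s.config.block_order,
                    "trial_index": t.trial_index,
                    "choice": 1 if t.choice == ADVANTAGEOUS else 0,
                    "outcome": t.outcome,
                    "reward_level": t.reward_level,
                    "effort_level": t.effort_level,
                    "required_presses": t.required_presses,
                    "press_speed": t.press_speed,
                }
            )
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def frame_to_sessions(df: pd.DataFrame, base_config: TaskConfig | None = None
                      ) -> list[SessionData]:
    """Rebuild SessionData objects from a validated trials table."""
    validate_trials(df)
    base = base_config or TaskConfig()
    sessions = []
    for pid, grp in df.groupby("participant_id", sort=True):
        order = grp["block_order"].iloc[0]
        n_per_block = len(grp) // 2
        cfg = TaskConfig(
            reward_block_contingency=base.reward_block_contingency,
            effort_block_contingency=base.effort_block_contingency,
            high_effort_presses=base.high_effort_presses,
            low_effort_presses=base.low_effort_presses,
            trials_per_block=n_per_block,
            n_practice=base.n_practice,
            block_order=order,
            seed=base.seed,
        )
        trials = []
        for block in cfg.blocks_in_order:
            sub = grp[grp["block"] == block].sort_values("trial_index")
            for _, r in sub.iterrows():
                trials.append(
                    TrialRecord(
                        block=r["block"],
                        trial_index=int(r["trial_index"]),
                        choice=ADVANTAGEOUS if int(r["choice"]) == 1 else DISADVANTAGEOUS,
                        outcome=int(r["outcome"]),
                        reward_level=r["reward_level"],
                        effort_level=r["effort_level"],
                        required_presses=int(r["required_presses"]),
                        press_speed=None if pd.isna(r["press_speed"]) else float(r["press_speed"]),
                    )
                )
        sessions.append(SessionData(str(pid), cfg, trials))
    return sessions


def validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trials table missing columns: {missing}")
    bad_block = sorted(set(df["block"]) - set(BLOCKS))
    if bad_block:
        raise SchemaError(f"column 'block' contains invalid levels {bad_block}; expected {list(BLOCKS)}")
    bad_order = sorted(set(df["block_order"]) - set(BLOCK_ORDERS))
    if bad_order:
        raise SchemaError(f"column 'block_order' contains invalid levels {bad_order}")
    if not df["choice"].isin([0, 1]).all():
        raise SchemaError("column 'choice' must be 0/1 (1 = advantageous)")
    if not df["outcome"].isin([0, 1]).all():
        raise SchemaError("column 'outcome' must be 0/1 (1 = favourable)")
    for pid, grp in df.groupby("participant_id"):
        counts = grp["block"].value_counts()
        if set(counts.index) != set(BLOCKS) or counts.nunique() != 1:
            raise SchemaError(f"participant {pid}: both blocks must be present with equal trial counts")


def validate_participants(df: pd.DataFrame) -> None:
    required = (
        ["participant_id"]
        + questionnaires.BDI_COLUMNS
        + questionnaires.TEPS_COLUMNS
        + questionnaires.SHAPS_COLUMNS
        + questionnaires.STAI_COLUMNS
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"participants table missing columns: {missing}")
    if df["participant_id"].duplicated().any():
        raise SchemaError("duplicate participant_id in participants table")


def validate_ratings(df: pd.DataFrame) -> None:
    required = {"participant_id", "rating_type", "stimulus", "time", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"ratings table missing columns: {sorted(missing)}")
    if not df["time"].isin(["pre", "post"]).all():
        raise SchemaError("column 'time' must be pre/post")
    if not df["stimulus"].isin(["high", "low"]).all():
        raise SchemaError("column 'stimulus' must be high/low")
    if ((df["rating"] < 0) | (df["rating"] > 100)).any():
        raise SchemaError("ratings must lie in [0, 100]")


def read_csv(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    {"trials": validate_trials,
     "participants": validate_participants,
     "ratings": validate_ratings}[kind](df)
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
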