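"""Scoring for the four self-report instruments.

* BDI-II: 21 items coded 0-3; total 0-63 with severity bands 0-13 (low),
  14-28 (mild/moderate), 29-63 (severe). A reduced total excludes the four
  anhedonia items (loss of pleasure, loss of interest, loss of energy,
  loss of interest in sex), used as the depression covariate when anhedonia
  itself is the variable of interest.
* TEPS: 18 items on a 1-6 Likert scale, split into anticipatory (10 items)
  and consummatory (8 items) pleasure subscales; lower scores mean more
  anhedonia.
* SHAPS: 14 agree/disagree items; each disagree-type response scores 1, so
  the total is 0-14 with higher scores meaning more anhedonia.
* STAI trait: 20 items on a 1-4 scale with the anxiety-absent items reverse
  keyed; total 20-80, with totals strictly above 60 flagged as severe.

Item keys (TEPS subscale membership, STAI reverse-keyed set, BDI anhedonia
item numbers) follow the original published instruments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

# 1-based item numbers of the four BDI-II anhedonia items:
# 4 loss of pleasure, 12 loss of interest, 15 loss of energy, 21 loss of interest in sex
BDI_ANHEDONIA_ITEMS = (4, 12, 15, 21)

# TEPS subscale membership (1-based), anticipatory n=10, consummatory n=8
TEPS_ANTICIPATORY_ITEMS = (1, 4, 6, 8, 10, 11, 13, 15, 16, 18)
TEPS_CONSUMMATORY_ITEMS = (2, 3, 5, 7, 9, 12, 14, 17)

# STAI trait reverse-keyed (anxiety-absent) items, 1-based within the 20-item trait form
STAI_REVERSE_ITEMS = (1, 3, 6, 7, 10, 13, 14, 16, 19)

SEVERITY_LOW = "low"
SEVERITY_MILD_MODERATE = "mild_moderate"
SEVERITY_SEVERE = "severe"


class ResponseValidationError(ValueError):
    """Item responses violate the instrument's layout (count, range, missing)."""


def _validate(responses: Sequence[int], n_items: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(responses)
    if arr.shape != (n_items,):
        raise ResponseValidationError(
            f"{name} requires exactly {n_items} items, got shape {arr.shape}"
        )
    if pd.isna(arr).any():
        raise ResponseValidationError(f"{name} has missing items; imputation is not supported")
    arr = arr.astype(np.int64)
    if not np.array_equal(arr, np.asarray(responses, dtype=float)):
        raise ResponseValidationError(f"{name} responses must be integer codes")
    if arr.min() < lo or arr.max() > hi:
        raise ResponseValidationError(
            f"{name} responses must be in [{lo}, {hi}], got range "
            f"[{arr.min()}, {arr.max()}]"
        )
    return arr


@dataclass(frozen=True)
class BdiScore:
    total: int
    severity: str
    reduced_total: int


def bdi_severity(total: int) -> str:
    if total <= 13:
        return SEVERITY_LOW
    if total <= 28:
        return SEVERITY_MILD_MODERATE
    return SEVERITY_SEVERE


def score_bdi(responses: Sequence[int]) -> BdiScore:
    """Score the BDI-II: total, severity band, and anhedonia-reduced total."""
    arr = _validate(responses, 21, 0, 3, "BDI")
    total = int(arr.sum())
    keep = [i for i in range(21) if (i + 1) not in BDI_ANHEDONIA_ITEMS]
    return BdiScore(total=total, severity=bdi_severity(total), reduced_total=int(arr[keep].sum()))


def score_teps(responses: Sequence[int]) -> tuple[int, int]:
    """Score the TEPS into (anticipatory, consummatory) subscale sums."""
    arr = _validate(responses, 18, 1, 6, "TEPS")
    teps_a = int(sum(arr[i - 1] for i in TEPS_ANTICIPATORY_ITEMS))
    teps_c = int(sum(arr[i - 1] for i in TEPS_CONSUMMATORY_ITEMS))
    return teps_a, teps_c


def score_shaps(responses: Sequence[int]) -> int:
    """Score the SHAPS: count of disagree-type responses.

    Codes: 1 = strongly disagree, 2 = disagree, 3 = agree, 4 = strongly
    agree. Either disagree level scores 1, either agree level scores 0.
    """
    arr = _validate(responses, 14, 1, 4, "SHAPS")
    return int((arr <= 2).sum())


def score_stai(responses: Sequence[int]) -> tuple[int, bool]:
    """Score the STAI trait scale: (total, severe flag).

    Reverse-keyed items are inverted (5 - response) before summing; totals
    strictly above 60 are flagged as severe anxiety.
    """
    arr = _validate(responses, 20, 1, 4, "STAI")
    keyed = arr.copy()
    for i in STAI_REVERSE_ITEMS:
        keyed[i - 1] = 5 - keyed[i - 1]
    total = int(keyed.sum())
    return total, total > 60


@dataclass(frozen=True)
class SymptomScores:
    participant_id: str
    bdi_total: int
    bdi_severity: str
    bdi_reduced: int
    teps_a: int
    teps_c: int
    shaps_total: int
    stai_total: int
    stai_severe: bool


def _item_cols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:02d}" for i in range(1, n + 1)]


BDI_COLUMNS = _item_cols("bdi", 21)
TEPS_COLUMNS = _item_cols("teps", 18)
SHAPS_COLUMNS = _item_cols("shaps", 14)
STAI_COLUMNS = _item_cols("stai", 20)


def score_participants(participants: pd.DataFrame) -> pd.DataFrame:
    """Score a participant table with item-level columns into SymptomScores rows.

    Expects columns ``participant_id`` plus ``bdi_01..bdi_21``,
    ``teps_01..teps_18``, ``shaps_01..shaps_14``, ``stai_01..stai_20``.
    """
    required = ["participant_id"] + BDI_COLUMNS + TEPS_COLUMNS + SHAPS_COLUMNS + STAI_COLUMNS
    missing = [c for c in required if c not in participants.columns]
    if missing:
        raise ResponseValidationError(f"participants table is missing columns: {missing}")
    rows = []
    for _, row in participants.iterrows():
        bdi = score_bdi(row[BDI_COLUMNS].to_numpy())
        teps_a, teps_c = score_teps(row[TEPS_COLUMNS].to_numpy())
        shaps = score_shaps(row[SHAPS_COLUMNS].to_numpy())
        stai_total, stai_severe = score_stai(row[STAI_COLUMNS].to_numpy())
        rows.append(
            {
                "participant_id": row["participant_id"],
                "bdi_total": bdi.total,
                "bdi_severity": bdi.severity,
                "bdi_reduced": bdi.reduced_total,
                "teps_a": teps_a,
                "teps_c": teps_c,
                "shaps_total": shaps,
                "stai_total": stai_total,
                "stai_severe": stai_severe,
            }
        )
    return pd.DataFrame(rows)
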