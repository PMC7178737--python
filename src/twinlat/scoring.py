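"""Laterality scoring: hand-preference inventory and pegboard indexes.

The preference instrument is a 10-item inventory (a child-adapted Edinburgh
Handedness Inventory variant).  Each item is answered as left / right /
either, and — when a hand is named — always / usually.  Points go into a
Left and a Right column (2 for "always", 1 for "usually", 1 in both for
"either") and the laterality quotient is

    EHI = (RH - LH) / (RH + LH)

over the column totals, ranging from -1 (fully left) to +1 (fully right).
EHI2 binarises at zero, with a score of exactly zero counted as
non-right-handed.

The performance index comes from a peg-moving task: five timed trials per
hand, the best (fastest) three averaged, and

    PegQ = 2 (L - R) / (L + R)

on the per-hand means, positive when the right hand is faster.  PegQ2
binarises at zero the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITEMS",
    "EIGHT_ITEM_SUBSET",
    "ItemResponse",
    "HandPoints",
    "EHIScore",
    "PegQScore",
    "score_item",
    "compute_ehi",
    "classify_ehi2",
    "recode_item_binary",
    "recode_item_three_class",
    "infer_switch",
    "compute_pegq",
    "classify_pegq2",
    "score_study",
]

#: The ten inventory items, in administration order.
ITEMS = (
    "writing",
    "drawing",
    "throwing",
    "scissors",
    "toothbrush",
    "chopsticks",
    "spoon",
    "knife",
    "broom",
    "box_lid",
)

#: Items used for the switch-inference composite (everything but pen tasks).
EIGHT_ITEM_SUBSET = tuple(i for i in ITEMS if i not in ("writing", "drawing"))

_HANDS = frozenset({"left", "right", "either"})
_DEGREES = frozenset({"always", "usually"})


@dataclass(frozen=True)
class ItemResponse:
    """A single answered inventory item."""

    item: str
    hand: str
    degree: Optional[str] = None

    def __post_init__(self) -> None:
        if self.item not in ITEMS:
            raise ValueError(f"unknown item {self.item!r}; expected one of {ITEMS}")
        if self.hand not in _HANDS:
            raise ValueError(f"unknown hand {self.hand!r}; expected left/right/either")
        if self.hand != "either" and self.degree not in _DEGREES:
            raise ValueError(
                f"degree must be always/usually when hand={self.hand!r}, got {self.degree!r}"
            )


@dataclass(frozen=True)
class HandPoints:
    left: int
    right: int


@dataclass(frozen=True)
class EHIScore:
    value: float
    lh_sum: int
    rh_sum: int
    n_items: int


@dataclass(frozen=True)
class PegQScore:
    value: float
    left_mean: float
    right_mean: float


def score_item(response: ItemResponse) -> HandPoints:
    """Point decomposition of one item: always -> 2 in the preferred column,
    usually -> 1 in the preferred column, either -> 1 in both columns."""
    if response.hand == "either":
        return HandPoints(1, 1)
    pts = 2 if response.degree == "always" else 1
    if response.hand == "left":
        return HandPoints(pts, 0)
    return HandPoints(0, pts)


def compute_ehi(
    responses: Mapping[str, ItemResponse],
    items: Optional[Sequence[str]] = None,
) -> EHIScore:
    """Laterality quotient (RH - LH)/(RH + LH) over the selected items.

    Missing items are simply excluded (no imputation); an empty usable
    subset is an error rather than a silent zero.
    """
    selected = ITEMS if items is None else tuple(items)
    unknown = [i for i in selected if i not in ITEMS]
    if unknown:
        raise ValueError(f"unknown items in subset: {unknown}")
    lh = rh = 0
    n_used = 0
    for item in selected:
        resp = responses.get(item)
        if resp is None:
            continue
        pts = score_item(resp)
        lh += pts.left
        rh += pts.right
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable items: all responses missing in the selected subset")
    return EHIScore(value=(rh - lh) / (rh + lh), lh_sum=lh, rh_sum=rh, n_items=n_used)


def classify_ehi2(value: float) -> int:
    """Binarise EHI at zero: >0 -> 1 (right-handed), <=0 -> 0 (non-right)."""
    return int(value > 0)


def recode_item_binary(response: ItemResponse) -> int:
    """Right -> 1; left or no preference -> 0 (used for writing/drawing hand)."""
    return int(response.hand == "right")


def recode_item_three_class(response: ItemResponse) -> str:
    """Three-way preference class: LH / NP / RH (degree ignored)."""
    if response.hand == "left":
        return "LH"
    if response.hand == "right":
        return "RH"
    return "NP"


def infer_switch(responses: Mapping[str, ItemResponse]) -> Optional[bool]:
    """Flag a likely forced writing-hand switch.

    True when the subject writes with the right hand yet the left column
    total over the eight non-pen items exceeds the right column total.
    Returns ``None`` when the writing item or all eight composite items
    are missing.
    """
    writing = responses.get("writing")
    if writing is None:
        return None
    present = [i for i in EIGHT_ITEM_SUBSET if i in responses]
    if not present:
        return None
    if recode_item_binary(writing) != 1:
        return False
    sub = compute_ehi(responses, items=EIGHT_ITEM_SUBSET)
    return sub.lh_sum > sub.rh_sum


def compute_pegq(
    left_times: Sequence[float], right_times: Sequence[float]
) -> PegQScore:
    """Pegboard laterality index 2(L-R)/(L+R) on best-3-of-5 trial means.

    "Best" means fastest; ties keep the earlier trials (numpy's stable
    partial sort makes the selection deterministic).
    """
    left = np.asarray(left_times, dtype=float)
    right = np.asarray(right_times, dtype=float)
    for name, arr in (("left", left), ("right", right)):
        if arr.size < 3:
            raise ValueError(f"{name} hand has {arr.size} trials; need at least 3")
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} hand has non-positive or non-finite trial times")
    lmean = float(np.sort(left, kind="stable")[:3].mean())
    rmean = float(np.sort(right, kind="stable")[:3].mean())
    value = 2.0 * (lmean - rmean) / (lmean + rmean)
    return PegQScore(value=value, left_mean=lmean, right_mean=rmean)


def classify_pegq2(value: float) -> int:
    """Binarise PegQ at zero: positive -> 1, otherwise 0."""
    return int(value > 0)


def _responses_from_frame(group: pd.DataFrame) -> dict[str, ItemResponse]:
    out: dict[str, ItemResponse] = {}
    for row in group.itertuples(index=False):
        degree = None if pd.isna(row.degree) or row.degree == "" else str(row.degree)
        resp = ItemResponse(item=str(row.item_id), hand=str(row.hand), degree=degree)
        if resp.item in out:
            raise ValueError(
                f"duplicate response for item {resp.item!r}, subject {row.subject_id!r}"
            )
        out[resp.item] = resp
    return out


def score_study(
    items: pd.DataFrame, pegs: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Score a whole study from long-format tables.

    Parameters
    ----------
    items : DataFrame with columns subject_id, item_id, hand, degree
        One row per answered item.
    pegs : DataFrame with columns subject_id, hand, trial_index, time_seconds
        Optional pegboard trials; subjects may appear in either table only.

    Returns
    -------
    DataFrame with one row per subject: writing_bin, drawing_bin, EHI, EHI2,
    PegQ, PegQ2, switch_flag, n_items_used.  Measures a subject lacks are NaN.
    """
    records: dict[str, dict] = {}

    if items is not None and len(items):
        for sid, group in items.groupby("subject_id", sort=False):
            responses = _responses_from_frame(group)
            row: dict = {"subject_id": sid}
            if "writing" in responses:
                row["writing_bin"] = recode_item_binary(responses["writing"])
            if "drawing" in responses:
                row["drawing_bin"] = recode_item_binary(responses["drawing"])
            if responses:
                ehi = compute_ehi(responses)
                row["EHI"] = ehi.value
                row["EHI2"] = classify_ehi2(ehi.value)
                row["n_items_used"] = ehi.n_items
            switch = infer_switch(responses)
            if switch is not None:
                row["switch_flag"] = int(switch)
            records[sid] = row

    if pegs is not None and len(pegs):
        for sid, group in pegs.groupby("subject_id", sort=False):
            left = group.loc[group["hand"] == "left"].sort_values("trial_index")
            right = group.loc[group["hand"] == "right"].sort_values("trial_index")
            score = compute_pegq(
                left["time_seconds"].to_numpy(), right["time_seconds"].to_numpy()
            )
            row = records.setdefault(sid, {"subject_id": sid})
            row["PegQ"] = score.value
            row["PegQ2"] = classify_pegq2(score.value)

    cols = [
        "subject_id",
        "writing_bin",
        "drawing_bin",
        "EHI",
        "EHI2",
        "PegQ",
        "PegQ2",
        "switch_flag",
        "n_items_used",
    ]
    out = pd.DataFrame.from_records(list(records.values()))
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols].reset_index(drop=True)
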