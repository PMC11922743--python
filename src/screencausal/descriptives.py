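"""Crude (unadjusted) program metrics: rates per 1,000, PPVs, triage summaries.

Every rate and PPV is recomputed from its own counts at full precision;
the one-decimal display rounding (round half away from zero, as in
screening-program reports) never feeds back into computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CohortTable

__all__ = [
    "UndefinedRateError",
    "crude_rate",
    "ppv_crude",
    "display_round",
    "triage_summary",
    "cohort_summary",
    "CohortSummary",
]


class UndefinedRateError(ZeroDivisionError):
    """Rate or PPV requested with a zero denominator."""


def display_round(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the program tables."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def crude_rate(events: int, n: int, per: float = 1000.0) -> float:
    """Events per ``per`` screened women (full precision)."""
    if n <= 0:
        raise UndefinedRateError("rate undefined for n = 0")
    if not 0 <= events <= n:
        raise ValueError(f"events={events} outside [0, n={n}]")
    return events / n * per


def ppv_crude(true_positives: int, positives: int) -> float:
    """Positive predictive value in percent."""
    if positives <= 0:
        raise UndefinedRateError("PPV undefined for zero positives")
    if not 0 <= true_positives <= positives:
        raise ValueError("true_positives outside [0, positives]")
    return 100.0 * true_positives / positives


@dataclass
class GroupBlock:
    """Counts and derived metrics for one study group (or overall)."""

    n: int = 0
    consensus: int = 0
    recall: int = 0
    biopsy: int = 0
    cancers: int = 0
    by_invasiveness: dict = field(default_factory=dict)
    by_stage: dict = field(default_factory=dict)
    by_grade: dict = field(default_factory=dict)
    by_size: dict = field(default_factory=dict)

    def rates(self) -> dict:
        if self.n == 0:
            nan = float("nan")
            return {"consensus_pct": nan, "recall_per_1000": nan,
                    "biopsy_per_1000": nan, "detection_per_1000": nan,
                    "ppv_recall_pct": nan, "ppv_biopsy_pct": nan}
        out = {
            "consensus_pct": 100.0 * self.consensus / self.n,
            "recall_per_1000": crude_rate(self.recall, self.n),
            "biopsy_per_1000": crude_rate(self.biopsy, self.n),
            "detection_per_1000": crude_rate(self.cancers, self.n),
        }
        out["ppv_recall_pct"] = (ppv_crude(self.cancers, self.recall)
                                 if self.recall else float("nan"))
        out["ppv_biopsy_pct"] = (ppv_crude(self.cancers, self.biopsy)
                                 if self.biopsy else float("nan"))
        return out


@dataclass
class TriageBlock:
    """AI-prediction counts for one group, denominators = group n."""

    n: int = 0
    normal: int = 0
    normal_consensus: int = 0
    normal_recall: int = 0
    normal_biopsy: int = 0
    normal_cancer: int = 0
    sn_triggered: int = 0
    sn_shown: int = 0
    sn_accepted: int = 0
    sn_accepted_recall: int = 0
    sn_accepted_cancer: int = 0

    def fractions(self) -> dict:
        if self.n == 0:
            return {}
        return {k: getattr(self, k) / self.n * 100.0
                for k in ("normal", "normal_consensus", "normal_recall",
                          "normal_biopsy", "normal_cancer", "sn_triggered",
                          "sn_shown", "sn_accepted", "sn_accepted_recall",
                          "sn_accepted_cancer")}


@dataclass
class CohortSummary:
    groups: dict  # name -> GroupBlock, names: ai / control / overall
    triage: dict  # name -> TriageBlock


def _group_masks(df: pd.DataFrame) -> dict[str, np.ndarray]:
    grp = df["study_group"].to_numpy(object)
    return {"ai": grp == "ai", "control": grp == "control",
            "overall": np.ones(len(df), dtype=bool)}


def _count_block(df: pd.DataFrame, mask: np.ndarray) -> GroupBlock:
    sub = df.loc[mask]
    det = sub["cancer_detected"].astype(bool)
    blk = GroupBlock(
        n=int(mask.sum()),
        consensus=int(sub["consensus"].sum()),
        recall=int(sub["recall"].sum()),
        biopsy=int(sub["biopsy"].sum()),
        cancers=int(det.sum()),
    )
    cancers = sub.loc[det]
    blk.by_invasiveness = cancers["invasiveness"].value_counts().to_dict()
    blk.by_stage = cancers["stage"].value_counts(dropna=True).to_dict()
    inv = cancers.loc[cancers["invasiveness"] == "invasive"]
    blk.by_grade = inv["grade"].value_counts(dropna=True).to_dict()
    blk.by_size = inv["size_class"].value_counts(dropna=True).to_dict()
    return blk


def _triage_block(df: pd.DataFrame, mask: np.ndarray) -> TriageBlock:
    sub = df.loc[mask]
    tag = sub["ai_normal_tag"].astype(bool)
    acc = sub["safety_net_accepted"].astype("Int64").fillna(0).astype(bool)
    return TriageBlock(
        n=int(mask.sum()),
        normal=int(tag.sum()),
        normal_consensus=int((tag & sub["consensus"].astype(bool)).sum()),
        normal_recall=int((tag & sub["recall"].astype(bool)).sum()),
        normal_biopsy=int((tag & sub["biopsy"].astype(bool)).sum()),
        normal_cancer=int((tag & sub["cancer_detected"].astype(bool)).sum()),
        sn_triggered=int(sub["safety_net_triggered"].sum()),
        sn_shown=int(sub["safety_net_shown"].astype("Int64").fillna(0).sum()),
        sn_accepted=int(acc.sum()),
        sn_accepted_recall=int((acc & sub["recall"].astype(bool)).sum()),
        sn_accepted_cancer=int((acc & sub["cancer_detected"].astype(bool)).sum()),
    )


def triage_summary(table: CohortTable) -> dict:
    """AI normal-triage and safety-net counts with group-denominator percents."""
    masks = _group_masks(table.df)
    return {name: _triage_block(table.df, m) for name, m in masks.items()}


def cohort_summary(table: CohortTable) -> CohortSummary:
    """Complete population summary by study group and overall."""
    masks = _group_masks(table.df)
    return CohortSummary(
        groups={name: _count_block(table.df, m) for name, m in masks.items()},
        triage={name: _triage_block(table.df, m) for name, m in masks.items()},
    )


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Flatten a summary into a tidy frame (one row per group x metric)."""
    rows = []
    for name, blk in summary.groups.items():
        row = {"group": name, "n": blk.n, "consensus_n": blk.consensus,
               "recall_n": blk.recall, "biopsy_n": blk.biopsy,
               "cancers_n": blk.cancers}
        row.update({k: v for k, v in blk.rates().items()})
        tri = summary.triage[name]
        row["normal_tag_n"] = tri.normal
        row["normal_tag_pct"] = 100.0 * tri.normal / blk.n if blk.n else float("nan")
        row["safety_net_triggered_n"] = tri.sn_triggered
        rows.append(row)
    return pd.DataFrame(rows)
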