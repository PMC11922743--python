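"""Deterministic reconstruction of the published study's count structure.

The multicenter German screening implementation study that this package
models published its population and AI-prediction tables as absolute
counts (screened women, consensus conferences, recalls, biopsies,
detected cancers, normal-triage and safety-net cells, per study group).
:func:`reference_cohort` assembles a synthetic record table whose
marginal counts reproduce those published cells exactly, so the crude
descriptive arithmetic (rates per 1,000, PPVs, triage fractions,
automation workload fraction) can be recomputed from an actual table
rather than asserted.

The reconstruction is synthetic: joint distributions beyond the
published margins (e.g., covariates x outcomes) are filled in by a fixed
deterministic block layout and carry no information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import CohortTable

__all__ = ["REFERENCE_COUNTS", "reference_cohort"]


#: published marginal counts per study group
REFERENCE_COUNTS: dict = {
    "ai": {
        "n": 260_739,
        "consensus": 32_341, "recall": 11_603, "biopsy": 2_843, "cancers": 1_679,
        "normal": 154_891, "normal_consensus": 8_032, "normal_recall": 1_905,
        "normal_biopsy": 82, "normal_cancer": 20,
        "sn_triggered": 3_959, "sn_shown": 2_233, "sn_accepted": 1_077,
        "sn_accepted_recall": 541, "sn_accepted_cancer": 204,
        "both_readers_ai": 107_769,
        "dcis": 341, "invasive": 1_308, "other": 30,
        "stage_invasive": {"1": 881, "2": 327, "3": 30, "4": 2, "X": 23, "missing": 45},
        "grade": {"1": 288, "2": 771, "3": 135, "X": 48, "missing": 66},
        "size": {"le10mm": 475, "10to20mm": 572, "gt20mm": 253, "missing": 8},
        "dense": 94_955, "nondense": 165_332, "density_missing": 452,
        "first_round": 43_449,
    },
    "control": {
        "n": 201_079,
        "consensus": 21_996, "recall": 7_727, "biopsy": 1_981, "cancers": 1_202,
        "normal": 107_164, "normal_consensus": 5_454, "normal_recall": 1_162,
        "normal_biopsy": 86, "normal_cancer": 25,
        "sn_triggered": 3_140, "sn_shown": None, "sn_accepted": None,
        "sn_accepted_recall": None, "sn_accepted_cancer": None,
        "both_readers_ai": 0,
        "dcis": 203, "invasive": 981, "other": 18,
        "stage_invasive": {"1": 588, "2": 281, "3": 24, "4": 0, "X": 16, "missing": 72},
        "grade": {"1": 230, "2": 551, "3": 155, "X": 27, "missing": 18},
        "size": {"le10mm": 350, "10to20mm": 418, "gt20mm": 210, "missing": 3},
        "dense": 63_125, "nondense": 137_889, "density_missing": 65,
        "first_round": 35_680,
    },
    "excluded": {"outcome_missing": 666, "cancelled": 610},
}


def _blocks_for_group(c: dict, is_ai: bool) -> list[tuple[int, dict]]:
    """Ordered constant-value blocks along the outcome chain.

    Each block is (row count, column overrides).  Outcome levels:
    cancer > biopsy-only > recall-only > consensus-only > none; within
    each level the published normal-tag and safety-net cells are carved
    out, safety-net rows never overlapping normal-tag rows.
    """
    Y = dict(consensus=1, recall=1, biopsy=1, cancer_detected=1)
    B = dict(consensus=1, recall=1, biopsy=1)
    R = dict(consensus=1, recall=1)
    C = dict(consensus=1)
    sn = dict(safety_net_triggered=1, safety_net_shown=1, safety_net_accepted=1)

    acc_cancer = c["sn_accepted_cancer"] or 0
    acc_recall = c["sn_accepted_recall"] or 0
    acc_total = c["sn_accepted"] or 0
    shown = c["sn_shown"] or 0

    blocks = []
    # cancers
    blocks.append((acc_cancer, {**Y, **sn}))
    blocks.append((c["normal_cancer"], {**Y, "ai_normal_tag": 1}))
    blocks.append((c["cancers"] - acc_cancer - c["normal_cancer"], Y))
    # biopsy without cancer
    b_nc = c["biopsy"] - c["cancers"]
    b_norm = c["normal_biopsy"] - c["normal_cancer"]
    blocks.append((b_norm, {**B, "ai_normal_tag": 1}))
    blocks.append((b_nc - b_norm, B))
    # recall without biopsy
    r_nb = c["recall"] - c["biopsy"]
    r_norm = c["normal_recall"] - c["normal_biopsy"]
    r_acc = acc_recall - acc_cancer
    blocks.append((r_acc, {**R, **sn}))
    blocks.append((r_norm, {**R, "ai_normal_tag": 1}))
    blocks.append((r_nb - r_acc - r_norm, R))
    # consensus without recall
    c_nr = c["consensus"] - c["recall"]
    c_norm = c["normal_consensus"] - c["normal_recall"]
    c_acc = acc_total - acc_recall
    blocks.append((c_acc, {**C, **sn}))
    blocks.append((c_norm, {**C, "ai_normal_tag": 1}))
    blocks.append((c_nr - c_acc - c_norm, C))
    # no consensus
    none_n = c["n"] - c["consensus"]
    shown_rej = shown - acc_total
    trig_unshown = c["sn_triggered"] - shown if is_ai else c["sn_triggered"]
    none_norm = c["normal"] - c["normal_consensus"]
    if is_ai:
        blocks.append((shown_rej, dict(safety_net_triggered=1, safety_net_shown=1,
                                       safety_net_accepted=0)))
        blocks.append((trig_unshown, dict(safety_net_triggered=1, safety_net_shown=0,
                                          safety_net_accepted=0)))
    else:
        blocks.append((trig_unshown, dict(safety_net_triggered=1)))
    blocks.append((none_norm, dict(ai_normal_tag=1)))
    rest = none_n - none_norm - shown_rej - trig_unshown if is_ai else \
        none_n - none_norm - trig_unshown
    blocks.append((rest, {}))
    for n, _ in blocks:
        if n < 0:
            raise ValueError("published counts are internally inconsistent")
    return blocks


def _alloc(counts: dict[str, int]) -> np.ndarray:
    toks, reps = zip(*counts.items())
    return np.repeat(np.array(toks, dtype=object), np.array(reps, dtype=np.int64))


def _group_frame(name: str, c: dict) -> pd.DataFrame:
    is_ai = name == "ai"
    n = c["n"]
    cols = {
        "consensus": np.zeros(n, np.int64), "recall": np.zeros(n, np.int64),
        "biopsy": np.zeros(n, np.int64), "cancer_detected": np.zeros(n, np.int64),
        "ai_normal_tag": np.zeros(n, np.int64),
        "safety_net_triggered": np.zeros(n, np.int64),
        "safety_net_shown": np.zeros(n, np.int64),
        "safety_net_accepted": np.zeros(n, np.int64),
    }
    pos = 0
    for cnt, overrides in _blocks_for_group(c, is_ai):
        for col, val in overrides.items():
            cols[col][pos:pos + cnt] = val
        pos += cnt
    assert pos == n

    det = cols["cancer_detected"].astype(bool)
    n_canc = int(det.sum())
    inv = _alloc({"dcis": c["dcis"], "invasive": c["invasive"], "other": c["other"]})
    assert inv.size == n_canc
    stage = np.empty(n_canc, dtype=object)
    stage[inv == "dcis"] = "0"
    stage[inv == "other"] = "X"
    stage[inv == "invasive"] = _alloc(c["stage_invasive"])
    grade = np.full(n_canc, None, dtype=object)
    size = np.full(n_canc, None, dtype=object)
    grade[inv == "invasive"] = _alloc(c["grade"])
    size[inv == "invasive"] = _alloc(c["size"])

    invasiveness = np.full(n, "none", dtype=object)
    stage_full = np.full(n, None, dtype=object)
    grade_full = np.full(n, None, dtype=object)
    size_full = np.full(n, None, dtype=object)
    idx = np.flatnonzero(det)
    invasiveness[idx], stage_full[idx] = inv, stage
    grade_full[idx], size_full[idx] = grade, size

    # covariates: deterministic fill matching the published margins
    density = _alloc({"dense": c["dense"], "nondense": c["nondense"],
                      "missing": c["density_missing"]})
    srounds = _alloc({"first": c["first_round"], "followup": n - c["first_round"]})
    both = c["both_readers_ai"]
    r1 = np.ones(n, np.int64) if is_ai else np.zeros(n, np.int64)
    r2 = np.zeros(n, np.int64)
    if is_ai:
        r2[:both] = 1

    shown_col = cols["safety_net_shown"].astype(float)
    acc_col = cols["safety_net_accepted"].astype(float)
    if not is_ai:
        shown_col[:] = np.nan
        acc_col[:] = np.nan

    return pd.DataFrame({
        "woman_id": np.char.add(f"{name}-", np.arange(n).astype(str)).astype(object),
        "age_years": pd.array(np.full(n, 58), dtype="Int64"),
        "density_class": density,
        "screening_round": srounds,
        "reader_set_id": np.full(n, "rs-ref", dtype=object),
        "reader1_id": np.full(n, "r-a", dtype=object),
        "reader2_id": np.full(n, "r-b", dtype=object),
        "supervised": np.zeros(n, np.int64),
        "reader1_used_ai": r1,
        "reader2_used_ai": r2,
        "study_group": np.full(n, name, dtype=object),
        "ai_normal_tag": cols["ai_normal_tag"],
        "safety_net_triggered": cols["safety_net_triggered"],
        "safety_net_shown": pd.array(shown_col, dtype="Int64"),
        "safety_net_accepted": pd.array(acc_col, dtype="Int64"),
        "consensus": cols["consensus"],
        "recall": cols["recall"],
        "biopsy": cols["biopsy"],
        "cancer_detected": cols["cancer_detected"],
        "invasiveness": invasiveness,
        "stage": pd.array(stage_full, dtype=object),
        "grade": pd.array(grade_full, dtype=object),
        "size_class": pd.array(size_full, dtype=object),
        "outcome_missing": np.zeros(n, np.int64),
        "cancelled": np.zeros(n, np.int64),
    })


def reference_cohort(include_excluded: bool = False) -> CohortTable:
    """Assemble the reconstructed cohort (461,818 analyzable records).

    With ``include_excluded=True`` the administratively excluded records
    (missing outcome data, cancellations) are appended with their flags
    set, restoring the pre-exclusion total of 463,094.
    """
    frames = [_group_frame(g, REFERENCE_COUNTS[g]) for g in ("ai", "control")]
    if include_excluded:
        exc = REFERENCE_COUNTS["excluded"]
        proto = frames[1].iloc[[0]].copy()
        rows = []
        for kind, cnt in (("outcome_missing", exc["outcome_missing"]),
                          ("cancelled", exc["cancelled"])):
            blk = proto.loc[proto.index.repeat(cnt)].reset_index(drop=True)
            for col in ("consensus", "recall", "biopsy", "cancer_detected"):
                blk[col] = 0
            blk["invasiveness"] = "none"
            blk["stage"] = pd.NA
            blk[kind] = 1
            blk["woman_id"] = [f"{kind}-{i}" for i in range(cnt)]
            rows.append(blk)
        frames += rows
    df = pd.concat(frames, ignore_index=True)
    df["stage"] = df["stage"].where(df["stage"].notna(), pd.NA)
    df["grade"] = df["grade"].where(df["grade"].notna(), pd.NA)
    df["size_class"] = df["size_class"].where(df["size_class"].notna(), pd.NA)
    return CohortTable(df, provenance="simulated")
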