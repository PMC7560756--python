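"""Low-level interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)``. Two intervals
overlap iff they share at least one base, i.e. ``max(starts) < min(ends)``;
abutting intervals ([a,b) and [b,c)) do NOT overlap but ARE coalesced by
:func:`merge_frame` because the union is contiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def merge_frame(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Sort and coalesce intervals per chromosome.

    Intervals whose separation is <= ``gap`` bases are merged (gap=0 merges
    overlapping and abutting intervals only).
    """
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    df = df[INTERVAL_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort")
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if int(s) - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def overlaps_merged(
    query: pd.DataFrame, merged: pd.DataFrame
) -> np.ndarray:
    """Boolean per query interval: does it share >=1 bp with any merged interval?

    ``merged`` must be sorted and non-overlapping per chromosome (the output
    of :func:`merge_frame`). Uses the fact that for disjoint sorted
    intervals the ends are sorted too, so the only candidate is the last
    interval starting before the query end.
    """
    q = query.reset_index(drop=True)
    hits = np.zeros(len(q), dtype=bool)
    if len(q) == 0 or len(merged) == 0:
        return hits
    by_chrom = {c: sub for c, sub in merged.groupby("chrom")}
    for chrom, sub in q.groupby("chrom"):
        reg = by_chrom.get(chrom)
        if reg is None:
            continue
        rs = reg["start"].to_numpy()
        re_ = reg["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        idx = np.searchsorted(rs, qe, side="left") - 1
        ok = idx >= 0
        cand_end = np.where(ok, re_[np.clip(idx, 0, None)], 0)
        hits[sub.index.to_numpy()] = ok & (cand_end > qs)
    return hits


def overlap_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: >=1 bp overlap with any target interval.

    Targets need not be disjoint; they are merged first.
    """
    return overlaps_merged(query.reset_index(drop=True), merge_frame(targets))


def overlap_pairs(
    query: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """All (query_index, target_index) pairs sharing >=1 bp.

    Plain sweep per chromosome; intended for gene/peak-scale inputs.
    Returns a frame with columns ``q`` and ``t`` (positional indices).
    """
    qs_list: list[np.ndarray] = []
    ts_list: list[np.ndarray] = []
    q = query.reset_index(drop=True)
    t = targets.reset_index(drop=True)
    for chrom, tq in q.groupby("chrom"):
        tt = t[t["chrom"] == chrom]
        if len(tt) == 0:
            continue
        t_sorted = tt.sort_values("start")
        t_starts = t_sorted["start"].to_numpy()
        t_ends = t_sorted["end"].to_numpy()
        t_idx = t_sorted.index.to_numpy()
        for qi, q_start, q_end in zip(
            tq.index.to_numpy(), tq["start"].to_numpy(), tq["end"].to_numpy()
        ):
            hi = np.searchsorted(t_starts, q_end, side="left")
            sel = np.flatnonzero(t_ends[:hi] > q_start)
            if sel.size:
                qs_list.append(np.full(sel.size, qi))
                ts_list.append(t_idx[sel])
    if not qs_list:
        return pd.DataFrame({"q": pd.Series(dtype=int), "t": pd.Series(dtype=int)})
    return pd.DataFrame(
        {"q": np.concatenate(qs_list), "t": np.concatenate(ts_list)}
    )
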