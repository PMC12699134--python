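"""Vectorised genomic-interval primitives shared across the pipeline.

All intervals are 0-based half-open ``[start, end)`` on a named chromosome.
The helpers here operate on numpy arrays grouped per chromosome; callers in
higher-level modules handle the chromosome bookkeeping.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "overlap_counts",
    "overlap_any",
    "count_with_min_overlap",
    "midpoint_counts",
    "merge_intervals",
]


def overlap_counts(
    query_starts: np.ndarray,
    query_ends: np.ndarray,
    subj_starts: np.ndarray,
    subj_ends: np.ndarray,
) -> np.ndarray:
    """Number of subject intervals overlapping each query by >= 1 bp.

    Uses the classic complement trick: an interval fails to overlap
    ``[qs, qe)`` iff its start >= qe or its end <= qs, and those two
    conditions are mutually exclusive, so
    ``count = (#starts < qe) - (#ends <= qs)``.
    """
    qs = np.asarray(query_starts, dtype=np.int64)
    qe = np.asarray(query_ends, dtype=np.int64)
    starts = np.sort(np.asarray(subj_starts, dtype=np.int64))
    ends = np.sort(np.asarray(subj_ends, dtype=np.int64))
    n_start_before = np.searchsorted(starts, qe, side="left")
    n_end_before = np.searchsorted(ends, qs, side="right")
    return (n_start_before - n_end_before).astype(np.int64)


def overlap_any(query_starts, query_ends, subj_starts, subj_ends) -> np.ndarray:
    """Boolean: does each query overlap at least one subject interval?"""
    return overlap_counts(query_starts, query_ends, subj_starts, subj_ends) > 0


def count_with_min_overlap(
    query_starts: np.ndarray,
    query_ends: np.ndarray,
    subj_starts: np.ndarray,
    subj_ends: np.ndarray,
    min_overlap: int,
) -> np.ndarray:
    """Per query, number of subjects overlapping by >= ``min_overlap`` bp.

    ``min_overlap=1`` reduces to :func:`overlap_counts`. For larger minima
    the criterion depends on both endpoints of each subject, so candidates
    are sliced by sorted start and checked exactly; subjects of very
    heterogeneous lengths still work because the candidate window is bounded
    by the longest subject.
    """
    if min_overlap <= 1:
        return overlap_counts(query_starts, query_ends, subj_starts, subj_ends)
    qs = np.asarray(query_starts, dtype=np.int64)
    qe = np.asarray(query_ends, dtype=np.int64)
    ss = np.asarray(subj_starts, dtype=np.int64)
    se = np.asarray(subj_ends, dtype=np.int64)
    if ss.size == 0:
        return np.zeros(qs.size, dtype=np.int64)
    order = np.argsort(ss, kind="stable")
    ss, se = ss[order], se[order]
    max_len = int((se - ss).max())
    lo = np.searchsorted(ss, qs - max_len, side="left")
    hi = np.searchsorted(ss, qe, side="left")
    out = np.zeros(qs.size, dtype=np.int64)
    for i in range(qs.size):
        a, b = lo[i], hi[i]
        if a >= b:
            continue
        ov = np.minimum(se[a:b], qe[i]) - np.maximum(ss[a:b], qs[i])
        out[i] = int(np.count_nonzero(ov >= min_overlap))
    return out


def midpoint_counts(
    frag_starts: np.ndarray,
    frag_ends: np.ndarray,
    window_starts: np.ndarray,
    window_ends: np.ndarray,
) -> np.ndarray:
    """Number of fragments whose midpoint falls inside each window."""
    mids = np.sort(
        (np.asarray(frag_starts, np.int64) + np.asarray(frag_ends, np.int64)) // 2
    )
    lo = np.searchsorted(mids, np.asarray(window_starts, np.int64), side="left")
    hi = np.searchsorted(mids, np.asarray(window_ends, np.int64), side="left")
    return (hi - lo).astype(np.int64)


def merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping or book-ended intervals.

    Returns merged (starts, ends, groups) where ``groups[i]`` is the index of
    the merged interval each input interval belongs to (inputs taken in
    coordinate-sorted order internally; group ids refer to input order).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    n = starts.size
    if n == 0:
        return starts, ends, np.zeros(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    groups = np.empty(n, dtype=np.int64)
    m_starts, m_ends = [], []
    cur_s = cur_e = None
    gid = -1
    for idx in order:
        s, e = int(starts[idx]), int(ends[idx])
        if cur_e is None or s > cur_e:  # book-ended (s == cur_e) merges
            gid += 1
            cur_s, cur_e = s, e
            m_starts.append(s)
            m_ends.append(e)
        else:
            cur_e = max(cur_e, e)
            m_ends[gid] = cur_e
        groups[idx] = gid
    return np.array(m_starts, np.int64), np.array(m_ends, np.int64), groups
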