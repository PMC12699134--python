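"""Sliding-window RNA-over-input enrichment peak caller.

The genome is scanned in overlapping windows (default 500 bp, stride
100 bp). Per window the caller records input and RNA fragment counts, an
enrichment ratio and an exact binomial p-value, then merges passing windows
into peaks and applies the published filters: p < 1e-5, log2 enrichment >=
2.5, and a regular-chromosome whitelist.

Statistical choices
-------------------
* Counting assigns each fragment to the windows containing its midpoint
  (``count_mode="midpoint"``). STARR-seq transcribes whole inserts, so a
  fragment that barely clips a window carries no information about it;
  midpoint assignment also keeps the planted-activity estimator unbiased.
  ``count_mode="overlap"`` (>= 1 bp) is available.
* The default test is the conditionally exact binomial: given
  ``t = k_rna + k_in``, under the null ``k_rna ~ Binomial(t, N_rna / (N_rna
  + N_in))``. The plug-in alternative ``P(X >= k_rna | N_rna, k_in/N_in)``
  treats the input proportion as known and becomes anti-conservative at
  high depth because the input has sampling noise of its own; it is kept as
  ``p_method="plugin"``.
* Enrichment ratios are composition-corrected by the median window ratio
  (median-of-ratios, as in RNA-seq size factors): strong planted enhancers
  shift the RNA library's composition, so raw ratios are globally deflated
  by the mean sampling weight; dividing by the genome-wide median restores
  background to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .quantify import FragmentSet

__all__ = ["scan_windows", "call_peaks", "DEFAULT_WHITELIST"]

DEFAULT_WHITELIST = ("1", "2", "3", "4", "5", "6", "7", "8", "9", "10", "X")


def scan_windows(
    input_frags: FragmentSet,
    rna_frags: FragmentSet,
    window_bp: int = 500,
    stride_bp: int = 100,
    min_input: int = 10,
    count_mode: str = "midpoint",
    p_method: str = "conditional",
    normalize: str = "median",
    pseudocount: float = 0.5,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Window statistics table over the whole genome.

    Windows with fewer than ``min_input`` input fragments are retained but
    flagged ``low_input`` (they are never called). Returns columns: chrom,
    start, end, k_input, k_rna, enrichment, log2_enrichment, p_value,
    low_input. ``enrichment`` is composition-corrected unless
    ``normalize="none"``.
    """
    if input_frags.total_fragments == 0 or rna_frags.total_fragments == 0:
        raise ValueError("both libraries must be nonempty")
    chrom_lengths = chrom_lengths or input_frags.chrom_lengths or rna_frags.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths required (FragmentSet.chrom_lengths unset)")

    frames = []
    for chrom, length in chrom_lengths.items():
        if length < window_bp:
            continue  # window larger than chromosome: skip
        starts = np.arange(0, length - window_bp + 1, stride_bp, dtype=np.int64)
        ends = starts + window_bp
        row = dict(chrom=chrom, start=starts, end=ends)
        for key, frags in (("k_input", input_frags), ("k_rna", rna_frags)):
            fs, fe = frags.by_chrom(chrom)
            if count_mode == "midpoint":
                row[key] = intervals.midpoint_counts(fs, fe, starts, ends)
            elif count_mode == "overlap":
                row[key] = intervals.overlap_counts(starts, ends, fs, fe)
            else:
                raise ValueError(f"unknown count_mode {count_mode!r}")
        frames.append(pd.DataFrame(row))
    if not frames:
        raise ValueError("no chromosome is long enough for the requested window")
    win = pd.concat(frames, ignore_index=True)

    k_in = win["k_input"].to_numpy(float)
    k_rna = win["k_rna"].to_numpy(float)
    n_in = float(input_frags.total_fragments)
    n_rna = float(rna_frags.total_fragments)

    needs_pc = (k_in == 0) | (k_rna == 0)
    num = np.where(needs_pc, k_rna + pseudocount, k_rna)
    den = np.where(needs_pc, k_in + pseudocount, k_in)
    ratio = (num / n_rna) / (den / n_in)

    if p_method == "conditional":
        t = (k_in + k_rna).astype(np.int64)
        p0 = n_rna / (n_rna + n_in)
        p = stats.binom.sf(win["k_rna"].to_numpy(np.int64) - 1, t, p0)
        p[t == 0] = 1.0
    elif p_method == "plugin":
        p0 = np.clip(k_in / n_in, 1e-300, 1.0)
        p = stats.binom.sf(win["k_rna"].to_numpy(np.int64) - 1, int(n_rna), p0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    low_input = win["k_input"].to_numpy(np.int64) < min_input
    if normalize == "median":
        usable = ratio[~low_input]
        factor = float(np.median(usable)) if usable.size else 1.0
        factor = factor if factor > 0 else 1.0
    elif normalize == "none":
        factor = 1.0
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    enrichment = ratio / factor

    win["enrichment"] = enrichment
    win["log2_enrichment"] = np.log2(enrichment)
    win["p_value"] = np.clip(p, 0.0, 1.0)
    win["low_input"] = low_input
    win.attrs["normalization_factor"] = factor
    win.attrs["n_input"] = int(n_in)
    win.attrs["n_rna"] = int(n_rna)
    return win


def call_peaks(
    window_stats: pd.DataFrame,
    p_threshold: float = 1e-5,
    log2fc_threshold: float = 2.5,
    chrom_whitelist=DEFAULT_WHITELIST,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Merge passing windows into peaks and apply the published filters.

    ``fc_scale="log2"`` reads the enrichment cutoff as log2 fold change
    (>= 2.5 in log2, i.e. >= 5.7-fold); ``"linear"`` reads it as linear
    enrichment > 2.5. Windows flagged low-input never pass. Overlapping or
    book-ended passing windows merge into one peak whose summit is the
    midpoint of the best-enrichment window and whose statistics come from
    that window. Output is coordinate-sorted with columns: chrom, start,
    end, summit, log2_enrichment, p_value, n_windows, passes_filters.
    """
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    if whitelist is not None and not whitelist:
        raise ValueError("chromosome whitelist is empty")

    if fc_scale == "log2":
        fc_pass = window_stats["log2_enrichment"] >= log2fc_threshold
    elif fc_scale == "linear":
        fc_pass = window_stats["enrichment"] > log2fc_threshold
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    passing = window_stats[
        (window_stats["p_value"] < p_threshold) & fc_pass & ~window_stats["low_input"]
    ]
    if whitelist is not None:
        passing = passing[passing["chrom"].isin(whitelist)]

    peaks = []
    for chrom, sub in passing.groupby("chrom", sort=False):
        ms, me, groups = intervals.merge_intervals(
            sub["start"].to_numpy(), sub["end"].to_numpy()
        )
        sub = sub.reset_index(drop=True)
        for gid in range(ms.size):
            members = sub[groups == gid]
            # best window: max enrichment, ties broken by smaller p then position
            best = members.sort_values(
                ["enrichment", "p_value", "start"], ascending=[False, True, True]
            ).iloc[0]
            peaks.append(
                dict(
                    chrom=chrom,
                    start=int(ms[gid]),
                    end=int(me[gid]),
                    summit=int((best["start"] + best["end"]) // 2),
                    log2_enrichment=float(best["log2_enrichment"]),
                    p_value=float(best["p_value"]),
                    n_windows=int(len(members)),
                    passes_filters=True,
                )
            )
    cols = ["chrom", "start", "end", "summit", "log2_enrichment",
            "p_value", "n_windows", "passes_filters"]
    out = pd.DataFrame(peaks, columns=cols)
    if len(out):
        out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
        out["peak_id"] = [f"peak{i + 1:05d}" for i in range(len(out))]
    else:
        out["peak_id"] = pd.Series(dtype=str)
    return out


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """narrowPeak-style BED6+ output (summit as offset in column 10)."""
    df = peaks.copy()
    df["name"] = df["peak_id"]
    df["score"] = np.clip((df["log2_enrichment"] * 100).round(), 0, 1000).astype(int)
    df["strand"] = "."
    df["signalValue"] = df["log2_enrichment"]
    with np.errstate(divide="ignore"):
        df["pValue"] = -np.log10(np.maximum(df["p_value"], 1e-300))
    df["qValue"] = -1
    df["peak"] = df["summit"] - df["start"]
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "peak"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
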