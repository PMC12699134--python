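"""Fragment counting, depth normalisation and reporter statistics.

STARR-seq activity of a target is the fold change between its
reads-per-million (RPM) abundance in the self-transcribed RNA library and in
the plasmid input library:

    activity_fc = (k_rna * 1e6 / N_rna) / (k_in * 1e6 / N_in)

A pseudocount of 0.5 is added to both raw counts whenever either is zero so
that log2 activity stays finite; targets with too few input fragments are
flagged unquantifiable instead of being reported with a noisy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals

__all__ = [
    "FragmentSet",
    "count_fragments",
    "rpm_normalize",
    "rpkm_normalize",
    "targeted_activity",
    "signal_to_noise",
    "replicate_correlation",
    "reporter_normalize",
    "reporter_correlation",
]


@dataclass
class FragmentSet:
    """A sequenced fragment library (input DNA or reporter RNA).

    ``intervals`` has columns chrom/start/end, 0-based half-open.
    ``chrom_lengths`` is optional but required by genome-wide operations
    (window scanning, replicate correlation).
    """

    library_id: str
    role: str  # "input" | "rna"
    replicate: int
    intervals: pd.DataFrame
    chrom_lengths: dict[str, int] | None = field(default=None)

    def __post_init__(self):
        if self.role not in ("input", "rna"):
            raise ValueError(f"role must be 'input' or 'rna', got {self.role!r}")
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("fragment starts must be < ends")
        if self.chrom_lengths is not None:
            bad = set(iv["chrom"].unique()) - set(self.chrom_lengths)
            if bad:
                raise ValueError(f"fragments on chromosomes absent from genome: {sorted(bad)}")

    @property
    def total_fragments(self) -> int:
        return len(self.intervals)

    def chromosomes(self) -> list[str]:
        if self.chrom_lengths is not None:
            return list(self.chrom_lengths)
        return sorted(self.intervals["chrom"].unique())

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    def to_bed(self, path) -> None:
        from .io import write_bed

        df = self.intervals.copy()
        df["name"] = self.library_id
        write_bed(df, path)


def count_fragments(
    fragments: FragmentSet,
    regions: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """Fragments overlapping each region by >= ``min_overlap_bp`` (default 1 bp).

    A fragment may count toward several regions. Regions on chromosomes not
    present in the fragment library's genome raise an error naming the
    chromosome.
    """
    known = set(fragments.chromosomes())
    out = np.zeros(len(regions), dtype=np.int64)
    for chrom, sub in regions.groupby("chrom", sort=False):
        if chrom not in known:
            raise ValueError(f"region chromosome {chrom!r} not present in fragment library")
        fs, fe = fragments.by_chrom(chrom)
        idx = sub.index.to_numpy()
        pos = np.flatnonzero(regions.index.isin(idx))
        out[pos] = intervals.count_with_min_overlap(
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            fs,
            fe,
            min_overlap_bp,
        )
    return out


def rpm_normalize(counts, library_total: int) -> np.ndarray:
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_total


def rpkm_normalize(counts, library_total: int, region_lengths_bp) -> np.ndarray:
    lens = np.asarray(region_lengths_bp, dtype=float)
    if np.any(lens <= 0):
        raise ValueError("region lengths must be positive")
    return rpm_normalize(counts, library_total) / (lens / 1e3)


def targeted_activity(
    rna_counts,
    input_counts,
    rna_total: int,
    input_total: int,
    target_ids=None,
    min_input_count: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-target activity table (RPM fold change RNA over input).

    Targets whose raw input count falls below ``min_input_count`` are kept in
    the table but flagged ``quantifiable=False``.
    """
    k_rna = np.asarray(rna_counts, dtype=float)
    k_in = np.asarray(input_counts, dtype=float)
    if k_rna.shape != k_in.shape:
        raise ValueError("rna and input count vectors differ in length")
    needs_pc = (k_rna == 0) | (k_in == 0)
    num = np.where(needs_pc, k_rna + pseudocount, k_rna)
    den = np.where(needs_pc, k_in + pseudocount, k_in)
    rpm_rna = rpm_normalize(num, rna_total)
    rpm_in = rpm_normalize(den, input_total)
    fc = rpm_rna / rpm_in
    df = pd.DataFrame(
        dict(
            raw_count_rna=k_rna.astype(np.int64),
            raw_count_input=k_in.astype(np.int64),
            rpm_rna=rpm_normalize(k_rna, rna_total),
            rpm_input=rpm_normalize(k_in, input_total),
            activity_fc=fc,
            activity_log2=np.log2(fc),
            quantifiable=k_in >= min_input_count,
        )
    )
    if target_ids is not None:
        df.insert(0, "target_id", list(target_ids))
    return df


def signal_to_noise(
    activity: pd.DataFrame, positive_ids, negative_ids, id_col: str = "target_id"
) -> pd.DataFrame:
    """Fold change of each positive's activity over the mean negative activity."""
    negative_ids = list(negative_ids)
    if not negative_ids:
        raise ValueError("at least one negative control region is required")
    table = activity.set_index(id_col)
    neg = table.loc[negative_ids, "activity_fc"].to_numpy(float)
    if not np.all(np.isfinite(neg)):
        raise ValueError("negative control activities must be finite")
    noise = float(neg.mean())
    pos = table.loc[list(positive_ids), "activity_fc"].to_numpy(float)
    return pd.DataFrame(
        dict(target_id=list(positive_ids), activity_fc=pos, snr=pos / noise)
    )


def _binned_rpm(frags: FragmentSet, chrom_lengths: dict[str, int], bin_bp: int):
    counts = []
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, length + bin_bp, bin_bp)
        starts, ends = edges[:-1], np.minimum(edges[1:], length)
        fs, fe = frags.by_chrom(chrom)
        counts.append(intervals.overlap_counts(starts, ends, fs, fe))
    counts = np.concatenate(counts)
    return rpm_normalize(counts, frags.total_fragments)


def replicate_correlation(
    frags_a: FragmentSet,
    frags_b: FragmentSet,
    bin_bp: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> float:
    """R^2 of per-bin RPM between two libraries over ``bin_bp`` windows.

    The genome is partitioned into non-overlapping bins; bins with zero
    fragments in both replicates are excluded so that the shared empty tail
    does not dominate the correlation.
    """
    chrom_lengths = chrom_lengths or frags_a.chrom_lengths or frags_b.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths are required (set FragmentSet.chrom_lengths)")
    a = _binned_rpm(frags_a, chrom_lengths, bin_bp)
    b = _binned_rpm(frags_b, chrom_lengths, bin_bp)
    keep = (a > 0) | (b > 0)
    if not keep.any():
        raise ValueError("no bins with signal in either replicate")
    r = stats.pearsonr(a[keep], b[keep]).statistic
    return float(r * r)


def reporter_normalize(
    raw: pd.Series, reference_id: str, background_id: str
) -> pd.Series:
    """Percent-of-reference normalisation with background subtraction.

    ``100 * (raw - background) / (reference - background)`` — the scale used
    to express reporter (GFP/SEAP) output relative to a full-length viral
    promoter/enhancer construct.
    """
    bg = float(raw.loc[background_id])
    ref = float(raw.loc[reference_id])
    if ref <= bg:
        raise ValueError("reference signal must exceed background (degenerate normalization)")
    out = 100.0 * (raw.astype(float) - bg) / (ref - bg)
    out.name = "pct_of_reference"
    return out


def reporter_correlation(table_a: pd.Series, table_b: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided p over construct ids shared by both tables."""
    shared = table_a.index.intersection(table_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared constructs")
    res = stats.pearsonr(table_a.loc[shared], table_b.loc[shared])
    return float(res.statistic), float(res.pvalue)
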