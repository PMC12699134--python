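"""Screen-design utilities: summit tiling, model window datasets, cloning arms.

Tiling fragments a peak into 500 bp tiles centred on the summit with 200 bp
overlap between neighbours (stride 300), labelled -3..-1, summit, +1..+3.
Window datasets cut 249 bp windows at stride 100 around each summit (the
central window plus three on either side), attach a per-window activity
fold change, and split peaks 80/10/10 into train/validation/test with all
windows of one peak kept in the same split.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantify import FragmentSet, count_fragments

__all__ = [
    "tile_peak",
    "prepare_window_dataset",
    "add_cloning_arms",
    "INSERT_5P_ADAPTER",
    "INSERT_3P_ADAPTER",
    "HOMOLOGY_ARM_5P",
    "HOMOLOGY_ARM_3P",
]

log = logging.getLogger(__name__)

# fixed synthesis flanks: vector homology arms + sequencing adapters
HOMOLOGY_ARM_5P = "TAGAGCATGCACCGG"
INSERT_5P_ADAPTER = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
INSERT_3P_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
HOMOLOGY_ARM_3P = "TCGACGAATTCGGCC"


def _seq(genome: dict[str, bytearray], chrom: str, start: int, end: int) -> str:
    return bytes(genome[chrom][start:end]).decode()


def tile_peak(
    peak,
    genome: dict[str, bytearray],
    tile_bp: int = 500,
    overlap_bp: int = 200,
    n_flank: int = 3,
) -> pd.DataFrame:
    """Summit-centred tiles for a targeted screen.

    ``peak`` needs attributes/keys chrom and summit. The summit tile spans
    ``[summit - tile_bp/2, summit + tile_bp/2)``; flanking tiles sit at
    stride ``tile_bp - overlap_bp`` on either side up to ``+/-n_flank``.
    Out-of-bounds tiles are dropped with a warning.
    """
    if tile_bp <= overlap_bp:
        raise ValueError("tile_bp must exceed overlap_bp")
    if isinstance(peak, dict):
        chrom, summit = peak["chrom"], int(peak["summit"])
        peak_id = peak.get("peak_id", "peak")
    else:
        chrom, summit = peak.chrom, int(peak.summit)
        peak_id = getattr(peak, "peak_id", "peak")
    stride = tile_bp - overlap_bp
    chrom_len = len(genome[chrom])
    rows = []
    for k in range(-n_flank, n_flank + 1):
        start = summit - tile_bp // 2 + k * stride
        end = start + tile_bp
        label = "summit" if k == 0 else f"{k:+d}"
        if start < 0 or end > chrom_len:
            log.warning("tile %s of %s out of bounds; dropped", label, peak_id)
            continue
        rows.append(dict(peak_id=peak_id, label=label, chrom=chrom,
                         start=start, end=end, sequence=_seq(genome, chrom, start, end)))
    return pd.DataFrame(rows, columns=["peak_id", "label", "chrom", "start", "end", "sequence"])


def prepare_window_dataset(
    peaks: pd.DataFrame,
    genome: dict[str, bytearray],
    input_frags: FragmentSet,
    rna_frags: FragmentSet,
    window_bp: int = 249,
    stride_bp: int = 100,
    flank_windows: int = 3,
    n_background: int = 0,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Sequence/activity windows for training an activity model.

    Per peak: the central window ``[summit - (window_bp-1)//2, ... )`` (the
    odd length puts the extra base downstream) plus ``flank_windows``
    windows on either side at ``stride_bp``. Window activity is the log2
    RPM fold change of fragments overlapping the window (pseudocount 0.5
    when a count is zero). Optional background windows are drawn uniformly
    from non-peak territory. Peaks (and each background window) are randomly
    assigned whole to train/validation/test at the given proportions.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    rng = np.random.default_rng(seed)
    half = (window_bp - 1) // 2
    rows = []
    for rec in peaks.itertuples():
        chrom_len = len(genome[rec.chrom])
        for k in range(-flank_windows, flank_windows + 1):
            start = int(rec.summit) - half + k * stride_bp
            end = start + window_bp
            if start < 0 or end > chrom_len:
                log.warning("window %+d of %s out of bounds; dropped", k, rec.peak_id)
                continue
            rows.append(dict(peak_id=rec.peak_id, offset_index=k, chrom=rec.chrom,
                             start=start, end=end))
    if n_background:
        chroms = list(genome)
        peak_by_chrom = {c: sub for c, sub in peaks.groupby("chrom")}
        placed = 0
        while placed < n_background:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(genome[chrom]) - window_bp))
            end = start + window_bp
            sub = peak_by_chrom.get(chrom)
            if sub is not None and bool(
                ((sub["start"] - 1_000 < end) & (sub["end"] + 1_000 > start)).any()
            ):
                continue
            placed += 1
            rows.append(dict(peak_id=f"background{placed:05d}", offset_index=0,
                             chrom=chrom, start=start, end=end))
    df = pd.DataFrame(rows)
    if not len(df):
        return df

    regions = df[["chrom", "start", "end"]]
    k_in = count_fragments(input_frags, regions)
    k_rna = count_fragments(rna_frags, regions)
    needs_pc = (k_in == 0) | (k_rna == 0)
    num = np.where(needs_pc, k_rna + 0.5, k_rna)
    den = np.where(needs_pc, k_in + 0.5, k_in)
    fc = (num / rna_frags.total_fragments) / (den / input_frags.total_fragments)
    df["activity_log2"] = np.log2(fc)
    df["sequence"] = [
        _seq(genome, c, s, e) for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]

    # grouped random split: every window of a peak shares its split
    ids = df["peak_id"].unique()
    order = rng.permutation(len(ids))
    n_train = int(round(split[0] * len(ids)))
    n_val = int(round(split[1] * len(ids)))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            assignment[ids[idx]] = "train"
        elif rank < n_train + n_val:
            assignment[ids[idx]] = "validation"
        else:
            assignment[ids[idx]] = "test"
    df["split"] = df["peak_id"].map(assignment)
    return df


def add_cloning_arms(insert_sequence: str) -> str:
    """Synthesis-ready construct: homology arms + adapters around the insert.

    Output is ``5' arm + 5' adapter + insert + 3' adapter + 3' arm``,
    bit-exact fixed flanks.
    """
    if not insert_sequence:
        raise ValueError("insert sequence is empty")
    if set(insert_sequence.upper()) - set("ACGT"):
        raise ValueError("insert must contain only A/C/G/T")
    return (HOMOLOGY_ARM_5P + INSERT_5P_ADAPTER + insert_sequence
            + INSERT_3P_ADAPTER + HOMOLOGY_ARM_3P)
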