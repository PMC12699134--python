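"""PWM scanning with exact p-values, motif enrichment, and YY1 analyses.

Scanning scores every position of both strands with a log-odds matrix and
converts scores to p-values using the *exact* null distribution of the
score under a 0-order background model. Scores are discretised to a fixed
resolution (default 1e-3 log2 units) and the distribution of the integer
score sum is obtained by dynamic programming over motif positions — the
same construction FIMO uses — so the p-value of a score equals the tail sum
of that distribution exactly (up to the discretisation).

The module also carries the downstream motif analyses: shifted-background
construction, presence/absence enrichment with Fisher's exact test, YY1
motif-dosage statistics, and YY1 core mutagenesis (ATGG -> CTCG) for
reporter construct design.

MEME minimal files are read by a parser in this module: the probability
matrix is consumed at full printed precision, which the exact p-value
machinery requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals
from .quantify import FragmentSet, count_fragments

__all__ = [
    "PWMModel",
    "read_meme",
    "write_meme",
    "load_bundled_motifs",
    "scan_pwm",
    "dedup_hits",
    "shift_background",
    "motif_enrichment",
    "yy1_dosage",
    "mutate_yy1",
    "select_mutagenesis_candidates",
]

_ALPHABET = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_TABLE = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")

YY1_CORE_WT = "ATGG"
YY1_CORE_MUT = "CTCG"


def revcomp(seq: str) -> str:
    return seq.encode().translate(_RC_TABLE)[::-1].decode()


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class PWMModel:
    """Position weight matrix with exact score-distribution p-values.

    ``probs`` is a (width, 4) matrix of per-position base probabilities in
    ACGT order; columns sum to 1. Log-odds are computed against the 0-order
    ``background`` after adding ``pseudocount * background`` to each
    probability (FIMO's convention), in log2 units.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = None
    pseudocount: float = 0.1
    resolution: float = 1e-3

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("probability columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        adj = (self.probs + self.pseudocount * self.background) / (1.0 + self.pseudocount)
        self.log_odds = np.log2(adj / self.background)
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds not finite; increase pseudocount")
        self.int_scores = np.round(self.log_odds / self.resolution).astype(np.int64)
        self._dist_cache = None

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    @property
    def core_offset(self) -> int:
        """Offset of the conserved YY1 'ATGG' core within the consensus."""
        off = self.consensus.find(YY1_CORE_WT)
        if off < 0:
            raise ValueError(f"motif {self.motif_id}: consensus lacks an {YY1_CORE_WT} core")
        return off

    # -- exact null distribution ------------------------------------------

    def score_distribution(self) -> tuple[int, np.ndarray, np.ndarray]:
        """(min_sum, pmf, tail) of the integer score under the background.

        ``tail[s - min_sum] = P(S >= s)``, computed by convolving the
        per-position score distributions (dynamic programming over the
        integer score lattice).
        """
        if self._dist_cache is not None:
            return self._dist_cache
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(self.width):
            s_j = self.int_scores[j]
            new_lo = cur_lo + int(s_j.min())
            new_hi = cur_lo + cur.size - 1 + int(s_j.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                off = cur_lo + int(s_j[b]) - new_lo
                new[off : off + cur.size] += self.background[b] * cur
            cur, cur_lo = new, new_lo
        pmf = cur
        tail = np.cumsum(pmf[::-1])[::-1]
        self._dist_cache = (cur_lo, pmf, tail)
        return self._dist_cache

    def pvalue(self, score: float) -> float:
        """Exact tail p-value P(S >= score) of a log2 log-odds score."""
        lo, _pmf, tail = self.score_distribution()
        s = int(round(score / self.resolution))
        idx = s - lo
        if idx < 0:
            return 1.0
        if idx >= tail.size:
            return 0.0
        return float(tail[idx])

    def min_score_for_p(self, p_threshold: float) -> int:
        """Smallest integer score whose exact p-value is < p_threshold."""
        lo, _pmf, tail = self.score_distribution()
        idx = np.searchsorted(-tail, -p_threshold, side="right")
        while idx < tail.size and tail[idx] >= p_threshold:
            idx += 1
        if idx >= tail.size:
            return lo + tail.size - 1
        return lo + int(idx)

    def reverse_complement_matrix(self) -> np.ndarray:
        return self.int_scores[::-1, ::-1]


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme(path_or_handle) -> list[PWMModel]:
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    motifs: list[PWMModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freqs = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freqs.get(b, 0.25) for b in _ALPHABET])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(v) for v in lines[i + j].split()])
            i += w
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)  # absorb printing round-off
            motifs.append(PWMModel(name, probs, background=background))
        i += 1
    return motifs


def write_meme(motifs: list[PWMModel], path) -> None:
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
           "Background letter frequencies"]
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    out.append(" ".join(f"{b} {f:.6f}" for b, f in zip(_ALPHABET, bg)))
    for m in motifs:
        out += ["", f"MOTIF {m.motif_id}",
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0"]
        for row in m.probs:
            out.append(" ".join(f"{v:.6f}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def load_bundled_motifs() -> list[PWMModel]:
    """The package's minimal PWM set (a YY1-like and an ETS-like motif).

    These are synthetic matrices built around the factors' conserved cores
    (YY1: ATGG; ETS: GGAA); any MEME-format motif library can be supplied
    in their place.
    """
    ref = resources.files("starrmap").joinpath("data/motifs/core_motifs.meme")
    with ref.open() as fh:
        return read_meme(fh)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    w = int_matrix.shape[0]
    L = codes.size - w + 1
    scores = np.zeros(L, dtype=np.int64)
    safe = np.where(codes < 0, 0, codes)
    for j in range(w):
        scores += int_matrix[j, safe[j : j + L]]
    return scores


def scan_pwm(
    sequences: dict[str, str],
    pwm: PWMModel,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """All motif instances with exact p-value < ``p_threshold``, both strands.

    Positions containing N are skipped. When the two strands produce hits at
    the same start, only the better-scoring one is reported. Returns
    columns: sequence_id, start, strand, score, p_value.
    """
    lo, _pmf, tail = pwm.score_distribution()
    min_int = pwm.min_score_for_p(p_threshold)
    rc_matrix = pwm.reverse_complement_matrix()
    rows = []
    for seq_id, seq in sequences.items():
        if len(seq) < pwm.width:
            continue
        codes = _encode(seq)
        w = pwm.width
        L = codes.size - w + 1
        has_n = np.convolve((codes < 0).astype(np.int64), np.ones(w, dtype=np.int64), "valid") > 0
        fwd = _window_scores(codes, pwm.int_scores)
        rev = _window_scores(codes, rc_matrix)
        for strand, sc in (("+", fwd), ("-", rev)):
            ok = (sc >= min_int) & ~has_n
            for pos in np.flatnonzero(ok):
                s = int(sc[pos])
                rows.append(
                    (seq_id, int(pos), strand, s * pwm.resolution, float(tail[s - lo]))
                )
    hits = pd.DataFrame(rows, columns=["sequence_id", "start", "strand", "score", "p_value"])
    if len(hits):
        # same-position opposite-strand duplicates: keep the better score
        hits = (
            hits.sort_values("score", ascending=False)
            .drop_duplicates(["sequence_id", "start"], keep="first")
            .sort_values(["sequence_id", "start"])
            .reset_index(drop=True)
        )
    return hits


def dedup_hits(hits: pd.DataFrame, width: int) -> pd.DataFrame:
    """Collapse overlapping hits of one motif greedily by score."""
    if not len(hits):
        return hits
    kept = []
    for seq_id, sub in hits.groupby("sequence_id", sort=False):
        sub = sub.sort_values("score", ascending=False)
        taken: list[tuple[int, int]] = []
        for row in sub.itertuples():
            s, e = row.start, row.start + width
            if any(s < te and e > ts for ts, te in taken):
                continue
            taken.append((s, e))
            kept.append(row.Index)
    return hits.loc[sorted(kept)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# backgrounds + enrichment
# ---------------------------------------------------------------------------

def shift_background(
    peak_calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    shift_bp: int = 10_000,
    avoid: pd.DataFrame | None = None,
    input_frags: FragmentSet | None = None,
    min_input: int = 10,
) -> pd.DataFrame:
    """Peak coordinates shifted +``shift_bp``, filtered to clean background.

    Shifted regions are removed when they run past the chromosome end,
    overlap any region in ``avoid`` (typically the retained peak set), or
    have fewer than ``min_input`` input fragments (poor input coverage).
    """
    bg = peak_calls[["chrom", "start", "end"]].copy()
    bg["start"] = bg["start"] + shift_bp
    bg["end"] = bg["end"] + shift_bp
    limit = bg["chrom"].map(chrom_lengths)
    bg = bg[bg["end"] <= limit].reset_index(drop=True)
    if avoid is not None and len(avoid) and len(bg):
        drop = np.zeros(len(bg), dtype=bool)
        for chrom, sub in bg.groupby("chrom"):
            av = avoid[avoid["chrom"] == chrom]
            hit = intervals.overlap_any(
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                av["start"].to_numpy(), av["end"].to_numpy(),
            )
            drop[sub.index.to_numpy()] = hit
        bg = bg[~drop].reset_index(drop=True)
    if input_frags is not None and len(bg):
        cov = count_fragments(input_frags, bg)
        bg = bg[cov >= min_input].reset_index(drop=True)
    return bg


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWMModel],
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-motif presence enrichment of targets over background.

    A sequence "has" a motif iff it carries >= 1 hit at the scan threshold.
    Fold is the ratio of presence percentages (0.5 added to every cell of
    the 2x2 table when any cell is zero); p is a one-sided Fisher's exact
    test, with Benjamini-Hochberg correction across motifs.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must both be nonempty")
    n_t, n_b = len(target_seqs), len(background_seqs)
    rows = []
    for pwm in pwms:
        t_hit = scan_pwm(target_seqs, pwm, p_threshold)
        b_hit = scan_pwm(background_seqs, pwm, p_threshold)
        k_t = t_hit["sequence_id"].nunique() if len(t_hit) else 0
        k_b = b_hit["sequence_id"].nunique() if len(b_hit) else 0
        table = np.array([[k_t, n_t - k_t], [k_b, n_b - k_b]], dtype=float)
        if (table == 0).any():
            fold_table = table + 0.5
        else:
            fold_table = table
        pct_t = 100.0 * k_t / n_t
        pct_b = 100.0 * k_b / n_b
        fold = (fold_table[0, 0] / fold_table[0].sum()) / (
            fold_table[1, 0] / fold_table[1].sum()
        )
        _odds, p = stats.fisher_exact(table.astype(int), alternative="greater")
        rows.append(
            dict(motif_id=pwm.motif_id, n_target=k_t, n_background=k_b,
                 pct_target=pct_t, pct_background=pct_b, fold=fold, p_value=float(p))
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# YY1 dosage + mutagenesis
# ---------------------------------------------------------------------------

def yy1_dosage(
    activity_log2: np.ndarray,
    motif_counts: np.ndarray,
    cap: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Activity by motif-count bin (0,1,...,cap-1,'cap+') plus trend stats.

    Returns (bin table, stats) where stats holds the one-way ANOVA p across
    bins and the least-squares slope of activity on the capped count. With
    all counts in one bin no trend is computed (slope NaN).
    """
    a = np.asarray(activity_log2, dtype=float)
    c = np.minimum(np.asarray(motif_counts, dtype=np.int64), cap)
    labels = [str(i) for i in range(cap)] + [f"{cap}+"]
    rows = []
    groups = []
    for i in range(cap + 1):
        vals = a[c == i]
        rows.append(
            dict(bin=labels[i], n=int(vals.size),
                 mean_activity=float(vals.mean()) if vals.size else np.nan,
                 median_activity=float(np.median(vals)) if vals.size else np.nan)
        )
        if vals.size >= 2:
            groups.append(vals)
    table = pd.DataFrame(rows)
    info: dict = {"anova_p": np.nan, "slope": np.nan, "slope_p": np.nan}
    if len(groups) >= 2:
        info["anova_p"] = float(stats.f_oneway(*groups).pvalue)
    if np.unique(c).size >= 2:
        res = stats.linregress(c.astype(float), a)
        info["slope"] = float(res.slope)
        info["slope_p"] = float(res.pvalue)
    return table, info


def mutate_yy1(sequence: str, hits: pd.DataFrame, pwm: PWMModel) -> tuple[str, pd.DataFrame]:
    """Disrupt each YY1 hit by writing CTCG over its conserved ATGG core slot.

    The edit is positional: the four conserved core positions of the motif
    model (where the consensus reads ATGG) are replaced, in the hit's
    orientation, by CTCG — so a plus-strand hit's ATGG becomes CTCG and a
    minus-strand hit's genomic CCAT becomes CGAG. The replacement disrupts
    the motif even for degenerate matches whose core deviates from ATGG.
    Sequence length never changes; the log records each edit. A motif model
    whose consensus lacks the ATGG core raises (PWM/core mismatch).
    """
    seq = bytearray(sequence.encode())
    core = pwm.core_offset  # raises if the PWM has no ATGG core
    w = pwm.width
    log = []
    for row in hits.itertuples():
        if row.strand == "+":
            mut = YY1_CORE_MUT
            pos = row.start + core
        else:
            mut = revcomp(YY1_CORE_MUT)
            pos = row.start + (w - core - len(YY1_CORE_WT))
        wt = seq[pos : pos + 4].decode()
        log.append(dict(start=int(row.start), strand=row.strand,
                        core_position=int(pos), wt=wt, mut=mut))
        seq[pos : pos + 4] = mut.encode()
    return seq.decode(), pd.DataFrame(log, columns=["start", "strand", "core_position", "wt", "mut"])


def select_mutagenesis_candidates(
    enhancers: pd.DataFrame,
    pwm: PWMModel,
    top_n: int = 50,
    min_hits: int = 2,
    pad_bp: int = 10,
    p_threshold: float = 1e-4,
    max_rounds: int = 5,
) -> pd.DataFrame:
    """Wild-type/mutant design pairs for the most active YY1-rich peaks.

    ``enhancers`` needs columns enhancer_id, activity_log2, sequence. Peaks
    with >= ``min_hits`` deduplicated YY1 hits are ranked by activity and
    the top ``top_n`` kept (all of them, with a warning, if fewer qualify).
    Each design is trimmed to the minimal window covering every hit plus
    ``pad_bp`` of padding; mutation is applied and re-scanned until the
    mutant carries no hit at the scan threshold.
    """
    rows = []
    for rec in enhancers.itertuples():
        hits = scan_pwm({rec.enhancer_id: rec.sequence}, pwm, p_threshold)
        hits = dedup_hits(hits, pwm.width)
        if len(hits) < min_hits:
            continue
        lo = max(0, int(hits["start"].min()) - pad_bp)
        hi = min(len(rec.sequence), int(hits["start"].max()) + pwm.width + pad_bp)
        rows.append(dict(enhancer_id=rec.enhancer_id, activity_log2=rec.activity_log2,
                         n_yy1_hits=len(hits), window_start=lo, window_end=hi,
                         wt_sequence=rec.sequence[lo:hi]))
    if len(rows) < top_n:
        warnings.warn(
            f"only {len(rows)} peaks qualify (requested top {top_n}); emitting all",
            stacklevel=2,
        )
    rows.sort(key=lambda r: -r["activity_log2"])
    rows = rows[:top_n]
    for r in rows:
        mut = r["wt_sequence"]
        for _ in range(max_rounds):
            hits = dedup_hits(scan_pwm({"x": mut}, pwm, p_threshold), pwm.width)
            if not len(hits):
                break
            mut, _log = mutate_yy1(mut, hits, pwm)
        r["mut_sequence"] = mut
    return pd.DataFrame(
        rows,
        columns=["enhancer_id", "activity_log2", "n_yy1_hits",
                 "window_start", "window_end", "wt_sequence", "mut_sequence"],
    )
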