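"""Synthetic STARR-seq study generator.

Builds a small multi-chromosome genome with planted enhancers and emits the
full set of inputs the analysis consumes: input/RNA fragment libraries,
chromatin peak tracks, a gene model, expression and tissue-specificity
tables, plus the ground truth needed for parameter-recovery checks.

The generative model
--------------------
* Enhancer log2 activities are uniform over a configurable range whose
  default spans roughly six- to 117-fold RNA:input enrichment.
* The RNA library is drawn from the input fragment distribution by rejection
  sampling: a candidate fragment that overlaps a planted enhancer by at
  least ``min(250 bp, half the enhancer length)`` is accepted with relative
  weight ``2**activity``; all other candidates have weight 1. The plasmid
  assay transcribes whole inserts, so substantial overlap — not a single
  base — is what couples a fragment to an enhancer.
* YY1 motif instances are embedded with a count that rises linearly with
  activity (floor of the activity quantile times ``yy1_dosage_max``); ETS
  instances mark accessible enhancers.
* Roughly half the enhancers are "accessible" (they receive matching
  ATAC/H3K27ac peaks and a nearby H3K4me1 peak) and are preferentially
  placed TSS-proximal; "masked" enhancers are placed away from TSSs and get
  no active-chromatin marks.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GeneModel
from .quantify import FragmentSet

__all__ = [
    "SimConfig",
    "simulate_genome",
    "plant_enhancers",
    "simulate_fragments",
    "simulate_chromatin",
    "simulate_expression_and_tissue",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
ENHANCER_MIN_GAP = 2_000  # bp kept free between planted enhancers (keeps peaks resolvable)

TISSUE_SPECIFIC_LABELS = ("Tissue enhanced", "Tissue enriched", "Group enriched")
TISSUE_UBIQUITOUS_LABEL = "Low tissue specificity"


@dataclass
class SimConfig:
    seed: int = 0
    chromosome_names: tuple[str, ...] = ("1", "2", "scaffold_1")
    chromosome_length_bp: int = 500_000
    # enhancers are planted on regular chromosomes only; the scaffold stays
    # enhancer-free and exercises the chromosome whitelist downstream
    enhancer_chromosomes: tuple[str, ...] = ("1", "2")
    n_enhancers: int = 200
    activity_log2_range: tuple[float, float] = (2.6, 6.9)
    enhancer_length_bp: int = 500
    accessible_fraction: float = 0.49
    tss_proximal_fraction_accessible: float = 0.5
    yy1_dosage_max: int = 5
    ets_count_accessible: int = 2
    ets_count_masked: int = 0
    fragment_length_mean_bp: float = 800.0
    fragment_length_sd_bp: float = 50.0
    fragment_length_bounds_bp: tuple[int, int] = (100, 1500)
    n_input_fragments: int = 1_000_000
    n_rna_fragments: int = 1_000_000
    n_replicates: int = 2
    n_genes: int = 90
    n_decoy_peaks: int = 500
    h3k9me3_masked_probability: float = 0.3
    tissue_purity: float = 0.9
    expression_base_log2_tpm: float = 3.0
    expression_effect_log2: float = 3.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_names)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosome_names}

    def validate(self) -> None:
        lo, hi = self.activity_log2_range
        if not (lo >= 0 and lo < hi):
            raise ValueError("activity_log2_range must satisfy 0 <= low < high")
        if not 0.0 <= self.accessible_fraction <= 1.0:
            raise ValueError("accessible_fraction must be in [0, 1]")
        for name in ("chromosome_length_bp", "enhancer_length_bp", "n_input_fragments",
                     "n_rna_fragments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not set(self.enhancer_chromosomes) <= set(self.chromosome_names):
            raise ValueError("enhancer_chromosomes must be a subset of chromosome_names")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# genome + gene model
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict[str, bytearray], GeneModel]:
    """Random background genome plus a non-overlapping gene model."""
    config.validate()
    rng = _rng(config, 0)
    genome: dict[str, bytearray] = {}
    probs = np.asarray(config.base_composition, dtype=float)
    for chrom in config.chromosome_names:
        codes = rng.choice(4, size=config.chromosome_length_bp, p=probs)
        genome[chrom] = bytearray(_BASES[codes].tobytes())

    # genes: split across chromosomes, one gene per equally sized slot so
    # that placements can never overlap
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    margin = 5_000
    genes, exons = [], []
    gid = 0
    for chrom, n in zip(config.chromosome_names, per_chrom):
        if n == 0:
            continue
        usable = config.chromosome_length_bp - 2 * margin
        slot = usable // n
        if slot < 12_000:
            raise ValueError(
                f"chromosome {chrom!r} too short for {n} genes "
                f"(need >= {2 * margin + n * 12_000} bp)"
            )
        for i in range(n):
            gid += 1
            gene_id = f"g{gid:04d}"
            length = int(rng.integers(2_000, 8_001))
            lo = margin + i * slot
            start = int(rng.integers(lo, lo + slot - length))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            tts = end - 1 if strand == "+" else start
            gene_exons = _make_exons(rng, start, end)
            utr5 = int(rng.integers(100, 301))
            utr3 = int(rng.integers(100, 301))
            cds_start = _offset_in_exons(gene_exons, utr5 if strand == "+" else utr3)
            cds_end = _offset_in_exons_rev(gene_exons, utr3 if strand == "+" else utr5)
            genes.append(
                dict(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
                     tss=tss, tts=tts, cds_start=cds_start, cds_end=cds_end)
            )
            for es, ee in gene_exons:
                exons.append(dict(gene_id=gene_id, chrom=chrom, start=es, end=ee))
    return genome, GeneModel(pd.DataFrame(genes), pd.DataFrame(exons))


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _make_exons(rng, start: int, end: int) -> list[tuple[int, int]]:
    """2-3 exons spanning [start, end) with introns in between."""
    length = end - start
    k = int(rng.integers(2, 4))
    # allocate exon/intron lengths proportionally, min 200 bp each block
    n_blocks = 2 * k - 1
    raw = rng.random(n_blocks) + 0.2
    sizes = np.maximum((raw / raw.sum() * length).astype(int), 200)
    sizes[-1] = length - int(sizes[:-1].sum())
    if sizes[-1] < 200:  # fall back to a single split
        half = length // 2
        sizes = np.array([half - 150, 300, length - half - 150])
    pos = start
    exons = []
    for i, sz in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(sz)))
        pos += int(sz)
    exons[-1] = (exons[-1][0], end)
    return exons


def _offset_in_exons(exons, offset: int) -> int:
    for es, ee in exons:
        if offset < ee - es:
            return es + offset
        offset -= ee - es
    return exons[-1][1]


def _offset_in_exons_rev(exons, offset: int) -> int:
    for es, ee in reversed(exons):
        if offset < ee - es:
            return ee - offset
        offset -= ee - es
    return exons[0][0]


# ---------------------------------------------------------------------------
# enhancer planting
# ---------------------------------------------------------------------------

_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: bytes) -> bytes:
    return s.translate(_RC)[::-1]


def plant_enhancers(
    genome: dict[str, bytearray],
    gene_model: GeneModel,
    config: SimConfig,
) -> pd.DataFrame:
    """Plant enhancers and motif instances; returns the truth table.

    The genome is mutated in place so that every recorded motif instance is
    literally present in the emitted sequence. Accessible enhancers are
    assigned first (exact count ``round(accessible_fraction * n)``) and a
    configurable fraction of them is placed within +/-500 bp of a TSS.
    """
    config.validate()
    from .motifs import load_bundled_motifs

    rng = _rng(config, 1)
    pwms = {m.motif_id: m for m in load_bundled_motifs()}
    yy1, ets = pwms["YY1_syn"], pwms["ETS_syn"]
    length = config.enhancer_length_bp
    if max(yy1.width, ets.width) > length:
        raise ValueError("motif wider than the enhancer length")
    lo, hi = config.activity_log2_range

    n = config.n_enhancers
    n_acc = int(round(config.accessible_fraction * n))
    accessible = np.zeros(n, dtype=bool)
    accessible[:n_acc] = True
    n_prox = int(round(config.tss_proximal_fraction_accessible * n_acc))

    genes = gene_model.genes
    cand_genes = genes[genes["chrom"].isin(config.enhancer_chromosomes)]
    tss_by_chrom = {
        c: np.sort(sub["tss"].to_numpy(np.int64))
        for c, sub in genes.groupby("chrom")
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chromosome_names}
    margin = 2_000
    chroms = list(config.enhancer_chromosomes)

    def conflicts(chrom, start, end) -> bool:
        for s, e in occupied[chrom]:
            if start < e + ENHANCER_MIN_GAP and end > s - ENHANCER_MIN_GAP:
                return True
        return False

    def near_tss(chrom, mid, radius) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            return False
        i = np.searchsorted(tss, mid)
        for j in (i - 1, i):
            if 0 <= j < tss.size and abs(int(tss[j]) - mid) <= radius:
                return True
        return False

    records = []
    prox_gene_order = cand_genes.sample(frac=1.0, random_state=int(rng.integers(2**31))) \
        if len(cand_genes) else cand_genes
    prox_iter = iter(prox_gene_order.itertuples())
    placed_prox = 0
    for idx in range(n):
        want_prox = accessible[idx] and placed_prox < n_prox
        start = None
        for _ in range(200):
            if want_prox:
                try:
                    g = next(prox_iter)
                except StopIteration:
                    want_prox = False
                    continue
                mid = int(g.tss) + int(rng.integers(-500, 501))
                chrom = g.chrom
                s = mid - length // 2
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(margin, config.chromosome_length_bp - margin - length))
            e = s + length
            if s < margin or e > config.chromosome_length_bp - margin:
                continue
            if conflicts(chrom, s, e):
                continue
            if not accessible[idx] and near_tss(chrom, (s + e) // 2, 1_000):
                continue  # masked enhancers stay TSS-distal
            start = s
            break
        if start is None:
            raise ValueError(
                "could not place all enhancers; genome too short for "
                f"{n} x {length} bp enhancers"
            )
        if want_prox:
            placed_prox += 1
        end = start + length
        occupied[chrom].append((start, end))

        activity = float(rng.uniform(lo, hi))
        q = (activity - lo) / (hi - lo)
        n_yy1 = min(int(math.floor(q * config.yy1_dosage_max)), config.yy1_dosage_max)
        n_ets = config.ets_count_accessible if accessible[idx] else config.ets_count_masked

        inst = [(yy1.consensus, "yy1")] * n_yy1 + [(ets.consensus, "ets")] * n_ets
        _embed_motifs(genome[chrom], start, end, inst, rng)

        mid = (start + end) // 2
        nearest = _nearest_gene(genes, chrom, mid)
        records.append(
            dict(
                enhancer_id=f"enh{idx + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                true_log2_activity=activity,
                n_yy1_motifs=n_yy1,
                n_ets_motifs=n_ets,
                accessible=bool(accessible[idx]),
                nearest_gene_id=nearest,
                tissue_class="",
            )
        )
    truth = pd.DataFrame(records)
    if len(truth):
        truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    return truth


def _embed_motifs(seq: bytearray, start: int, end: int, instances, rng) -> None:
    """Write motif consensus instances at spaced positions inside [start, end)."""
    if not instances:
        return
    k = len(instances)
    span = end - start
    slot = span // k
    for i, (consensus, _kind) in enumerate(instances):
        w = len(consensus)
        if slot <= w:
            raise ValueError("too many motif instances for enhancer length")
        off = start + i * slot + int(rng.integers(0, slot - w))
        word = consensus.encode()
        if rng.random() < 0.5:
            word = _revcomp(word)
        seq[off : off + w] = word


def _nearest_gene(genes: pd.DataFrame, chrom: str, pos: int) -> str:
    sub = genes[genes["chrom"] == chrom]
    if not len(sub):
        return ""
    d = (sub["tss"] - pos).abs()
    return str(sub.loc[d.idxmin(), "gene_id"])


# ---------------------------------------------------------------------------
# fragment libraries
# ---------------------------------------------------------------------------

def simulate_fragments(
    genome: dict[str, bytearray],
    truth: pd.DataFrame,
    config: SimConfig,
    replicate_seed: int,
    replicate: int = 1,
) -> tuple[FragmentSet, FragmentSet]:
    """One replicate's input and RNA fragment libraries.

    Input fragments start uniformly over the genome with Normal lengths
    clipped to the configured bounds. RNA fragments are rejection-sampled
    from that same distribution with weight ``2**activity`` for candidates
    overlapping an enhancer by at least ``min(250, enhancer_length / 2)`` bp.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(replicate_seed), 2]))
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total_len = int(cum[-1])

    enh = _enhancer_weight_tables(truth, names, config)

    def draw(n: int):
        g = rng.integers(0, total_len, size=n)
        ci = np.searchsorted(cum, g, side="right") - 1
        start = g - cum[ci]
        ln = rng.normal(config.fragment_length_mean_bp, config.fragment_length_sd_bp, size=n)
        lo_b, hi_b = config.fragment_length_bounds_bp
        ln = np.clip(np.round(ln), lo_b, hi_b).astype(np.int64)
        end = np.minimum(start + ln, lengths[ci])
        return ci, start.astype(np.int64), end

    # input library
    ci, fs, fe = draw(config.n_input_fragments)
    input_df = pd.DataFrame(
        dict(chrom=np.array(names, dtype=object)[ci], start=fs, end=fe)
    )

    # RNA library by batched rejection sampling; the acceptance bound is the
    # largest planted weight (1 when no enhancers exist)
    w_max = 2.0 ** float(truth["true_log2_activity"].max()) if len(truth) else 1.0
    need = config.n_rna_fragments
    kept_c, kept_s, kept_e = [], [], []
    got = 0
    batch = max(200_000, min(4_000_000, need))
    while got < need:
        ci, fs, fe = draw(batch)
        w = _fragment_weights(ci, fs, fe, enh)
        acc = rng.random(batch) * w_max < w
        kept_c.append(ci[acc])
        kept_s.append(fs[acc])
        kept_e.append(fe[acc])
        got += int(acc.sum())
    ci = np.concatenate(kept_c)[:need]
    fs = np.concatenate(kept_s)[:need]
    fe = np.concatenate(kept_e)[:need]
    rna_df = pd.DataFrame(dict(chrom=np.array(names, dtype=object)[ci], start=fs, end=fe))

    mk = lambda role, df: FragmentSet(
        library_id=f"{role}_rep{replicate}",
        role=role,
        replicate=replicate,
        intervals=df,
        chrom_lengths=chrom_lengths,
    )
    return mk("input", input_df), mk("rna", rna_df)


def _enhancer_weight_tables(truth: pd.DataFrame, names: list[str], config: SimConfig):
    ov_min = min(250, int(math.ceil(config.enhancer_length_bp / 2)))
    tables = {}
    for i, chrom in enumerate(names):
        sub = truth[truth["chrom"] == chrom] if len(truth) else truth
        if sub is None or not len(sub):
            tables[i] = None
            continue
        sub = sub.sort_values("start")
        tables[i] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            2.0 ** sub["true_log2_activity"].to_numpy(float),
            ov_min,
        )
    return tables


def _fragment_weights(ci, fs, fe, enh_tables) -> np.ndarray:
    w = np.ones(ci.size, dtype=float)
    for i, tab in enh_tables.items():
        if tab is None:
            continue
        es, ee, ew, ov_min = tab
        mask = ci == i
        if not mask.any():
            continue
        s, e = fs[mask], fe[mask]
        best = np.ones(s.size, dtype=float)
        j_hi = np.searchsorted(es, e, side="left")  # enhancers starting before frag end
        for off in (1, 2, 3):  # planted enhancers are spaced, <=3 can touch a fragment
            j = j_hi - off
            valid = j >= 0
            jj = np.where(valid, j, 0)
            ov = np.minimum(ee[jj], e) - np.maximum(es[jj], s)
            hit = valid & (ov >= ov_min)
            best = np.where(hit, np.maximum(best, ew[jj]), best)
        w[mask] = best
    return w


# ---------------------------------------------------------------------------
# chromatin tracks
# ---------------------------------------------------------------------------

def simulate_chromatin(truth: pd.DataFrame, config: SimConfig) -> dict[str, pd.DataFrame]:
    """ATAC / H3K27ac / H3K4me1 / H3K9me3 peak tracks consistent with truth.

    Accessible enhancers get an overlapping ATAC and H3K27ac peak and an
    H3K4me1 peak within +/-3 kb; masked enhancers optionally carry a weak
    H3K9me3 peak. Decoy ATAC/H3K27ac/H3K4me1 peaks that do not touch any
    enhancer create chromatin-predicted-but-inactive regions.
    """
    rng = _rng(config, 3)
    tracks = {k: [] for k in ("atac", "h3k27ac", "h3k4me1", "h3k9me3")}
    L = config.chromosome_length_bp

    for rec in truth.itertuples() if len(truth) else []:
        if rec.accessible:
            j1, j2 = rng.integers(50, 201, size=2)
            tracks["atac"].append((rec.chrom, max(0, rec.start - j1), min(L, rec.end + j2)))
            j1, j2 = rng.integers(50, 301, size=2)
            tracks["h3k27ac"].append((rec.chrom, max(0, rec.start - j1), min(L, rec.end + j2)))
            off = int(rng.integers(-2_500, 2_501))
            c = (rec.start + rec.end) // 2 + off
            tracks["h3k4me1"].append((rec.chrom, max(0, c - 250), min(L, c + 250)))
        elif rng.random() < config.h3k9me3_masked_probability:
            tracks["h3k9me3"].append((rec.chrom, max(0, rec.start - 250), min(L, rec.end + 250)))

    # decoys: chromatin peaks with no enhancer underneath
    enh_by_chrom = {
        c: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for c, sub in (truth.groupby("chrom") if len(truth) else [])
    }
    chroms = list(config.chromosome_names)
    for key in ("atac", "h3k27ac", "h3k4me1"):
        placed = 0
        while placed < config.n_decoy_peaks:
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, L - 600))
            e = s + int(rng.integers(300, 601))
            es, ee = enh_by_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            # keep decoys clear of enhancers, including the 3 kb histone flank
            if np.any((es < e + 3_000) & (ee > s - 3_000)):
                continue
            tracks[key].append((chrom, s, e))
            placed += 1

    out = {}
    for key, rows in tracks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out[key] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# expression + tissue tables
# ---------------------------------------------------------------------------

def simulate_expression_and_tissue(
    truth: pd.DataFrame,
    gene_model: GeneModel,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TPM table and tissue-specificity lookup coupled to enhancer truth.

    Genes nearest to accessible enhancers draw from a log-normal TPM
    distribution whose mean increases with enhancer strength; all other
    genes (including those near masked enhancers) draw from the baseline.
    Tissue labels are biased (accessible -> ubiquitous) at the configured
    purity. Returns (expression, tissue_lookup, truth-with-tissue-classes).
    """
    rng = _rng(config, 4)
    lo, hi = config.activity_log2_range
    genes = gene_model.genes
    boost = {}
    acc_genes, masked_genes = set(), set()
    for rec in truth.itertuples() if len(truth) else []:
        if not rec.nearest_gene_id:
            continue
        if rec.accessible:
            acc_genes.add(rec.nearest_gene_id)
            q = (rec.true_log2_activity - lo) / (hi - lo)
            boost[rec.nearest_gene_id] = max(
                boost.get(rec.nearest_gene_id, 0.0), config.expression_effect_log2 * q
            )
        else:
            masked_genes.add(rec.nearest_gene_id)
    masked_genes -= acc_genes

    log2_tpm = rng.normal(config.expression_base_log2_tpm, 1.0, size=len(genes))
    gene_ids = genes["gene_id"].tolist()
    for i, g in enumerate(gene_ids):
        log2_tpm[i] += boost.get(g, 0.0)
    expression = pd.DataFrame(dict(gene_id=gene_ids, tpm=2.0 ** log2_tpm))

    labels = []
    for g in gene_ids:
        if g in acc_genes:
            ubiq = rng.random() < config.tissue_purity
        elif g in masked_genes:
            ubiq = rng.random() >= config.tissue_purity
        else:
            ubiq = rng.random() < 0.5
        if ubiq:
            labels.append(TISSUE_UBIQUITOUS_LABEL)
        else:
            labels.append(TISSUE_SPECIFIC_LABELS[int(rng.integers(len(TISSUE_SPECIFIC_LABELS)))])
    tissue = pd.DataFrame(dict(gene_id=gene_ids, rna_tissue_specificity=labels))

    lut = dict(zip(gene_ids, labels))
    truth = truth.copy()
    if len(truth):
        truth["tissue_class"] = [
            "ubiquitous" if lut.get(g, "") == TISSUE_UBIQUITOUS_LABEL else "tissue_specific"
            for g in truth["nearest_gene_id"]
        ]
    return expression, tissue, truth


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    config: SimConfig
    genome: dict[str, bytearray]
    gene_model: GeneModel
    truth: pd.DataFrame
    input_libraries: list[FragmentSet]
    rna_libraries: list[FragmentSet]
    chromatin: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    tissue: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_study(config: SimConfig, n_replicates: int | None = None) -> StudyData:
    """Run the full generator end to end (genome -> tables)."""
    config.validate()
    genome, gene_model = simulate_genome(config)
    truth = plant_enhancers(genome, gene_model, config)
    reps = config.n_replicates if n_replicates is None else n_replicates
    inputs, rnas = [], []
    for r in range(1, reps + 1):
        rep_seed = (int(config.seed) * 1_000 + r) % (2**31)
        fs_in, fs_rna = simulate_fragments(genome, truth, config, rep_seed, replicate=r)
        inputs.append(fs_in)
        rnas.append(fs_rna)
    chromatin = simulate_chromatin(truth, config)
    expression, tissue, truth = simulate_expression_and_tissue(truth, gene_model, config)
    return StudyData(config, genome, gene_model, truth, inputs, rnas,
                     chromatin, expression, tissue)
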