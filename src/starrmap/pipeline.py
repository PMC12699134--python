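"""Configured end-to-end pipeline: simulate -> quantify -> callpeaks ->
classify -> annotate -> motifs -> design.

A single YAML config (with defaults equal to the published analysis
parameters: peak p < 1e-5, log2 enrichment >= 2.5, strength thresholds from
changepoints, H3K4me1 flank 3 kb, motif p < 1e-4, background shift 10 kb,
500/200 tiling, 249/100 windows) drives all stages. Every run writes a
resolved-config snapshot and a manifest with seeds, record counts and
output checksums so results can be reproduced and compared byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, design, motifs, peaks, quantify, strength, synth
from .io import write_bed, write_fasta, write_gtf

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "callpeaks", "classify", "annotate", "motifs", "design")

_DEFAULTS: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "sim": {},  # overrides for synth.SimConfig fields
    "peaks": {
        "window_bp": 500,
        "stride_bp": 100,
        "min_input": 10,
        "p_threshold": 1e-5,
        "log2fc_threshold": 2.5,
        "fc_scale": "log2",
        "chrom_whitelist": list(peaks.DEFAULT_WHITELIST),
        "unfiltered_p_threshold": 1e-3,
        "unfiltered_log2fc_threshold": 1.0,
    },
    "strength": {"penalty": None, "method": "auto",
                 "strong_lower": None, "weak_upper": None},
    "annotate": {"h3k4me1_flank_bp": 3000},
    "motifs": {"p_threshold": 1e-4, "shift_bp": 10_000, "min_input": 10,
               "top_n": 50, "min_hits": 2},
    "design": {"tile_bp": 500, "overlap_bp": 200, "window_bp": 249,
               "stride_bp": 100, "flank_windows": 3, "n_background": 200,
               "n_top_tiled": 50, "split": [0.8, 0.1, 0.1]},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class DataError(RuntimeError):
    """Missing or inconsistent stage data (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    settings: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = copy.deepcopy(_DEFAULTS)
        sim_fields = set(synth.SimConfig().to_dict())
        for key, value in (raw or {}).items():
            if key not in cfg:
                raise ConfigError(f"unknown config key: {key!r}")
            if isinstance(cfg[key], dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                allowed = sim_fields if key == "sim" else set(cfg[key])
                for k2 in value:
                    if k2 not in allowed:
                        raise ConfigError(f"unknown config key: {key}.{k2}")
                cfg[key].update(value)
            else:
                cfg[key] = value
        unknown_stages = set(cfg["stages"]) - set(STAGES)
        if unknown_stages:
            raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def __getitem__(self, key):
        return self.settings[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.settings
    stages = list(cfg["stages"])
    seed = int(cfg["seed"])

    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    manifest = {"package": "starrmap", "version": __version__, "seed": seed,
                "stages": [], "outputs": {}}
    products: dict = {}

    def need(key: str, stage: str):
        if key not in products:
            raise DataError(f"stage {stage!r} requires output of an earlier stage; "
                            f"enable and run the stage producing {key!r} first")
        return products[key]

    def record(stage: str, counts: dict, files: list[Path]):
        manifest["stages"].append({"stage": stage, "records": counts})
        for f in files:
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)

    if "simulate" in stages:
        sim_cfg = synth.SimConfig(**{"seed": seed, **cfg["sim"]})
        study = synth.simulate_study(sim_cfg)
        products["study"] = study
        files = []
        write_fasta(study.genome, outdir / "genome.fa")
        files.append(outdir / "genome.fa")
        write_gtf(study.gene_model, outdir / "genes.gtf")
        files.append(outdir / "genes.gtf")
        study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        files.append(outdir / "truth.tsv")
        for fs in study.input_libraries + study.rna_libraries:
            p = outdir / f"{fs.library_id}.bed"
            fs.to_bed(p)
            files.append(p)
        for name, df in study.chromatin.items():
            p = outdir / f"{name}_peaks.bed"
            write_bed(df, p)
            files.append(p)
        study.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        study.tissue.to_csv(outdir / "tissue.tsv", sep="\t", index=False)
        files += [outdir / "expression.tsv", outdir / "tissue.tsv"]
        record("simulate", {"enhancers": len(study.truth),
                            "genes": len(study.gene_model.genes)}, files)

    if "quantify" in stages:
        study = need("study", "quantify")
        r2 = np.nan
        if len(study.rna_libraries) >= 2:
            r2 = quantify.replicate_correlation(
                study.rna_libraries[0], study.rna_libraries[1], bin_bp=500)
        products["replicate_r2"] = r2
        pd.DataFrame([{"statistic": "rna_replicate_r2_500bp", "value": r2}]).to_csv(
            outdir / "replicate_correlation.tsv", sep="\t", index=False)
        record("quantify", {"replicate_pairs": 1 if np.isfinite(r2) else 0},
               [outdir / "replicate_correlation.tsv"])

    if "callpeaks" in stages:
        study = need("study", "callpeaks")
        pooled_rna = _pool(study.rna_libraries)
        pooled_in = _pool(study.input_libraries)
        pk = cfg["peaks"]
        windows = peaks.scan_windows(
            pooled_in, pooled_rna, window_bp=pk["window_bp"], stride_bp=pk["stride_bp"],
            min_input=pk["min_input"])
        whitelist = tuple(str(c) for c in pk["chrom_whitelist"])
        called = peaks.call_peaks(windows, p_threshold=pk["p_threshold"],
                                  log2fc_threshold=pk["log2fc_threshold"],
                                  chrom_whitelist=whitelist, fc_scale=pk["fc_scale"])
        unfiltered = peaks.call_peaks(
            windows, p_threshold=pk["unfiltered_p_threshold"],
            log2fc_threshold=pk["unfiltered_log2fc_threshold"],
            chrom_whitelist=None, fc_scale=pk["fc_scale"])
        products.update(windows=windows, peaks=called, unfiltered_peaks=unfiltered,
                        pooled_rna=pooled_rna, pooled_input=pooled_in)
        peaks.write_narrowpeak(called, outdir / "peaks.narrowPeak")
        peaks.write_narrowpeak(unfiltered, outdir / "peaks_unfiltered.narrowPeak")
        record("callpeaks", {"windows": len(windows), "peaks": len(called),
                             "unfiltered_peaks": len(unfiltered)},
               [outdir / "peaks.narrowPeak", outdir / "peaks_unfiltered.narrowPeak"])

    if "classify" in stages:
        called = need("peaks", "classify")
        if not len(called):
            raise DataError("no peaks to classify")
        st = cfg["strength"]
        ranked = np.sort(called["log2_enrichment"].to_numpy())
        if st["strong_lower"] is not None and st["weak_upper"] is not None:
            thresholds = strength.StrengthThresholds(
                float(st["strong_lower"]), float(st["weak_upper"]))
        else:
            thresholds = strength.derive_thresholds(
                ranked, penalty=st["penalty"], method=st["method"])
        called = called.copy()
        called["strength_class"] = strength.classify_strength(
            called["log2_enrichment"], thresholds)
        products["peaks"] = called
        products["thresholds"] = thresholds
        header = (f"# strong_lower_log2={thresholds.strong_lower_log2:.4f}\t"
                  f"weak_upper_log2={thresholds.weak_upper_log2:.4f}\n")
        path = outdir / "strength_classes.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            called[["peak_id", "log2_enrichment", "strength_class"]].to_csv(
                fh, sep="\t", index=False)
        record("classify", {c: int((called["strength_class"] == c).sum())
                            for c in strength.CLASS_ORDER}, [path])

    if "annotate" in stages:
        study = need("study", "annotate")
        called = need("peaks", "annotate")
        an = cfg["annotate"]
        called = called.copy()
        called["accessible"] = annotate.annotate_accessibility(called, study.chromatin["atac"])
        called["h3k27ac"] = annotate.annotate_histone(called, study.chromatin["h3k27ac"], 0)
        called["h3k4me1"] = annotate.annotate_histone(
            called, study.chromatin["h3k4me1"], an["h3k4me1_flank_bp"])
        called["h3k9me3"] = annotate.annotate_histone(called, study.chromatin["h3k9me3"], 0)
        feats = annotate.annotate_genomic_feature(called, study.gene_model)
        called = pd.concat([called.reset_index(drop=True), feats], axis=1)
        called["tissue_class"] = annotate.classify_tissue(
            called["nearest_gene_id"], study.tissue).to_numpy()
        products["peaks"] = called
        path = outdir / "annotated_peaks.tsv"
        called.to_csv(path, sep="\t", index=False)
        record("annotate", {"annotated": len(called),
                            "accessible": int(called["accessible"].sum())}, [path])

    if "motifs" in stages:
        study = need("study", "motifs")
        called = need("peaks", "motifs")
        unfiltered = need("unfiltered_peaks", "motifs")
        mo = cfg["motifs"]
        pwms = motifs.load_bundled_motifs()
        yy1 = next(m for m in pwms if m.motif_id.startswith("YY1"))

        peak_seqs = _region_seqs(study.genome, called)
        bg = motifs.shift_background(
            unfiltered, study.chrom_lengths, shift_bp=mo["shift_bp"],
            avoid=called, input_frags=products["pooled_input"],
            min_input=mo["min_input"])
        bg["peak_id"] = [f"bg{i + 1:05d}" for i in range(len(bg))]
        bg_seqs = _region_seqs(study.genome, bg)
        if not len(bg):
            raise DataError("no background regions survive filtering")
        enr = motifs.motif_enrichment(peak_seqs, bg_seqs, pwms, mo["p_threshold"])
        enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)

        hits = motifs.scan_pwm(peak_seqs, yy1, mo["p_threshold"])
        hits = motifs.dedup_hits(hits, yy1.width)
        hits.to_csv(outdir / "yy1_hits.tsv", sep="\t", index=False)
        counts = hits.groupby("sequence_id").size()
        per_peak = called.set_index("peak_id")
        yy1_counts = np.array([counts.get(p, 0) for p in per_peak.index])
        dosage_table, dosage_stats = motifs.yy1_dosage(
            per_peak["log2_enrichment"].to_numpy(), yy1_counts)
        dosage_table.to_csv(outdir / "yy1_dosage.tsv", sep="\t", index=False)

        cand_input = pd.DataFrame(dict(
            enhancer_id=per_peak.index,
            activity_log2=per_peak["log2_enrichment"].to_numpy(),
            sequence=[peak_seqs[p] for p in per_peak.index]))
        designs = motifs.select_mutagenesis_candidates(
            cand_input, yy1, top_n=mo["top_n"], min_hits=mo["min_hits"],
            p_threshold=mo["p_threshold"])
        designs.to_csv(outdir / "yy1_mutagenesis.tsv", sep="\t", index=False)
        products.update(yy1_hits=hits, yy1_counts=yy1_counts,
                        dosage=(dosage_table, dosage_stats), mutagenesis=designs)
        record("motifs", {"backgrounds": len(bg), "yy1_hits": len(hits),
                          "mutagenesis_designs": len(designs)},
               [outdir / "motif_enrichment.tsv", outdir / "yy1_hits.tsv",
                outdir / "yy1_dosage.tsv", outdir / "yy1_mutagenesis.tsv"])

    if "design" in stages:
        study = need("study", "design")
        called = need("peaks", "design")
        de = cfg["design"]
        top = called.sort_values("log2_enrichment", ascending=False).head(de["n_top_tiled"])
        tiles = pd.concat(
            [design.tile_peak(p, study.genome, de["tile_bp"], de["overlap_bp"])
             for p in top.itertuples()],
            ignore_index=True) if len(top) else pd.DataFrame()
        tiles.to_csv(outdir / "tiles.tsv", sep="\t", index=False)
        ds = design.prepare_window_dataset(
            called, study.genome, products["pooled_input"], products["pooled_rna"],
            window_bp=de["window_bp"], stride_bp=de["stride_bp"],
            flank_windows=de["flank_windows"], n_background=de["n_background"],
            split=tuple(de["split"]), seed=seed)
        ds.to_csv(outdir / "window_dataset.tsv", sep="\t", index=False)
        products.update(tiles=tiles, window_dataset=ds)
        record("design", {"tiles": len(tiles), "windows": len(ds)},
               [outdir / "tiles.tsv", outdir / "window_dataset.tsv"])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _pool(libraries) -> quantify.FragmentSet:
    df = pd.concat([fs.intervals for fs in libraries], ignore_index=True)
    first = libraries[0]
    return quantify.FragmentSet(
        library_id=f"{first.role}_pooled", role=first.role, replicate=0,
        intervals=df, chrom_lengths=first.chrom_lengths)


def _region_seqs(genome: dict[str, bytearray], regions: pd.DataFrame) -> dict[str, str]:
    ids = regions["peak_id"] if "peak_id" in regions.columns else regions.index.astype(str)
    return {
        str(i): bytes(genome[c][s:e]).decode()
        for i, c, s, e in zip(ids, regions["chrom"], regions["start"], regions["end"])
    }
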