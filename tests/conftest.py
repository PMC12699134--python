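"""Shared fixtures: one small and one full-scale synthetic study.

The small study keeps most unit tests fast; the full-scale study uses the
generator defaults (200 enhancers, 1M fragments per library) and is shared
by the recovery/power checks so the expensive simulation runs once.
"""

import numpy as np
import pandas as pd
import pytest

from starrmap import motifs, peaks, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SimConfig(
        seed=7,
        chromosome_length_bp=150_000,
        n_enhancers=24,
        n_genes=24,
        n_input_fragments=120_000,
        n_rna_fragments=120_000,
        n_replicates=1,
        n_decoy_peaks=80,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """Generator defaults: the study conditions for recovery checks."""
    return synth.simulate_study(synth.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_windows(default_study):
    return peaks.scan_windows(
        default_study.input_libraries[0], default_study.rna_libraries[0]
    )


@pytest.fixture(scope="session")
def default_peaks(default_windows, default_study):
    return peaks.call_peaks(
        default_windows, chrom_whitelist=default_study.config.enhancer_chromosomes
    )


@pytest.fixture(scope="session")
def yy1_pwm():
    return next(m for m in motifs.load_bundled_motifs() if m.motif_id == "YY1_syn")


@pytest.fixture(scope="session")
def ets_pwm():
    return next(m for m in motifs.load_bundled_motifs() if m.motif_id == "ETS_syn")


def overlap_truth_peaks(truth: pd.DataFrame, called: pd.DataFrame) -> pd.DataFrame:
    """Match each truth enhancer to an overlapping called peak (or none)."""
    rows = []
    for rec in truth.itertuples():
        sub = called[
            (called["chrom"] == rec.chrom)
            & (called["start"] < rec.end)
            & (called["end"] > rec.start)
        ]
        center = (rec.start + rec.end) // 2
        if len(sub):
            pk = sub.iloc[0]
            rows.append(
                dict(
                    enhancer_id=rec.enhancer_id,
                    true_log2_activity=rec.true_log2_activity,
                    detected=True,
                    est_log2=float(pk["log2_enrichment"]),
                    summit_error=abs(int(pk["summit"]) - center),
                )
            )
        else:
            rows.append(
                dict(
                    enhancer_id=rec.enhancer_id,
                    true_log2_activity=rec.true_log2_activity,
                    detected=False,
                    est_log2=np.nan,
                    summit_error=np.nan,
                )
            )
    return pd.DataFrame(rows)
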