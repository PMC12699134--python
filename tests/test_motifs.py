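"""PWM machinery: exact p-values, scanning, enrichment, YY1 operations."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starrmap import motifs
from starrmap.motifs import PWMModel, revcomp
from _oracles import enumerate_pwm_tail


def random_pwm(seed, width):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4) * 0.7, size=width)
    bg = rng.dirichlet(np.ones(4) * 5.0)
    return PWMModel(f"rand{seed}w{width}", probs, background=bg)


def embed(rng, pre, word, post):
    mk = lambda n: "".join(rng.choice(list("ACGT"), n))
    return mk(pre) + word + mk(post)


class TestExactPvalues:
    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    def test_dp_tail_matches_enumeration(self, width):
        pwm = random_pwm(width, width)
        lo, _pmf, tail = pwm.score_distribution()
        ss, enum_tail = enumerate_pwm_tail(pwm)
        dp_tail = np.array([tail[s - lo] for s in ss])
        assert np.abs(dp_tail - enum_tail).max() < 1e-12

    def test_consensus_scores_maximal_with_minimal_p(self, yy1_pwm):
        hits = motifs.scan_pwm({"s": yy1_pwm.consensus}, yy1_pwm, p_threshold=1e-3)
        assert len(hits) == 1
        best = yy1_pwm.int_scores.max(axis=1).sum() * yy1_pwm.resolution
        assert hits["score"][0] == pytest.approx(best)
        assert hits["p_value"][0] == pytest.approx(yy1_pwm.pvalue(best))

    def test_pvalue_monotone_in_score(self, yy1_pwm):
        scores = np.linspace(-5, 18, 40)
        ps = [yy1_pwm.pvalue(s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            PWMModel("bad", np.full((5, 4), 0.3))
        with pytest.raises(ValueError):
            PWMModel("short", np.full((2, 4), 0.25))


class TestScanning:
    def test_reverse_complement_instance_reported_on_minus_strand(self, yy1_pwm):
        rng = np.random.default_rng(0)
        seq = embed(rng, 60, revcomp(yy1_pwm.consensus), 60)
        hits = motifs.scan_pwm({"s": seq}, yy1_pwm)
        assert (hits["strand"] == "-").sum() == 1
        assert hits["start"][0] == 60

    def test_scanning_is_strand_symmetric(self, yy1_pwm):
        rng = np.random.default_rng(4)
        seq = embed(rng, 100, yy1_pwm.consensus, 40) + revcomp(yy1_pwm.consensus)
        fwd = motifs.scan_pwm({"s": seq}, yy1_pwm)
        rev = motifs.scan_pwm({"s": revcomp(seq)}, yy1_pwm)
        assert len(fwd) == len(rev)
        L = len(seq)
        mirrored = sorted(L - yy1_pwm.width - rev["start"])
        assert mirrored == sorted(fwd["start"])

    def test_sequence_shorter_than_width_yields_no_hits(self, yy1_pwm):
        assert len(motifs.scan_pwm({"s": "ACGT"}, yy1_pwm)) == 0

    def test_n_containing_windows_skipped(self, yy1_pwm):
        broken = yy1_pwm.consensus[:6] + "N" + yy1_pwm.consensus[7:]
        assert len(motifs.scan_pwm({"s": broken}, yy1_pwm, p_threshold=0.5)) == 0

    def test_hit_substring_rescored_to_reported_score(self, yy1_pwm):
        rng = np.random.default_rng(8)
        seq = embed(rng, 30, yy1_pwm.consensus, 30)
        hits = motifs.scan_pwm({"s": seq}, yy1_pwm)
        for row in hits.itertuples():
            sub = seq[row.start : row.start + yy1_pwm.width]
            again = motifs.scan_pwm({"w": sub}, yy1_pwm, p_threshold=1.0)
            exact = again[(again["start"] == 0) & (again["strand"] == row.strand)]
            assert exact["score"].iloc[0] == pytest.approx(row.score)

    def test_overlapping_hits_deduplicated_by_score(self, yy1_pwm):
        hits = pd.DataFrame(dict(sequence_id=["a"] * 3, start=[0, 5, 30],
                                 strand=["+"] * 3, score=[10.0, 12.0, 8.0],
                                 p_value=[1e-5] * 3))
        kept = motifs.dedup_hits(hits, yy1_pwm.width)
        assert kept["start"].tolist() == [5, 30]


class TestMemeFormat:
    def test_round_trip_preserves_probabilities(self, tmp_path, yy1_pwm, ets_pwm):
        path = tmp_path / "m.meme"
        motifs.write_meme([yy1_pwm, ets_pwm], path)
        back = motifs.read_meme(path)
        assert [m.motif_id for m in back] == ["YY1_syn", "ETS_syn"]
        assert np.allclose(back[0].probs, yy1_pwm.probs, atol=1e-6)

    def test_background_frequencies_parsed(self):
        txt = ("MEME version 4\n\nALPHABET= ACGT\n\n"
               "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
               "MOTIF tiny\nletter-probability matrix: alength= 4 w= 4\n"
               "1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 1\n")
        m = motifs.read_meme(io.StringIO(txt))[0]
        assert m.background.tolist() == pytest.approx([0.3, 0.2, 0.2, 0.3])
        assert m.consensus == "ACGT"


class TestShiftBackground:
    def test_plus_10kb_arithmetic(self):
        pk = pd.DataFrame([("1", 1_000, 1_800)], columns=["chrom", "start", "end"])
        bg = motifs.shift_background(pk, {"1": 100_000})
        assert (bg["start"][0], bg["end"][0]) == (11_000, 11_800)

    def test_region_near_chromosome_end_removed(self):
        pk = pd.DataFrame([("1", 95_000, 95_800)], columns=["chrom", "start", "end"])
        assert len(motifs.shift_background(pk, {"1": 100_000})) == 0

    def test_shifted_region_overlapping_peak_removed(self):
        pk = pd.DataFrame([("1", 1_000, 1_800), ("1", 50_000, 50_500)],
                          columns=["chrom", "start", "end"])
        bg = motifs.shift_background(pk, {"1": 100_000}, avoid=pk.iloc[:1])
        assert len(bg) == 2  # neither shifted region lands on the avoided peak
        bg2 = motifs.shift_background(
            pk, {"1": 100_000},
            avoid=pd.DataFrame([("1", 11_200, 11_400)], columns=["chrom", "start", "end"]))
        assert (bg2["start"] == 60_000).all()

    def test_poor_input_coverage_removed(self, small_study):
        pk = small_study.truth[["chrom", "start", "end"]].copy()
        bg_all = motifs.shift_background(pk, small_study.chrom_lengths)
        bg_cov = motifs.shift_background(
            pk, small_study.chrom_lengths,
            input_frags=small_study.input_libraries[0], min_input=10)
        assert len(bg_cov) <= len(bg_all)


class TestEnrichment:
    def test_fisher_matches_hypergeometric_tail(self, yy1_pwm):
        rng = np.random.default_rng(2)
        mk = lambda n: "".join(rng.choice(list("ACGT"), n))
        targets = {f"t{i}": (embed(rng, 40, yy1_pwm.consensus, 40) if i < 20 else mk(92))
                   for i in range(100)}
        background = {f"b{i}": (embed(rng, 40, yy1_pwm.consensus, 40) if i < 5 else mk(92))
                      for i in range(100)}
        out = motifs.motif_enrichment(targets, background, [yy1_pwm]).iloc[0]
        k_t, k_b = out["n_target"], out["n_background"]
        assert k_t >= 20 and k_b >= 5  # embedded instances all found
        expected_p = stats.hypergeom.sf(k_t - 1, 200, k_t + k_b, 100)
        assert out["p_value"] == pytest.approx(expected_p, rel=1e-9)
        if (k_t, k_b) == (20, 5):
            assert out["fold"] == pytest.approx(4.0)

    def test_identical_sets_are_unenriched(self, yy1_pwm):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": embed(rng, 30, yy1_pwm.consensus, 30) for i in range(30)}
        out = motifs.motif_enrichment(seqs, seqs, [yy1_pwm]).iloc[0]
        assert out["fold"] == pytest.approx(1.0)
        assert out["p_value"] >= 0.5

    def test_empty_sets_rejected(self, yy1_pwm):
        with pytest.raises(ValueError):
            motifs.motif_enrichment({}, {"b": "ACGT"}, [yy1_pwm])


class TestDosage:
    def test_bin_labels_cover_zero_to_five_plus(self):
        table, _info = motifs.yy1_dosage(np.arange(12, dtype=float),
                                         np.arange(12) % 7)
        assert table["bin"].tolist() == ["0", "1", "2", "3", "4", "5+"]

    def test_all_zero_counts_give_single_bin_no_trend(self):
        table, info = motifs.yy1_dosage(np.array([3.0, 4.0, 5.0]), np.zeros(3, int))
        assert table[table["n"] > 0]["bin"].tolist() == ["0"]
        assert np.isnan(info["slope"])

    def test_planted_dosage_trend_recovered(self, small_study, yy1_pwm):
        truth = small_study.truth
        seqs = {r.enhancer_id: bytes(small_study.genome[r.chrom][r.start:r.end]).decode()
                for r in truth.itertuples()}
        hits = motifs.dedup_hits(motifs.scan_pwm(seqs, yy1_pwm), yy1_pwm.width)
        counts = hits.groupby("sequence_id").size()
        c = np.array([counts.get(e, 0) for e in truth["enhancer_id"]])
        _table, info = motifs.yy1_dosage(truth["true_log2_activity"].to_numpy(), c)
        assert info["slope"] > 0


class TestMutagenesis:
    def test_plus_strand_core_replaced(self, yy1_pwm):
        rng = np.random.default_rng(5)
        seq = embed(rng, 50, yy1_pwm.consensus, 50)
        hits = motifs.scan_pwm({"s": seq}, yy1_pwm)
        mut, log = motifs.mutate_yy1(seq, hits, yy1_pwm)
        assert len(mut) == len(seq)
        assert "ATGG" in seq and log["wt"][0] == "ATGG" and log["mut"][0] == "CTCG"
        pos = log["core_position"][0]
        assert mut[pos:pos + 4] == "CTCG"

    def test_minus_strand_ccat_becomes_cgag(self, yy1_pwm):
        rng = np.random.default_rng(6)
        seq = embed(rng, 50, revcomp(yy1_pwm.consensus), 50)
        hits = motifs.scan_pwm({"s": seq}, yy1_pwm)
        assert hits["strand"][0] == "-"
        mut, log = motifs.mutate_yy1(seq, hits, yy1_pwm)
        assert log["wt"][0] == "CCAT" and log["mut"][0] == "CGAG"
        pos = log["core_position"][0]
        assert mut[pos:pos + 4] == "CGAG"

    def test_no_hits_returns_sequence_unchanged(self, yy1_pwm):
        seq = "ACGT" * 30
        mut, log = motifs.mutate_yy1(seq, motifs.scan_pwm({"s": seq}, yy1_pwm), yy1_pwm)
        assert mut == seq and len(log) == 0

    def test_mutation_is_idempotent(self, yy1_pwm):
        rng = np.random.default_rng(7)
        seq = embed(rng, 40, yy1_pwm.consensus, 20) + embed(rng, 0, revcomp(yy1_pwm.consensus), 30)
        mut, _ = motifs.mutate_yy1(seq, motifs.scan_pwm({"s": seq}, yy1_pwm), yy1_pwm)
        again, _ = motifs.mutate_yy1(mut, motifs.scan_pwm({"m": mut}, yy1_pwm), yy1_pwm)
        assert again == mut

    def test_pwm_without_core_rejected(self, ets_pwm):
        hits = pd.DataFrame(dict(sequence_id=["s"], start=[0], strand=["+"],
                                 score=[10.0], p_value=[1e-5]))
        with pytest.raises(ValueError, match="core"):
            motifs.mutate_yy1("A" * 20, hits, ets_pwm)


class TestMutagenesisCandidates:
    def _enhancer_table(self, yy1_pwm, n=8, n_instances=2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            parts = []
            for _ in range(n_instances):
                parts.append("".join(rng.choice(list("ACGT"), 40)) + yy1_pwm.consensus)
            seq = "".join(parts) + "".join(rng.choice(list("ACGT"), 40))
            rows.append(dict(enhancer_id=f"e{i}", activity_log2=float(5 + i), sequence=seq))
        return pd.DataFrame(rows)

    def test_single_hit_peaks_excluded(self, yy1_pwm):
        table = pd.concat([
            self._enhancer_table(yy1_pwm, n=3, n_instances=2),
            self._enhancer_table(yy1_pwm, n=2, n_instances=1, seed=9).assign(
                enhancer_id=["solo1", "solo2"]),
        ], ignore_index=True)
        with pytest.warns(UserWarning):
            out = motifs.select_mutagenesis_candidates(table, yy1_pwm, top_n=50)
        assert set(out["enhancer_id"]) == {"e0", "e1", "e2"}

    def test_trimmed_window_contains_every_hit(self, yy1_pwm):
        table = self._enhancer_table(yy1_pwm, n=5)
        with pytest.warns(UserWarning):
            out = motifs.select_mutagenesis_candidates(table, yy1_pwm, top_n=50)
        for row in out.itertuples():
            hits = motifs.scan_pwm({"w": row.wt_sequence}, yy1_pwm)
            assert len(hits) >= row.n_yy1_hits

    def test_mutants_carry_no_residual_hits(self, yy1_pwm):
        table = self._enhancer_table(yy1_pwm, n=6, n_instances=3)
        with pytest.warns(UserWarning):
            out = motifs.select_mutagenesis_candidates(table, yy1_pwm, top_n=50)
        for row in out.itertuples():
            assert len(motifs.scan_pwm({"m": row.mut_sequence}, yy1_pwm)) == 0
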