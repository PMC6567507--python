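"""Generator contracts: duplex geometry, truth calibration, backgrounds."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from hairpin2pare import rna_fold as rf
from hairpin2pare import synthetic_data as sd
from hairpin2pare import tag_processing as tp
from hairpin2pare.io_core import Library, SampleSheet, load_config
from hairpin2pare.seqs import dinucleotide_shuffle, to_dna


class TestBuildPrecursor:
    def test_perfect_stem_recovered_by_folding(self, rng):
        pre = sd.build_precursor(rng, mature_length=21, stem_mismatches=0, loop_length=4)
        fr = rf.fold(pre.sequence)
        n_pairs = sum(1 for p in fr.pair_table if p >= 0) // 2
        assert n_pairs >= 19
        ms, me = pre.mature_span
        paired_in_mature = sum(1 for p in range(ms, me) if fr.pair_table[p] >= 0)
        assert paired_in_mature >= 19

    def test_length_arithmetic(self, rng):
        p19 = sd.build_precursor(rng, mature_length=19, n_isomirs=0)
        p24 = sd.build_precursor(rng, mature_length=24, n_isomirs=0)
        assert len(p24.sequence) - len(p19.sequence) == 10  # two arms of +5 each

    def test_seed_determinism(self):
        a = sd.build_precursor(np.random.default_rng(5))
        b = sd.build_precursor(np.random.default_rng(5))
        assert a.sequence == b.sequence and a.isomir_offsets == b.isomir_offsets

    def test_loop_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            sd.build_precursor(rng, loop_length=3)

    def test_mature_in_precursor_and_spans_disjoint(self, rng):
        for _ in range(10):
            pre = sd.build_precursor(rng)
            assert pre.mature_seq in pre.sequence
            assert pre.star_seq in pre.sequence
            a, b = sorted([pre.mature_span, pre.star_span])
            assert a[1] <= b[0]

    def test_isomir_shifts_bounded(self, rng):
        pre = sd.build_precursor(rng, n_isomirs=3)
        for d5, d3 in pre.isomir_offsets:
            assert abs(d5) <= 3 and abs(d3) <= 3 and (d5, d3) != (0, 0)

    def test_duplex_overhangs_by_construction(self, rng):
        """Folding the construction shows exactly 2-nt 3' overhangs."""
        for _ in range(10):
            pre = sd.build_precursor(rng)
            fr = rf.fold(pre.sequence)
            m5, m3 = pre.mature_span[0], pre.mature_span[1] - 1
            s5, s3 = pre.star_span[0], pre.star_span[1] - 1
            assert fr.pair_table[m3 - 2] == s5
            assert fr.pair_table[m5] == s3 - 2


class TestGenome:
    def test_precursors_verbatim_in_genome(self, rng):
        pres = [sd.build_precursor(rng, pid=f"p{i}") for i in range(5)]
        genome, decoys, bed = sd.assemble_genome(rng, pres, n_decoys=3, spacer_length=100)
        assert len(decoys) == 3 and len(bed) == 8
        for pre in pres:
            iv = pre.genome_placement
            seg = genome[iv.chrom][iv.start : iv.end]
            expected = to_dna(pre.sequence)
            if iv.strand == "-":
                from hairpin2pare.seqs import revcomp

                seg = revcomp(seg)
            assert seg == expected


class TestSrnaSimulation:
    def _one_mirna_truth(self, rpm):
        pre = sd.build_precursor(np.random.default_rng(0), n_isomirs=0)
        rows = []
        row = {
            "variant_id": "pre-1:m", "precursor_id": "pre-1", "kind": "mature",
            "arm": pre.arm, "sequence": to_dna(pre.mature_seq),
            "span_start": 0, "span_end": 21, "base_rpm": rpm, "is_de": False,
            "family": "",
        }
        for tp_ in (0, 1, 4):
            row[f"log2fc_{tp_}"] = 0.0
            row[f"rpm_control_{tp_}"] = rpm
            row[f"rpm_heat_{tp_}"] = rpm
        rows.append(row)
        return pd.DataFrame(rows), pre

    def test_near_poisson_count_calibration(self):
        # 1000 RPM at depth 10^6 and dispersion -> 0: collapsed count within 5%
        truth, pre = self._one_mirna_truth(1000.0)
        lib = Library("l1", "control", 0, 1)
        rng = np.random.default_rng(42)
        genome = {"c": to_dna(pre.sequence) + "ACGT" * 2000}
        reads = sd.generate_library_reads(
            rng, truth, lib, genome, depth=1_000_000, dispersion=0.0
        )
        trimmed = tp.trim_library(reads, "TGGAATTCTCGGGTGCCAAGG")
        counts = Counter(tp.size_select(trimmed, 18, 24))
        obs = counts[to_dna(pre.mature_seq)]
        assert abs(obs - 1000) / 1000 < 0.05

    def test_zero_planted_gives_pure_background(self):
        truth, pre = self._one_mirna_truth(1000.0)
        truth = truth.iloc[0:0]
        rng = np.random.default_rng(1)
        genome = {"c": "ACGT" * 500}
        reads = sd.generate_library_reads(rng, truth, Library("l", "heat", 0, 1), genome,
                                          depth=5000)
        assert len(reads) == 5000

    def test_depth_error(self):
        truth, _ = self._one_mirna_truth(10.0)
        with pytest.raises(ValueError):
            sd.generate_library_reads(
                np.random.default_rng(1), truth, Library("l", "heat", 0, 1), {"c": "ACGT" * 100},
                depth=0,
            )

    def test_two_seeds_differ_same_truth(self, small_config):
        ds1 = sd.simulate_dataset(small_config, 101)
        ds2 = sd.simulate_dataset(small_config, 202)
        r1 = ds1.library_reads("control_0DAT_rep1")
        r2 = ds2.library_reads("control_0DAT_rep1")
        assert Counter(r1) != Counter(r2)

    def test_background_length_mode_is_24(self):
        rng = np.random.default_rng(3)
        frags = sd.background_inserts(rng, {"c": "ACGT" * 2000}, 5000)
        lens = Counter(len(f) for f in frags)
        assert max(lens, key=lens.get) == 24
        assert min(lens) >= 18 and max(lens) <= 30


class TestTruthTable:
    def test_non_de_identical_means_and_de_floor(self, rng):
        pres = [sd.build_precursor(rng, pid=f"p{i}") for i in range(12)]
        truth = sd.build_truth(rng, pres, de_fraction=0.25, min_abs_log2fc=1.0)
        cells = [c for c in truth.columns if c.startswith("rpm_")]
        non_de = truth[~truth.is_de]
        assert np.allclose(non_de[cells].std(axis=1), 0.0)
        de = truth[truth.is_de]
        assert (de["log2fc_0"].abs() >= 1.0).all()
        assert de["precursor_id"].nunique() == 3

    def test_dataset_determinism(self, small_config):
        a = sd.simulate_dataset(small_config, 7)
        b = sd.simulate_dataset(small_config, 7)
        pd.testing.assert_frame_equal(a.truth_mirna, b.truth_mirna)
        assert a.genome == b.genome
        assert a.library_reads("heat_0DAT_rep1") == b.library_reads("heat_0DAT_rep1")


class TestPareSimulation:
    def _setup(self, seed=0, n_targets=3, n_decoys=1):
        rng = np.random.default_rng(seed)
        mirnas = {
            f"m{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 21)) for i in range(6)
        }
        tx, targets = sd.build_transcripts(rng, mirnas, n_targets, n_decoys, 400)
        return rng, mirnas, tx, targets

    def test_planted_site_is_revcomp_of_mirna(self):
        from hairpin2pare.seqs import revcomp

        _, mirnas, tx, targets = self._setup()
        seqs = dict(tx)
        for row in targets[~targets.is_decoy].itertuples():
            mseq = mirnas[row.mirna]
            site = seqs[row.transcript_id][row.site_start : row.site_start + len(mseq)]
            assert site == revcomp(mseq)
            assert row.cleavage_pos == row.site_start + len(mseq) - 10

    def test_no_background_single_five_prime_end(self):
        rng, _, tx, targets = self._setup()
        tags = sd.simulate_pare_library(rng, tx, targets, background_fraction=0.0)
        starts = set()
        seqs = dict(tx)
        one = targets[~targets.is_decoy].iloc[0]
        sig = seqs[one.transcript_id][one.cleavage_pos : one.cleavage_pos + 20]
        assert any(s == sig for _, s in tags)

    def test_background_only_has_no_dominant_position(self):
        rng = np.random.default_rng(5)
        frac_max = []
        for trial in range(20):
            _, _, tx, targets = self._setup(seed=trial)
            targets = targets.assign(is_decoy=True)  # suppress all signal
            tags = sd.simulate_pare_library(rng, tx, targets, background_fraction=0.5)
            counts = Counter(s for _, s in tags)
            if not counts:
                continue
            total = sum(counts.values())
            frac_max.append(max(counts.values()) / total)
        assert np.median(frac_max) < 0.5

    def test_cleavage_outside_transcript_errors(self):
        rng, _, tx, targets = self._setup()
        targets.loc[targets.index[0], "cleavage_pos"] = 10_000
        with pytest.raises(ValueError):
            sd.simulate_pare_library(rng, tx, targets)

    def test_peak_at_cleavage_with_default_background(self):
        hits = 0
        trials = 30
        for t in range(trials):
            rng, _, tx, targets = self._setup(seed=100 + t, n_targets=1, n_decoys=0)
            tags = sd.simulate_pare_library(rng, tx, targets, background_fraction=0.5)
            from hairpin2pare import degradome as dg

            profiles = dg.build_profiles(Counter(s for _, s in tags if 19 <= len(s) <= 21), tx)
            row = targets.iloc[0]
            prof = profiles[row.transcript_id]
            if prof.abundance.argmax() == row.cleavage_pos:
                hits += 1
        assert hits / trials > 0.9


def test_dinucleotide_shuffle_preserves_counts(rng):
    seq = "ACGUACGGUUACGCAUGGCA"
    for _ in range(10):
        s = dinucleotide_shuffle(seq, rng)
        assert sorted(s) == sorted(seq)
        assert s[0] == seq[0] and s[-1] == seq[-1]
        orig = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
        new = Counter(s[i : i + 2] for i in range(len(s) - 1))
        assert orig == new


def test_dinucleotide_shuffle_rejects_degenerate():
    with pytest.raises(ValueError):
        dinucleotide_shuffle("AAAAAAA", np.random.default_rng(0))
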