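"""Tag mapping, candidate extraction, star prediction, naming."""
import numpy as np
import pandas as pd
import pytest

from hairpin2pare import mirna_discovery as md
from hairpin2pare import rna_fold as rf
from hairpin2pare import synthetic_data as sd
from hairpin2pare.io_core import GenomicInterval
from hairpin2pare.seqs import dinucleotide_shuffle, revcomp, to_dna, to_rna


class TestMapTagsExact:
    GENOME = {"c1": "A" * 30 + "ACGTTGCAACGGTTACGATCAGG" + "T" * 30}

    def test_planted_substring(self):
        tag = "ACGTTGCAACGGTTACGATC"
        pl = md.map_tags_exact([tag], self.GENOME)
        assert len(pl) == 1
        row = pl.iloc[0]
        assert (row.chrom, row.start, row.strand) == ("c1", 30, "+")

    def test_reverse_strand(self):
        tag = revcomp("ACGTTGCAACGGTTACGATC")
        pl = md.map_tags_exact([tag], self.GENOME)
        assert len(pl) == 1 and pl.iloc[0].strand == "-"
        seg = self.GENOME["c1"][pl.iloc[0].start : pl.iloc[0].end]
        assert revcomp(seg) == tag

    def test_n_never_matches(self):
        pl = md.map_tags_exact(["ACGTTGCAACGGTTACGATN"], self.GENOME)
        assert pl.empty

    def test_multi_placement_counted(self):
        tag = "ACGTACGTACGTACGTACGT"
        genome = {"c1": "TT" + tag + "CCTTGGCCAAGGCCTT" + tag + "GG"}
        pl = md.map_tags_exact([tag], genome)
        # the repeat is internally periodic; all placements are genuine
        assert (pl.strand == "+").sum() == 2


def _perfect_hairpin_fold():
    """24-nt hairpin with pairs (i, 23 - i) for i = 0..9."""
    seq = "G" * 10 + "AAAA" + "C" * 10
    pair = [-1] * 24
    for i in range(10):
        pair[i], pair[23 - i] = 23 - i, i
    db = "(" * 10 + "...." + ")" * 10
    return rf.FoldResult(to_rna(seq), db, pair, -30.0)


class TestPredictStar:
    def test_pair_table_arithmetic_oracle(self):
        fold = _perfect_hairpin_fold()
        # mature 2..11 -> p(9) = 14, p(2) + 2 = 23 -> star = 14..23
        span, seq, geom = md.predict_star(fold, (2, 12))
        assert span == (14, 24)
        assert seq == fold.sequence[14:24]
        assert geom

    def test_projection_beyond_precursor_clamps(self):
        fold = _perfect_hairpin_fold()
        span, seq, geom = md.predict_star(fold, (0, 10))
        assert not geom  # star 3' projection exceeds the precursor end
        assert span is not None and span[1] == 24

    def test_planted_duplex_recovered_exactly(self, rng):
        for _ in range(20):
            pre = sd.build_precursor(rng, mature_length=int(rng.integers(20, 23)))
            fold = rf.fold(pre.sequence)
            span, seq, geom = md.predict_star(fold, pre.mature_span)
            assert span == pre.star_span
            assert seq == pre.star_seq
            assert geom

    def test_loop_straddling_mature_has_no_star(self):
        fold = _perfect_hairpin_fold()
        span, seq, geom = md.predict_star(fold, (6, 18))  # covers the loop
        assert span is None and not geom


class TestArmAssignment:
    def test_arm_flips_under_reverse_complement(self, rng):
        pre = sd.build_precursor(rng, arm="5p")
        fold = rf.fold(pre.sequence)
        loop = md._single_loop(fold, pre.mature_span)
        assert md._arm_of(pre.mature_span, loop, len(pre.sequence)) == "5p"

        from hairpin2pare.seqs import revcomp_rna

        rc = revcomp_rna(pre.sequence)
        n = len(pre.sequence)
        rc_span = (n - pre.mature_span[1], n - pre.mature_span[0])
        fold_rc = rf.fold(rc)
        loop_rc = md._single_loop(fold_rc, rc_span)
        assert md._arm_of(rc_span, loop_rc, n) == "3p"


class TestExtractWindows:
    def _planted_genome(self, seed=0, n=3):
        rng = np.random.default_rng(seed)
        pres = [sd.build_precursor(rng, pid=f"p{i}") for i in range(n)]
        genome, decoys, bed = sd.assemble_genome(rng, pres, n_decoys=n, spacer_length=300)
        return rng, pres, genome, decoys, bed

    @staticmethod
    def _mature_genome_tag(pre):
        iv = pre.genome_placement
        dna = to_dna(pre.mature_seq)
        return dna if iv.strand == "+" else dna  # tags are given in sense space

    def test_annotation_mode_windows_equal_bed(self):
        rng, pres, genome, decoys, bed = self._planted_genome()
        tags = [to_dna(p.mature_seq) for p in pres]
        placements = md.map_tags_exact(tags, genome)
        abundance = {t: 100 for t in tags}
        cands = md.extract_precursor_windows(
            placements, genome, abundance, annotation=bed
        )
        by_id = {name for iv, name in bed}
        assert all(c.id in by_id for c in cands)
        locus_by_name = dict((name, iv) for iv, name in bed)
        for c in cands:
            assert c.locus == locus_by_name[c.id]
        assert {c.id for c in cands} == {p.id for p in pres}

    def test_denovo_window_contains_planted_duplex(self):
        """De novo windows recover the planted duplex for most precursors
        (folding in arbitrary genomic context occasionally hides a stem)."""
        hits = 0
        trials = 12
        for t in range(trials):
            rng = np.random.default_rng(300 + t)
            pre = sd.build_precursor(rng, pid="p0")
            genome, _, _ = sd.assemble_genome(rng, [pre], n_decoys=1, spacer_length=300)
            tag = to_dna(pre.mature_seq)
            placements = md.map_tags_exact([tag], genome)
            cands = md.extract_precursor_windows(
                placements, genome, {tag: 50}, annotation=None
            )
            iv = pre.genome_placement
            lo = iv.start + min(pre.mature_span[0], pre.star_span[0])
            hi = iv.start + max(pre.mature_span[1], pre.star_span[1])
            if iv.strand == "-":
                lo = iv.end - max(pre.mature_span[1], pre.star_span[1])
                hi = iv.end - min(pre.mature_span[0], pre.star_span[0])
            if any(
                c.locus.overlaps(iv) and c.locus.start <= lo and c.locus.end >= hi
                for c in cands
            ):
                hits += 1
        assert hits / trials >= 0.8

    def test_shuffled_decoys_mostly_rejected(self):
        rng = np.random.default_rng(9)
        rejected = 0
        trials = 25
        for t in range(trials):
            pre = sd.build_precursor(rng, pid=f"p{t}")
            dec = dinucleotide_shuffle(to_dna(pre.sequence), rng)
            genome = {"c": "ACGT" * 80 + dec + "TTGCA" * 60}
            s = int(rng.integers(0, len(dec) - 21))
            tag = dec[s : s + 21]
            placements = md.map_tags_exact([tag], genome)
            cands = md.extract_precursor_windows(
                placements, genome, {tag: 50}, annotation=None
            )
            if not cands:
                rejected += 1
        assert rejected / trials >= 0.8


class TestAscertainment:
    def _setup(self, star_reads: bool, star_in_catalog: bool):
        rng = np.random.default_rng(11)
        pres = [sd.build_precursor(rng, pid=f"p{i}", arm="5p") for i in range(2)]
        genome, decoys, bed = sd.assemble_genome(rng, pres, n_decoys=2, spacer_length=300)
        pre = pres[0]
        tag_m = to_dna(pre.mature_seq)
        tag_s = to_dna(pre.star_seq)
        tag_m2 = to_dna(pres[1].mature_seq)
        libs = {"l1": {tag_m: 120, tag_m2: 80}}
        if star_reads:
            libs["l1"][tag_s] = 5
        counts = pd.DataFrame(libs).fillna(0).astype(int)
        counts.index.name = "sequence"
        placements = md.map_tags_exact(counts.index, genome)
        abundance = {t: int(c) for t, c in counts.sum(axis=1).items()}
        cands = md.extract_precursor_windows(placements, genome, abundance, annotation=bed)
        catalog = [("tae-miR9000a-3p*", to_rna(tag_s))] if star_in_catalog else []
        mirnas = md.ascertain_mirnas(
            cands, placements, counts, set(counts.index), catalog
        )
        return pre, mirnas

    def test_star_reads_give_star_evidence(self):
        pre, mirnas = self._setup(star_reads=True, star_in_catalog=False)
        m = next(x for x in mirnas if x.sequence == to_dna(pre.mature_seq))
        assert m.star_evidence
        assert m.star_sequence == to_dna(pre.star_seq)

    def test_no_star_reads_no_catalog_no_evidence(self):
        pre, mirnas = self._setup(star_reads=False, star_in_catalog=False)
        m = next(x for x in mirnas if x.sequence == to_dna(pre.mature_seq))
        assert not m.star_evidence
        assert m.star_sequence == to_dna(pre.star_seq)  # still predicted

    def test_catalog_star_gives_star_evidence(self):
        pre, mirnas = self._setup(star_reads=False, star_in_catalog=True)
        m = next(x for x in mirnas if x.sequence == to_dna(pre.mature_seq))
        assert m.star_evidence

    def test_mirna_occurs_verbatim_in_its_precursor(self):
        pre, mirnas = self._setup(star_reads=True, star_in_catalog=False)
        assert mirnas  # the span-vs-sequence assertion runs inside ascertain

    def test_decoy_only_tag_not_ascertained(self):
        rng = np.random.default_rng(12)
        pres = [sd.build_precursor(rng, pid="p0")]
        genome, decoys, bed = sd.assemble_genome(rng, pres, n_decoys=5, spacer_length=300)
        dec = decoys[0]
        seg = genome[dec.chrom][dec.start : dec.start + 21]
        counts = pd.DataFrame({"l1": {seg: 200}})
        counts.index.name = "sequence"
        placements = md.map_tags_exact(counts.index, genome)
        only_decoy = placements[placements.apply(
            lambda r: any(d.chrom == r.chrom and d.start <= r.start and r.end <= d.end
                          for d in decoys), axis=1)]
        assert not only_decoy.empty  # maps to the decoy...
        cands = md.extract_precursor_windows(
            placements, genome, {seg: 200}, annotation=bed
        )
        mirnas = md.ascertain_mirnas(cands, placements, counts, {seg}, [])
        assert all(not m.precursor_id.startswith("decoy") for m in mirnas)


class TestFamilyAssignment:
    CATALOG = [
        ("tae-miR166a-5p", "UCGGACCAGGCUUCAUUCCCC"),
        ("tae-miR167b-5p", "UCGGACCAGGCUUCAUUCCCA"),
        ("tae-miR528a-5p", "AAGGGGUGGGGUCGGGCUCGC"),
    ]

    def test_exact_hit(self):
        assert md.assign_family("AAGGGGTGGGGTCGGGCTCGC", self.CATALOG) == "miR528"

    def test_three_mismatches_is_novel(self):
        seq = "AAGGGGTGGGGTCGGGCGAAA"  # 3 edits from miR528a
        assert md.assign_family(seq, self.CATALOG) == "novel"

    def test_tie_breaks_to_smallest_family(self):
        # 1 mismatch from both miR166a and miR167b
        seq = "TCGGACCAGGCTTCATTCCCG"
        assert md.assign_family(seq, self.CATALOG) == "miR166"

    def test_empty_catalog_novel(self):
        assert md.assign_family("ACGTACGTACGTACGTACGT", []) == "novel"

    def test_length_difference_window(self):
        long_seq = "AA" + "AAGGGGTGGGGTCGGGCTCGC" + "TT"  # +4 nt: too long
        assert md.assign_family(long_seq, self.CATALOG) == "novel"


class TestNaming:
    def _mirnas(self, order=(0, 1, 2)):
        rng = np.random.default_rng(21)
        pres = [sd.build_precursor(rng, pid=f"p{i}", arm="5p") for i in range(2)]
        genome, _, bed = sd.assemble_genome(rng, pres, n_decoys=0, spacer_length=200)
        pre = pres[0]
        tags = {
            to_dna(pre.mature_seq): 100,
            to_dna(pre.sequence[pre.mature_span[0] + 1 : pre.mature_span[1] + 1]): 40,
            to_dna(pres[1].mature_seq): 60,
        }
        counts = pd.DataFrame({"l1": tags})
        counts.index.name = "sequence"
        counts = counts.iloc[list(order)]
        placements = md.map_tags_exact(counts.index, genome)
        abundance = {t: int(c) for t, c in counts.sum(axis=1).items()}
        cands = md.extract_precursor_windows(placements, genome, abundance, annotation=bed)
        catalog = [("tae-miR528a-5p", to_rna(pre.mature_seq)),
                   ("tae-miR166a-5p", to_rna(pres[1].mature_seq))]
        mirnas = md.ascertain_mirnas(cands, placements, counts, set(counts.index), catalog)
        return md.name_mirnas(mirnas, cands, catalog), pres

    def test_isomir_variant_numbering(self):
        named, pres = self._mirnas()
        mine = sorted(
            [m for m in named if m.precursor_id == "p0"], key=lambda m: m.name
        )
        assert [m.name for m in mine] == ["miR528-1.1-5p", "miR528-1.2-5p"]
        # variant .1 is the more abundant one
        assert mine[0].total_count > mine[1].total_count

    def test_names_invariant_to_input_order(self):
        a, _ = self._mirnas(order=(0, 1, 2))
        b, _ = self._mirnas(order=(2, 0, 1))
        assert [m.name for m in a] == [m.name for m in b]

    def test_isomir_groups_table(self):
        named, _ = self._mirnas()
        groups = md.isomir_groups(named)
        g0 = groups[groups.precursor_id == "p0"]
        assert set(g0["shift_5p"]) == {0, 1}
        assert (g0["group_size"] == 2).all()
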