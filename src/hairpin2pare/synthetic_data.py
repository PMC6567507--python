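"""Synthetic sRNA-seq and PARE data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 24 libraries (2 treatments x 3 timepoints x 4 replicates), 18-24 nt
small-RNA reads dominated by the 21- and 24-nt size classes, hairpin
precursors carrying miRNA/miRNA* duplexes with 2-nt 3' overhangs and 1-3 nt
isomiR end shifts, planted heat-responsive fold changes with a recovery
profile over timepoints, dinucleotide-shuffled decoy loci as negative
controls for discovery specificity, and degradome libraries whose 5'-end
peaks sit at miRNA-guided cleavage sites.

Counts are negative binomial with variance mu + phi*mu^2 (phi default 0.1,
typical sRNA-seq overdispersion). isomiR proportions are drawn once per
precursor from a Dirichlet and held fixed across libraries.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rna_fold
from .io_core import GenomicInterval, Library, SampleSheet, write_bed, write_fasta, write_fastq
from .seqs import complement_rna, dinucleotide_shuffle, random_seq, revcomp, to_dna, to_rna

# background fragment length profile: 18..30 nt with a 24-nt mode
_BG_LENGTHS = np.arange(18, 31)
_BG_WEIGHTS = np.array([2, 2, 3, 4, 5, 6, 14, 6, 4, 3, 2, 1, 1], dtype=float)
_BG_WEIGHTS /= _BG_WEIGHTS.sum()

_FAMILY_POOL = [
    "miR156", "miR159", "miR166", "miR167", "miR169", "miR319", "miR393",
    "miR398", "miR399", "miR528", "miR1118", "miR1120", "miR1121", "miR1122",
    "miR1135", "miR1136", "miR9662", "miR9772",
]


@dataclass
class PlantedPrecursor:
    """A hairpin precursor with planted mature/star duplex geometry.

    Spans are half-open on the precursor. The mature/star duplex has 2-nt 3'
    overhangs on both ends by construction; isomiR offsets are (5' shift,
    3' shift) pairs with each shift in [-3, +3].
    """

    id: str
    sequence: str  # RNA
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str  # arm carrying the mature sequence: 5p | 3p
    isomir_offsets: list[tuple[int, int]] = field(default_factory=list)
    family: str = ""
    genome_placement: GenomicInterval | None = None

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_span[0] : self.mature_span[1]]

    @property
    def star_seq(self) -> str:
        return self.sequence[self.star_span[0] : self.star_span[1]]

    def variant_spans(self) -> list[tuple[str, tuple[int, int]]]:
        """Mature plus isomiR spans as (label, span)."""
        out = [("m", self.mature_span)]
        ms, me = self.mature_span
        for k, (d5, d3) in enumerate(self.isomir_offsets, 1):
            out.append((f"i{k}", (ms + d5, me + d3)))
        return out


def build_precursor(
    rng: np.random.Generator,
    mature_length: int = 21,
    stem_mismatches: int = 1,
    loop_length: int = 8,
    flank_length: int = 15,
    arm: str | None = None,
    n_isomirs: int = 2,
    pid: str = "pre-1",
    validate_fold: bool = True,
) -> PlantedPrecursor:
    """Construct flank + arm + loop + arm + flank with a planted duplex.

    The star strand is the complement of the mature offset so that both 3'
    ends overhang the duplex by exactly 2 nt. ``stem_mismatches`` pairs are
    converted to G:U wobbles (weakening the stem without moving it). When
    ``validate_fold`` is set the construction is resampled until the built-in
    folder recovers the planted duplex anchors, so the geometry is guaranteed
    on the generator's own output.
    """
    if not (19 <= mature_length <= 24):
        raise ValueError("mature_length must be in [19, 24]")
    if loop_length < 4:
        raise ValueError("loop_length must be >= 4 (hairpin cannot fold)")
    L = mature_length
    if arm is None:
        arm = "5p" if rng.integers(0, 2) == 0 else "3p"
    if arm not in ("5p", "3p"):
        raise ValueError(f"invalid arm {arm!r}")

    mature = random_seq(rng, L)
    for attempt in range(60):
        if attempt and attempt % 20 == 0:
            mature = random_seq(rng, L)
        # duplex partner: star[j] pairs mature[L-3-j] for j in 0..L-3,
        # last two star bases are the star's unpaired 3' overhang
        star = [complement_rna(mature[L - 3 - j]) for j in range(L - 2)]
        star += list(random_seq(rng, 2))
        # G:U wobbles at random paired positions
        wobble_idx = [j for j in range(L - 2) if mature[L - 3 - j] in "GU"]
        rng.shuffle(wobble_idx)
        for j in wobble_idx[:stem_mismatches]:
            star[j] = "U" if mature[L - 3 - j] == "G" else "G"
        star = "".join(star)
        loop = random_seq(rng, loop_length)
        f5 = random_seq(rng, flank_length)
        f3 = random_seq(rng, flank_length)
        if arm == "5p":
            seq = f5 + mature + loop + star + f3
            mspan = (flank_length, flank_length + L)
            sspan = (flank_length + L + loop_length, flank_length + 2 * L + loop_length)
        else:
            seq = f5 + star + loop + mature + f3
            sspan = (flank_length, flank_length + L)
            mspan = (flank_length + L + loop_length, flank_length + 2 * L + loop_length)
        pre = PlantedPrecursor(pid, seq, mspan, sspan, arm)
        if not validate_fold:
            break
        fr = rna_fold.fold(seq)
        ok, _ = rna_fold.is_hairpin(fr, mature_span=mspan)
        pt = fr.pair_table
        m5, m3 = mspan[0], mspan[1] - 1
        s5, s3 = sspan[0], sspan[1] - 1
        if ok and pt[m3 - 2] == s5 and pt[m5] == s3 - 2:
            break
    else:
        raise RuntimeError(f"could not build a fold-validated precursor for {pid}")

    # isomiR end shifts, 1-3 nt, kept within the precursor and the 18-24 nt
    # size window, never swallowing the whole loop
    offsets: list[tuple[int, int]] = []
    seen = {(0, 0)}
    tries = 0
    while len(offsets) < n_isomirs and tries < 50:
        tries += 1
        d5, d3 = int(rng.integers(-3, 4)), int(rng.integers(-3, 4))
        if (d5, d3) in seen or (d5 == 0 and d3 == 0):
            continue
        s, e = mspan[0] + d5, mspan[1] + d3
        if not (0 <= s < e <= len(seq)) or not (18 <= e - s <= 24):
            continue
        if arm == "5p" and e > sspan[0]:
            continue
        if arm == "3p" and s < sspan[1]:
            continue
        seen.add((d5, d3))
        offsets.append((d5, d3))
    pre.isomir_offsets = offsets
    return pre


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def assemble_genome(
    rng: np.random.Generator,
    precursors: list[PlantedPrecursor],
    n_decoys: int,
    spacer_length: int = 1500,
    chrom_names: tuple[str, ...] = ("Chr1A", "Chr2B", "Chr3D"),
) -> tuple[dict[str, str], list[GenomicInterval], list[tuple[GenomicInterval, str]]]:
    """Interleave precursors and dinucleotide-shuffled decoy loci with random
    spacers over a few chromosomes; strands are random. Sets each precursor's
    genome_placement and returns (genome, decoy intervals, locus BED entries).
    """
    loci: list[tuple[str, str, object]] = []
    for pre in precursors:
        loci.append((pre.id, to_dna(pre.sequence), pre))
    for d in range(n_decoys):
        src = precursors[int(rng.integers(0, len(precursors)))]
        shuffled = dinucleotide_shuffle(to_dna(src.sequence), rng)
        loci.append((f"decoy-{d + 1}", shuffled, None))
    order = rng.permutation(len(loci))
    loci = [loci[i] for i in order]

    genome: dict[str, list[str]] = {c: [] for c in chrom_names}
    lengths = {c: 0 for c in chrom_names}
    decoys: list[GenomicInterval] = []
    bed: list[tuple[GenomicInterval, str]] = []
    for idx, (name, dna, pre) in enumerate(loci):
        chrom = chrom_names[idx % len(chrom_names)]
        spacer = random_seq(
            rng, int(rng.integers(spacer_length // 2, spacer_length * 3 // 2 + 1)), "ACGT"
        )
        genome[chrom].append(spacer)
        lengths[chrom] += len(spacer)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placed = dna if strand == "+" else revcomp(dna)
        iv = GenomicInterval(chrom, lengths[chrom], lengths[chrom] + len(dna), strand)
        genome[chrom].append(placed)
        lengths[chrom] += len(dna)
        bed.append((iv, name))
        if pre is None:
            decoys.append(iv)
        else:
            pre.genome_placement = iv
    for chrom in chrom_names:
        tail = random_seq(rng, spacer_length // 2, "ACGT")
        genome[chrom].append(tail)
    return {c: "".join(parts) for c, parts in genome.items()}, decoys, bed


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------

def build_truth(
    rng: np.random.Generator,
    precursors: list[PlantedPrecursor],
    timepoints=(0, 1, 4),
    rpm_total: float = 700_000.0,
    base_rpm_range=(100.0, 30_000.0),
    star_ratio_mean: float = 0.2,
    de_fraction: float = 0.3,
    min_abs_log2fc: float = 1.0,
    timepoint_lfc_profile=(1.0, 0.5, 0.25),
) -> pd.DataFrame:
    """One row per planted sequence variant (mature, isomiRs, star) with its
    true RPM mean in every design cell and the true heat-vs-control log2 fold
    change per timepoint. Non-DE variants have identical means everywhere;
    the DE subset scales the planted fold change by a per-timepoint recovery
    profile (full effect at 0 days after treatment, decaying afterwards)."""
    lo, hi = base_rpm_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(precursors)))
    n_de = int(round(de_fraction * len(precursors)))
    de_idx = set(rng.choice(len(precursors), size=n_de, replace=False).tolist())
    rows = []
    for i, pre in enumerate(precursors):
        labels = pre.variant_spans()
        alpha = np.array([8.0] + [1.0] * (len(labels) - 1))
        props = rng.dirichlet(alpha)
        star_ratio = float(np.exp(rng.normal(np.log(star_ratio_mean), 0.5)))
        lfc = 0.0
        if i in de_idx:
            sign = 1.0 if rng.integers(0, 2) == 0 else -1.0
            lfc = sign * (min_abs_log2fc + rng.exponential(0.75))
        star_arm = "3p" if pre.arm == "5p" else "5p"
        entries = [
            (f"{pre.id}:{lab}", lab, span, pre.arm, props[k])
            for k, (lab, span) in enumerate(labels)
        ]
        entries.append((f"{pre.id}:star", "star", pre.star_span, star_arm, star_ratio))
        for vid, lab, span, arm, prop in entries:
            row = {
                "variant_id": vid,
                "precursor_id": pre.id,
                "kind": "mature" if lab == "m" else ("star" if lab == "star" else "isomir"),
                "arm": arm,
                "sequence": to_dna(pre.sequence[span[0] : span[1]]),
                "span_start": span[0],
                "span_end": span[1],
                "base_rpm": base[i] * prop,
                "is_de": i in de_idx,
                "family": pre.family,
            }
            for t, tp in enumerate(timepoints):
                cell_lfc = lfc * timepoint_lfc_profile[t]
                row[f"log2fc_{tp}"] = cell_lfc
                row[f"rpm_control_{tp}"] = base[i] * prop
                row[f"rpm_heat_{tp}"] = base[i] * prop * 2.0 ** cell_lfc
            rows.append(row)
    truth = pd.DataFrame(rows)
    # scale the planted fraction of each library to rpm_total (the remainder
    # is background); scaling uses the across-cell mean so RPMs stay exact
    cell_cols = [c for c in truth.columns if c.startswith("rpm_")]
    scale = rpm_total / truth[cell_cols].mean(axis=1).sum()
    truth[cell_cols] = truth[cell_cols] * scale
    truth["base_rpm"] = truth["base_rpm"] * scale
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial via gamma-Poisson; Var = mu + phi*mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def planted_insert_counts(
    rng: np.random.Generator, truth: pd.DataFrame, treatment: str, timepoint: int,
    depth: int, dispersion: float,
) -> Counter:
    """Per-variant NB counts for one library (inserts in DNA space)."""
    mu = truth[f"rpm_{treatment}_{timepoint}"].to_numpy() * depth / 1e6
    counts = nb_draw(rng, mu, dispersion)
    out: Counter = Counter()
    for seq, n in zip(truth["sequence"], counts):
        if n > 0:
            out[seq] += int(n)
    return out


def background_inserts(rng: np.random.Generator, genome: dict[str, str], n: int) -> list[str]:
    """Random genomic fragments, 18-30 nt with a 24-nt mode, both strands."""
    chroms = list(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    lengths = rng.choice(_BG_LENGTHS, size=n, p=_BG_WEIGHTS)
    strands = rng.integers(0, 2, size=n)
    starts = rng.random(n)
    out = []
    for ci, ln, st, u in zip(chrom_idx, lengths, strands, starts):
        seq = genome[chroms[ci]]
        pos = int(u * (len(seq) - ln))
        frag = seq[pos : pos + ln]
        out.append(frag if st == 0 else revcomp(frag))
    return out


def generate_library_reads(
    rng: np.random.Generator,
    truth: pd.DataFrame,
    lib: Library,
    genome: dict[str, str],
    depth: int = 200_000,
    dispersion: float = 0.1,
    adapter: str = "TGGAATTCTCGGGTGCCAAGG",
    read_length: int = 50,
) -> list[str]:
    """Raw machine reads for one library: adapter-appended planted and
    background inserts truncated to the machine read length, shuffled."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    planted = planted_insert_counts(
        rng, truth, lib.treatment, lib.timepoint_days, depth, dispersion
    )
    n_planted = sum(planted.values())
    n_bg = max(0, depth - n_planted)
    inserts: list[str] = []
    for seq, n in planted.items():
        inserts.extend([seq] * n)
    inserts.extend(background_inserts(rng, genome, n_bg))
    reads = [(ins + adapter)[:read_length] for ins in inserts]
    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm]


# ---------------------------------------------------------------------------
# Transcripts and degradome
# ---------------------------------------------------------------------------

def build_transcripts(
    rng: np.random.Generator,
    mirna_seqs: dict[str, str],
    n_targets: int = 12,
    n_decoys: int = 6,
    transcript_length: int = 500,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Coding sequences with planted miRNA target sites.

    Each target transcript embeds the perfect reverse complement of one
    miRNA; decoy transcripts embed a dinucleotide-shuffled site instead (no
    real complementarity). Returns (transcripts, target truth table); the
    cleavage position is the transcript base paired to miRNA position 10.
    """
    names = list(mirna_seqs)
    if n_targets > len(names):
        raise ValueError("not enough miRNAs to plant the requested targets")
    rows = []
    transcripts = []
    chosen = [names[int(i)] for i in rng.choice(len(names), size=n_targets, replace=False)]
    for t, mir in enumerate(chosen):
        mseq = to_dna(mirna_seqs[mir])
        L = len(mseq)
        body = random_seq(rng, transcript_length, "ACGT")
        w = int(rng.integers(60, transcript_length - 60 - L))
        site = revcomp(mseq)
        tid = f"transcript_{t + 1:03d}"
        transcripts.append((tid, body[:w] + site + body[w + L :]))
        rows.append(
            {
                "transcript_id": tid,
                "mirna": mir,
                "site_start": w,
                "cleavage_pos": w + L - 10,
                "is_decoy": False,
            }
        )
    for d in range(n_decoys):
        mir = names[int(rng.integers(0, len(names)))]
        mseq = to_dna(mirna_seqs[mir])
        L = len(mseq)
        body = random_seq(rng, transcript_length, "ACGT")
        w = int(rng.integers(60, transcript_length - 60 - L))
        site = dinucleotide_shuffle(revcomp(mseq), rng)
        tid = f"decoy_transcript_{d + 1:03d}"
        transcripts.append((tid, body[:w] + site + body[w + L :]))
        rows.append(
            {
                "transcript_id": tid,
                "mirna": mir,
                "site_start": w,
                "cleavage_pos": -1,
                "is_decoy": True,
            }
        )
    return transcripts, pd.DataFrame(rows)


_PARE_LENGTHS = np.array([18, 19, 20, 21, 22])
_PARE_WEIGHTS = np.array([0.05, 0.25, 0.40, 0.25, 0.05])


def simulate_pare_library(
    rng: np.random.Generator,
    transcripts: list[tuple[str, str]],
    planted_targets: pd.DataFrame,
    signal_mean: float = 50.0,
    dispersion: float = 0.1,
    background_fraction: float = 0.5,
    n_background_positions: int = 40,
) -> list[tuple[str, str]]:
    """Degradome tags: 20-nt signal fragments whose 5' end sits exactly at
    each planted cleavage position, over a background of 5' ends at uniform
    positions with exponentially distributed per-position abundance."""
    seqs = dict(transcripts)
    reads: list[str] = []
    bg_mean = signal_mean * background_fraction / max(1e-9, 1.0 - background_fraction)
    for _, row in planted_targets.iterrows():
        if row["is_decoy"]:
            continue
        t = int(row["cleavage_pos"])
        seq = seqs[row["transcript_id"]]
        if not (0 <= t <= len(seq) - 20):
            raise ValueError(f"cleavage position {t} outside {row['transcript_id']}")
        n_sig = int(nb_draw(rng, signal_mean, dispersion))
        reads.extend([seq[t : t + 20]] * n_sig)
    for tid, seq in transcripts:
        n_bg = int(rng.poisson(bg_mean))
        if n_bg == 0:
            continue
        pos = rng.integers(0, len(seq) - 22, size=n_background_positions)
        weights = rng.exponential(1.0, size=n_background_positions)
        alloc = rng.multinomial(n_bg, weights / weights.sum())
        for p, k in zip(pos, alloc):
            if k == 0:
                continue
            ln = int(rng.choice(_PARE_LENGTHS, p=_PARE_WEIGHTS))
            reads.append(seq[int(p) : int(p) + ln])
    perm = rng.permutation(len(reads))
    return [(f"pare_{i + 1}", reads[j]) for i, j in enumerate(perm)]


# ---------------------------------------------------------------------------
# Catalog and full-dataset orchestration
# ---------------------------------------------------------------------------

def build_catalog(
    rng: np.random.Generator, precursors: list[PlantedPrecursor], fraction: float = 0.7
) -> list[tuple[str, str]]:
    """Known-miRNA catalog (miRBase-style headers) covering a fraction of the
    planted families; assigns each precursor its family name in place."""
    n_fam = max(1, min(len(_FAMILY_POOL), int(np.ceil(len(precursors) / 3))))
    fam_names = [_FAMILY_POOL[i % len(_FAMILY_POOL)] for i in range(n_fam)]
    for i, pre in enumerate(precursors):
        pre.family = fam_names[i % n_fam]
    known = set(
        rng.choice(sorted(set(fam_names)), size=int(round(fraction * n_fam)), replace=False)
    )
    catalog = []
    counters: Counter = Counter()
    for pre in precursors:
        if pre.family not in known:
            continue
        counters[pre.family] += 1
        k = counters[pre.family]
        star_arm = "3p" if pre.arm == "5p" else "5p"
        catalog.append((f"tae-{pre.family}{chr(96 + k)}-{pre.arm}", to_rna(pre.mature_seq)))
        catalog.append((f"tae-{pre.family}{chr(96 + k)}-{star_arm}*", to_rna(pre.star_seq)))
    return catalog


@dataclass
class SyntheticDataset:
    """Everything one run of the generator produces, plus lazy per-library
    read expansion (reads are only materialised when asked for)."""

    config: dict
    seed: int
    sample_sheet: SampleSheet
    precursors: list[PlantedPrecursor]
    decoy_intervals: list[GenomicInterval]
    genome: dict[str, str]
    locus_bed: list[tuple[GenomicInterval, str]]
    truth_mirna: pd.DataFrame
    catalog: list[tuple[str, str]]
    transcripts: list[tuple[str, str]]
    truth_targets: pd.DataFrame
    pare_tags: list[tuple[str, str]]
    _lib_seeds: dict[str, np.random.SeedSequence] = field(default_factory=dict)

    def library_reads(self, library_id: str) -> list[str]:
        sim = self.config["simulate"]
        lib = next(l for l in self.sample_sheet if l.library_id == library_id)
        rng = np.random.default_rng(self._lib_seeds[library_id])
        return generate_library_reads(
            rng,
            self.truth_mirna,
            lib,
            self.genome,
            depth=sim["depth"],
            dispersion=sim["dispersion"],
            adapter=sim["adapter"],
            read_length=sim["read_length"],
        )

    def target_mirna_seqs(self) -> dict[str, str]:
        mat = self.truth_mirna[self.truth_mirna["kind"] == "mature"]
        return dict(zip(mat["variant_id"], mat["sequence"]))

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.genome.items()), out / "genome.fa")
        write_bed(self.locus_bed, out / "loci.bed")
        write_bed(
            [(p.genome_placement, p.id) for p in self.precursors], out / "precursors.bed"
        )
        write_fasta(self.catalog, out / "catalog.fa")
        write_fasta(self.transcripts, out / "transcripts.fa")
        self.sample_sheet.write(out / "sample_sheet.tsv")
        self.truth_mirna.to_csv(out / "truth_mirna.tsv", sep="\t", index=False)
        self.truth_targets.to_csv(out / "truth_targets.tsv", sep="\t", index=False)
        write_fasta(self.pare_tags, out / "pare_tags.fa")
        srna = out / "srna"
        srna.mkdir(exist_ok=True)
        for lib in self.sample_sheet:
            reads = self.library_reads(lib.library_id)
            write_fastq(
                (
                    (f"{lib.library_id}_{i + 1}", r, "I" * len(r))
                    for i, r in enumerate(reads)
                ),
                srna / f"{lib.library_id}.fastq",
            )


def simulate_dataset(config: dict, seed: int) -> SyntheticDataset:
    """Deterministic full-dataset generation from a config and a seed."""
    sim = config["simulate"]
    design = config["design"]
    ss_master = np.random.SeedSequence(seed)
    n_streams = 6
    streams = ss_master.spawn(n_streams)
    rng_pre, rng_genome, rng_truth, rng_cat, rng_tx, rng_pare = (
        np.random.default_rng(s) for s in streams
    )

    sheet = SampleSheet.default_design(
        timepoints=tuple(design["timepoints"]), replicates=design["replicates"]
    )

    lo, hi = sim["mature_length_range"]
    precursors = []
    for i in range(sim["n_precursors"]):
        precursors.append(
            build_precursor(
                rng_pre,
                mature_length=int(rng_pre.integers(lo, hi + 1)),
                stem_mismatches=sim["stem_wobbles"],
                loop_length=sim["loop_length"],
                flank_length=sim["flank_length"],
                n_isomirs=int(rng_pre.integers(1, sim["max_isomirs"] + 1)),
                pid=f"pre-{i + 1}",
            )
        )
    catalog = build_catalog(rng_cat, precursors, sim["catalog_fraction"])
    genome, decoys, bed = assemble_genome(
        rng_genome, precursors, sim["n_decoys"], sim["spacer_length"]
    )
    truth = build_truth(
        rng_truth,
        precursors,
        timepoints=tuple(design["timepoints"]),
        rpm_total=sim["rpm_total"],
        base_rpm_range=tuple(sim["base_rpm_range"]),
        star_ratio_mean=sim["star_ratio_mean"],
        de_fraction=sim["de_fraction"],
        min_abs_log2fc=sim["min_abs_log2fc"],
        timepoint_lfc_profile=tuple(sim["timepoint_lfc_profile"]),
    )

    pare_cfg = sim["pare"]
    mat = truth[truth["kind"] == "mature"].sort_values("base_rpm", ascending=False)
    mir_seqs = dict(zip(mat["variant_id"], mat["sequence"]))
    transcripts, targets = build_transcripts(
        rng_tx,
        mir_seqs,
        n_targets=pare_cfg["n_target_transcripts"],
        n_decoys=pare_cfg["n_decoy_transcripts"],
        transcript_length=pare_cfg["transcript_length"],
    )
    pare_tags = simulate_pare_library(
        rng_pare,
        transcripts,
        targets,
        signal_mean=pare_cfg["signal_mean"],
        dispersion=sim["dispersion"],
        background_fraction=pare_cfg["background_fraction"],
        n_background_positions=pare_cfg["n_background_positions"],
    )

    lib_streams = ss_master.spawn(len(sheet))
    lib_seeds = {lib.library_id: s for lib, s in zip(sheet, lib_streams)}
    return SyntheticDataset(
        config=config,
        seed=seed,
        sample_sheet=sheet,
        precursors=precursors,
        decoy_intervals=decoys,
        genome=genome,
        locus_bed=bed,
        truth_mirna=truth,
        catalog=catalog,
        transcripts=transcripts,
        truth_targets=targets,
        pare_tags=pare_tags,
        _lib_seeds=lib_seeds,
    )
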