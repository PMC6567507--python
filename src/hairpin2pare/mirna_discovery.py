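"""miRNA ascertainment: exact tag mapping, hairpin-evidence assembly, star
prediction, isomiR grouping, family assignment and naming.

Biogenesis evidence for a tag requires (a) an exact placement inside a
retained hairpin candidate and (b) the tag not straddling the terminal loop.
Star support is evidence-grading, not a hard filter: a miRNA is reported
without star reads, but star_evidence is only set when the duplex shows the
canonical 2-nt 3' overhangs and the predicted star is either sequenced or
catalogued.

Candidate precursor loci come either from a supplied annotation (BED/GFF3)
or de novo from windows around tag clusters; both modes are provided because
locus derivation is upstream of the sequencing evidence itself.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rna_fold
from .io_core import GenomicInterval, RunManifest
from .seqs import revcomp, to_dna, to_rna

_FAMILY_RE = re.compile(r"(miR[0-9]+)")


# ---------------------------------------------------------------------------
# Exact mapping
# ---------------------------------------------------------------------------

def map_tags_exact(tags, genome: dict[str, str], seed_k: int = 18) -> pd.DataFrame:
    """All full-length 0-mismatch placements of each tag on both strands.

    Seed-and-verify against a k-mer index of the genome (k = 18, the minimum
    retained tag length). Tags containing N get no placements. Returns a
    DataFrame (tag, chrom, start, end, strand); a tag may occur many times.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in sorted(genome.items()):
        for pos in range(len(seq) - seed_k + 1):
            index.setdefault(seq[pos : pos + seed_k], []).append((chrom, pos))
    rows = []
    for tag in tags:
        t = to_dna(tag)
        if "N" in t or len(t) < seed_k:
            continue
        for query, strand in ((t, "+"), (revcomp(t), "-")):
            for chrom, pos in index.get(query[:seed_k], ()):
                if genome[chrom][pos : pos + len(query)] == query:
                    rows.append((tag, chrom, pos, pos + len(t), strand))
    return pd.DataFrame(rows, columns=["tag", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Precursor candidates
# ---------------------------------------------------------------------------

@dataclass
class PrecursorCandidate:
    """A candidate hairpin locus: window, oriented sequence, fold, and the
    single terminal loop (in precursor coordinates, 5'->3' on the locus
    strand)."""

    id: str
    locus: GenomicInterval
    sequence: str  # RNA, 5'->3' on the locus strand
    fold: rna_fold.FoldResult
    loop: tuple[int, int]  # innermost pair closing the terminal loop
    anchor_span: tuple[int, int]
    supporting_tags: list = field(default_factory=list)

    def genome_to_precursor(self, start: int, end: int) -> tuple[int, int]:
        if self.locus.strand == "+":
            return start - self.locus.start, end - self.locus.start
        return self.locus.end - end, self.locus.end - start


def _fold_window(genome, iv: GenomicInterval):
    seq = genome[iv.chrom][iv.start : iv.end]
    if iv.strand == "-":
        seq = revcomp(seq)
    return to_rna(seq)


def arm_duplex_ok(
    pair_table, span: tuple[int, int], max_span_slack: int = 4, min_stack: int = 14
) -> bool:
    """Mature-duplex criterion from plant miRNA annotation practice: the
    span must pair mostly (>= half its bases) into a compact duplex on the
    opposite arm - partners all outside the span, on one side, covering no
    more than the span length + a small bulge allowance, and forming at
    least one near-uninterrupted helix of min_stack stacked pairs (about two
    helical turns). Chance stems in retained hairpins are fragmented into
    short helices and fail this; genuine mature/star/isomiR arms pass."""
    s, e = span
    n = len(pair_table)
    s, e = max(s, 0), min(e, n)
    partners = [pair_table[p] for p in range(s, e) if pair_table[p] >= 0]
    if len(partners) < (e - s) / 2.0:
        return False
    lo, hi = min(partners), max(partners)
    if not (hi < s or lo >= e):  # self-pairing or loop-straddling span
        return False
    if (hi - lo + 1) > (e - s) + max_span_slack:
        return False
    run = best = 0
    for p in range(s, e):
        q = pair_table[p]
        if q >= 0 and p + 1 < n and pair_table[p + 1] == q - 1:
            run += 1
        elif q >= 0 and run > 0:
            run += 1  # closing pair of a stack
            best = max(best, run)
            run = 0
        else:
            best = max(best, run)
            run = 0
    best = max(best, run)
    return best >= min_stack


def _single_loop(fold, anchor_span):
    """The one terminal loop subtended by the anchor span's pairs."""
    loops = rna_fold.terminal_loops(fold.pair_table)
    pt = fold.pair_table
    subtended = set()
    for p in range(*anchor_span):
        if 0 <= p < len(pt) and pt[p] >= 0:
            a, b = sorted((p, pt[p]))
            subtended.update(l for l in loops if a <= l[0] and l[1] <= b)
    return sorted(subtended)[0] if subtended else None


def _anchor_tag_span(placements: pd.DataFrame, abundance: dict[str, int]):
    """Placement of the most abundant tag (ties: lexicographically smallest)."""
    best = None
    for row in placements.itertuples():
        key = (-abundance.get(row.tag, 0), row.tag, row.start)
        if best is None or key < best[0]:
            best = (key, row)
    return best[1]


def _refined_windows(genome, iv: GenomicInterval, anchor):
    """The window itself plus, when the fold suggests it, the window trimmed
    to the widest pair subtending the anchor tag (a second fold of the
    trimmed extent often recovers a clean hairpin that flanking sequence
    obscured)."""
    yield iv
    seq = _fold_window(genome, iv)
    fr = rna_fold.fold(seq)
    if iv.strand == "+":
        a_s, a_e = anchor.start - iv.start, anchor.end - iv.start
    else:
        a_s, a_e = iv.end - anchor.end, iv.end - anchor.start
    touching = [
        (i, j) for i, j in enumerate(fr.pair_table) if j > i and i < a_e and j >= a_s
    ]
    if not touching:
        return
    i, j = max(touching, key=lambda ij: ij[1] - ij[0])
    lo, hi = max(0, i - 2), min(len(seq), j + 3)
    if hi - lo < 40 or (lo < 3 and hi > len(seq) - 3):
        return
    if iv.strand == "+":
        yield GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi, iv.strand)
    else:
        yield GenomicInterval(iv.chrom, iv.end - hi, iv.end - lo, iv.strand)


def cluster_placements(placements: pd.DataFrame, max_gap: int = 15) -> list[pd.DataFrame]:
    """Merge placements within max_gap on the same chrom/strand."""
    clusters = []
    for (_, _), grp in placements.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end", "tag"])
        current: list[int] = []
        cur_end = None
        for idx, row in zip(grp.index, grp.itertuples()):
            if cur_end is not None and row.start > cur_end + max_gap:
                clusters.append(grp.loc[current])
                current = []
            current.append(idx)
            cur_end = row.end if cur_end is None else max(cur_end, row.end)
        if current:
            clusters.append(grp.loc[current])
    return clusters


def extract_precursor_windows(
    placements: pd.DataFrame,
    genome: dict[str, str],
    abundance: dict[str, int],
    flanks=(30, 60, 100, 150),
    threshold_per_nt: float = -0.2,
    annotation: list[tuple[GenomicInterval, str]] | None = None,
    cluster_gap: int = 15,
    manifest: RunManifest | None = None,
) -> list[PrecursorCandidate]:
    """Hairpin-passing precursor candidates.

    Annotation mode (loci supplied): each annotated interval carrying at
    least one same-strand placement is folded once and assessed with the most
    abundant tag as the mature anchor. De-novo mode: windows of increasing
    flank size around each tag cluster are folded and the lowest
    energy-per-nt window passing the hairpin test is retained.
    """
    candidates: list[PrecursorCandidate] = []
    n_assessed = 0
    if annotation is not None:
        for iv, name in annotation:
            sub = placements[
                (placements["chrom"] == iv.chrom)
                & (placements["strand"] == iv.strand)
                & (placements["start"] >= iv.start)
                & (placements["end"] <= iv.end)
            ]
            if sub.empty:
                continue
            n_assessed += 1
            seq = _fold_window(genome, iv)
            fr = rna_fold.fold(seq)
            anchor = _anchor_tag_span(sub, abundance)
            cand = PrecursorCandidate(name, iv, seq, fr, (0, 0), (0, 0))
            aspan = cand.genome_to_precursor(anchor.start, anchor.end)
            ok, _ = rna_fold.is_hairpin(fr, threshold_per_nt, aspan)
            if not ok or not arm_duplex_ok(fr.pair_table, aspan):
                continue
            loop = _single_loop(fr, aspan)
            if loop is None:
                continue
            cand.loop, cand.anchor_span = loop, aspan
            candidates.append(cand)
    else:
        for cl in cluster_placements(placements, cluster_gap):
            n_assessed += 1
            chrom = cl["chrom"].iloc[0]
            strand = cl["strand"].iloc[0]
            cs, ce = int(cl["start"].min()), int(cl["end"].max())
            anchor = _anchor_tag_span(cl, abundance)
            best = None
            # per flank size, try symmetric and one-sided extensions: the
            # hairpin partner arm lies to one side of the cluster, and extra
            # sequence on the far side only disturbs the fold
            shapes = []
            for f in flanks:
                shapes.extend([(f, f), (f, 2), (2, f)])
            for f5, f3 in shapes:
                ws = max(0, cs - f5)
                we = min(len(genome[chrom]), ce + f3)
                if we - ws < 40 or we - ws > 500:
                    continue
                for iv in _refined_windows(
                    genome, GenomicInterval(chrom, ws, we, strand), anchor
                ):
                    seq = _fold_window(genome, iv)
                    fr = rna_fold.fold(seq)
                    cand = PrecursorCandidate(
                        f"locus_{chrom}_{iv.start + 1}_{strand}", iv, seq, fr, (0, 0), (0, 0)
                    )
                    aspan = cand.genome_to_precursor(anchor.start, anchor.end)
                    ok, _ = rna_fold.is_hairpin(fr, threshold_per_nt, aspan)
                    if not ok or not arm_duplex_ok(fr.pair_table, aspan):
                        continue
                    loop = _single_loop(fr, aspan)
                    if loop is None:
                        continue
                    cand.loop, cand.anchor_span = loop, aspan
                    if best is None or fr.energy_per_nt < best.fold.energy_per_nt:
                        best = cand
            if best is not None:
                candidates.append(best)
    if manifest is not None:
        manifest.add("precursor_windows", "loci_assessed", n_assessed)
        manifest.add("precursor_windows", "candidates_retained", len(candidates))
    return candidates


# ---------------------------------------------------------------------------
# Star prediction
# ---------------------------------------------------------------------------

def predict_star(
    fold: rna_fold.FoldResult, mature_span: tuple[int, int]
) -> tuple[tuple[int, int] | None, str | None, bool]:
    """Star span from the duplex geometry: with p() the pairing partner,
    star = [p(m3 - 2), p(m5) + 2] (positions given for either arm by the
    same projection). Unpaired anchors are scanned <= 3 nt inward, the
    scanned offset carried into the projection. Returns (span, sequence,
    exact 2-nt 3'-overhang geometry on both ends).

    A mature span straddling the loop (anchors pairing inside the span
    itself) yields no star.
    """
    pt = fold.pair_table
    n = len(pt)
    m5, m3 = mature_span[0], mature_span[1] - 1
    if not (0 <= m5 < m3 < n):
        return None, None, False

    def scan_in(pos, direction):
        for off in range(0, 4):
            q = pos + direction * off
            if m5 <= q <= m3 and pt[q] >= 0:
                return q, off
        return None, None

    a1, off1 = scan_in(m3 - 2, -1)  # anchor for the star 5' end
    a2, off2 = scan_in(m5, +1)  # anchor for the star 3' end
    if a1 is None or a2 is None:
        return None, None, False
    p1, p2 = pt[a1], pt[a2]
    if m5 <= p1 <= m3 or m5 <= p2 <= m3:  # span straddles its own loop
        return None, None, False
    star_start = p1 - off1
    star_end = p2 + off2 + 2 + 1  # inclusive 3' end p(m5)+2, made half-open
    clamped = star_start < 0 or star_end > n
    star_start, star_end = max(0, star_start), min(n, star_end)
    if star_end - star_start < (m3 - m5 + 1) - 4:  # degenerate projection
        return None, None, False
    geometry_ok = (off1 == 0 and off2 == 0 and not clamped)
    return (star_start, star_end), fold.sequence[star_start:star_end], geometry_ok


# ---------------------------------------------------------------------------
# Ascertainment
# ---------------------------------------------------------------------------

@dataclass
class MatureMiRNA:
    name: str
    sequence: str  # DNA space
    precursor_id: str
    arm: str
    span: tuple[int, int]  # on the primary precursor
    star_sequence: str | None
    star_evidence: bool
    family: str
    multi_locus_count: int
    total_count: int
    locus_label: str


def _tag_straddles_loop(span, loop) -> bool:
    li, lj = loop
    return span[0] <= li and span[1] - 1 >= lj


def _arm_of(span, loop, seq_len) -> str:
    mid = (loop[0] + loop[1]) / 2.0
    center = (span[0] + span[1] - 1) / 2.0
    return "5p" if center < mid else "3p"


def ascertain_mirnas(
    candidates: list[PrecursorCandidate],
    placements: pd.DataFrame,
    tag_counts: pd.DataFrame,
    all_tag_seqs: set[str],
    catalog: list[tuple[str, str]] | None = None,
    manifest: RunManifest | None = None,
) -> list[MatureMiRNA]:
    """Turn filtered tags with hairpin evidence into mature miRNAs.

    A tag is ascertained iff it places inside a retained candidate on the
    locus strand and does not straddle the terminal loop. The ascertained
    record carries the predicted star, graded star evidence and the number
    of distinct retained loci the tag maps within.
    """
    catalog = catalog or []
    catalog_seqs = {to_dna(s) for _, s in catalog}
    totals = tag_counts.sum(axis=1)
    by_tag: dict[str, list] = {}
    cand_order = sorted(
        candidates, key=lambda c: (c.locus.chrom, c.locus.start, c.locus.strand)
    )
    for cand in cand_order:
        iv = cand.locus
        sub = placements[
            (placements["chrom"] == iv.chrom)
            & (placements["strand"] == iv.strand)
            & (placements["start"] >= iv.start)
            & (placements["end"] <= iv.end)
        ]
        for row in sub.itertuples():
            span = cand.genome_to_precursor(row.start, row.end)
            if _tag_straddles_loop(span, cand.loop):
                continue
            if not arm_duplex_ok(cand.fold.pair_table, span):
                continue
            by_tag.setdefault(row.tag, []).append((cand, span))

    mirnas = []
    for tag in sorted(by_tag, key=lambda t: (-int(totals.get(t, 0)), t)):
        hits = by_tag[tag]
        cand, span = hits[0]  # primary = first in genomic order
        assert to_dna(cand.sequence[span[0] : span[1]]) == to_dna(tag)
        star_span, star_seq, geometry_ok = predict_star(cand.fold, span)
        star_dna = to_dna(star_seq) if star_seq else None
        observed = star_dna in all_tag_seqs if star_dna else False
        in_catalog = star_dna in catalog_seqs if star_dna else False
        star_evidence = bool(geometry_ok and (observed or in_catalog))
        mirnas.append(
            MatureMiRNA(
                name="",  # assigned by name_mirnas
                sequence=to_dna(tag),
                precursor_id=cand.id,
                arm=_arm_of(span, cand.loop, len(cand.sequence)),
                span=span,
                star_sequence=star_dna,
                star_evidence=star_evidence,
                family="",
                multi_locus_count=len({c.id for c, _ in hits}),
                total_count=int(totals.get(tag, 0)),
                locus_label=cand.locus.label(),
            )
        )
    if manifest is not None:
        manifest.add("ascertainment", "tags_with_hairpin_evidence", len(by_tag))
        manifest.add("ascertainment", "mirnas_ascertained", len(mirnas))
        manifest.add(
            "ascertainment", "with_star_evidence", sum(m.star_evidence for m in mirnas)
        )
    return mirnas


# ---------------------------------------------------------------------------
# Families and names
# ---------------------------------------------------------------------------

def _best_ungapped(a: str, b: str) -> int:
    """Minimum Hamming distance sliding the shorter inside the longer."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a) + 1
    for off in range(len(b) - len(a) + 1):
        d = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, d)
    return best


def assign_family(
    sequence: str,
    catalog: list[tuple[str, str]],
    max_mismatches: int = 2,
    max_len_diff: int = 2,
) -> str:
    """Family of the best catalog match (<= 2 mismatches, length diff <= 2,
    ungapped); ties go to the lexicographically smallest family; no match
    (or an empty catalog) gives 'novel'."""
    seq = to_dna(sequence)
    best: tuple[int, str] | None = None
    for cid, cseq in catalog:
        cs = to_dna(cseq)
        if abs(len(cs) - len(seq)) > max_len_diff:
            continue
        d = _best_ungapped(seq, cs)
        if d > max_mismatches:
            continue
        m = _FAMILY_RE.search(cid)
        fam = m.group(1) if m else cid
        if best is None or (d, fam) < best:
            best = (d, fam)
    return best[1] if best else "novel"


def name_mirnas(
    mirnas: list[MatureMiRNA],
    candidates: list[PrecursorCandidate],
    catalog: list[tuple[str, str]] | None = None,
    max_mismatches: int = 2,
    max_len_diff: int = 2,
) -> list[MatureMiRNA]:
    """Assign families and deterministic names family-precursorIndex.variant-arm
    (miR528-1.2-5p pattern): precursors within a family numbered by genomic
    order, variants within a precursor by descending total abundance."""
    catalog = catalog or []
    loci = {c.id: c.locus for c in candidates}
    for m in mirnas:
        m.family = assign_family(m.sequence, catalog, max_mismatches, max_len_diff)

    # family label for novels: one pseudo-family per precursor group, numbered
    # by genomic order of first appearance
    precursor_family: dict[str, str] = {}
    for m in sorted(
        mirnas, key=lambda m: (loci[m.precursor_id].chrom, loci[m.precursor_id].start)
    ):
        if m.precursor_id in precursor_family:
            continue
        fams = sorted(
            {x.family for x in mirnas if x.precursor_id == m.precursor_id and x.family != "novel"}
        )
        precursor_family[m.precursor_id] = fams[0] if fams else "novel"
    novel_counter = 0
    for pid in sorted(
        precursor_family, key=lambda p: (loci[p].chrom, loci[p].start)
    ):
        if precursor_family[pid] == "novel":
            novel_counter += 1
            precursor_family[pid] = f"novel-{novel_counter}"

    # number precursors within each family by genomic order
    fam_precursors: dict[str, list[str]] = {}
    for pid in sorted(precursor_family, key=lambda p: (loci[p].chrom, loci[p].start)):
        fam_precursors.setdefault(precursor_family[pid], []).append(pid)
    pre_index = {
        pid: i + 1 for fam, pids in fam_precursors.items() for i, pid in enumerate(pids)
    }

    grouped: dict[str, list[MatureMiRNA]] = {}
    for m in mirnas:
        grouped.setdefault(m.precursor_id, []).append(m)
    for pid, members in grouped.items():
        members.sort(key=lambda m: (-m.total_count, m.sequence))
        fam = precursor_family[pid]
        for v, m in enumerate(members, 1):
            m.family = fam if not fam.startswith("novel-") else "novel"
            m.name = f"{fam}-{pre_index[pid]}.{v}-{m.arm}"
    mirnas.sort(key=lambda m: m.name)
    return mirnas


def isomir_groups(mirnas: list[MatureMiRNA]) -> pd.DataFrame:
    """Per-precursor isomiR groups with pairwise 5'/3' shifts vs the most
    abundant member."""
    rows = []
    grouped: dict[str, list[MatureMiRNA]] = {}
    for m in mirnas:
        grouped.setdefault(m.precursor_id, []).append(m)
    for pid in sorted(grouped):
        members = sorted(grouped[pid], key=lambda m: (-m.total_count, m.sequence))
        ref = members[0]
        for m in members:
            rows.append(
                {
                    "precursor_id": pid,
                    "name": m.name,
                    "sequence": m.sequence,
                    "arm": m.arm,
                    "shift_5p": m.span[0] - ref.span[0] if m.arm == ref.arm else np.nan,
                    "shift_3p": m.span[1] - ref.span[1] if m.arm == ref.arm else np.nan,
                    "group_size": len(members),
                }
            )
    return pd.DataFrame(rows)


def mirna_table(mirnas: list[MatureMiRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": m.name,
                "sequence": m.sequence,
                "precursor_locus": m.locus_label,
                "precursor_id": m.precursor_id,
                "arm": m.arm,
                "star_sequence": m.star_sequence or "",
                "star_evidence": m.star_evidence,
                "family": m.family,
                "multi_locus_count": m.multi_locus_count,
                "total_count": m.total_count,
            }
            for m in mirnas
        ]
    )


def mirna_counts(mirnas: list[MatureMiRNA], tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Count matrix (miRNA name x library) for differential expression."""
    rows = [m.sequence for m in mirnas]
    seqs = tag_counts.index
    dna_index = {to_dna(s): s for s in seqs}
    out = tag_counts.loc[[dna_index[r] for r in rows]].copy()
    out.index = pd.Index([m.name for m in mirnas], name="mirna")
    return out
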