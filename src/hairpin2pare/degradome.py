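"""PARE/degradome stage: 5'-end profiles, plant miRNA target scoring,
cleavage-site categorization, shuffle-based significance and t-plot tables.

Target scoring uses the classical plant-targeting penalty scheme on the
ungapped antisense alignment: match 0, G:U wobble 0.5, mismatch 1.0, with
penalties doubled at miRNA positions 2-13 (1-based from the miRNA 5' end).
The cleavage site is the transcript nucleotide paired to miRNA position 10;
its significance is assessed against dinucleotide-preserving shuffles of
the miRNA re-run through the identical search.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqs import dinucleotide_shuffle, to_dna

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# penalty[miRNA base, target base]: Watson-Crick 0, G:U wobble 0.5, else 1
_PEN = np.ones((5, 5))
for _m, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PEN[_ENC[_m], _ENC[_t]] = 0.0
_PEN[_ENC["G"], _ENC["T"]] = 0.5
_PEN[_ENC["T"], _ENC["G"]] = 0.5


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in to_dna(seq)], dtype=np.int64)


def _position_weights(L: int) -> np.ndarray:
    """Alignment-column weights: column j faces miRNA position L - j
    (1-based from the miRNA 5' end); core positions 2-13 are doubled."""
    k = L - np.arange(L)  # miRNA position per column
    return np.where((k >= 2) & (k <= 13), 2.0, 1.0)


@dataclass
class DegradomeProfile:
    transcript_id: str
    length: int
    abundance: np.ndarray  # raw 5'-end counts per 0-based position

    @property
    def total(self) -> int:
        return int(self.abundance.sum())


def build_profiles(
    tag_counts: Mapping[str, int], transcripts: Iterable[tuple[str, str]]
) -> dict[str, DegradomeProfile]:
    """Exact full-length sense-strand placements of degradome tags; each
    placement adds the tag count to the 5'-end position. Multi-mapping tags
    increment every placement."""
    profiles = {
        tid: DegradomeProfile(tid, len(seq), np.zeros(len(seq), dtype=np.int64))
        for tid, seq in transcripts
    }
    seqs = dict(transcripts)
    for tag, count in tag_counts.items():
        t = to_dna(tag)
        for tid, seq in seqs.items():
            start = seq.find(t)
            while start != -1:
                profiles[tid].abundance[start] += count
                start = seq.find(t, start + 1)
    return profiles


# ---------------------------------------------------------------------------
# Target scoring
# ---------------------------------------------------------------------------

def score_target(mirna: str, transcript_window: str) -> tuple[float, str]:
    """Penalty score of the antisense alignment of a miRNA against an
    equal-length transcript window, plus a printable alignment."""
    m = _encode(mirna)
    t = _encode(transcript_window)
    if len(m) != len(t):
        raise ValueError("window length must equal miRNA length (ungapped mode)")
    L = len(m)
    w = _position_weights(L)
    pen = _PEN[m[::-1], t]
    score = float(np.sum(w * pen))
    sym = "".join(
        "|" if p == 0 else ("o" if p == 0.5 else " ") for p in pen
    )
    mir = to_dna(mirna)
    align = (
        f"target 5' {to_dna(transcript_window)} 3'\n"
        f"          {sym}\n"
        f"miRNA  3' {mir[::-1]} 5'"
    )
    return score, align


def scan_transcript(mirna: str, transcript: str) -> np.ndarray:
    """Scores of every window start (vectorized sliding scan)."""
    m = _encode(mirna)[::-1]
    t = _encode(transcript)
    L = len(m)
    if len(t) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    w = _position_weights(L)
    scores = np.zeros(windows.shape[0])
    for j in range(L):
        scores += w[j] * _PEN[m[j], windows[:, j]]
    return scores


def find_candidate_sites(
    mirna: str, transcripts: Iterable[tuple[str, str]], threshold: float = 6.0
) -> list[tuple[str, int, float]]:
    """(transcript_id, window_start, score) for all windows scoring <=
    threshold."""
    out = []
    for tid, seq in transcripts:
        scores = scan_transcript(mirna, seq)
        for w in np.flatnonzero(scores <= threshold):
            out.append((tid, int(w), float(scores[w])))
    return out


def locate_cleavage(window_start: int, mirna_length: int) -> int:
    """Transcript position paired to miRNA position 10.

    With miRNA position 1 pairing transcript position t = window_start +
    L - 1 (antisense), the cleavage position is t - 9; the 5' end of the 3'
    cleavage fragment sits here."""
    if mirna_length < 10:
        raise ValueError("alignment shorter than 10 nt has no position 10")
    return window_start + mirna_length - 10


def categorize(profile: DegradomeProfile, cleavage_pos: int) -> int | None:
    """Degradome peak category ladder: 0 unique maximum, 1 tied maximum,
    2 above the median of nonzero positions, 3 otherwise, 4 a single read;
    None when no read starts at the cleavage position."""
    if profile.total <= 0:
        raise ValueError("profile has no reads")
    a = int(profile.abundance[cleavage_pos])
    if a == 0:
        return None
    if a == 1:
        return 4
    nz = profile.abundance[profile.abundance > 0]
    mx = int(nz.max())
    if a == mx:
        return 0 if int((profile.abundance == mx).sum()) == 1 else 1
    return 2 if a > float(np.median(nz)) else 3


def target_pvalue(
    mirna: str,
    transcripts: list[tuple[str, str]],
    profiles: dict[str, DegradomeProfile],
    observed_score: float,
    observed_category: int,
    n_shuffles: int,
    rng: np.random.Generator,
    score_threshold: float = 6.0,
) -> float:
    """Empirical p-value from dinucleotide-preserving miRNA shuffles.

    Each shuffle re-runs the identical transcriptome search; a shuffle
    succeeds when it yields any site with score <= the observed score AND a
    degradome category <= the observed category. p = (1 + successes) /
    (n_shuffles + 1)."""
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    thr = min(score_threshold, observed_score)
    successes = 0
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(to_dna(mirna), rng)
        for tid, w, s in find_candidate_sites(shuf, transcripts, thr):
            prof = profiles.get(tid)
            if prof is None or prof.total == 0:
                continue
            c = locate_cleavage(w, len(shuf))
            if not (0 <= c < prof.length):
                continue
            cat = categorize(prof, c)
            if cat is not None and cat <= observed_category:
                successes += 1
                break
    return (1.0 + successes) / (n_shuffles + 1.0)


# ---------------------------------------------------------------------------
# Pipeline and reports
# ---------------------------------------------------------------------------

def find_targets(
    mirna_seqs: Mapping[str, str],
    transcripts: list[tuple[str, str]],
    tag_counts: Mapping[str, int],
    rng: np.random.Generator,
    score_threshold: float = 6.0,
    n_shuffles: int = 100,
) -> pd.DataFrame:
    """Full target search: candidate sites, cleavage positions, degradome
    abundance and category, shuffle p-values. Cleavage positions are
    reported 1-based."""
    profiles = build_profiles(tag_counts, transcripts)
    seqs = dict(transcripts)
    rows = []
    for name in sorted(mirna_seqs):
        mseq = to_dna(mirna_seqs[name])
        sites = find_candidate_sites(mseq, transcripts, score_threshold)
        for tid, w, score in sites:
            prof = profiles[tid]
            c = locate_cleavage(w, len(mseq))
            if not (0 <= c < prof.length) or prof.total == 0:
                continue
            cat = categorize(prof, c)
            if cat is None:
                continue
            abundance = int(prof.abundance[c])
            _, align = score_target(mseq, seqs[tid][w : w + len(mseq)])
            p = target_pvalue(
                mseq, transcripts, profiles, score, cat, n_shuffles, rng, score_threshold
            )
            rows.append(
                {
                    "mirna": name,
                    "transcript_id": tid,
                    "score": score,
                    "cleavage_pos": c + 1,
                    "pare_abundance": abundance,
                    "category": cat,
                    "p_value": p,
                    "alignment": align.replace("\n", "; "),
                }
            )
    cols = [
        "mirna", "transcript_id", "score", "cleavage_pos", "pare_abundance",
        "category", "p_value", "alignment",
    ]
    return pd.DataFrame(rows, columns=cols)


def filter_and_report(
    hits: pd.DataFrame,
    profiles: dict[str, DegradomeProfile] | None = None,
    p_threshold: float = 0.05,
    min_abundance: int = 4,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Retain hits with p < 0.05 and raw cleavage-site abundance > 4 (both
    strict), and emit per-hit t-plot tables."""
    if hits.empty:
        return hits.copy(), {}
    keep = (hits["p_value"] < p_threshold) & (hits["pare_abundance"] > min_abundance)
    retained = hits.loc[keep].reset_index(drop=True)
    tplots = {}
    if profiles is not None:
        for row in retained.itertuples():
            prof = profiles[row.transcript_id]
            tplots[f"{row.mirna}@{row.transcript_id}"] = tplot_table(
                prof, row.cleavage_pos - 1
            )
    return retained, tplots


def tplot_table(profile: DegradomeProfile, cleavage_pos: int) -> pd.DataFrame:
    """Target-plot content: per-position degradome abundance with the
    predicted cleavage site flagged (positions 1-based)."""
    return pd.DataFrame(
        {
            "position": np.arange(1, profile.length + 1),
            "abundance": profile.abundance,
            "is_cleavage_site": np.arange(profile.length) == cleavage_pos,
        }
    )


def collapse_pare_tags(seqs: Iterable[str], min_len: int = 19, max_len: int = 21) -> Counter:
    """Size-select and collapse degradome reads into distinct tags."""
    out: Counter = Counter()
    for s in seqs:
        if min_len <= len(s) <= max_len:
            out[to_dna(s)] += 1
    return out
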