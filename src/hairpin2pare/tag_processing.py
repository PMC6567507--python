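"""Read-to-tag stage: adapter trimming, size selection, tag collapsing and
reads-per-million (RPM) filtering.

Tags live in a pandas DataFrame indexed by sequence with one integer count
column per library, ordered by descending total count (ties lexicographic).
RPM is computed against each library's retained-read total.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_core import RunManifest


def trim_adapter(read: str, adapter: str, min_overlap: int = 7) -> str | None:
    """Insert preceding the leftmost occurrence of the longest matching
    adapter prefix (>= min_overlap nt, exact match). Returns None when no
    adapter evidence is found (the read carries no insert-size information).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper()
    adapter = adapter.upper()
    n, m = len(read), len(adapter)
    for p in range(0, n - min_overlap + 1):
        ov = min(n - p, m)
        if read[p : p + ov] == adapter[:ov]:
            return read[:p]
    return None


def trim_library(reads: Iterable[str], adapter: str, min_overlap: int = 7,
                 manifest: RunManifest | None = None, stage: str = "trim") -> list[str]:
    out = []
    n_in = n_rejected = 0
    for read in reads:
        n_in += 1
        insert = trim_adapter(read, adapter, min_overlap)
        if insert is None or not insert:
            n_rejected += 1
        else:
            out.append(insert)
    if manifest is not None:
        manifest.add(stage, "reads_in", n_in)
        manifest.add(stage, "reads_out", len(out))
        manifest.add(stage, "reads_rejected_no_adapter_or_empty", n_rejected)
    return out


def size_select(seqs: Iterable[str], min_len: int, max_len: int,
                manifest: RunManifest | None = None, stage: str = "size_select") -> list[str]:
    """Retain sequences with min_len <= length <= max_len."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    seqs = list(seqs)
    kept = [s for s in seqs if min_len <= len(s) <= max_len]
    if manifest is not None:
        manifest.add(stage, "reads_in", len(seqs))
        manifest.add(stage, "reads_out", len(kept))
    return kept


def collapse_tags(reads_per_library: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Collapse reads to distinct tags with per-library counts.

    Deterministic row order: descending total count, ties lexicographic by
    sequence. Columns follow the input library order.
    """
    counters = {lib: Counter(reads_per_library[lib]) for lib in reads_per_library}
    return collapse_counters(counters)


def collapse_counters(counters: Mapping[str, Counter]) -> pd.DataFrame:
    """Same as collapse_tags but from pre-counted per-library Counters."""
    libraries = list(counters)
    sequences: set[str] = set()
    for c in counters.values():
        sequences.update(c)
    idx = pd.Index(sorted(sequences), name="sequence")
    df = pd.DataFrame(
        {lib: [counters[lib].get(s, 0) for s in idx] for lib in libraries},
        index=idx,
        dtype=np.int64,
    )
    order = df.sum(axis=1).sort_values(ascending=False, kind="stable").index
    return df.loc[order]


def library_totals(tags: pd.DataFrame) -> pd.Series:
    return tags.sum(axis=0)


def rpm(tags: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Reads per million per library; totals default to the tag-table sums."""
    if totals is None:
        totals = library_totals(tags)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"library with zero retained reads: {list(zero.index)}")
    return tags * 1e6 / totals


def rpm_filter(tags: pd.DataFrame, threshold: float = 10.0,
               totals: pd.Series | None = None,
               manifest: RunManifest | None = None) -> pd.DataFrame:
    """Keep tags reaching >= threshold RPM in at least one library."""
    rpm_df = rpm(tags, totals)
    kept = tags.loc[rpm_df.max(axis=1) >= threshold]
    if manifest is not None:
        manifest.add("rpm_filter", "tags_in", int(len(tags)))
        manifest.add("rpm_filter", "tags_out", int(len(kept)))
        manifest.add("rpm_filter", "threshold", threshold)
    return kept


def exclude_sequences(tags: pd.DataFrame, exclusion: Iterable[str],
                      manifest: RunManifest | None = None) -> pd.DataFrame:
    """Exact-match removal against a user-supplied exclusion set (stands in
    for structural/chloroplast RNA screens; empty by default)."""
    excl = {s.upper().replace("U", "T") for s in exclusion}
    kept = tags.loc[[s for s in tags.index if s not in excl]]
    if manifest is not None:
        manifest.add("exclusion", "tags_in", int(len(tags)))
        manifest.add("exclusion", "tags_out", int(len(kept)))
    return kept
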