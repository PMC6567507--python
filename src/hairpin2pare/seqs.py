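"""Small sequence utilities shared across modules (DNA/RNA, no external deps)."""
from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTUN", "TGCAAN")
_RNA_COMP = str.maketrans("ACGUTN", "UGCAAN")

BASES_DNA = "ACGT"
BASES_RNA = "ACGU"


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T)."""
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMP)[::-1]


def complement_rna(base: str) -> str:
    return base.translate(_RNA_COMP)


def random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES_RNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle: permute a sequence preserving exact
    dinucleotide counts (and therefore mononucleotide counts, first and last
    characters).

    Raises ValueError when the sequence carries fewer than 3 distinct
    dinucleotides - such sequences have no meaningful shuffle space.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 4:
        raise ValueError("sequence too short for dinucleotide shuffling")
    dinucs = {seq[i : i + 2] for i in range(n - 1)}
    if len(dinucs) < 3:
        raise ValueError("fewer than 3 distinct dinucleotides; cannot shuffle")

    # Multigraph of successor edges; an Eulerian path from seq[0] to seq[-1]
    # spells a dinucleotide-preserving permutation.
    edges: dict[str, list[str]] = {}
    for i in range(n - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]

    for _ in range(200):
        # Pick a random final edge per non-terminal vertex; keep only if the
        # chosen edges form an arborescence into `last` (Altschul-Erikson).
        final_edge = {}
        ok = True
        for v, targets in edges.items():
            if v == last:
                continue
            final_edge[v] = targets[int(rng.integers(0, len(targets)))]
        for v in final_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = final_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        # Shuffle remaining edges, append the reserved final edge last.
        walk_edges: dict[str, list[str]] = {}
        for v, targets in edges.items():
            pool = list(targets)
            if v in final_edge:
                pool.remove(final_edge[v])
            perm = rng.permutation(len(pool))
            pool = [pool[i] for i in perm]
            if v in final_edge:
                pool.append(final_edge[v])
            walk_edges[v] = pool
        out = [seq[0]]
        cur = seq[0]
        counters = {v: 0 for v in walk_edges}
        for _ in range(n - 1):
            nxt = walk_edges[cur][counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("failed to find an Eulerian shuffle (should not happen)")
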