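"""Hairpin secondary-structure prediction used as biogenesis evidence.

A deliberately simple nested-structure model: allowed pairs G:C (-3.0),
A:U (-2.0), G:U (-1.0) kcal/mol, minimum hairpin loop of 3 unpaired nt,
minimum total energy found by a Nussinov-style dynamic program with a
deterministic traceback. The per-nucleotide energy threshold used downstream
(default -0.2 kcal/mol/nt) was calibrated against Turner-model folders on
plant precursors and is configurable; an adapter to an external folder
(RNAfold) is provided for users who want full nearest-neighbour energies.
"""
from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass

import numpy as np

from .io_core import ConfigError, FormatError

try:  # numba accelerates the O(n^3) DP; a pure-Python path is kept as fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


MIN_LOOP = 3
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# pair energies, kcal/mol; 0 = not pairable
_EMAT = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _e in [("G", "C", -3), ("A", "U", -2), ("G", "U", -1)]:
    _EMAT[_CODE[_a], _CODE[_b]] = _e
    _EMAT[_CODE[_b], _CODE[_a]] = _e


@dataclass
class FoldResult:
    sequence: str
    dotbracket: str
    pair_table: list[int]  # partner index per position, -1 if unpaired
    energy_kcal: float

    @property
    def energy_per_nt(self) -> float:
        return self.energy_kcal / len(self.sequence)

    def validate(self) -> None:
        """Assert the structural invariants (balanced, nested, involution)."""
        n = len(self.sequence)
        assert len(self.dotbracket) == n and len(self.pair_table) == n
        stack = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                assert self.pair_table[j] == i and self.pair_table[i] == j
                assert i - j > MIN_LOOP
            else:
                assert self.pair_table[i] == -1
        assert not stack
        assert self.energy_kcal <= 0


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise FormatError(f"invalid RNA character {exc.args[0]!r}") from None


@njit(cache=True)
def _nussinov_dp(codes, emat, min_loop):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    E = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                e = emat[codes[i], codes[k]]
                if e < 0:
                    inner = E[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = E[k + 1, j] if k + 1 <= j else 0
                    cand = e + inner + right
                    if cand < best:
                        best = cand
            E[i, j] = best
    return E


def _traceback(E, codes, min_loop) -> list[int]:
    """Deterministic: at each (i, j) prefer pairing i with the smallest
    partner achieving the optimum; otherwise leave i unpaired."""
    n = codes.shape[0]
    pair = [-1] * n
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = E[i, j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            e = _EMAT[codes[i], codes[k]]
            if e < 0:
                inner = E[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = E[k + 1, j] if k + 1 <= j else 0
                if e + inner + right == target:
                    pair[i], pair[k] = k, i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pair


def fold(sequence: str) -> FoldResult:
    """Minimum-energy nested structure of an RNA sequence (10..500 nt)."""
    if not (10 <= len(sequence) <= 500):
        raise ValueError(f"sequence length {len(sequence)} outside [10, 500]")
    codes = _encode(sequence)
    E = _nussinov_dp(codes, _EMAT, MIN_LOOP)
    pair = _traceback(E, codes, MIN_LOOP)
    db = "".join(
        "(" if (q := pair[i]) > i else (")" if q >= 0 else ".") for i in range(len(pair))
    )
    return FoldResult(sequence.upper().replace("T", "U"), db, pair, float(E[0, len(pair) - 1]))


# ---------------------------------------------------------------------------
# Hairpin assessment
# ---------------------------------------------------------------------------

def terminal_loops(pair_table) -> list[tuple[int, int]]:
    """Innermost pairs: each closes exactly one terminal (hairpin) loop."""
    pairs = [(i, j) for i, j in enumerate(pair_table) if j > i]
    loops = []
    for i, j in pairs:
        if all(pair_table[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def _loops_within(loops, a, b):
    return [l for l in loops if a <= l[0] and l[1] <= b]


def is_hairpin(
    fold_result: FoldResult,
    threshold_per_nt: float = -0.2,
    mature_span: tuple[int, int] | None = None,
) -> tuple[bool, dict]:
    """Hairpin biogenesis test: energy per nucleotide strictly below the
    threshold, and exactly one terminal loop on the structural path carrying
    the candidate mature span (multi-loop structures are rejected).

    With a mature span (half-open) the path condition requires that (a) at
    least half the span is paired, (b) all pairs of the span subtend one and
    the same terminal loop (the span lies on a single stem), and (c) the
    widest pair touching the span encloses exactly that one loop. Without a
    span the structure must contain exactly one terminal loop globally.
    """
    pt = fold_result.pair_table
    epn = fold_result.energy_per_nt
    loops = terminal_loops(pt)
    diag = {
        "energy_per_nt": epn,
        "n_terminal_loops": len(loops),
        "paired_fraction": None,
        "loops_on_path": None,
    }
    if epn >= threshold_per_nt or not loops:
        return False, diag

    if mature_span is None:
        ok = len(loops) == 1
        diag["loops_on_path"] = len(loops)
        return ok, diag

    s, e = mature_span
    span_pairs = [(p, pt[p]) for p in range(max(s, 0), min(e, len(pt))) if pt[p] >= 0]
    diag["paired_fraction"] = len(span_pairs) / max(e - s, 1)
    if diag["paired_fraction"] < 0.5:
        return False, diag

    subtended = set()
    for p, q in span_pairs:
        a, b = (p, q) if p < q else (q, p)
        subtended.update(_loops_within(loops, a, b))
    diag["loops_on_path"] = len(subtended)
    if len(subtended) != 1:
        return False, diag

    touching = [
        (i, j) for i, j in enumerate(pt) if j > i and i < e and j >= s
    ]
    widest = max(touching, key=lambda ij: ij[1] - ij[0])
    if len(_loops_within(loops, widest[0], widest[1])) != 1:
        return False, diag
    return True, diag


# ---------------------------------------------------------------------------
# External folder (RNAfold-compatible) adapter
# ---------------------------------------------------------------------------

_EXT_RE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def pair_table_from_dotbracket(db: str) -> list[int]:
    pair = [-1] * len(db)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError("unbalanced dot-bracket string")
            j = stack.pop()
            pair[i], pair[j] = j, i
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise FormatError("unbalanced dot-bracket string")
    return pair


def external_folder_adapter(sequence: str, command: str = "RNAfold") -> FoldResult:
    """Fold through an external Turner-model folder (sequence on stdin,
    dot-bracket + energy on stdout). Interchangeable with :func:`fold`."""
    if shutil.which(command) is None:
        raise ConfigError(
            f"external folder {command!r} not found on PATH; "
            "set folding.engine: builtin to use the internal model"
        )
    seq = sequence.upper().replace("T", "U")
    proc = subprocess.run(
        [command, "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    for line in proc.stdout.splitlines():
        m = _EXT_RE.match(line.strip())
        if m:
            db, energy = m.group(1), float(m.group(2))
            if len(db) != len(seq):
                raise FormatError("external folder returned a structure of wrong length")
            return FoldResult(seq, db, pair_table_from_dotbracket(db), energy)
    raise FormatError(f"could not parse output of {command!r}: {proc.stdout!r}")
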