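"""Independent brute-force reference implementations used only by tests.

Each function here recomputes a quantity by exhaustive enumeration or a
dense scan, deliberately sharing no code with the package's own
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def exhaustive_affine_global(a: str, b: str, sub, gap_open: float,
                             gap_extend: float) -> float:
    """Best global alignment score by enumerating every alignment path.

    Affine gaps: the first residue of a gap costs ``gap_open``, each
    further residue ``gap_extend``; terminal gaps are penalized.
    """
    best = -math.inf

    def rec(i: int, j: int, last: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + sub[a[i], b[j]])
        if i < len(a):
            pen = gap_extend if last == "X" else gap_open
            rec(i + 1, j, "X", score - pen)
        if j < len(b):
            pen = gap_extend if last == "Y" else gap_open
            rec(i, j + 1, "Y", score - pen)

    rec(0, 0, "", 0.0)
    return best


def exhaustive_affine_local(a: str, b: str, sub, gap_open: float,
                            gap_extend: float) -> float:
    """Best local alignment score: the empty alignment (score 0) or the
    best global alignment over any pair of non-empty substrings."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = exhaustive_affine_global(a[i0:i1], b[j0:j1], sub,
                                                 gap_open, gap_extend)
                    best = max(best, s)
    return best


def exhaustive_window_mean_max(values: list[float], window: int) -> float:
    """Max over explicitly enumerated windows of the window mean."""
    n = len(values)
    if n <= window:
        return sum(values) / n
    best = -math.inf
    for start in range(n - window + 1):
        chunk = values[start:start + window]
        best = max(best, sum(chunk) / window)
    return best


def grid_scan_isoelectric_point(charge_fn, step: float = 1e-5) -> float:
    """pH minimizing |net charge| on a dense grid over [0, 14]."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.abs(charge_fn(grid))
    return float(grid[int(np.argmin(charges))])


def loop_alignment_features(i: int, scores_nw: np.ndarray, scores_sw: np.ndarray,
                            labels: list[str]) -> dict[str, float]:
    """Plain double-loop recomputation of the six MaxScore features."""
    out: dict[str, float] = {}
    for tag, mat in (("nw", scores_nw), ("sw", scores_sw)):
        s0 = s1 = -math.inf
        for j in range(len(labels)):
            if j == i:
                continue
            if labels[j] == "negative":
                s0 = max(s0, mat[i, j])
            elif labels[j] == "positive":
                s1 = max(s1, mat[i, j])
        out[f"MaxScore0_{tag}"] = s0
        out[f"MaxScore1_{tag}"] = s1
        out[f"DiffMaxScore_{tag}"] = s1 - s0
    return out


def substring_in_any(fragment: str, sequences) -> bool:
    """Brute-force substring scan over a collection of sequences."""
    return any(fragment in s for s in sequences)


def max_identity_any_window(a: str, b: str, window: int = 11) -> int:
    """Exhaustive offset x window scan: the largest number of positional
    matches of ``a`` against ``b`` inside any ``window``-long stretch,
    over every ungapped relative offset."""
    best = 0
    for off in range(-(len(a) - 1), len(b)):
        matches = []
        for p in range(len(a)):
            q = p + off
            if 0 <= q < len(b):
                matches.append(1 if a[p] == b[q] else 0)
        if not matches:
            continue
        w = min(window, len(matches))
        for start in range(len(matches) - w + 1):
            best = max(best, sum(matches[start:start + w]))
    return best


def violates_novelty(seq: str, train_seqs, test_seqs, max_stretch: int = 3,
                     max_identities: int = 5, window: int = 11) -> bool:
    """Re-check both novelty constraints from scratch."""
    k = max_stretch + 1
    for start in range(len(seq) - k + 1):
        if substring_in_any(seq[start:start + k], list(train_seqs) + list(test_seqs)):
            return True
    for t in train_seqs:
        if max_identity_any_window(seq, t, window) > max_identities:
            return True
    return False
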