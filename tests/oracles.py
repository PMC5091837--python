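"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: alignment is a literal
per-offset scan, the chi-squared statistic is the textbook double sum, and
the decay oracle is a coarse grid search over (A, k).
"""

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _mismatches(read: str, ref: str, offset: int) -> int:
    window = ref[offset:offset + len(read)]
    return sum(1 for a, b in zip(read, window)
               if a != b or a == "N" or b == "N")


def brute_force_align(read: str, ref: str, max_mismatches: int):
    """Exhaustive ungapped scan, forward then reverse complement.

    Returns (mapped, offset, mismatches, strand) with the best placement
    chosen by (mismatches, forward-first, smallest offset).
    """
    best = None
    for rank, (strand, seq) in enumerate((("+", read), ("-", _revcomp(read)))):
        for off in range(len(ref) - len(read) + 1):
            mm = _mismatches(seq, ref, off)
            cand = (mm, rank, off, strand)
            if best is None or cand[:3] < best[:3]:
                best = cand
    mm, _, off, strand = best
    if mm <= max_mismatches:
        return True, off, mm, strand
    return False, None, None, None


def pearson_chi2(table) -> tuple[float, int]:
    """Textbook Pearson chi-squared on an r x c contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def grid_search_decay(times, values, n_grid: int = 200):
    """Coarse global scan of y = A exp(-k t); returns (A, k, sse)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    best = (np.nan, np.nan, np.inf)
    for a in np.linspace(0.2 * y.max(), 2.0 * y.max(), n_grid):
        for k in np.linspace(0.0, 3.0, n_grid):
            sse = float(((y - a * np.exp(-k * t)) ** 2).sum())
            if sse < best[2]:
                best = (float(a), float(k), sse)
    return best
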