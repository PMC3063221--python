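"""Sliding-window (local) accessibilities for long sequences.

Global folding of an n-nucleotide molecule costs O(n^3); for very long
sequences (mRNAs, chromosomes) one instead folds every window of a fixed
width ``W`` and restricts pairs to a maximum span.  Because an interval
near the middle of the sequence lies in more windows than one near an
end, the per-interval values are *averaged over exactly the windows that
contain the interval*, so every interval receives total weight one
regardless of how many windows see it.

The implementation refolds each of the ``n - W + 1`` full-width windows
independently and averages; with ``W >= n`` there is a single window and
the result is identical to the global computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._core import UpdateCounts
from .accessibility import PART_NAMES, AccessibilityResult, accessibility_all
from .energy_model import EnergyParameters
from .inside import fill_inside
from .outside import fill_outside, record_accessibility_helpers
from .sequence import RnaSequence


@dataclass(frozen=True)
class WindowConfig:
    """Local-folding parameters: ``u <= max_pair_span <= window``.

    window:
        Width W of the sliding window, nt.
    max_pair_span:
        Maximum span ``j - i`` of any base pair within a window
        (default: the window width).
    max_unpaired_len:
        Longest interval length reported (default: ``max_pair_span``).
    """

    window: int
    max_pair_span: int | None = None
    max_unpaired_len: int | None = None

    def resolve(self, n: int) -> tuple[int, int, int]:
        """Clip to the sequence length and apply defaults; returns
        ``(W, span, u)``.  Raises on ``u > span``."""
        W = self.window
        if W > n:
            warnings.warn(f"window {W} clipped to sequence length {n}")
            W = n
        if W < 1:
            raise ValueError("window must be >= 1")
        span = W if self.max_pair_span is None else self.max_pair_span
        if span > W:
            warnings.warn(f"max_pair_span {span} clipped to window {W}")
            span = W
        u = span if self.max_unpaired_len is None else self.max_unpaired_len
        if u > span:
            raise ValueError(
                f"max_unpaired_len {u} exceeds max_pair_span {span}"
            )
        return W, span, u


def windowed_accessibility(
    seq: RnaSequence,
    p: EnergyParameters,
    cfg: WindowConfig,
    *,
    scale: float = 1.0,
) -> AccessibilityResult:
    """Window-averaged ``pu`` for every interval of length <= ``u``.

    Each interval's value is the mean of its unpaired probability over
    every length-``W`` window fully containing it (near the sequence
    ends this is simply a smaller set of windows).  Pairs are restricted
    to spans <= ``max_pair_span`` within each window.
    """
    n = seq.n
    W, span, u = cfg.resolve(n)

    sums = {k: np.zeros((n + 2, n + 2)) for k in PART_NAMES}
    hits = np.zeros((n + 2, n + 2))
    counts = UpdateCounts()
    for w in range(1, n - W + 2):
        sub = seq.subsequence(w, w + W - 1)
        ins = fill_inside(sub, p, scale=scale, max_pair_span=span)
        out = fill_outside(sub, p, ins)
        record_accessibility_helpers(sub, p, ins, out)
        res = accessibility_all(sub, p, ins, out, max_len=u)
        block = res.pu[1 : W + 1, 1 : W + 1]
        valid = ~np.isnan(block)
        hits[w : w + W, w : w + W][valid] += 1.0
        for k in PART_NAMES:
            pblock = res.parts[k][1 : W + 1, 1 : W + 1]
            sums[k][w : w + W, w : w + W][valid] += pblock[valid]
        counts = counts.merged(res.counts).merged(ins.counts).merged(
            out.counts
        )

    with np.errstate(invalid="ignore"):
        parts = {k: sums[k] / hits for k in PART_NAMES}
    pu = sum(parts.values())
    return AccessibilityResult(seq, p, pu, parts, u, counts)
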