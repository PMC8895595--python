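"""Low-complexity and compositionally biased region (LCR/CBR) annotation.

Deposit-forming proteins are typically intrinsically disordered and carry
long regions dominated by a handful of residues.  Two sliding-window scans
quantify this:

* ``scan_low_complexity`` -- a SEG-like two-threshold Shannon-entropy scan:
  windows at or below a trigger entropy seed segments, which extend through
  neighbouring windows at or below a (looser) extension entropy.
* ``scan_residue_bias`` -- a binomial enrichment scan for a chosen residue
  set: a window is biased when the upper binomial tail of its residue-set
  count under the background frequencies falls at or below a cutoff.

Per-window tails are diagnostics, not hypothesis tests: no multiple-testing
correction is applied.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from depositcomp.sequence_io import CANONICAL, ProteinRecord

logger = logging.getLogger(__name__)

#: Average SwissProt residue frequencies (release-level averages, used as an
#: optional background in place of the uniform 1/20 default).
SWISSPROT_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_s = sum(SWISSPROT_FREQS.values())
SWISSPROT_FREQS = {r: v / _s for r, v in SWISSPROT_FREQS.items()}

UNIFORM_FREQS = {r: 1.0 / 20.0 for r in CANONICAL}


@dataclass(frozen=True)
class BiasSegment:
    """One annotated region, 0-based half-open [start, end).

    ``score`` is the minimum window entropy in bits for ``low_complexity``
    segments, and the -log10 of the smallest per-window binomial tail for
    ``residue_bias`` segments.
    """

    start: int
    end: int
    kind: str
    dominant_residues: frozenset[str]
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment coordinates [{self.start}, {self.end})")
        if self.kind not in ("low_complexity", "residue_bias"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanParams:
    """Sliding-window scan parameters.

    window: window length in residues.
    k_trigger / k_extend: entropy thresholds in bits (trigger <= extend).
    p_threshold: binomial upper-tail cutoff for residue-bias windows.
    merge_gap: segments closer than this many residues are merged.
    background: per-residue frequency vector (sums to 1).
    """

    window: int = 25
    k_trigger: float = 2.2
    k_extend: float = 2.5
    p_threshold: float = 1e-6
    merge_gap: int = 10
    background: dict[str, float] = field(default_factory=lambda: dict(UNIFORM_FREQS))

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.k_trigger > self.k_extend:
            raise ValueError("k_trigger must be <= k_extend")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"background frequencies sum to {total}, expected 1")


def window_entropy(window: str) -> float:
    """Shannon entropy in bits of the residue usage of a window."""
    if not window:
        raise ValueError("empty window")
    n = len(window)
    h = 0.0
    for count in Counter(window).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def _entropy_profile(seq: str, window: int) -> np.ndarray:
    """Entropy of every window, by incremental count updates (O(n) symbol moves)."""
    n_windows = len(seq) - window + 1
    counts = Counter(seq[:window])
    out = np.empty(n_windows)

    def h(counter: Counter) -> float:
        total = window
        acc = 0.0
        for c in counter.values():
            p = c / total
            acc -= p * math.log2(p)
        return acc

    out[0] = h(counts)
    for i in range(1, n_windows):
        left, right = seq[i - 1], seq[i + window - 1]
        if left != right:
            counts[left] -= 1
            if counts[left] == 0:
                del counts[left]
            counts[right] += 1
        out[i] = h(counts)
    return out


def _runs_to_segments(
    keep: np.ndarray, window: int
) -> list[tuple[int, int, int, int]]:
    """Maximal runs of kept window indices -> (seg_start, seg_end, run_lo, run_hi)."""
    segments = []
    i = 0
    n = len(keep)
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            segments.append((i, j - 1 + window, i, j - 1))
            i = j
        else:
            i += 1
    return segments


def merge_segments(
    segments: list[BiasSegment], merge_gap: int
) -> list[BiasSegment]:
    """Merge segments separated by at most *merge_gap* residues (idempotent).

    Merged scores keep the most extreme value: minimum for entropy scores,
    maximum for -log10 tails; dominant residue sets are unioned.
    """
    if not segments:
        return []
    kinds = {s.kind for s in segments}
    if len(kinds) > 1:
        raise ValueError("cannot merge segments of mixed kinds")
    kind = kinds.pop()
    ordered = sorted(segments, key=lambda s: (s.start, s.end))
    merged = [ordered[0]]
    for seg in ordered[1:]:
        prev = merged[-1]
        if seg.start - prev.end <= merge_gap:
            score = (
                min(prev.score, seg.score)
                if kind == "low_complexity"
                else max(prev.score, seg.score)
            )
            merged[-1] = BiasSegment(
                start=prev.start,
                end=max(prev.end, seg.end),
                kind=kind,
                dominant_residues=prev.dominant_residues | seg.dominant_residues,
                score=score,
            )
        else:
            merged.append(seg)
    return merged


def _modal_residues(segment_seq: str) -> frozenset[str]:
    counts = Counter(segment_seq)
    top = max(counts.values())
    return frozenset(r for r, c in counts.items() if c == top)


def scan_low_complexity(
    record: ProteinRecord, params: ScanParams | None = None
) -> list[BiasSegment]:
    """Two-threshold entropy scan.

    A maximal run of consecutive windows with entropy <= k_extend becomes a
    segment iff it contains at least one window with entropy <= k_trigger;
    the segment spans from the first window start to the last window end.
    Segments within merge_gap are merged.  A sequence shorter than the window
    yields no segments (with a warning).
    """
    params = params or ScanParams()
    seq = record.sequence
    if len(seq) < params.window:
        logger.warning(
            "record %r shorter than window (%d < %d); no scan performed",
            record.id, len(seq), params.window,
        )
        return []
    h = _entropy_profile(seq, params.window)
    extend = h <= params.k_extend
    segments = []
    for start, end, lo, hi in _runs_to_segments(extend, params.window):
        run_h = h[lo : hi + 1]
        if run_h.min() <= params.k_trigger:
            segments.append(
                BiasSegment(
                    start=start,
                    end=end,
                    kind="low_complexity",
                    dominant_residues=_modal_residues(seq[start:end]),
                    score=float(run_h.min()),
                )
            )
    return merge_segments(segments, params.merge_gap)


def scan_residue_bias(
    record: ProteinRecord,
    residues: set[str] | str,
    params: ScanParams | None = None,
) -> list[BiasSegment]:
    """Binomial residue-set enrichment scan.

    For each window the upper tail P(X >= k) of a Binomial(window, p) count is
    computed, where k is the observed count of the queried residues and p
    their total background mass; windows with tail <= p_threshold form
    segments as in the entropy scan (no separate trigger level).
    """
    params = params or ScanParams()
    residues = frozenset(residues)
    if not residues:
        raise ValueError("empty residue set")
    p = sum(params.background.get(r, 0.0) for r in residues)
    if p <= 0:
        raise ValueError(
            f"queried residues {sorted(residues)} have zero background mass"
        )
    seq = record.sequence
    if len(seq) < params.window:
        logger.warning(
            "record %r shorter than window (%d < %d); no scan performed",
            record.id, len(seq), params.window,
        )
        return []
    w = params.window
    n_windows = len(seq) - w + 1
    member = np.frombuffer(
        bytes(1 if c in residues else 0 for c in seq), dtype=np.uint8
    )
    csum = np.concatenate([[0], np.cumsum(member)])
    k = csum[w:] - csum[:-w]  # residue-set count per window
    tails = binom.sf(k - 1, w, p)
    keep = tails <= params.p_threshold
    segments = []
    for start, end, lo, hi in _runs_to_segments(keep, w):
        best_k = int(k[lo : hi + 1].max())
        # -log10 tail via the log survival function to survive underflow
        log_tail = binom.logsf(best_k - 1, w, p) / math.log(10)
        segments.append(
            BiasSegment(
                start=start,
                end=end,
                kind="residue_bias",
                dominant_residues=residues,
                score=float(-log_tail),
            )
        )
    return merge_segments(segments, params.merge_gap)


def coverage(segments: list[BiasSegment], length: int) -> float:
    """Fraction of the sequence covered by non-overlapping segments."""
    if length <= 0:
        raise ValueError("length must be positive")
    ordered = sorted(segments, key=lambda s: s.start)
    covered = 0
    prev_end = -1
    for seg in ordered:
        if seg.start < prev_end:
            raise ValueError(
                f"overlapping segments at {seg.start} (previous ends {prev_end}); "
                "merge before computing coverage"
            )
        if seg.end > length:
            raise ValueError("segment extends past sequence length")
        covered += len(seg)
        prev_end = seg.end
    return covered / length
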