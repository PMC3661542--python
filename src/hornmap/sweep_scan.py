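"""Sliding-window haplotype-homozygosity sweep scan.

For each window of ``width`` consecutive markers, the frequency of every
complete haplotype is computed within each breed.  For a candidate haplotype
``h`` the across-breed normalized frequency is

    sum over breeds of freq(h in breed) / divisor

with frequency 0 where ``h`` is absent and ``divisor`` the number of breeds.
The window statistic is the maximum of this quantity over haplotypes — the
normalized frequency of the window's most frequent haplotype, a proxy for
(lack of) local haplotype diversity.  Windows whose statistic strictly
exceeds ``mean + k * sd`` over all windows of the scan (population SD,
default ``k = 4``) are flagged as putative sweep windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentError, DegenerateInputError, RangeError
from .formats_io import MISSING, GenomicInterval, HaplotypePanel


def _window_counts(mat: np.ndarray, start: int, width: int) -> Tuple[list, np.ndarray]:
    """Unique windowed haplotypes (as byte keys) and their counts, excluding
    rows with a missing allele inside the window."""
    sub = mat[:, start : start + width]
    ok = ~(sub == MISSING).any(axis=1)
    sub = np.ascontiguousarray(sub[ok])
    if sub.shape[0] == 0:
        return [], np.empty(0, dtype=np.int64)
    voids = sub.view(np.dtype((np.void, width))).ravel()
    uniq, counts = np.unique(voids, return_counts=True)
    return [u.tobytes() for u in uniq], counts


def _key_to_str(key: bytes) -> str:
    return "".join(str(b) for b in key)


def window_haplotype_frequencies(
    panel: HaplotypePanel, window: Tuple[int, int]
) -> Dict[str, float]:
    """Within-breed haplotype frequencies for one marker window.

    ``window`` is ``(start_index, width)``.  Keys are canonical allele
    strings over the window; haplotypes with a missing allele anywhere in the
    window are excluded from both numerator and denominator, so frequencies
    sum to 1 over the complete haplotypes.
    """
    start, width = window
    if width < 1 or start < 0 or start + width > panel.n_markers:
        raise RangeError(
            f"window ({start}, {width}) outside marker bounds [0, {panel.n_markers})"
        )
    keys, counts = _window_counts(panel.haplotypes, start, width)
    total = counts.sum()
    return {_key_to_str(k): c / total for k, c in zip(keys, counts)}


def normalized_top_frequency(
    per_breed: Dict[str, Dict[str, float]], n_breeds_divisor: int
) -> Tuple[str, float]:
    """Across-breed normalized frequency of the most frequent haplotype.

    For every haplotype appearing in any breed, sums its per-breed
    frequencies (0 where absent) and divides by ``n_breeds_divisor``; returns
    the haplotype maximizing the result.  Ties break lexicographically on the
    haplotype key.
    """
    if not per_breed:
        raise DegenerateInputError("no breed frequency maps supplied")
    if n_breeds_divisor < len(per_breed):
        raise ValueError(
            f"divisor {n_breeds_divisor} smaller than number of breeds {len(per_breed)}"
        )
    sums: Dict[str, float] = {}
    for freqs in per_breed.values():
        for key, f in freqs.items():
            sums[key] = sums.get(key, 0.0) + f
    if not sums:
        raise DegenerateInputError("no complete haplotypes in any breed")
    best = min(sums.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0], best[1] / n_breeds_divisor


@dataclass(frozen=True)
class WindowStat:
    """Per-window scan record."""

    window_index: int
    marker_span: Tuple[int, int]  # (start_index, width)
    bp_span: GenomicInterval
    per_breed_top: Dict[str, Tuple[str, float]]
    top_haplotype_key: str
    normalized_top_frequency: float


@dataclass
class ScanSummary:
    """Whole-scan result: all window statistics plus the outlier flag rule
    ``normalized_top_frequency > mean + k * sd`` (strict; population SD)."""

    window_stats: List[WindowStat]
    mean_top: float
    sd_top: float
    k: float
    flagged_windows: List[int] = field(default_factory=list)

    @property
    def argmax_window(self) -> int:
        values = [w.normalized_top_frequency for w in self.window_stats]
        return self.window_stats[int(np.argmax(values))].window_index

    def to_dataframe(self):
        import pandas as pd

        flagged = set(self.flagged_windows)
        return pd.DataFrame(
            [
                {
                    "window_index": w.window_index,
                    "start_index": w.marker_span[0],
                    "width": w.marker_span[1],
                    "start_bp": w.bp_span.start_1based,
                    "end_bp": w.bp_span.end_1based,
                    "top_haplotype": w.top_haplotype_key,
                    "normalized_top_frequency": w.normalized_top_frequency,
                    "flagged": w.window_index in flagged,
                }
                for w in self.window_stats
            ]
        )


def scan(
    panels: Sequence[HaplotypePanel],
    width: int = 79,
    step: int = 1,
    k: float = 4.0,
    divisor: Optional[int] = None,
) -> ScanSummary:
    """Run the sliding-window scan across breed panels sharing one marker map.

    ``divisor`` defaults to the number of panels; passing a larger value
    reproduces normalization against a fixed breed count when some breeds are
    withheld.
    """
    if not panels:
        raise DegenerateInputError("no panels supplied")
    mm = panels[0].marker_map
    for p in panels[1:]:
        if p.marker_map != mm:
            raise AlignmentError(
                f"panel {p.breed!r} has a different marker map than {panels[0].breed!r}"
            )
    m = mm.n_markers
    if width < 1 or width > m:
        raise RangeError(f"window width {width} outside [1, {m}]")
    if step < 1:
        raise RangeError("step must be >= 1")
    div = divisor if divisor is not None else len(panels)
    if div < len(panels):
        raise ValueError("divisor smaller than the number of breeds scanned")

    stats: List[WindowStat] = []
    for w_idx, start in enumerate(range(0, m - width + 1, step)):
        sums: Dict[bytes, float] = {}
        per_breed_top: Dict[str, Tuple[str, float]] = {}
        for panel in panels:
            keys, counts = _window_counts(panel.haplotypes, start, width)
            if len(keys) == 0:
                continue
            total = counts.sum()
            top_i = int(np.argmax(counts))  # per-breed report only
            per_breed_top[panel.breed] = (
                _key_to_str(keys[top_i]),
                counts[top_i] / total,
            )
            for key, c in zip(keys, counts):
                sums[key] = sums.get(key, 0.0) + c / total
        if not sums:
            raise DegenerateInputError(
                f"window {w_idx}: no complete haplotype in any breed"
            )
        best_key, best_sum = min(sums.items(), key=lambda kv: (-kv[1], kv[0]))
        stats.append(
            WindowStat(
                window_index=w_idx,
                marker_span=(start, width),
                bp_span=mm.span(start, start + width - 1),
                per_breed_top=per_breed_top,
                top_haplotype_key=_key_to_str(best_key),
                normalized_top_frequency=best_sum / div,
            )
        )

    values = np.array([w.normalized_top_frequency for w in stats])
    mean_top = float(values.mean())
    sd_top = float(values.std(ddof=0))
    flagged = [
        w.window_index
        for w, v in zip(stats, values)
        if v > mean_top + k * sd_top
    ]
    return ScanSummary(stats, mean_top, sd_top, k, flagged)
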