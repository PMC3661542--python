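"""Shared-segment (IBD) detection among trait carriers.

Identity is exact marker-wise matching of phased haplotypes — no
probabilistic IBD model.  A missing allele cannot confirm identity, so any
column containing a missing call breaks the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError, RangeError
from .formats_io import MISSING, GenomicInterval, HaplotypePanel, MarkerMap


@dataclass(frozen=True)
class SharedSegment:
    """A maximal run of marker-wise identity across carrier haplotypes.

    ``marker_span`` is (start_index, end_index) with inclusive marker
    indices; ``haplotype_key`` is the canonical allele string over the span.
    """

    marker_span: Tuple[int, int]
    bp_span: GenomicInterval
    haplotype_key: str
    n_carriers: int


def _identity_runs(ident: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True, as (start, end) inclusive index pairs."""
    runs = []
    in_run, start = False, 0
    for j, v in enumerate(ident):
        if v and not in_run:
            in_run, start = True, j
        elif not v and in_run:
            runs.append((start, j - 1))
            in_run = False
    if in_run:
        runs.append((start, len(ident) - 1))
    return runs


def shared_segment(
    carrier_haplotypes: Sequence[np.ndarray],
    marker_map: MarkerMap,
    anchor: Optional[int] = None,
    min_length_markers: int = 1,
) -> Optional[SharedSegment]:
    """Maximal segment shared identically by all carrier haplotypes.

    With ``anchor`` (a marker index), returns the maximal run containing it,
    or None if the anchor column is not shared.  Without an anchor, returns
    the longest run (leftmost on ties).  Returns None when no run reaches
    ``min_length_markers``.
    """
    H = np.asarray(carrier_haplotypes, dtype=np.uint8)
    if H.ndim != 2 or H.shape[0] == 0:
        raise DegenerateInputError("need at least one carrier haplotype")
    if H.shape[1] != marker_map.n_markers:
        raise RangeError("haplotype length does not match the marker map")
    if anchor is not None and not (0 <= anchor < marker_map.n_markers):
        raise RangeError(f"anchor {anchor} outside marker bounds")

    ident = np.all(H == H[0], axis=0) & np.all(H != MISSING, axis=0)
    runs = _identity_runs(ident)
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_length_markers]
    if not runs:
        return None
    if anchor is not None:
        chosen = next((r for r in runs if r[0] <= anchor <= r[1]), None)
        if chosen is None:
            return None
    else:
        chosen = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    s, e = chosen
    key = "".join(str(int(a)) for a in H[0, s : e + 1])
    return SharedSegment(
        marker_span=(s, e),
        bp_span=marker_map.span(s, e),
        haplotype_key=key,
        n_carriers=H.shape[0],
    )


def haplotype_frequency_in_panels(
    segment: SharedSegment, panels: Sequence[HaplotypePanel]
) -> Dict[str, float]:
    """Per-breed frequency of the shared haplotype over its marker span.

    Haplotypes with a missing allele in the span are excluded from the
    denominator; a breed with no complete haplotype gets ``nan``.
    """
    s, e = segment.marker_span
    key = np.frombuffer(segment.haplotype_key.encode(), dtype=np.uint8) - ord("0")
    out: Dict[str, float] = {}
    for panel in panels:
        if e >= panel.n_markers:
            raise RangeError(
                f"segment span ({s}, {e}) outside panel {panel.breed!r} map"
            )
        sub = panel.haplotypes[:, s : e + 1]
        ok = ~(sub == MISSING).any(axis=1)
        n = int(ok.sum())
        if n == 0:
            out[panel.breed] = float("nan")
            continue
        matches = int(np.all(sub[ok] == key, axis=1).sum())
        out[panel.breed] = matches / n
    return out
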