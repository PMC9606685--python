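"""Hydropathy-based transmembrane segment (TMS) counting.

Counting membrane-spanning helices separates the 11-TMS from the 12-TMS
architectures within the family. The detector is a plain Kyte-Doolittle
sliding-window scan: smooth per-residue hydropathy with a centered window,
take maximal runs above a threshold, merge runs separated by tiny gaps and
drop runs too short to be a helix.

Note on the run-length floor: a membrane helix of physical length L yields
an above-threshold run of smoothed values much shorter than L (roughly
L + 20 - 2k positions, where the window must overlap the hydrophobic
stretch by k ~ 14-18 of 19 residues before the average clears the 1.6
threshold, k depending on the stretch's composition). ``min_len`` therefore
applies to the *smoothed run*, not the physical helix, and its default of 4
is set just below the shortest run a genuine 19-residue stretch produces;
polar inter-helix linkers cannot cross the threshold at all, so a low floor
admits no spurious segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import GAP, KYTE_DOOLITTLE
from .seqcore import Sequence

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 4
DEFAULT_MERGE_GAP = 3


@dataclass(frozen=True)
class TmsAnnotation:
    """Predicted transmembrane segments (1-based inclusive) and their count."""

    segments: tuple[tuple[int, int], ...]
    count: int

    def __post_init__(self) -> None:
        prev_end = 0
        for lo, hi in self.segments:
            if lo > hi or lo <= prev_end:
                raise ValueError("segments must be disjoint and ascending")
            prev_end = hi
        if self.count != len(self.segments):
            raise ValueError("count must equal the number of segments")


def hydropathy(seq: Sequence | str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving average of Kyte-Doolittle values.

    Positions near the ends use shrunken windows (the average over the part
    of the window that exists). 'X' contributes 0 (neutral).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if GAP in residues:
        raise ValueError("hydropathy expects an unaligned sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = np.array([KYTE_DOOLITTLE[r] for r in residues], dtype=float)
    n = values.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def count_tms(
    seq: Sequence | str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> TmsAnnotation:
    """Count transmembrane segments of an unaligned protein sequence.

    Maximal runs of smoothed hydropathy >= ``threshold`` are taken as
    candidate segments; runs separated by <= ``merge_gap`` positions are
    merged; runs shorter than ``min_len`` are dropped. A sequence shorter
    than the window is processed with shrunken windows (with a warning).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if len(residues) < window:
        warnings.warn(
            f"sequence length {len(residues)} < window {window}; "
            "using shrunken windows throughout",
            stacklevel=2,
        )
    smooth = hydropathy(residues, window)
    above = smooth >= threshold

    runs: list[list[int]] = []
    start: int | None = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    kept = [
        (lo + 1, hi + 1) for lo, hi in merged if (hi - lo + 1) >= min_len
    ]
    return TmsAnnotation(segments=tuple(kept), count=len(kept))
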