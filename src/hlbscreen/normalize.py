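"""Input normalization: depth scaling, log2 ratio, smoothing.

Reimplements the screen's compare stage on the collapsed unit: both
coverage tracks are scaled to a common total (simple total-count scaling —
on a single 5 kb reference a paired local scaling scheme is undefined and
unnecessary), then a per-base log2 ratio with a pseudocount is taken. The
scaling rule applied is recorded on the track for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import CoverageTrack

DEFAULT_TARGET_TOTAL = 1e6
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class RatioTrack:
    """Per-base log2(ChIP/input) signal after depth scaling.

    A positive pseudocount keeps every value finite.
    """

    values: np.ndarray
    pseudocount: float
    scaling: str = "total-count"

    @property
    def unit_length(self) -> int:
        return len(self.values)


def depth_scale(track: CoverageTrack, target_total: float = DEFAULT_TARGET_TOTAL) -> np.ndarray:
    """Scale per-base counts so the track sums to ``target_total``.

    Shape-preserving and invariant under uniform rescaling of the input
    counts. An empty track (no mapped reads) is a degenerate input.
    """
    if track.n_mapped == 0:
        raise ValueError("cannot depth-scale a track with no mapped reads")
    total = float(track.values.sum())
    if total <= 0:
        raise ValueError("cannot depth-scale a track with zero total coverage")
    return track.values * (target_total / total)


def log2_ratio(
    chip: CoverageTrack,
    input_: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    target_total: float = DEFAULT_TARGET_TOTAL,
) -> RatioTrack:
    """log2((chip + p) / (input + p)) after scaling both tracks to a common total."""
    if chip.unit_length != input_.unit_length:
        raise ValueError(
            f"track length mismatch: chip {chip.unit_length} != input {input_.unit_length}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = depth_scale(chip, target_total)
    i = depth_scale(input_, target_total)
    values = np.log2((c + pseudocount) / (i + pseudocount))
    return RatioTrack(values, pseudocount)


def smooth(track, window: int) -> np.ndarray:
    """Circular centered moving average; window must be odd (1 = identity)."""
    values = track.values if hasattr(track, "values") else np.asarray(track, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1:
        return np.asarray(values, dtype=float).copy()
    half = window // 2
    ext = np.concatenate([values[-half:], values, values[:half]]).astype(float)
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    return (cs[window:] - cs[:-window]) / window
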