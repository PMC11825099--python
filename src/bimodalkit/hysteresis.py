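"""Tracking distribution shape along ordered condition sequences.

Hysteresis — dependence of the expression distribution on the history of
conditions, not only the current one — shows up as forward and backward
passes through the same conditions tracing different paths in the space of
the shape parameters (d, o).  (The height asymmetry h is not tracked: it is
sensitive to how cells are subsampled between passes.)

The loop gap operationalizes "the loop does not close": the mean Euclidean
distance in (d, o) between direction-matched conditions.  It is this
package's own metric; whether a gap is meaningful is judged against a
resampling null built from repeated equilibrated passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modality import ModalityConfig, DEFAULT_CONFIG, classify_modality, shape_params

__all__ = ["PathPoint", "HysteresisPath", "track_path", "loop_gap"]


@dataclass
class PathPoint:
    condition: str
    phase_index: int
    bimodal: bool
    d: float | None = None
    o: float | None = None


@dataclass
class HysteresisPath:
    points: list
    direction: str = "forward"

    def matched(self, other: "HysteresisPath") -> list[tuple[PathPoint, PathPoint]]:
        """Condition-label-matched point pairs that are bimodal in both paths."""
        by_label = {p.condition: p for p in other.points}
        out = []
        for p in self.points:
            q = by_label.get(p.condition)
            if q is not None and p.bimodal and q.bimodal:
                out.append((p, q))
        return out


def track_path(
    sequence,
    direction: str = "forward",
    kind: str = "count",
    config: ModalityConfig = DEFAULT_CONFIG,
) -> HysteresisPath:
    """Classify each condition in order and record (d, o) where bimodal.

    ``sequence`` is an ordered iterable of (condition label, values) pairs;
    non-bimodal conditions are kept as gaps (d = o = None), preserving order.
    """
    sequence = list(sequence)
    if len(sequence) < 2:
        raise ValueError("a path needs at least 2 conditions")
    points = []
    for i, (label, values) in enumerate(sequence):
        call = classify_modality(values, kind=kind, config=config)
        if call.is_bimodal:
            sp = shape_params(call, values, kind=kind)
            points.append(PathPoint(label, i, True, sp.d, sp.o))
        else:
            points.append(PathPoint(label, i, False))
    return HysteresisPath(points=points, direction=direction)


def loop_gap(forward: HysteresisPath, backward: HysteresisPath) -> float:
    """Mean Euclidean distance in (d, o) over direction-matched conditions.

    Zero iff the two paths coincide at every matched point; symmetric in its
    arguments.  Non-bimodal points are excluded (not imputed); it is an
    error if no matched bimodal conditions exist.
    """
    pairs = forward.matched(backward)
    if not pairs:
        raise ValueError("no matched bimodal conditions between the paths")
    dists = [
        np.hypot(p.d - q.d, p.o - q.o) for p, q in pairs
    ]
    return float(np.mean(dists))
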