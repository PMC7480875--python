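"""Geometry of the 8x8 option grid.

Every option is a pair of integer feature values ``(d1, d2)`` with each
index in ``0..7`` — a location on a spatial grid or a (tilt, stripe
frequency) combination of a Gabor patch; the two readings share identical
geometry. Options are enumerated row-major (``d1`` major) into a flat
index ``j = d1 * 8 + d2``.
"""

from __future__ import annotations

import numpy as np

N_SIDE = 8
N_OPTIONS = N_SIDE * N_SIDE

#: (64, 2) integer array of all option coordinates in flat-index order.
COORDS = np.array([(d1, d2) for d1 in range(N_SIDE) for d2 in range(N_SIDE)], dtype=np.int64)

_diff = COORDS[:, None, :] - COORDS[None, :, :]

#: (64, 64) squared Euclidean distances between options, in raw grid units.
SQ_EUCLIDEAN = np.sum(_diff.astype(float) ** 2, axis=-1)

#: (64, 64) Manhattan distances between options (range 0..14).
MANHATTAN = np.sum(np.abs(_diff), axis=-1)

del _diff


def flat_index(d1: int, d2: int) -> int:
    """Map a coordinate pair to its flat option index."""
    if not (0 <= d1 < N_SIDE and 0 <= d2 < N_SIDE):
        raise ValueError(f"coordinates ({d1}, {d2}) outside the {N_SIDE}x{N_SIDE} grid")
    return int(d1) * N_SIDE + int(d2)


def coord(j: int) -> tuple[int, int]:
    """Map a flat option index back to its ``(d1, d2)`` coordinates."""
    if not 0 <= j < N_OPTIONS:
        raise ValueError(f"flat index {j} outside [0, {N_OPTIONS})")
    return int(j) // N_SIDE, int(j) % N_SIDE


def as_flat(option) -> int:
    """Accept either a flat index or a coordinate pair and return the flat index."""
    if np.isscalar(option) or isinstance(option, (int, np.integer)):
        j = int(option)
        if not 0 <= j < N_OPTIONS:
            raise ValueError(f"flat index {j} outside [0, {N_OPTIONS})")
        return j
    d1, d2 = option
    return flat_index(int(d1), int(d2))


def chance_manhattan_distance() -> float:
    """Expected Manhattan distance between two independent uniform options.

    Brute-force mean over all 64 x 64 ordered pairs; equals 5.25 on the
    8x8 grid and serves as the chance baseline for search-distance analyses.
    """
    return float(MANHATTAN.mean())
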