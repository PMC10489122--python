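"""Curvature-derived surface metrics.

At each vertex of the reconstructed cortical surface the two principal
normal curvatures K1 (maximum) and K2 (minimum) summarise local shape.
Two scalar metrics are derived from them:

* mean curvature  ``H = (K1 + K2) / 2``
* folding index   ``FI = |K1| * (|K1| - |K2|)``

The folding index is only guaranteed non-negative when the pair is
ordered by absolute magnitude (|K1| >= |K2|): a saddle vertex with
K1 = 1, K2 = -2 has max/min ordering but |K1| < |K2|.  Construction
therefore orders by |.| before FI is evaluated, so FI >= 0 always holds
(matching the FreeSurfer convention); mean curvature is unaffected
because it is symmetric in its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PrincipalCurvaturePair:
    """Principal curvatures at a surface vertex, in 1/length units.

    ``k1``/``k2`` are stored ordered so that ``|k1| >= |k2|``.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k1) and math.isfinite(self.k2)):
            raise ValueError("principal curvatures must be finite")
        if abs(self.k1) < abs(self.k2):
            hi, lo = self.k2, self.k1
            object.__setattr__(self, "k1", hi)
            object.__setattr__(self, "k2", lo)


def mean_curvature(pair: PrincipalCurvaturePair) -> float:
    """Mean curvature H = (K1 + K2) / 2."""
    return (pair.k1 + pair.k2) / 2.0


def folding_index(pair: PrincipalCurvaturePair) -> float:
    """Folding index FI = |K1| * (|K1| - |K2|), with |K1| >= |K2|.

    Zero on flat patches and on umbilic/sphere-like vertices where the
    magnitudes coincide; large where one curvature direction dominates,
    i.e. along the walls of sulci and the crowns of gyri.
    """
    a1, a2 = abs(pair.k1), abs(pair.k2)
    return a1 * (a1 - a2)


def mean_curvature_arrays(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Vectorised mean curvature over per-vertex arrays."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if not (np.isfinite(k1).all() and np.isfinite(k2).all()):
        raise ValueError("principal curvatures must be finite")
    return (k1 + k2) / 2.0


def folding_index_arrays(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Vectorised folding index; orders each pair by |.| first."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if not (np.isfinite(k1).all() and np.isfinite(k2).all()):
        raise ValueError("principal curvatures must be finite")
    hi = np.maximum(np.abs(k1), np.abs(k2))
    lo = np.minimum(np.abs(k1), np.abs(k2))
    return hi * (hi - lo)
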