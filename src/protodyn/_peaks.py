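"""Sub-grid peak localisation shared by dose curves and depth profiles."""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError


def parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Locate the maximum of a sampled curve with sub-grid precision.

    Fits a parabola through the three samples bracketing the discrete
    maximum and returns its apex abscissa.  At either boundary the grid
    maximum itself is returned.

    Raises
    ------
    DegenerateInputError
        If the curve is empty or flat (no unique maximum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty curve has no peak")
    if np.ptp(y) == 0:
        raise DegenerateInputError("flat curve has no peak")
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    # vertex of the Lagrange parabola through the three bracketing samples
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if den == 0:
        return float(x1)
    apex = x1 - 0.5 * num / den
    # clamp to the bracketing interval
    return float(min(max(apex, x0), x2))
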