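"""Cross-stratum effect-size concordance via a fitted center line and
sigma band.

Paired effect sizes (beta in stratum A on x, stratum B on y) are fitted
with ordinary least squares of y on x; each point's signed perpendicular
distance to the line is

    d_i = (y_i - slope*x_i - intercept) / sqrt(1 + slope^2),

and sigma is the sample standard deviation of the distances.  Points within
``band_mult * sigma`` of the line (default 1.5, i.e. a +/-1.5-sigma band)
that lie in quadrant 1 (both effects positive) or quadrant 3 (both
negative) are labeled concordant (``consistent_up`` / ``consistent_down``).
Points outside the band are labeled by quadrant, with Q1/Q3 split by the
side of the line: a positive residual means the stratum-B effect is the
stronger one (``_top``), a negative residual the stratum-A effect
(``_bottom``).

A point sitting exactly on an axis is assigned the quadrant obtained by
giving the zero coordinate the sign of the non-zero one (the concordant
side); a point at the origin is treated as quadrant 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DegenerateInputError

LABELS = ("consistent_up", "consistent_down", "Q1_top", "Q1_bottom",
          "Q2", "Q3_top", "Q3_bottom", "Q4")


@dataclass
class CenterLineModel:
    """OLS center line of the 2D effect-size cloud plus residual spread."""

    slope: float
    intercept: float
    sigma: float
    band_mult: float = 1.5

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed perpendicular distance of points to the line."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (y - self.slope * x - self.intercept) / np.sqrt(1 + self.slope ** 2)

    @property
    def band_halfwidth(self) -> float:
        return self.band_mult * self.sigma


def fit_center_line(points: pd.DataFrame | np.ndarray,
                    band_mult: float = 1.5) -> CenterLineModel:
    """Fit the center line by OLS of y on x (with intercept) and compute the
    sample SD of the signed perpendicular distances.

    ``points`` is an (n, 2) array or a DataFrame with columns x, y (first
    two columns used).  Requires >= 3 points and non-constant x.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DegenerateInputError("points must be n x 2")
    arr = arr[:, :2]
    if arr.shape[0] < 3:
        raise DegenerateInputError(
            f"center line needs >= 3 points, got {arr.shape[0]}"
        )
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateInputError("x values are all equal: line undefined")
    slope, intercept = np.polyfit(x, y, deg=1)
    model = CenterLineModel(slope=float(slope), intercept=float(intercept),
                            sigma=0.0, band_mult=band_mult)
    d = model.distance(x, y)
    model.sigma = float(np.std(d, ddof=1))
    return model


def _effective_signs(x: float, y: float) -> tuple[float, float]:
    sx, sy = np.sign(x), np.sign(y)
    if sx == 0 and sy == 0:
        return 1.0, 1.0
    if sx == 0:
        sx = sy
    if sy == 0:
        sy = sx
    return sx, sy


def classify_effect_pairs(points: pd.DataFrame,
                          model: CenterLineModel) -> pd.DataFrame:
    """Label each effect pair (see module docstring).

    ``points`` is a DataFrame with columns ``x`` and ``y`` indexed by
    analyte id.  Returns a DataFrame with x, y, signed ``distance`` and
    ``label``.  With ``sigma == 0`` every off-line point falls outside the
    band (documented behavior, not an error).
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    d = model.distance(x, y)
    # absolute tolerance absorbs float noise for points exactly on the line
    tol = 1e-12 * (1.0 + np.abs(x) + np.abs(y))
    within = np.abs(d) <= model.band_halfwidth + tol
    labels = []
    for xi, yi, di, wi in zip(x, y, d, within):
        sx, sy = _effective_signs(xi, yi)
        if sx > 0 and sy > 0:        # quadrant 1
            if wi:
                labels.append("consistent_up")
            else:
                labels.append("Q1_top" if di > 0 else "Q1_bottom")
        elif sx < 0 and sy < 0:      # quadrant 3
            if wi:
                labels.append("consistent_down")
            else:
                labels.append("Q3_top" if di > 0 else "Q3_bottom")
        elif sx < 0 and sy > 0:
            labels.append("Q2")
        else:
            labels.append("Q4")
    return pd.DataFrame({"x": x, "y": y, "distance": d, "label": labels},
                        index=points.index)


def concordance_fraction(assignments: pd.DataFrame) -> float:
    """Fraction of points labeled consistent_up or consistent_down."""
    if len(assignments) == 0:
        raise DegenerateInputError("no assignments: fraction undefined")
    consistent = assignments["label"].isin(["consistent_up", "consistent_down"])
    return float(consistent.mean())
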