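"""Ordinary-least-squares line fit shared by the standard-curve and
relaxometry modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept/goodness of a straight-line fit y = intercept + slope*x."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a line fit needs at least 2 points")
        if not np.isfinite(self.slope):
            raise ValueError("non-finite slope")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"R² out of [0, 1]: {self.r_squared}")

    @classmethod
    def fit(cls, x, y) -> "LinearFit":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if x.size < 2:
            raise ValueError("need at least 2 points")
        if np.ptp(x) == 0:
            raise ValueError("x values are constant; slope undefined")
        res = stats.linregress(x, y)
        # linregress r is NaN when y is constant: a flat line fits exactly
        r2 = 1.0 if np.ptp(y) == 0 else float(res.rvalue) ** 2
        return cls(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=min(max(r2, 0.0), 1.0),
            n_points=int(x.size),
            x_range=(float(x.min()), float(x.max())),
        )

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)
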