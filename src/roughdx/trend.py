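"""Longitudinal trend analysis for single observation series.

For a registered patient the per-observation series over encounters is
fitted with a least-squares polynomial trendline (order 3 by default, capped
at n-1 points), its R-squared is reported, and the polynomial is evaluated
forward to forecast the next encounters.  The attribute's "normal"
reference-range interval (desirable/optimal for the lipid attributes) is
exposed as an overlay band for prognosis plots.

Numerical note: x values are centred before fitting to keep the cubic
normal equations well conditioned; coefficients are reported in the
original encounter-index coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import MISSING, DecisionTable
from .discretization import builtin_schemes


class TrendError(ValueError):
    pass


#: Which reference-range label counts as the "normal" band per attribute.
NORMAL_LABELS = {
    "BMI": "normal", "SBP": "normal", "DBP": "normal", "FBS": "normal",
    "TG": "normal", "HDL": "normal", "AST": "normal", "ALT": "normal",
    "TC": "desirable", "LDL": "optimal",
    # the 4-5.9 HbA1c interval is the non-diabetic range; its guideline
    # label in the interval vocabulary is "hypoglycemia"
    "Hba1c": "hypoglycemia",
}


@dataclass
class ObservationSeries:
    pid: str
    attribute: str
    points: list     # ordered (encounter index, value)

    def __post_init__(self):
        xs = [x for x, _ in self.points]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise TrendError("encounter indices must be strictly increasing")
        if any(not math.isfinite(float(y)) for _, y in self.points):
            raise TrendError("series values must be finite")

    @classmethod
    def from_table(cls, table: DecisionTable, pid: str, attribute: str):
        idx = table.patients().get(pid)
        if idx is None:
            raise TrendError(f"unknown patient {pid!r}")
        pts = []
        for i in idx:
            r = table.records[i]
            v = r.values.get(attribute, MISSING)
            if v is not MISSING:
                pts.append((r.encounter_id, float(v)))
        return cls(pid=pid, attribute=attribute, points=pts)


@dataclass
class TrendModel:
    pid: str
    attribute: str
    degree: int
    coefficients: list          # ascending powers, original coordinates
    r_squared: float
    x_last: float
    forecasts: list = field(default_factory=list)
    normal_band: tuple | None = None

    def predict(self, x) -> float:
        return float(sum(c * x ** p for p, c in enumerate(self.coefficients)))


def fit_trend(series: ObservationSeries, degree: int = 3) -> TrendModel:
    """Least-squares polynomial trend of effective degree min(degree, n-1).

    R^2 = 1 - SS_res/SS_tot, with the convention R^2 = 1 when both sums are
    zero (constant series fitted exactly).
    """
    pts = series.points
    if len(pts) < 2:
        raise TrendError("need at least 2 points to fit a trend")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(x)) != len(x):
        raise TrendError("duplicate encounter indices")
    eff = min(degree, len(pts) - 1)
    x0 = x.mean()
    coef_c = np.polynomial.polynomial.polyfit(x - x0, y, eff)
    # shift back to original coordinates
    poly = np.polynomial.Polynomial(coef_c)(np.polynomial.Polynomial([-x0, 1.0]))
    coefficients = list(np.asarray(poly.coef, dtype=float))
    coefficients += [0.0] * (eff + 1 - len(coefficients))
    fitted = np.polynomial.polynomial.polyval(x - x0, coef_c)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return TrendModel(
        pid=series.pid,
        attribute=series.attribute,
        degree=eff,
        coefficients=coefficients,
        r_squared=r2,
        x_last=float(x[-1]),
        normal_band=annotate_band(series.attribute),
    )


def forecast(model: TrendModel, horizon: int = 3) -> list:
    """Evaluate the trend polynomial at the next ``horizon`` encounters."""
    if horizon < 1:
        raise TrendError("horizon must be >= 1")
    out = [(model.x_last + h, model.predict(model.x_last + h))
           for h in range(1, horizon + 1)]
    model.forecasts = out
    return out


def annotate_band(attribute: str, schemes: dict | None = None):
    """Finite bounds of the attribute's "normal" reference interval, or None
    when the attribute has no reference table.  One-sided intervals yield
    None on the unbounded side."""
    schemes = schemes or builtin_schemes()
    scheme = schemes.get(attribute)
    label = NORMAL_LABELS.get(attribute)
    if scheme is None or label is None:
        return None
    for iv in scheme.intervals:
        if iv.label == label:
            lo = None if math.isinf(iv.low) else iv.low
            hi = None if math.isinf(iv.high) else iv.high
            return (lo, hi)
    return None


def plot_trend(series: ObservationSeries, model: TrendModel,
               horizon: int = 3, path=None):
    """Scatter-line plot of the series with the fitted trendline, forecasts
    and the normal-range band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [p[0] for p in series.points]
    y = [p[1] for p in series.points]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, y, "o-", color="tab:blue", lw=2, label="observations")
    grid = np.linspace(min(x), max(x) + horizon, 200)
    ax.plot(grid, [model.predict(g) for g in grid], "k--",
            label=f"order-{model.degree} trend (R$^2$={model.r_squared:.3f})")
    fc = forecast(model, horizon)
    ax.plot([p[0] for p in fc], [p[1] for p in fc], "ks", label="forecast")
    if model.normal_band:
        lo, hi = model.normal_band
        lo = lo if lo is not None else min(min(y), *(p[1] for p in fc)) - 1
        hi = hi if hi is not None else max(max(y), *(p[1] for p in fc)) + 1
        ax.axhspan(lo, hi, color="orange", alpha=0.25, label="normal range")
    ax.set_xlabel("encounter")
    ax.set_ylabel(series.attribute)
    ax.set_title(f"{series.pid}: {series.attribute}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
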