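"""Group-separation statistics for brain-age predictions.

Each diagnostic group's predictions (predicted age ``y`` versus chronological
age ``x``) are summarized by an ordinary least-squares line of best fit (LOBF)
plus the standard deviation of the residuals about that line.  Two statistics
quantify how far apart two groups' prediction distributions sit over a
chronological-age window:

* **BAD** (brain age difference, years): the window-averaged vertical gap
  between the two LOBFs,

  .. math:: \\mathrm{BAD} = \\frac{1}{x_{max}-x_{min}}
            \\int_{x_{min}}^{x_{max}}
            \\bigl[\\mathrm{LOBF}_{AD}(x) - \\mathrm{LOBF}_{CU}(x)\\bigr]\\,dx

* **ID** (integrated difference, dimensionless in [0, 1]): each group's
  predictions at age ``x`` are modeled as a normal density over ``y`` centred
  on its LOBF with the group's residual SD; ID is the normalized integral of
  the absolute difference between the two density surfaces,

  .. math:: \\mathrm{ID} = \\frac{1}{2(x_{max}-x_{min})}
            \\int_{x_{min}}^{x_{max}} \\int_{-\\infty}^{\\infty}
            \\bigl|f_{AD}(x,y) - f_{CU}(x,y)\\bigr|\\,dy\\,dx

  which is the window-average of the total-variation distance between the two
  conditional normals.  0 means identical distributions; 1 means disjoint.

The inner ``y`` integral is evaluated in closed form through normal-CDF
evaluations at the points where the two densities cross (one crossing for
equal SDs, up to two otherwise); the outer ``x`` integral uses fixed-order
Gauss–Legendre quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import DegenerateFitError, ConfigurationError

__all__ = [
    "AgeWindow",
    "GroupFit",
    "MetricsResult",
    "fit_lobf",
    "compute_bad",
    "build_group_pdf",
    "compute_id",
    "compute_id_windows",
]

#: Default quadrature order for the outer (chronological age) integral.
DEFAULT_NODES = 64


@dataclass(frozen=True)
class AgeWindow:
    """Closed chronological-age interval ``[x_min, x_max]`` in years."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ConfigurationError(
                f"AgeWindow requires x_min < x_max, got [{self.x_min}, {self.x_max}]"
            )

    @property
    def span(self) -> float:
        return self.x_max - self.x_min

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    def subdivide(self, increment: float) -> list["AgeWindow"]:
        """Partition into consecutive sub-windows of width ``increment``.

        If ``increment`` does not evenly divide the span, the final
        sub-window is truncated at ``x_max``.
        """
        if increment <= 0:
            raise ConfigurationError(f"increment must be positive, got {increment}")
        edges = [self.x_min]
        while edges[-1] + increment < self.x_max - 1e-9:
            edges.append(edges[-1] + increment)
        edges.append(self.x_max)
        return [AgeWindow(a, b) for a, b in zip(edges[:-1], edges[1:])]


#: The standard evaluation window: ages 55–75, where the regressors
#: retain discriminative power.
TARGET_WINDOW = AgeWindow(55.0, 75.0)


@dataclass(frozen=True)
class GroupFit:
    """One group's prediction line of best fit and residual spread.

    ``predict(x) = slope * x + intercept`` is the group's expected predicted
    age at chronological age ``x``; ``sigma`` is the standard deviation of the
    prediction residuals about that line (homoscedastic by construction).
    """

    slope: float
    intercept: float
    sigma: float
    n: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateFitError(f"GroupFit requires n >= 2, got {self.n}")
        if self.sigma < 0:
            raise DegenerateFitError(f"GroupFit requires sigma >= 0, got {self.sigma}")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class MetricsResult:
    """One row of a differentiation-metrics table: BAD, ID and the group SDs."""

    bad: float
    id: float
    sigma_cu: float
    sigma_ad: float
    window: AgeWindow
    n_cu_tested: int
    n_ad_tested: int
    labels: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = dict(self.labels)
        row.update(
            window=f"{self.window.x_min:g}-{self.window.x_max:g}",
            bad=self.bad,
            sigma_cu=self.sigma_cu,
            sigma_ad=self.sigma_ad,
            id=self.id,
            n_cu_tested=self.n_cu_tested,
            n_ad_tested=self.n_ad_tested,
        )
        return row


def fit_lobf(preds, group: str | None = None, *, ddof: int = 0) -> GroupFit:
    """Ordinary least-squares line of predicted age on chronological age.

    Parameters
    ----------
    preds
        Either a prediction table (DataFrame with ``age``, ``predicted_age``
        and ``diagnosis`` columns) or a ``(x, y)`` pair of arrays.
    group
        If given and ``preds`` is a table, restrict to rows whose
        ``diagnosis`` equals this label.
    ddof
        Delta degrees of freedom for the residual standard deviation.  The
        default 0 is the population convention (divide by n).

    Raises
    ------
    DegenerateFitError
        Fewer than two points, or all chronological ages identical.
    """
    if isinstance(preds, pd.DataFrame):
        table = preds
        if group is not None:
            table = table[table["diagnosis"] == group]
        x = table["age"].to_numpy(dtype=float)
        y = table["predicted_age"].to_numpy(dtype=float)
    else:
        x, y = preds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)

    n = x.size
    if n < 2:
        raise DegenerateFitError(f"need at least 2 points to fit a line, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all chronological ages identical; slope undefined")

    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    sigma = float(np.sqrt(np.sum(residuals**2) / (n - ddof)))
    return GroupFit(
        slope=float(slope),
        intercept=float(intercept),
        sigma=sigma,
        n=int(n),
        group=group or "",
    )


def compute_bad(fit_cu: GroupFit, fit_ad: GroupFit, window: AgeWindow) -> float:
    """Window-averaged AD−CU gap between the two lines of best fit, in years.

    For straight lines the average of the difference over the window equals
    the difference evaluated at the window midpoint.  Positive values mean AD
    subjects are predicted older than CU subjects of the same age; the sign
    may flip at high ages where the lines cross.
    """
    mid = window.midpoint
    return float(fit_ad.predict(mid) - fit_cu.predict(mid))


def build_group_pdf(fit: GroupFit, x: float):
    """Normal density over predicted age ``y`` at chronological age ``x``.

    Returns a frozen ``scipy.stats.norm`` with mean ``LOBF(x)`` and scale
    ``sigma``.  A zero residual SD has no proper density; that degenerate
    case is handled inside :func:`compute_id` and rejected here.
    """
    if fit.sigma <= 0:
        raise DegenerateFitError(
            "sigma = 0: prediction distribution is a point mass; no density exists"
        )
    return norm(loc=float(fit.predict(x)), scale=fit.sigma)


def _abs_diff_integral(m1: float, s1: float, m2: float, s2: float) -> float:
    """∫ |N(m1,s1) − N(m2,s2)| dy, i.e. twice the total-variation distance.

    Closed form via CDF evaluations at the density crossing points: the sign
    of the difference is constant between crossings, so the integral is the
    sum of |ΔCDF| over the intervals they delimit.
    """
    if s1 == s2:
        if m1 == m2:
            return 0.0
        # single crossing at the midpoint of the means
        return 2.0 * (2.0 * norm.cdf(abs(m1 - m2) / (2.0 * s1)) - 1.0)

    # roots of the quadratic from equating the two normal log-densities
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 - 2.0 * math.log(s1 / s2)
    disc = b * b - 4.0 * a * c
    roots: list[float] = []
    if disc > 0:
        sq = math.sqrt(disc)
        roots = sorted([(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)])
    elif disc == 0:
        roots = [-b / (2.0 * a)]

    d_at = [norm.cdf(r, m1, s1) - norm.cdf(r, m2, s2) for r in roots]
    # D = F1 − F2 vanishes at ±∞; sum |ΔD| across the delimited intervals
    points = [0.0, *d_at, 0.0]
    return float(sum(abs(points[i + 1] - points[i]) for i in range(len(points) - 1)))


def _tv_at(fit_a: GroupFit, fit_b: GroupFit, x: np.ndarray) -> np.ndarray:
    """Total-variation distance between the two groups' densities at each x."""
    mean_a = fit_a.predict(x)
    mean_b = fit_b.predict(x)
    if fit_a.sigma == 0 or fit_b.sigma == 0:
        # a point mass differs totally from any other distribution unless both
        # are point masses at the same location
        both_point = fit_a.sigma == 0 and fit_b.sigma == 0
        same = np.isclose(mean_a, mean_b, rtol=0.0, atol=1e-12)
        return np.where(both_point & same, 0.0, 1.0).astype(float)
    return np.array(
        [
            0.5 * _abs_diff_integral(ma, fit_a.sigma, mb, fit_b.sigma)
            for ma, mb in zip(np.atleast_1d(mean_a), np.atleast_1d(mean_b))
        ]
    )


def compute_id(
    fit_cu: GroupFit,
    fit_ad: GroupFit,
    window: AgeWindow,
    *,
    nodes: int = DEFAULT_NODES,
) -> float:
    """Integrated difference between the two prediction-density surfaces.

    The normalization ``1 / (2 * span)`` makes the result the window-average
    total-variation distance, hence always in [0, 1]: 0 for coinciding
    (LOBF, sigma) pairs, approaching 1 as the distributions separate.
    Symmetric in its two group arguments.
    """
    nodes_x, weights = np.polynomial.legendre.leggauss(nodes)
    # map from [-1, 1] onto the window
    x = window.midpoint + 0.5 * window.span * nodes_x
    tv = _tv_at(fit_cu, fit_ad, x)
    # quadrature of TV over the window, divided by the span == weighted mean
    value = float(np.sum(weights * tv) * 0.5)
    return min(max(value, 0.0), 1.0)


def compute_id_windows(
    fit_cu: GroupFit,
    fit_ad: GroupFit,
    window: AgeWindow,
    increment: float,
    *,
    nodes: int = DEFAULT_NODES,
) -> list[tuple[AgeWindow, float]]:
    """ID evaluated on consecutive sub-windows of width ``increment``.

    Each sub-window's value is exactly :func:`compute_id` restricted to it,
    e.g. increments of 4 years on [55, 75] give the five ranges
    55–59, 59–63, 63–67, 67–71 and 71–75.
    """
    return [
        (sub, compute_id(fit_cu, fit_ad, sub, nodes=nodes))
        for sub in window.subdivide(increment)
    ]
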