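"""Dissociation-constant estimation from EMSA binding series.

An electrophoretic mobility shift series titrates total DNA against a
fixed amount of protein; band intensities give the bound and free DNA
concentration per reaction. Two classical single-site models are fitted:

* Michaelis–Menten (hyperbolic saturation): Bound = Bmax·Total/(Kd + Total),
  fitted by nonlinear least squares;
* Scatchard linearisation: Bound/Free regressed on Bound, slope = -1/Kd,
  intercept = Bmax/Kd, by ordinary least squares.

On noiseless single-site data the two agree exactly; with noise the
Scatchard estimate is biased (the linearisation distorts the error
structure), which is why both are reported side by side. Conversion of gel
band intensity to concentration is the caller's job; this module consumes
concentrations (nM).
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .core import ValidationError


@dataclass(frozen=True)
class BindingSeries:
    """Per-reaction total, bound and free DNA concentrations (nM)."""

    total: np.ndarray
    bound: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", np.asarray(self.total, dtype=float))
        object.__setattr__(self, "bound", np.asarray(self.bound, dtype=float))
        if self.total.shape != self.bound.shape:
            raise ValidationError("total and bound must have equal length")
        if (self.bound < 0).any() or (self.bound > self.total).any():
            raise ValidationError("require 0 <= bound <= total per reaction")

    @property
    def free(self) -> np.ndarray:
        return self.total - self.bound

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingSeries":
        if not {"total", "bound"} <= set(df.columns):
            raise ValidationError("binding series needs columns: total, bound")
        return cls(df["total"].to_numpy(), df["bound"].to_numpy())


@dataclass(frozen=True)
class KdEstimate:
    kd: float
    bmax: float
    model: str  # michaelis_menten | scatchard
    rss: float
    ill_determined: bool = False

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError(f"non-positive Kd {self.kd}")


def _mm(total: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * total / (kd + total)


def fit_michaelis_menten(series: BindingSeries) -> KdEstimate:
    """Nonlinear least-squares fit of the hyperbolic saturation model.

    Starts at Bmax0 = 1.1·max(bound), Kd0 = median(total). The estimate is
    flagged ill-determined when the relative standard error of Kd exceeds
    50%, or when every titration point lies more than an order of magnitude
    above the fitted Kd — a fully saturated series where the curvature
    carrying Kd information is absent from the sampled range.
    """
    if np.unique(series.total).size < 3:
        raise ValidationError("need >= 3 distinct total concentrations")
    scale = float(series.bound.max())
    if scale <= 0:
        raise ValidationError("no binding detected: bound is zero everywhere")
    # bound is nondimensionalised by its maximum so Bmax and Kd are fitted
    # on comparable scales regardless of concentration units
    try:
        popt, pcov = curve_fit(
            _mm,
            series.total,
            series.bound / scale,
            p0=(1.1, float(np.median(series.total))),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValidationError(f"Michaelis-Menten fit did not converge: {exc}") from None
    bmax, kd = float(popt[0]) * scale, float(popt[1])
    resid = series.bound - _mm(series.total, bmax, kd)
    rss = float((resid**2).sum())
    kd_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    return KdEstimate(
        kd=kd,
        bmax=bmax,
        model="michaelis_menten",
        rss=rss,
        ill_determined=(
            not np.isfinite(kd_se)
            or kd_se / kd > 0.5
            or float(series.total.min()) > 10.0 * kd
        ),
    )


def fit_scatchard(series: BindingSeries) -> KdEstimate:
    """Ordinary least squares of Bound/Free on Bound (Scatchard plot).

    Reactions with no detectable free DNA (free = 0, i.e. full occupancy of
    the probe) carry an undefined Bound/Free and are excluded from the
    regression with a warning.
    """
    free = series.free
    used = free > 0
    if not used.all():
        warnings.warn(
            f"excluding {int((~used).sum())} reaction(s) with free = 0 from the "
            "Scatchard regression",
            stacklevel=2,
        )
    if used.sum() < 2:
        raise ValidationError("Scatchard fit requires >= 2 reactions with free > 0")
    x = series.bound[used]
    y = series.bound[used] / free[used]
    if np.unique(x).size < 2:
        raise ValidationError("need >= 2 distinct bound values")
    fit = linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise ValidationError(
            f"no saturable binding: Scatchard slope {slope:.4g} is nonnegative"
        )
    kd = -1.0 / slope
    bmax = -intercept / slope
    rss = float(((y - (intercept + slope * x)) ** 2).sum())
    return KdEstimate(kd=kd, bmax=bmax, model="scatchard", rss=rss)


def fit_both(series: BindingSeries) -> pd.DataFrame:
    """Fit both models and return one row per model."""
    rows = []
    for fn in (fit_michaelis_menten, fit_scatchard):
        est = fn(series)
        rows.append(
            {
                "model": est.model,
                "kd": est.kd,
                "bmax": est.bmax,
                "rss": est.rss,
                "ill_determined": est.ill_determined,
            }
        )
    return pd.DataFrame(rows)


def simulate_series(
    kd: float,
    bmax: float,
    totals: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BindingSeries:
    """Generate a single-site binding series with Gaussian noise on Bound.

    ``noise_sd`` is in concentration units (a fraction of Bmax is the
    conventional choice); Bound is clipped into [0, Total].
    """
    totals = np.asarray(totals, dtype=float)
    bound = _mm(totals, bmax, kd)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        bound = bound + rng.normal(0.0, noise_sd, size=totals.shape)
    bound = np.clip(bound, 0.0, totals)
    return BindingSeries(total=totals, bound=bound)


def equilibrium_series(kd: float, bmax: float, totals: Sequence[float]) -> BindingSeries:
    """Noiseless series from the exact single-site mass-action equilibrium.

    Solves P + D <-> PD with total protein ``bmax`` and total DNA per
    reaction: Bound is the smaller root of
    B^2 - (T + Bmax + Kd) B + T*Bmax = 0, so Bound/Free is exactly linear
    in Bound (the Scatchard identity holds without approximation). The
    hyperbolic model in *total* DNA is only the weak-depletion
    approximation of this equilibrium.
    """
    totals = np.asarray(totals, dtype=float)
    s = totals + bmax + kd
    bound = (s - np.sqrt(s * s - 4.0 * totals * bmax)) / 2.0
    return BindingSeries(total=totals, bound=bound)
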