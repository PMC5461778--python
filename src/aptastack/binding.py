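"""Filter-binding curves and Hill-equation dissociation-constant fits.

Fraction bound for one sample is

    Fb = counts_nitrocellulose / (counts_nitrocellulose + counts_nylon)

and a titration of protein concentration [P] (nM) against Fb is fit by
constrained nonlinear least squares to the Hill equation

    Fb = Min + (Max - Min) / (1 + (Kd / [P])**n)

with Kd > 0, n > 0 and 0 <= Min <= Max <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["BindingCurve", "HillFit", "fraction_bound", "hill_equation", "fit_hill"]


def fraction_bound(counts_nitrocellulose: float, counts_nylon: float) -> float:
    """Bound fraction from the two membranes' radioactivity counts."""
    if counts_nitrocellulose < 0 or counts_nylon < 0:
        raise ValueError("counts must be non-negative")
    total = counts_nitrocellulose + counts_nylon
    if total == 0:
        raise ValueError("no signal: both membrane counts are zero")
    return counts_nitrocellulose / total


def hill_equation(conc, kd: float, n: float, min_frac: float, max_frac: float):
    conc = np.asarray(conc, dtype=float)
    return min_frac + (max_frac - min_frac) / (1.0 + (kd / conc) ** n)


@dataclass
class BindingCurve:
    """Protein concentrations (nM) against measured bound fractions."""

    concentrations: np.ndarray
    fractions_bound: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.fractions_bound, dtype=float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("concentrations and fractions must be equal-length vectors")
        keep = c > 0  # a zero-concentration point cannot enter the ratio term
        self.concentrations = c[keep]
        self.fractions_bound = f[keep]

    @classmethod
    def from_counts(cls, concentrations, counts_nc, counts_nylon) -> "BindingCurve":
        fb = [fraction_bound(a, b) for a, b in zip(counts_nc, counts_nylon)]
        return cls(np.asarray(concentrations, float), np.asarray(fb))


@dataclass
class HillFit:
    kd: float  # nM
    hill_n: float
    min_frac: float
    max_frac: float
    rss: float
    converged: bool
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "kd_nM": self.kd,
            "hill_n": self.hill_n,
            "min_frac": self.min_frac,
            "max_frac": self.max_frac,
            "rss": self.rss,
            "converged": self.converged,
        }


def _initial_kd(conc: np.ndarray, fb: np.ndarray) -> float:
    """Concentration at which interpolated Fb crosses the observed midpoint."""
    order = np.argsort(conc)
    c, f = conc[order], fb[order]
    mid = (f.min() + f.max()) / 2.0
    above = np.nonzero(f >= mid)[0]
    if above.size == 0 or above[0] == 0:
        return float(np.median(c))
    i = above[0]
    c0, c1, f0, f1 = c[i - 1], c[i], f[i - 1], f[i]
    if f1 == f0:
        return float(c1)
    # interpolate in log-concentration
    t = (mid - f0) / (f1 - f0)
    return float(np.exp(np.log(c0) + t * (np.log(c1) - np.log(c0))))


def fit_hill(curve: BindingCurve, min_points: int = 5) -> HillFit:
    """Constrained least-squares Hill fit; deterministic given the data.

    Starting values: Kd at the observed half-saturation concentration,
    n = 1, Min/Max at the observed extremes.  Parameters are box
    constrained (Kd > 0, n > 0, fractions in [0, 1]); the Min <= Max
    ordering holds at the start and is preserved in practice by the data.
    """
    c = np.asarray(curve.concentrations, float)
    f = np.asarray(curve.fractions_bound, float)
    if c.size < min_points:
        raise ValueError(f"need >= {min_points} positive-concentration points")
    if np.log10(c.max() / c.min()) < 1.0:
        raise ValueError("concentrations must span at least one decade")
    x0 = np.array([_initial_kd(c, f), 1.0, max(f.min(), 0.0), min(f.max(), 1.0)])
    eps = 1e-12
    lower = np.array([eps, eps, 0.0, 0.0])
    upper = np.array([np.inf, np.inf, 1.0, 1.0])
    x0 = np.clip(x0, lower + eps, None)

    def resid(p):
        return hill_equation(c, *p) - f

    res = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    kd, n, mn, mx = res.x
    if mn > mx:  # degenerate decreasing fit; swap to honor the invariant
        mn, mx = mx, mn
    return HillFit(
        kd=float(kd),
        hill_n=float(n),
        min_frac=float(mn),
        max_frac=float(mx),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
        message=res.message,
    )
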