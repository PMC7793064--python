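"""Logicle (biexponential) transformation for flow-cytometry fluorescence.

The logicle scale of Parks, Roederer & Moore (Cytometry A, 2006) is linear
around zero — where compensated data are roughly normally distributed and may
be negative — and asymptotically logarithmic at high intensity.  It is the
standard display/analysis scale for compensated cytometry data.

The transform is parameterised by

* ``t`` — top of the raw data scale (a.u.), e.g. 262144 for an 18-bit ADC;
* ``m`` — total display width in decades;
* ``w`` — width of the linearised region around zero, in decades;
* ``a`` — additional negative decades displayed below zero.

The *inverse* transform (display -> raw value) has the closed biexponential
form ``B(y) = a_c * exp(b*y) - c_c * exp(-d*y) - f_c`` with coefficients
derived from (t, w, m, a); the forward transform inverts ``B`` numerically.
``B`` is strictly increasing, so a safeguarded bisection converges to machine
precision and the transform is deterministic.

Display values are expressed in decades, i.e. on ``[0, m + a]`` for
non-negative input (the conventional axis annotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["LogicleParams", "Logicle", "logicle", "inverse_logicle"]


@dataclass(frozen=True)
class LogicleParams:
    """Parameter set (w, t, m, a) of the logicle scale, all in decades except t."""

    w: float = 0.75
    t: float = 262144.0
    m: float = 4.5
    a: float = 0.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"logicle top of scale t must be > 0, got {self.t}")
        if self.m <= 0:
            raise ValueError(f"logicle decades m must be > 0, got {self.m}")
        if self.w < 0:
            raise ValueError(f"logicle width w must be >= 0, got {self.w}")
        if self.a < 0:
            raise ValueError(f"logicle extra negative decades a must be >= 0, got {self.a}")
        if self.w > self.m / 2:
            raise ValueError("logicle width w may not exceed m/2")


class Logicle:
    """Callable logicle transform for a fixed parameter set.

    ``transform`` maps raw fluorescence to display decades; ``inverse`` maps
    display decades back to the raw scale.  Negative raw values are handled by
    the symmetric reflection of the biexponential about the linearisation
    centre, as in the reference implementation.
    """

    def __init__(self, params: LogicleParams | None = None) -> None:
        p = params or LogicleParams()
        self.params = p
        total = p.m + p.a
        self._decades = total
        # unit-scale geometry: y in [0, 1] spans (m + a) decades
        self._w = p.w / total
        x2 = p.a / total
        self._x1 = x2 + self._w
        self._x0 = x2 + 2.0 * self._w
        self._b = total * np.log(10.0)
        self._d = self._solve_d(self._b, self._w)
        c_a = np.exp(self._x0 * (self._b + self._d))
        mf_a = np.exp(self._b * self._x1) - c_a / np.exp(self._d * self._x1)
        self._a = p.t / ((np.exp(self._b) - mf_a) - c_a / np.exp(self._d))
        self._c = c_a * self._a
        # offset chosen so that B(x1) = 0 (raw zero sits at the linear centre)
        self._f = mf_a * self._a

    @staticmethod
    def _solve_d(b: float, w: float) -> float:
        # root of 2 (ln d - ln b) + w (b + d) = 0 in (0, b]; d = b when w = 0
        if w == 0.0:
            return b

        def fn(d: float) -> float:
            return 2.0 * (np.log(d) - np.log(b)) + w * (b + d)

        return float(brentq(fn, 1e-12, b, xtol=1e-14, rtol=8.9e-16))

    # -- inverse: display decades -> raw value -------------------------------
    def _biexp(self, y: np.ndarray) -> np.ndarray:
        return self._a * np.exp(self._b * y) - self._c * np.exp(-self._d * y) - self._f

    def inverse(self, decades):
        """Map display decades back to raw fluorescence (vectorised)."""
        y = np.asarray(decades, dtype=float) / self._decades
        neg = y < self._x1
        y_ref = np.where(neg, 2.0 * self._x1 - y, y)
        v = self._biexp(y_ref)
        return np.where(neg, -v, v)

    # -- forward: raw value -> display decades -------------------------------
    def transform(self, values):
        """Map raw fluorescence to display decades (vectorised, monotone)."""
        x = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(x)):
            bad = np.flatnonzero(~np.isfinite(np.ravel(x)))
            raise ValueError(
                f"logicle transform requires finite input; {bad.size} non-finite "
                f"value(s), first offending flat indices {bad[:10].tolist()}"
            )
        sign = np.where(x < 0, -1.0, 1.0)
        v = np.abs(x)
        # bracket on unit scale: B(x1) = 0 and B is increasing
        lo = np.full(v.shape, self._x1)
        hi = np.full(v.shape, 1.0)
        # extend upper bracket for values above t
        while True:
            need = self._biexp(hi) < v
            if not np.any(need):
                break
            hi = np.where(need, hi + 0.5, hi)
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            below = self._biexp(mid) < v
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        y = 0.5 * (lo + hi)
        y = self._x1 + sign * (y - self._x1)
        return y * self._decades

    __call__ = transform


def logicle(values, params: LogicleParams | None = None):
    """Functional form of :meth:`Logicle.transform`."""
    return Logicle(params).transform(values)


def inverse_logicle(decades, params: LogicleParams | None = None):
    """Functional form of :meth:`Logicle.inverse`."""
    return Logicle(params).inverse(decades)
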