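"""Two-segment ("dual") power-law speed distribution.

Freely swimming tadpoles show a swimming-speed histogram that follows two
power-law regimes on [0, 200] mm/s joined at a critical point near 24 mm/s.
The density here is continuous at the breakpoint c:

    f(s) = K * s**(-a_low)                    for s_min <= s < c
    f(s) = K * c**(a_high - a_low) * s**(-a_high)   for c <= s <= s_max

with K fixed by normalization. The low exponent must be < 1 when s_min = 0
for the density to be integrable at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def _seg_integral(a: float, lo: float, hi: float) -> float:
    """Integral of s**(-a) over [lo, hi]."""
    if abs(a - 1.0) < 1e-9:
        if lo <= 0:
            return np.inf
        return np.log(hi / lo)
    p = 1.0 - a
    lo_p = 0.0 if lo == 0.0 else lo ** p
    return (hi ** p - lo_p) / p


@dataclass(frozen=True)
class DualPowerLaw:
    """Continuous two-segment power law on [s_min, s_max] with breakpoint c."""

    c: float = 24.0
    alpha_low: float = 0.5
    alpha_high: float = 2.5
    s_min: float = 0.0
    s_max: float = 200.0

    def __post_init__(self) -> None:
        if not (self.s_min <= self.c <= self.s_max):
            raise ValueError("breakpoint must lie inside [s_min, s_max]")
        if self.s_min == 0.0 and self.alpha_low >= 1.0:
            raise ValueError("alpha_low must be < 1 when s_min = 0 (integrability)")

    # segment normalization pieces: Z = Z1 + Z2, f = s^-a / Z on the low side
    @property
    def _z1(self) -> float:
        return _seg_integral(self.alpha_low, self.s_min, self.c)

    @property
    def _z2(self) -> float:
        return (self.c ** (self.alpha_high - self.alpha_low)
                * _seg_integral(self.alpha_high, self.c, self.s_max))

    @property
    def mass_low(self) -> float:
        """Probability mass below the breakpoint."""
        z1, z2 = self._z1, self._z2
        return z1 / (z1 + z2)

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        z = self._z1 + self._z2
        out = np.zeros_like(s)
        lo = (s >= self.s_min) & (s < self.c)
        hi = (s >= self.c) & (s <= self.s_max)
        with np.errstate(divide="ignore"):
            out[lo] = s[lo] ** (-self.alpha_low) / z
            out[hi] = (self.c ** (self.alpha_high - self.alpha_low)
                       * s[hi] ** (-self.alpha_high) / z)
        return out

    def cdf(self, s):
        s = np.clip(np.asarray(s, dtype=float), self.s_min, self.s_max)
        z = self._z1 + self._z2
        out = np.empty_like(s)
        lo = s < self.c
        out[lo] = _seg_integral_vec(self.alpha_low, self.s_min, s[lo]) / z
        out[~lo] = (self._z1 + self.c ** (self.alpha_high - self.alpha_low)
                    * _seg_integral_vec(self.alpha_high, self.c, s[~lo])) / z
        return out

    def ppf(self, q):
        """Analytic inverse CDF (used for sampling and as an oracle)."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantiles must lie in [0, 1]")
        z = self._z1 + self._z2
        target = q * z
        out = np.empty_like(q)
        lo = target < self._z1
        # low segment: invert (s^p - s_min^p)/p = target, p = 1 - a_low
        p = 1.0 - self.alpha_low
        smin_p = 0.0 if self.s_min == 0.0 else self.s_min ** p
        out[lo] = (smin_p + p * target[lo]) ** (1.0 / p)
        # high segment
        p2 = 1.0 - self.alpha_high
        scale = self.c ** (self.alpha_high - self.alpha_low)
        out[~lo] = (self.c ** p2 + p2 * (target[~lo] - self._z1) / scale) ** (1.0 / p2)
        return np.clip(out, self.s_min, self.s_max)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(_EPS, 1.0 - _EPS, size=size))

    def loglik(self, s: np.ndarray) -> float:
        s = np.asarray(s, dtype=float)
        if np.any((s < self.s_min) | (s > self.s_max)):
            return -np.inf
        z = self._z1 + self._z2
        hi = s >= self.c
        n2 = int(hi.sum())
        with np.errstate(divide="ignore"):
            ll = (-len(s) * np.log(z)
                  - self.alpha_low * np.log(s[~hi]).sum()
                  - self.alpha_high * np.log(s[hi]).sum()
                  + n2 * (self.alpha_high - self.alpha_low) * np.log(self.c))
        return float(ll)


def _seg_integral_vec(a: float, lo: float, hi: np.ndarray) -> np.ndarray:
    if abs(a - 1.0) < 1e-9:
        return np.log(hi / lo)
    p = 1.0 - a
    lo_p = 0.0 if lo == 0.0 else lo ** p
    return (hi ** p - lo_p) / p
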