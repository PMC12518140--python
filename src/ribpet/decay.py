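"""Physical decay of mixed positron emitters implanted by a radioactive ion beam.

A therapeutic :math:`^{11}`C beam implants, besides the projectiles themselves,
small admixtures of other positron emitters produced by fragmentation
(:math:`^{10}`C from projectile fragmentation, :math:`^{15}`O from the
oxygen-rich tissue).  The total PET signal therefore decays as a weighted sum
of exponentials,

.. math::

    A_\\mathrm{phys}(t) = \\sum_i w_i\\, 2^{-t/T_{1/2,i}},

with :math:`w_i` the fraction of isotope :math:`i` among the implanted
fragments and :math:`T_{1/2,i}` its half-life.  Dividing a measured
time-activity curve by this factor removes the physics and leaves the
biological washout, which is modelled in :mod:`ribpet.washout`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Isotope",
    "DecayMixture",
    "TimeActivitySeries",
    "c11_beam_mixture",
    "fraction_remaining",
    "decay_correct",
]

#: t-zero conventions for a time-activity series.
T_ZERO_END = "end_of_irradiation"
T_ZERO_START = "start_of_irradiation"
_T_ZERO_CHOICES = (T_ZERO_END, T_ZERO_START)


@dataclass(frozen=True)
class Isotope:
    """A positron emitter contributing to the implanted activity.

    Parameters
    ----------
    name : str
        Label, e.g. ``"11C"``.
    half_life_s : float
        Physical half-life in seconds; must be positive.
    fraction : float
        Weight of this isotope in the fragment mixture, >= 0.  Fractions are
        renormalised to unit sum by :class:`DecayMixture`.
    """

    name: str
    half_life_s: float
    fraction: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.half_life_s) or self.half_life_s <= 0:
            raise ValueError(f"half_life_s must be > 0, got {self.half_life_s!r}")
        if not np.isfinite(self.fraction) or self.fraction < 0:
            raise ValueError(f"fraction must be >= 0, got {self.fraction!r}")


@dataclass(frozen=True)
class DecayMixture:
    """An ordered set of isotopes with fractions renormalised to sum to 1.

    The fractions supplied at construction are kept in ``raw_fractions``
    (a simulation may quote weights that sum to slightly less than one, e.g.
    0.96 + 0.03 + 0.005 = 0.995); the ``isotopes`` field always holds the
    renormalised weights.
    """

    isotopes: tuple[Isotope, ...]
    raw_fractions: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        isotopes = tuple(self.isotopes)
        if not isotopes:
            raise ValueError("a DecayMixture needs at least one isotope")
        raw = tuple(iso.fraction for iso in isotopes)
        total = float(sum(raw))
        if total <= 0:
            raise ValueError("isotope fractions must have a positive sum")
        renorm = tuple(
            Isotope(iso.name, iso.half_life_s, iso.fraction / total) for iso in isotopes
        )
        object.__setattr__(self, "isotopes", renorm)
        object.__setattr__(self, "raw_fractions", raw)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([iso.fraction for iso in self.isotopes])

    @property
    def half_lives_s(self) -> np.ndarray:
        return np.array([iso.half_life_s for iso in self.isotopes])


def c11_beam_mixture() -> DecayMixture:
    """Positron-emitter mixture implanted by a ^11C ion beam in tissue.

    96% ^11C (T1/2 = 20.34 min), 3% ^10C (19 s) and 0.5% ^15O (2.04 min);
    the fractions are renormalised to unit sum at construction.
    """
    return DecayMixture(
        (
            Isotope("11C", 20.34 * 60.0, 0.96),
            Isotope("10C", 19.0, 0.03),
            Isotope("15O", 2.04 * 60.0, 0.005),
        )
    )


def fraction_remaining(mix: DecayMixture, t):
    """Undecayed fraction of a mixture after ``t`` seconds.

    Evaluates ``sum_i w_i 2**(-t/T_i)``.  Equals 1 at ``t = 0`` and is
    strictly decreasing in ``t``.  ``t`` may be a scalar or array; negative
    times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    w = mix.fractions
    half = mix.half_lives_s
    out = np.sum(w * np.exp2(-t_arr[..., None] / half), axis=-1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TimeActivitySeries:
    """Sampled activity (or counts per bin) versus time.

    ``times`` are bin-centre times in seconds, strictly increasing; ``values``
    are nonnegative activities in arbitrary units (no Bq calibration is
    attempted — it would depend on the reconstruction).  ``t_zero_convention``
    states whether t = 0 is the end or the start of the irradiation.
    """

    times: np.ndarray
    values: np.ndarray
    bin_width: float
    t_zero_convention: str = T_ZERO_END

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("series must contain at least one sample")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("values must be finite and >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.t_zero_convention not in _T_ZERO_CHOICES:
            raise ValueError(
                f"t_zero_convention must be one of {_T_ZERO_CHOICES}, "
                f"got {self.t_zero_convention!r}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


def decay_correct(
    series: TimeActivitySeries,
    mix: DecayMixture,
    *,
    min_fraction: float = 1e-12,
) -> TimeActivitySeries:
    """Divide out the physical decay of ``mix`` from a post-irradiation series.

    A series generated by pure physical decay becomes constant; what is left
    on real data is the biological washout factor.  Requires the
    end-of-irradiation t-zero convention (the decay factor is referenced to
    the end of the beam).

    Raises
    ------
    ValueError
        If the series uses the wrong t-zero convention, or if the remaining
        fraction underflows ``min_fraction`` at the latest times (dividing by
        it would amplify noise without bound; the caller must truncate).
    """
    if series.t_zero_convention != T_ZERO_END:
        raise ValueError(
            "decay_correct requires t_zero_convention='end_of_irradiation'"
        )
    frac = fraction_remaining(mix, series.times)
    if np.min(frac) < min_fraction:
        raise ValueError(
            f"physical decay factor underflows {min_fraction:g} at "
            f"t = {series.times[np.argmin(frac)]:g} s; truncate the series"
        )
    return TimeActivitySeries(
        times=series.times.copy(),
        values=series.values / frac,
        bin_width=series.bin_width,
        t_zero_convention=series.t_zero_convention,
    )
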