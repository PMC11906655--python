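"""Distance-dependent behavioural response functions.

A baited trap emits an attractant (pheromone plume, light) whose strength
decays with the distance ``d`` from the trap.  The walker's behaviour is
summarised by two parameters that may depend on ``d``:

* the **randomness parameter** ``r(d)`` — the standard deviation of the
  truncated-normal heading-offset distribution; small ``r`` means a
  near-ballistic approach to the trap, large ``r`` near-uniform headings;
* the **speed parameter** ``s(d)`` — the scale of the half-normal
  step-length distribution (mean step = ``s * sqrt(2/pi)``).

Four archetypal families are provided for each:

====  ==============================================  =========================
name  form                                            behavioural reading
====  ==============================================  =========================
r1    ``a * exp(b d)``                                attraction decays with
                                                      distance at accelerating
                                                      rate (convex)
r2    ``a d / (1 + b d)``                             decays at decelerating
                                                      rate (concave, bounded
                                                      by ``a/b``)
r3    ``J (d - a)(d - b) + 1``                        disorientation
                                                      ("dazzling") very close
                                                      to a strong source:
                                                      interior minimum at
                                                      ``(a+b)/2``
r4    ``(J e^{-a d} + q e^{b d}) / (1 + e^{b d})``    like r3 but saturating
                                                      at the asymptote ``q``
s1    ``c / sqrt(d) + h``                             speed boost near the
                                                      trap, slow decay
s2    ``c / d + h``                                   intermediate decay
s3    ``c / d**2 + h``                                inverse-square decay
                                                      (physical light
                                                      intensity)
s4    ``c * exp(-((d - d_max)/h)**2)``                peak speed at an
                                                      intermediate distance
====  ==============================================  =========================

Since ``r`` is a standard deviation it must stay positive; evaluations are
clamped below at a small floor (``r3`` with badly chosen parameters can dip
negative).  ``s1``–``s3`` diverge at ``d = 0``; in simulation this never
occurs because distance is measured to the trap *centre* and free walkers
always satisfy ``d >= R`` (trap radius).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "RParams",
    "SParams",
    "ResponseProfile",
    "eval_r",
    "eval_s",
    "r3_admissibility",
    "r3_minimum",
    "r_presets",
    "s_presets",
    "get_preset",
    "preset_names",
    "DEFAULT_R_FLOOR",
]

logger = logging.getLogger(__name__)

DEFAULT_R_FLOOR = 1e-6

R_FAMILIES = ("r1", "r2", "r3", "r4")
S_FAMILIES = ("s1", "s2", "s3", "s4")

# families for which a clamp warning has already been emitted this process
_clamp_warned: set[str] = set()


@dataclass(frozen=True)
class RParams:
    """Parameters of a randomness-response family.

    ``J`` is required for families r3 and r4, ``q`` for r4 only; unused
    parameters must be left as ``None``.  All declared parameters must be
    strictly positive.
    """

    family: str
    a: float
    b: float
    J: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.family not in R_FAMILIES:
            raise ValueError(
                f"unknown r family {self.family!r}; expected one of {R_FAMILIES}"
            )
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be strictly positive")
        if self.family in ("r3", "r4"):
            if self.J is None or not self.J > 0:
                raise ValueError(f"family {self.family} requires J > 0")
        elif self.J is not None:
            raise ValueError(f"family {self.family} does not take J")
        if self.family == "r4":
            if self.q is None or not self.q > 0:
                raise ValueError("family r4 requires q > 0")
        elif self.q is not None:
            raise ValueError(f"family {self.family} does not take q")


@dataclass(frozen=True)
class SParams:
    """Parameters of a speed-response family.

    ``d_max`` (distance of peak speed) is required for family s4 only.
    """

    family: str
    c: float
    h: float
    d_max: float | None = None

    def __post_init__(self) -> None:
        if self.family not in S_FAMILIES:
            raise ValueError(
                f"unknown s family {self.family!r}; expected one of {S_FAMILIES}"
            )
        if not (self.c > 0 and self.h > 0):
            raise ValueError("c and h must be strictly positive")
        if self.family == "s4":
            if self.d_max is None or not self.d_max > 0:
                raise ValueError("family s4 requires d_max > 0")
        elif self.d_max is not None:
            raise ValueError(f"family {self.family} does not take d_max")


RSpec = Union[RParams, float]
SSpec = Union[SParams, float]


def _as_array(d) -> tuple[np.ndarray, bool]:
    arr = np.asarray(d, dtype=float)
    return arr, arr.ndim == 0


def eval_r(spec: RSpec, d, r_floor: float = DEFAULT_R_FLOOR):
    """Evaluate the randomness parameter r at distance(s) ``d``.

    ``spec`` is either an :class:`RParams` or a positive constant.  The
    result is clamped below at ``r_floor`` (a standard deviation cannot be
    non-positive); a clamp is logged once per family, not raised.
    """
    arr, scalar = _as_array(d)
    if np.any(arr < 0):
        raise ValueError("distance d must be non-negative")
    if isinstance(spec, RParams):
        if spec.family == "r1":
            out = spec.a * np.exp(spec.b * arr)
        elif spec.family == "r2":
            out = spec.a * arr / (1.0 + spec.b * arr)
        elif spec.family == "r3":
            out = spec.J * (arr - spec.a) * (arr - spec.b) + 1.0
        else:  # r4, written in sigmoid form to avoid overflow at large b*d
            out = spec.J * np.exp(-spec.a * arr) * expit(-spec.b * arr) + spec.q * expit(
                spec.b * arr
            )
        key = spec.family
    else:
        if not spec > 0:
            raise ValueError("constant r must be strictly positive")
        out = np.full_like(arr, float(spec))
        key = "const"
    if np.any(out < r_floor):
        if key not in _clamp_warned:
            _clamp_warned.add(key)
            logger.info("r values for %s clamped at floor %.1e", key, r_floor)
        out = np.maximum(out, r_floor)
    return float(out) if scalar else out


def eval_s(spec: SSpec, d):
    """Evaluate the speed (step-scale) parameter s at distance(s) ``d``.

    Families s1–s3 diverge at ``d = 0`` and raise there; s4 is defined for
    all ``d >= 0``.
    """
    arr, scalar = _as_array(d)
    if np.any(arr < 0):
        raise ValueError("distance d must be non-negative")
    if isinstance(spec, SParams):
        if spec.family != "s4" and np.any(arr == 0):
            raise ValueError(
                f"family {spec.family} diverges at d=0 (inside the trap); "
                "distances in simulation are >= trap radius"
            )
        if spec.family == "s1":
            out = spec.c / np.sqrt(arr) + spec.h
        elif spec.family == "s2":
            out = spec.c / arr + spec.h
        elif spec.family == "s3":
            out = spec.c / arr**2 + spec.h
        else:
            out = spec.c * np.exp(-((arr - spec.d_max) ** 2) / spec.h**2)
    else:
        if not spec > 0:
            raise ValueError("constant s must be strictly positive")
        out = np.full_like(arr, float(spec))
    return float(out) if scalar else out


def r3_admissibility(params: RParams) -> tuple[float, bool]:
    """Admissibility statistic ``|a - b| sqrt(J)`` for family r3.

    The quadratic ``r3`` stays non-negative on the real line iff the
    statistic is at most 2; returns ``(statistic, statistic <= 2)``.
    """
    if params.family != "r3":
        raise ValueError("admissibility check applies to family r3 only")
    stat = abs(params.a - params.b) * np.sqrt(params.J)
    return float(stat), bool(stat <= 2.0)


def r3_minimum(params: RParams) -> tuple[float, float]:
    """Location and value of the r3 minimum, before any clamping.

    The parabola ``J (d-a)(d-b) + 1`` attains its minimum
    ``1 - J (a-b)^2 / 4`` at ``d = (a + b) / 2``.
    """
    if params.family != "r3":
        raise ValueError("minimum formula applies to family r3 only")
    d_star = 0.5 * (params.a + params.b)
    min_value = 1.0 - 0.25 * params.J * (params.a - params.b) ** 2
    return float(d_star), float(min_value)


@dataclass(frozen=True)
class ResponseProfile:
    """The pair of response functions governing one simulation.

    Either member may be a parametric family or a positive constant (the
    constant-response baseline).  ``r_floor`` is the clamp applied to r.
    """

    r_spec: RSpec
    s_spec: SSpec
    r_floor: float = DEFAULT_R_FLOOR

    def r(self, d):
        return eval_r(self.r_spec, d, r_floor=self.r_floor)

    def s(self, d):
        return eval_s(self.s_spec, d)

    def describe(self) -> dict:
        """JSON-serialisable echo of the profile, for run manifests."""

        def one(spec):
            if isinstance(spec, (RParams, SParams)):
                return {k: v for k, v in vars(spec).items() if v is not None}
            return {"constant": float(spec)}

        return {"r": one(self.r_spec), "s": one(self.s_spec), "r_floor": self.r_floor}


def r_presets(R: float = 5.0) -> dict[str, RParams]:
    """Registry of the published randomness-parameter rows.

    Several rows express ``b`` as a formula in the trap radius ``R``
    (``a1/R^2``, ``a1/(3R)``, ``a4/R``, ``a4^2``); these are resolved here,
    so the registry takes ``R`` as an argument (default 5, the reference
    trap radius).

    Resolved rows (a, b[, q, J]):

    * r1/row1: (0.5, a/R^2)    r1/row2: (1, a/(3R))    r1/row3: (0.14, 0.09)
    * r2/row1: (0.9, 0.8)      r2/row2: (1, 1)         r2/row3: (0.2, 0.09)
    * r3/row1: (15, 30, J=0.01)   r3/row2: (10, 25, J=0.01)
      r3/row3-flagged: (5, 50, J=0.01) — this parsing of the source table is
      ambiguous and violates the admissibility bound (statistic 4.5 > 2), so
      its minimum is negative and evaluation clamps at the floor; shipped
      under a flagged name rather than silently corrected.
      r3/row4: (20, 40, J=0.01)     r3/row5: (5, 20, J=0.01)
    * r4/row1: (0.8, 0.1, q=1, J=0.01)   r4/row2: (0.3, a/R, q=1, J=0.01)
      r4/row3: (0.5, 0.001, q=1, J=0.01) r4/row4: (0.5, a^2, q=1, J=0.01)
    * dazzle variants (interior-minimum sensitivity):
      r3/row1-dazzle: (15, 30, J=0.01)   r3/row2-dazzle: (15, 30, J=0.005)
      r3/row3-dazzle: (15, 30, J=0.002)
      r4/row1-dazzle: (0.3, 0.1, q=1, J=0.01)
      r4/row2-dazzle: (0.3, 0.1, q=2, J=0.01)
      r4/row3-dazzle: (0.3, 0.1, q=3, J=0.01)
    """
    return {
        "r1/row1": RParams("r1", 0.5, 0.5 / R**2),
        "r1/row2": RParams("r1", 1.0, 1.0 / (3 * R)),
        "r1/row3": RParams("r1", 0.14, 0.09),
        "r2/row1": RParams("r2", 0.9, 0.8),
        "r2/row2": RParams("r2", 1.0, 1.0),
        "r2/row3": RParams("r2", 0.2, 0.09),
        "r3/row1": RParams("r3", 15.0, 30.0, J=0.01),
        "r3/row2": RParams("r3", 10.0, 25.0, J=0.01),
        "r3/row3-flagged": RParams("r3", 5.0, 50.0, J=0.01),
        "r3/row4": RParams("r3", 20.0, 40.0, J=0.01),
        "r3/row5": RParams("r3", 5.0, 20.0, J=0.01),
        "r4/row1": RParams("r4", 0.8, 0.1, J=0.01, q=1.0),
        "r4/row2": RParams("r4", 0.3, 0.3 / R, J=0.01, q=1.0),
        "r4/row3": RParams("r4", 0.5, 0.001, J=0.01, q=1.0),
        "r4/row4": RParams("r4", 0.5, 0.5**2, J=0.01, q=1.0),
        "r3/row1-dazzle": RParams("r3", 15.0, 30.0, J=0.01),
        "r3/row2-dazzle": RParams("r3", 15.0, 30.0, J=0.005),
        "r3/row3-dazzle": RParams("r3", 15.0, 30.0, J=0.002),
        "r4/row1-dazzle": RParams("r4", 0.3, 0.1, J=0.01, q=1.0),
        "r4/row2-dazzle": RParams("r4", 0.3, 0.1, J=0.01, q=2.0),
        "r4/row3-dazzle": RParams("r4", 0.3, 0.1, J=0.01, q=3.0),
    }


def s_presets() -> dict[str, SParams]:
    """Registry of the published speed-parameter rows.

    The rows are scaled so the four families peak at comparable values and
    all fall below 1 within the reference field (trap radius 5, half-width
    25): s1 (6, 0.01), s2 (20, 0.3), s3 (100, 0.3), s4 (10, 5, d_max 22.5).
    """
    return {
        "s1": SParams("s1", 6.0, 0.01),
        "s2": SParams("s2", 20.0, 0.3),
        "s3": SParams("s3", 100.0, 0.3),
        "s4": SParams("s4", 10.0, 5.0, d_max=22.5),
    }


def preset_names() -> list[str]:
    return sorted(r_presets()) + sorted(s_presets())


def get_preset(name: str, R: float = 5.0) -> RParams | SParams:
    """Look up a named preset row; unknown names raise with the full list."""
    registry: dict[str, RParams | SParams] = {**r_presets(R), **s_presets()}
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(registry))}"
        ) from None
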