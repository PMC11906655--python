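"""One-step kinematics of a biased random walk toward a baited trap.

The walk is discrete-time: at each step an individual at ``(x, y)`` draws a
heading from a truncated normal centred on the bearing to the trap and a
step length from a half-normal, moves, is reflected back into the domain if
the proposed position falls outside, and is captured if its new distance to
the trap centre drops strictly below the trap radius.

The heading distribution is *absolute* (centred on the current bearing to
the attractant), not relative to the previous heading: this is a biased
random walk, not a correlated one.  Both distribution scales may depend on
the current distance to the trap through a
:class:`~trapwalk.response.ResponseProfile`.

All angles are radians; positions are continuous Cartesian coordinates with
the trap conventionally at the origin.  The unit time step is one
observation interval ("day").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import ndtr, ndtri

from .response import ResponseProfile

__all__ = [
    "TrapArena",
    "IndividualState",
    "bearing_to_trap",
    "sample_heading",
    "heading_pdf",
    "sample_step_length",
    "reflect_into_domain",
    "is_captured",
    "advance_individual",
    "step_positions",
]

_MAX_REFLECTIONS = 100


@dataclass(frozen=True)
class TrapArena:
    """Closed 2-D field with a circular trap.

    ``shape`` is "circle" (disc of radius ``extent`` about the trap centre)
    or "square" (axis-aligned square of side ``extent`` centred on the trap
    centre).  The boundary is impenetrable: proposed positions outside are
    mirrored back in.  The trap disc (radius ``trap_radius``) must lie
    strictly inside the domain.
    """

    shape: Literal["circle", "square"]
    extent: float
    trap_radius: float
    trap_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError("shape must be 'circle' or 'square'")
        if not self.extent > 0:
            raise ValueError("extent must be positive")
        if not self.trap_radius > 0:
            raise ValueError("trap_radius must be positive")
        half = self.extent if self.shape == "circle" else self.extent / 2.0
        if self.trap_radius >= half:
            raise ValueError("trap disc must lie strictly inside the domain")

    @property
    def area(self) -> float:
        if self.shape == "circle":
            return float(np.pi * self.extent**2)
        return float(self.extent**2)

    def contains(self, x, y):
        """Boolean mask: positions inside the closed domain."""
        xc, yc = self.trap_center
        if self.shape == "circle":
            return np.hypot(np.asarray(x) - xc, np.asarray(y) - yc) <= self.extent
        half = self.extent / 2.0
        return (np.abs(np.asarray(x) - xc) <= half) & (np.abs(np.asarray(y) - yc) <= half)

    def distance_to_trap(self, x, y):
        xc, yc = self.trap_center
        return np.hypot(np.asarray(x, dtype=float) - xc, np.asarray(y, dtype=float) - yc)


@dataclass(frozen=True)
class IndividualState:
    """Position and capture status of one walker."""

    position: tuple[float, float]
    status: Literal["free", "captured"] = "free"
    capture_step: int | None = None


def bearing_to_trap(position, trap_center=(0.0, 0.0)):
    """Bearing κ from a position toward the trap centre, in (−π, π].

    Accepts a single ``(x, y)`` pair or arrays of coordinates; a step of
    any positive length at heading κ strictly decreases the distance to
    the trap.  A position coincident with the trap centre has no bearing
    (such an individual would already be captured) and raises.
    """
    x, y = np.asarray(position[0], dtype=float), np.asarray(position[1], dtype=float)
    xa, ya = trap_center
    dx, dy = xa - x, ya - y
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError("position coincides with the trap centre")
    kappa = np.arctan2(dy, dx)
    return float(kappa) if kappa.ndim == 0 else kappa


def sample_heading(kappa, r, rng, size=None):
    """Draw heading(s) Θ = κ + δ, δ ~ truncated normal(0, r²) on [−π, π].

    Sampling is by inverse CDF on the truncated interval, so it is
    deterministic given the random stream and well behaved for any ``r``
    (large ``r`` tends to a uniform heading).  ``kappa`` and ``r`` may be
    arrays (broadcast); ``size`` overrides the output shape for scalar
    arguments.
    """
    kappa = np.asarray(kappa, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("randomness parameter r must be strictly positive")
    shape = np.broadcast_shapes(kappa.shape, r.shape) if size is None else (size,)
    lo = ndtr(-np.pi / r)
    hi = ndtr(np.pi / r)
    u = rng.random(shape)
    delta = r * ndtri(lo + u * (hi - lo))
    # guard the open endpoints of ndtri against u exactly 0/1
    delta = np.clip(delta, -np.pi, np.pi)
    theta = kappa + delta
    return float(theta) if theta.ndim == 0 else theta


def heading_pdf(theta, kappa, r):
    """Density of the truncated-normal heading on [κ−π, κ+π]."""
    theta = np.asarray(theta, dtype=float)
    if not r > 0:
        raise ValueError("randomness parameter r must be strictly positive")
    z = (theta - kappa) / r
    norm = ndtr(np.pi / r) - ndtr(-np.pi / r)
    pdf = np.exp(-0.5 * z**2) / (r * np.sqrt(2 * np.pi) * norm)
    return np.where(np.abs(theta - kappa) <= np.pi, pdf, 0.0)


def sample_step_length(s, rng, size=None):
    """Draw step length(s) from the half-normal with scale ``s``.

    Mean step is ``s * sqrt(2/pi)``; support is ``l >= 0``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("speed parameter s must be strictly positive")
    shape = s.shape if size is None else (size,)
    draw = np.abs(rng.standard_normal(shape))
    out = draw * s
    return float(out) if out.ndim == 0 else out


def reflect_into_domain(proposed, arena: TrapArena):
    """Mirror a proposed position (or arrays of them) back into the domain.

    Square domains mirror across each violated side; circular domains
    mirror radially across the boundary circle (ρ → 2L − ρ).  Mirroring
    repeats until the point is inside; a step so large that this does not
    terminate within 100 reflections signals a mis-scaled step distribution
    and raises.
    """
    x = np.asarray(proposed[0], dtype=float).copy()
    y = np.asarray(proposed[1], dtype=float).copy()
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    xc, yc = arena.trap_center

    if arena.shape == "square":
        half = arena.extent / 2.0
        for u, c in ((x, xc), (y, yc)):
            lo, hi = c - half, c + half
            for _ in range(_MAX_REFLECTIONS):
                below, above = u < lo, u > hi
                if not (below.any() or above.any()):
                    break
                u[below] = 2 * lo - u[below]
                u[above] = 2 * hi - u[above]
            else:
                raise RuntimeError(
                    "reflection did not terminate; step scale is far larger "
                    "than the domain"
                )
    else:
        L = arena.extent
        dx, dy = x - xc, y - yc
        rho = np.hypot(dx, dy)
        outside = rho > L
        if outside.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                ux = np.where(rho > 0, dx / rho, 0.0)
                uy = np.where(rho > 0, dy / rho, 0.0)
            for _ in range(_MAX_REFLECTIONS):
                over = rho > L
                if not over.any():
                    break
                rho[over] = 2 * L - rho[over]
                neg = rho < 0  # mirrored through the centre: flip the ray
                rho[neg] = -rho[neg]
                ux[neg], uy[neg] = -ux[neg], -uy[neg]
            else:
                raise RuntimeError(
                    "reflection did not terminate; step scale is far larger "
                    "than the domain"
                )
            x = np.where(outside, xc + rho * ux, x)
            y = np.where(outside, yc + rho * uy, y)

    if scalar:
        return float(x[0]), float(y[0])
    return x, y


def is_captured(position, arena: TrapArena):
    """Capture test: strictly inside the trap disc (distance < R)."""
    d = arena.distance_to_trap(position[0], position[1])
    out = d < arena.trap_radius
    return bool(out) if np.ndim(out) == 0 else out


def step_positions(x, y, arena: TrapArena, profile: ResponseProfile, rng):
    """Advance arrays of free-walker positions by one step (vectorised).

    Evaluates the response functions at the *pre-step* distance, draws
    headings and step lengths, applies the displacement, reflects at the
    boundary and returns ``(x_new, y_new, captured_mask)``.  Capture is
    tested at the new position only (the walk is observed at discrete
    times; chord crossings between observations do not count).
    """
    d = arena.distance_to_trap(x, y)
    r = np.broadcast_to(np.asarray(profile.r(d), dtype=float), d.shape)
    s = np.broadcast_to(np.asarray(profile.s(d), dtype=float), d.shape)
    kappa = bearing_to_trap((x, y), arena.trap_center)
    theta = sample_heading(kappa, r, rng)
    length = sample_step_length(s, rng)
    nx = x + length * np.cos(theta)
    ny = y + length * np.sin(theta)
    nx, ny = reflect_into_domain((nx, ny), arena)
    captured = arena.distance_to_trap(nx, ny) < arena.trap_radius
    return nx, ny, captured


def advance_individual(
    state: IndividualState,
    arena: TrapArena,
    profile: ResponseProfile,
    rng,
    step: int = 0,
) -> IndividualState:
    """Advance a single free individual by one step.

    Convenience scalar wrapper over :func:`step_positions`; the population
    simulation uses the vectorised path directly.  A captured individual's
    path is terminated, so advancing it is a precondition violation.
    """
    if state.status != "free":
        raise ValueError("cannot advance a captured individual")
    x = np.asarray([state.position[0]])
    y = np.asarray([state.position[1]])
    nx, ny, captured = step_positions(x, y, arena, profile, rng)
    new_pos = (float(nx[0]), float(ny[0]))
    if captured[0]:
        return replace(state, position=new_pos, status="captured", capture_step=step)
    return replace(state, position=new_pos)
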