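"""Population-level trap-count simulation.

A population of ``N0`` walkers starts uniformly distributed over the field
(excluding the trap disc) and performs the biased random walk of
:mod:`trapwalk.movement` synchronously.  After each step every walker's
capture condition is checked; captured walkers are removed from the
population and tallied.  The per-step tallies ``T_j``, their cumulative sum
``C_j`` and the remaining population ``N_j = N0 − C_j`` form the trap-count
series the analysis module works with.

Ensembles of replicate runs (independent seeds derived from one master
seed) average out the per-step stochasticity of ``T_j`` and expose the
underlying temporal pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .movement import TrapArena, step_positions
from .response import ResponseProfile, get_preset

__all__ = [
    "SimulationConfig",
    "TrapCountSeries",
    "EnsembleResult",
    "init_population",
    "run_simulation",
    "run_ensemble",
    "reference_setup",
    "REFERENCE_SETUPS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation (or ensemble)."""

    arena: TrapArena
    profile: ResponseProfile
    N0: int
    n_steps: int
    n_replicates: int = 1
    seed: int = 0
    record_snapshots: bool = False

    def __post_init__(self) -> None:
        if not self.N0 >= 1:
            raise ValueError("N0 must be at least 1")
        if not self.n_steps >= 1:
            raise ValueError("n_steps must be at least 1")
        if not self.n_replicates >= 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class TrapCountSeries:
    """Trap counts from one run: per-step ``T``, cumulative ``C``, remaining ``N``.

    Invariants: ``C = cumsum(T)``, ``N = N0 − C``, ``C`` non-decreasing,
    ``N`` non-increasing.  ``snapshots[j]`` (optional) holds the free
    positions *after* step ``j+1`` as an ``(n_free, 2)`` array; index −1 of
    a prepended snapshot is the initial state when recording is enabled.
    """

    T: np.ndarray
    C: np.ndarray
    N: np.ndarray
    N0: int
    snapshots: list[np.ndarray] | None = None

    @property
    def n_steps(self) -> int:
        return len(self.T)


@dataclass
class EnsembleResult:
    """Replicate × step matrix of per-step counts plus the column means."""

    T: np.ndarray  # shape (n_replicates, n_steps)
    mean_T: np.ndarray
    config: SimulationConfig
    seeds: list[int]

    @property
    def n_replicates(self) -> int:
        return self.T.shape[0]


def init_population(arena: TrapArena, N0: int, rng) -> np.ndarray:
    """Uniform initial positions over the domain minus the trap disc.

    Rejection sampling from the uniform distribution over the whole domain;
    every returned position satisfies ``d >= R`` (otherwise a fraction of
    the population would register as captured at step 0, which the model
    does not intend).  Returns an ``(N0, 2)`` array.
    """
    if N0 < 1:
        raise ValueError("N0 must be at least 1")
    trap_area = np.pi * arena.trap_radius**2
    if trap_area >= 0.99 * arena.area:
        raise ValueError("trap disc covers nearly the whole domain")
    xc, yc = arena.trap_center
    out = np.empty((N0, 2))
    filled = 0
    while filled < N0:
        n_draw = max(2 * (N0 - filled), 64)
        if arena.shape == "circle":
            rho = arena.extent * np.sqrt(rng.random(n_draw))
            phi = rng.uniform(-np.pi, np.pi, n_draw)
            xs, ys = xc + rho * np.cos(phi), yc + rho * np.sin(phi)
        else:
            half = arena.extent / 2.0
            xs = rng.uniform(xc - half, xc + half, n_draw)
            ys = rng.uniform(yc - half, yc + half, n_draw)
        keep = np.hypot(xs - xc, ys - yc) >= arena.trap_radius
        xs, ys = xs[keep], ys[keep]
        take = min(len(xs), N0 - filled)
        out[filled : filled + take, 0] = xs[:take]
        out[filled : filled + take, 1] = ys[:take]
        filled += take
    return out


def run_simulation(
    config: SimulationConfig,
    rng=None,
    initial: np.ndarray | None = None,
) -> TrapCountSeries:
    """Run one replicate and return its trap-count series.

    All free walkers are advanced synchronously each step, then captures
    are tallied and the captured walkers removed.  ``initial`` overrides
    the uniform initial positions (used e.g. for walkers released at a
    fixed distance).  Once the population is exhausted the remaining steps
    contribute zero counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if initial is None:
        pos = init_population(config.arena, config.N0, rng)
    else:
        pos = np.array(initial, dtype=float)
        if pos.shape != (config.N0, 2):
            raise ValueError("initial positions must have shape (N0, 2)")
    x, y = pos[:, 0].copy(), pos[:, 1].copy()
    T = np.zeros(config.n_steps, dtype=np.int64)
    snapshots: list[np.ndarray] | None = [] if config.record_snapshots else None
    if snapshots is not None:
        snapshots.append(np.column_stack([x, y]))
    for j in range(config.n_steps):
        if len(x) == 0:
            if snapshots is not None:
                snapshots.extend(
                    np.empty((0, 2)) for _ in range(config.n_steps - j)
                )
            break
        x, y, captured = step_positions(x, y, config.arena, config.profile, rng)
        T[j] = int(captured.sum())
        if captured.any():
            x, y = x[~captured], y[~captured]
        if snapshots is not None:
            snapshots.append(np.column_stack([x, y]))
    C = np.cumsum(T)
    N = config.N0 - C
    return TrapCountSeries(T=T, C=C, N=N, N0=config.N0, snapshots=snapshots)


def replicate_seeds(master_seed: int, n_replicates: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seed sequences spawned from the master seed."""
    return np.random.SeedSequence(master_seed).spawn(n_replicates)


def run_ensemble(config: SimulationConfig) -> EnsembleResult:
    """Run ``n_replicates`` independent replicates and average the counts.

    Replicate streams are spawned from ``SeedSequence(config.seed)``, so the
    full replicate matrix is bit-reproducible for a fixed master seed.
    """
    seqs = replicate_seeds(config.seed, config.n_replicates)
    T = np.zeros((config.n_replicates, config.n_steps), dtype=np.int64)
    for i, seq in enumerate(seqs):
        series = run_simulation(config, rng=np.random.default_rng(seq))
        T[i] = series.T
    return EnsembleResult(
        T=T,
        mean_T=T.mean(axis=0),
        config=config,
        seeds=[int(s.entropy) for s in seqs],
    )


REFERENCE_SETUPS = ("fig2_circle", "results_square")


def reference_setup(
    name: str,
    profile: ResponseProfile | None = None,
    **overrides,
) -> SimulationConfig:
    """Named reference configurations.

    * ``"fig2_circle"`` — the small closed circular-field demonstration:
      disc of radius 25, trap radius 5, 78 walkers, constant responses
      r = 0.5, s = 1.  A closed biased arena, so every walker is
      eventually captured.
    * ``"results_square"`` — the main experiment grid: square of side 50,
      trap radius 5, 10^4 walkers, 1000 steps, 30 replicates.  The
      response profile varies across the experiment and must be supplied.

    Keyword overrides replace any :class:`SimulationConfig` field.
    """
    if name == "fig2_circle":
        arena = TrapArena("circle", extent=25.0, trap_radius=5.0)
        cfg = SimulationConfig(
            arena=arena,
            profile=profile if profile is not None else ResponseProfile(0.5, 1.0),
            N0=78,
            n_steps=100,
            n_replicates=1,
        )
    elif name == "results_square":
        if profile is None:
            raise ValueError(
                "results_square needs a response profile (the experiment "
                "sweeps response-function combinations)"
            )
        arena = TrapArena("square", extent=50.0, trap_radius=5.0)
        cfg = SimulationConfig(
            arena=arena, profile=profile, N0=10_000, n_steps=1000, n_replicates=30
        )
    else:
        raise KeyError(
            f"unknown reference setup {name!r}; available: {', '.join(REFERENCE_SETUPS)}"
        )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
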