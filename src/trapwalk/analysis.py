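"""Trap-count series transforms and temporal-pattern classification.

Ensemble-mean daily trap counts from the baited-trap simulation fall into a
small number of qualitatively distinct temporal shapes:

* **P1** — counts decay monotonically from the start (the only shape an
  unbaited trap produces for an initially uniform population);
* **P2** — counts hold a long low-slope plateau, then transition to a
  rapid decay (the curve has a kink);
* **P3** — counts rise from a low initial value to a peak at an interior
  time, then decay;
* **P4** — counts first *decrease*, then rise to an interior peak, then
  decay.

Patterns 3 and 4 are the counter-intuitive ones: the counts rise while the
population in the field is strictly decreasing, purely because the
attractant reshapes the walkers' movement behaviour.  The verbal pattern
definitions are operationalised here by explicit, relative (scale-free)
thresholds; every decision quantity is reported in the diagnostics so a
classification can be audited.  Shapes that fit none of the rules (e.g.
two-peak series) classify as ``other`` by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import EnsembleResult

__all__ = [
    "PatternLabel",
    "cumulative",
    "smooth",
    "ensemble_mean",
    "classify_pattern",
]


@dataclass(frozen=True)
class PatternLabel:
    """Classification of one trap-count series.

    ``label`` is one of ``P1_monotone_decay``, ``P2_plateau_then_decay``,
    ``P3_rise_peak_decay``, ``P4_dip_rise_peak_decay`` or ``other``;
    ``peak_step`` (0-based index into the smoothed series) is present only
    for P3/P4.  ``diagnostics`` carries the decision quantities.
    """

    label: str
    peak_step: int | None = None
    diagnostics: dict = field(default_factory=dict)


def cumulative(T) -> np.ndarray:
    """Cumulative counts ``C_j = sum_{k<=j} T_k`` from per-step counts."""
    T = np.asarray(T)
    if len(T) == 0:
        raise ValueError("empty series")
    if np.any(T < 0):
        raise ValueError("per-step counts must be non-negative")
    return np.cumsum(T)


def smooth(series, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at edges.

    ``window`` must be odd, ≥ 1 and no longer than the series, so the
    output has the same length as the input.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError("window longer than series")
    if window == 1:
        return y.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(y)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def ensemble_mean(result: EnsembleResult) -> np.ndarray:
    """Column means of the replicate × step count matrix."""
    if result.T.shape[0] < 1:
        raise ValueError("ensemble has no replicates")
    return result.T.mean(axis=0)


def classify_pattern(
    series,
    window: int = 11,
    tau_frac: float = 0.02,
    plateau_slope_frac: float = 0.005,
    plateau_min_frac: float = 0.3,
    decay_factor: float = 4.0,
    peak_margin: float = 0.2,
) -> PatternLabel:
    """Classify an ensemble-mean daily-count series into P1–P4 or other.

    The series is first smoothed (centred moving average, default window
    11).  With ``ymax`` the smoothed maximum, the decision thresholds are
    all relative to ``ymax`` so the classification is invariant to positive
    rescaling:

    * ``tau = tau_frac * ymax`` — slack for "monotone within tolerance"
      and the minimum depth of a P4 initial decline;
    * ``tau_p = plateau_slope_frac * ymax`` — per-step slope below which a
      prefix counts as a P2 plateau; the plateau must cover at least
      ``plateau_min_frac`` of the series and the subsequent decay's maximum
      downward slope must exceed the plateau's mean slope by
      ``decay_factor``;
    * a peak is accepted for P3/P4 only if the start value is below
      ``(1 - peak_margin) * peak``.

    Decision order: interior-peak shapes (P4 before P3, since a P4 prefix
    is not monotone), then plateau-kink (P2), then plain monotone decay
    (P1), else ``other``.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 20:
        raise ValueError("series too short to classify (need >= 20 steps)")
    ys = smooth(y, window)
    n = len(ys)
    ymax = float(ys.max())
    if ymax <= 0:
        return PatternLabel("other", diagnostics={"ymax": ymax})
    tau = tau_frac * ymax
    tau_p = plateau_slope_frac * ymax
    diffs = np.diff(ys)
    p = int(np.argmax(ys))
    interior = 0 < p < n - 1
    diag: dict = {
        "ymax": ymax,
        "peak_index": p,
        "start_value": float(ys[0]),
        "end_value": float(ys[-1]),
        "max_rise": float(diffs.max()),
        "max_fall": float(-diffs.min()),
        "tau": tau,
        "tau_plateau": tau_p,
    }

    if interior and ys[0] < (1.0 - peak_margin) * ys[p]:
        pre = ys[: p + 1]
        pre_diffs = np.diff(pre)
        m = int(np.argmin(pre))
        diag["pre_min_index"] = m
        diag["pre_min_value"] = float(pre[m])
        if pre_diffs.min() >= -tau:
            return PatternLabel("P3_rise_peak_decay", peak_step=p, diagnostics=diag)
        if 0 < m < p and ys[0] - pre[m] > tau:
            return PatternLabel("P4_dip_rise_peak_decay", peak_step=p, diagnostics=diag)
        return PatternLabel("other", diagnostics=diag)

    # P1/P2 require an actual net decay, not merely "no rise within slack"
    if diffs.max() <= tau and ys[0] - ys[-1] > tau:
        # longest prefix of near-flat slopes = candidate plateau
        flat = np.abs(diffs) < tau_p
        k = int(np.argmin(flat)) if not flat.all() else len(diffs)
        diag["plateau_len"] = k
        if k >= plateau_min_frac * n and k < len(diffs):
            plateau_slope = float(np.abs(diffs[:k]).mean())
            max_decay = float(-diffs[k:].min())
            diag["plateau_slope"] = plateau_slope
            diag["max_decay_slope"] = max_decay
            if max_decay > decay_factor * max(plateau_slope, 1e-12) and max_decay > tau_p:
                return PatternLabel("P2_plateau_then_decay", diagnostics=diag)
        return PatternLabel("P1_monotone_decay", diagnostics=diag)

    return PatternLabel("other", diagnostics=diag)
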