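"""Scenario grid and the wave-following incidence-shock function.

Each pandemic wave, delineated by its FWHM interval ``[s_w, e_w]`` of
duration ``D_w``, contributes a piecewise-linear pulse to the relative
incidence increase ``A(t)``:

* linear *wash-in* from 0 at ``s_w`` to the wave's peak increase ``h_w``
  over a fraction ``W_in`` of the wave duration;
* a plateau at ``h_w`` until ``e_w + delta*D_w`` -- the *delay* ``delta``
  keeps incidence elevated while the infection wave is already subsiding;
* linear *wash-out* back to 0 over a fraction ``W_out`` of the duration.

Peak increases diminish across successive waves by exponential decay,
``h_w = h0 * exp(-lam*(w-1))``.  Contributions of overlapping waves sum.
The shock multiplies baseline incidence: ``i_eff = i_base * (1 + A(t))``,
uniformly over age and sex, so ``h0`` = 1, 5, 10 mean +100%, +500% and
+1000% at the first wave's peak.

The scenario grid holds a null baseline (scenario 0, ``A == 0``) plus the
full 3^4 factorial over ``h0`` in {1, 5, 10}, ``lam`` in {0.1, 0.2, 0.3},
``delta`` in {0, 0.25, 0.5} and ``W_in = W_out`` in {0.1, 0.2, 0.3} --
82 scenarios, numbered ``id = 27*a + 9*c + 3*b + d + 1`` with ``a, c, b,
d`` indexing ``h0``, ``lam``, ``delta`` and ``W`` ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wave_model import WaveSet

H0_LEVELS = (1.0, 5.0, 10.0)
LAMBDA_LEVELS = (0.1, 0.2, 0.3)
DELTA_LEVELS = (0.0, 0.25, 0.5)
W_LEVELS = (0.1, 0.2, 0.3)


@dataclass(frozen=True)
class ScenarioParams:
    """One scenario's (W_in, W_out, delta, h0, lam); id 0 is the null baseline."""

    scenario_id: int
    w_in: float
    w_out: float
    delta: float
    h0: float
    lam: float

    def __post_init__(self):
        if not 0 <= self.scenario_id <= 81:
            raise ValueError("scenario_id must lie in 0..81")
        if self.w_in != self.w_out:
            raise ValueError("wash-in and wash-out fractions are tied (w_in = w_out)")
        if self.scenario_id == 0 and self.h0 != 0.0:
            raise ValueError("scenario 0 is the baseline and must have h0 = 0")

    @property
    def is_baseline(self) -> bool:
        return self.scenario_id == 0


def scenario_grid() -> list[ScenarioParams]:
    """The 82 scenarios: baseline plus the full factorial, in id order."""
    grid = [ScenarioParams(0, 0.0, 0.0, 0.0, 0.0, 0.0)]
    for a, h0 in enumerate(H0_LEVELS):
        for c, lam in enumerate(LAMBDA_LEVELS):
            for b, delta in enumerate(DELTA_LEVELS):
                for d, w in enumerate(W_LEVELS):
                    grid.append(
                        ScenarioParams(
                            scenario_id=27 * a + 9 * c + 3 * b + d + 1,
                            w_in=w,
                            w_out=w,
                            delta=delta,
                            h0=h0,
                            lam=lam,
                        )
                    )
    grid.sort(key=lambda s: s.scenario_id)
    return grid


def scenario_table() -> pd.DataFrame:
    """The grid as a table (id, W_in, W_out, delta, h0, lambda)."""
    return pd.DataFrame(
        [
            {
                "scenario": s.scenario_id,
                "W_in": s.w_in,
                "W_out": s.w_out,
                "delta": s.delta,
                "h0": s.h0,
                "lambda": s.lam,
            }
            for s in scenario_grid()
        ]
    )


def wave_magnitude(h0: float, lam: float, w: int) -> float:
    """Peak relative increase at wave ``w`` (1-based): h0 * exp(-lam*(w-1))."""
    if w < 1:
        raise ValueError("wave index is 1-based")
    return h0 * np.exp(-lam * (w - 1))


class ShockFunction:
    """Piecewise-linear relative incidence increase A(t) >= 0.

    Stores one (nodes, heights) pulse per wave; evaluation sums the
    pulses (zero outside every envelope).
    """

    def __init__(self, pulses: list[tuple[np.ndarray, np.ndarray]]):
        self.pulses = [(np.asarray(x, float), np.asarray(y, float)) for x, y in pulses]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for xs, ys in self.pulses:
            total = total + np.interp(t, xs, ys, left=0.0, right=0.0)
        return total if total.ndim else float(total)

    @property
    def support(self) -> tuple[float, float] | None:
        if not self.pulses:
            return None
        return (
            min(float(xs[0]) for xs, _ in self.pulses),
            max(float(xs[-1]) for xs, _ in self.pulses),
        )


def build_shock(
    params: ScenarioParams, waves: WaveSet, shape: str = "trapezoid"
) -> ShockFunction:
    """Assemble A(t) from a fitted WaveSet and one scenario's parameters.

    ``shape='trapezoid'`` (default) holds the peak from the end of
    wash-in through the delayed wave end; ``shape='triangle'`` starts the
    wash-out immediately after the wash-in.
    """
    if params.is_baseline or params.h0 == 0.0:
        return ShockFunction([])
    pulses = []
    for w, (start, end) in enumerate(waves.intervals, start=1):
        duration = end - start
        if duration <= 0:
            raise ValueError(f"wave {w} has a degenerate FWHM interval")
        h = wave_magnitude(params.h0, params.lam, w)
        rise_end = start + params.w_in * duration
        if shape == "trapezoid":
            fall_start = end + params.delta * duration
            xs = [start, rise_end, fall_start, fall_start + params.w_out * duration]
            ys = [0.0, h, h, 0.0]
        elif shape == "triangle":
            xs = [start, rise_end, rise_end + params.w_out * duration]
            ys = [0.0, h, 0.0]
        else:
            raise ValueError("shape must be 'trapezoid' or 'triangle'")
        pulses.append((np.asarray(xs), np.asarray(ys)))
    return ShockFunction(pulses)


def apply_shock(base_incidence, shock: ShockFunction):
    """Wrap a baseline incidence rule with the multiplicative shock.

    ``base_incidence`` is a callable (age, time) -> rate; the returned
    rule is ``i_eff(age, time) = i_base(age, time) * (1 + A(time))``,
    uniform over age (and sex, since rules are per sex).
    """

    def effective(age, time):
        return np.asarray(base_incidence(age, time), float) * (1.0 + shock(time))

    return effective
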