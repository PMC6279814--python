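"""Right-continuous step functions for cumulative hazards and survivor curves."""

from __future__ import annotations

import numpy as np


class StepFunction:
    """A right-continuous step function ``f(t) = values[i]`` for
    ``knots[i] <= t < knots[i+1]``, with ``f(t) = init`` for ``t < knots[0]``.

    Cumulative-hazard estimators (Breslow, Nelson-Aalen) and Kaplan-Meier
    survivor curves are both of this form.
    """

    __slots__ = ("knots", "values", "init")

    def __init__(self, knots, values, init: float = 0.0):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        if knots.ndim != 1 or knots.shape != values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size > 1 and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.values = values
        self.init = float(init)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(idx < 0, self.init, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """f(t-): value just before t (left-continuous evaluation)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="left") - 1
        out = np.where(idx < 0, self.init, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    @property
    def final_value(self) -> float:
        return float(self.values[-1]) if self.values.size else self.init

    @property
    def final_knot(self) -> float:
        return float(self.knots[-1]) if self.knots.size else -np.inf

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StepFunction({self.knots.size} knots on [{self.knots[0] if self.knots.size else None}, {self.final_knot}])"
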