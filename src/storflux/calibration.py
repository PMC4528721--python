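"""NGAM calibration: match simulated total storage flux to measurement.

The non-growth-associated maintenance energy (NGAM) is the free energy
parameter of the N-limited simulations: every mmol of maintenance ATP must be
regenerated by respiring substrate that could otherwise be stored, so for the
flux-based objectives the total storage flux decreases monotonically with
NGAM.  Calibration inverts that curve by bisection so that the simulated
total storage production rate (mg-COD/(g-COD biomass.h)) equals the measured
one; each objective function gets its own NGAM.

The environmental-MOMA objective is the known exception: its storage total is
insensitive to NGAM (futile cycles absorb the maintenance demand), so its
calibration fails with a :class:`CalibrationRangeError` carrying the
achievable range, and the pipeline falls back to a fixed conventional value
(0.5 mmol/(g-DW.h)).
"""

from __future__ import annotations

from dataclasses import dataclass

from .fba import Environment, FluxVector
from .model import MetabolicModel
from .objectives import ObjectiveSpec, nonlimited_reference, predict_storage

__all__ = [
    "NgamCurve",
    "CalibrationError",
    "CalibrationRangeError",
    "ngam_sweep",
    "calibrate_ngam",
    "ENV_MOMA_FALLBACK_NGAM",
]

#: Conventional NGAM adopted when calibration is impossible (flat curve).
ENV_MOMA_FALLBACK_NGAM = 0.5  # mmol/(g-DW.h)

DEFAULT_BRACKET = (0.0, 20.0)


class CalibrationError(RuntimeError):
    """Calibration could not be performed."""


class CalibrationRangeError(CalibrationError):
    """The measured total is outside the achievable storage range."""

    def __init__(self, target: float, lo: float, hi: float):
        self.target, self.achievable = target, (min(lo, hi), max(lo, hi))
        super().__init__(
            f"measured total {target:.4g} outside achievable total-storage "
            f"range [{self.achievable[0]:.4g}, {self.achievable[1]:.4g}] "
            "over the NGAM bracket")


@dataclass
class NgamCurve:
    """Total storage flux as a function of NGAM for one objective."""

    objective: str
    substrate: str
    ngam: list[float]
    total_storage: list[float | None]  # None where infeasible

    def feasible_points(self) -> list[tuple[float, float]]:
        return [(g, t) for g, t in zip(self.ngam, self.total_storage)
                if t is not None]


def _total_at(model: MetabolicModel, env_growth: Environment,
              env_limited: Environment, objective: ObjectiveSpec,
              ngam: float, reference: FluxVector | None) -> float | None:
    pred = predict_storage(model, env_growth, env_limited, objective,
                           ngam=ngam, reference=reference)
    return pred.total_storage_flux if pred.optimal else None


def ngam_sweep(model: MetabolicModel, env_growth: Environment,
               env_limited: Environment, objective: ObjectiveSpec,
               ngam_grid: list[float], substrate: str = "") -> NgamCurve:
    """Evaluate total storage over a strictly increasing NGAM grid."""
    if len(ngam_grid) < 2 or any(b <= a for a, b in zip(ngam_grid,
                                                        ngam_grid[1:])):
        raise ValueError("ngam_grid must be strictly increasing with >= 2 "
                         "points")
    reference = (nonlimited_reference(model, env_growth)
                 if objective.uses_reference else None)
    totals = [_total_at(model, env_growth, env_limited, objective, g,
                        reference) for g in ngam_grid]
    return NgamCurve(objective.name, substrate, list(ngam_grid), totals)


def calibrate_ngam(model: MetabolicModel, env_growth: Environment,
                   env_limited: Environment, objective: ObjectiveSpec,
                   measured_total: float,
                   bracket: tuple[float, float] = DEFAULT_BRACKET,
                   rel_tol: float = 1e-4, ngam_tol: float = 1e-6,
                   ) -> tuple[float, float]:
    """Find the NGAM at which simulated total storage matches measurement.

    Bisection over ``bracket``; monotonicity of the curve is pre-checked on
    five probe points.  Returns ``(ngam, achieved_total)``.  Raises
    :class:`CalibrationRangeError` when the target is unreachable (this is
    how a flat env-MOMA curve is detected) and :class:`CalibrationError` when
    the curve is not monotone or infeasible on the bracket.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    reference = (nonlimited_reference(model, env_growth)
                 if objective.uses_reference else None)

    def f(g: float) -> float | None:
        return _total_at(model, env_growth, env_limited, objective, g,
                         reference)

    probes = [lo + (hi - lo) * i / 4 for i in range(5)]
    vals = [f(g) for g in probes]
    feas = [(g, t) for g, t in zip(probes, vals) if t is not None]
    if not feas:
        raise CalibrationError(
            "objective infeasible on the whole NGAM bracket")
    # High NGAM eventually exceeds the respiratory ATP supply; locate the
    # feasibility edge so the usable bracket is as wide as possible.
    infeas_after = [g for g, t in zip(probes, vals)
                    if t is None and g > feas[-1][0]]
    if infeas_after:
        a, b = feas[-1][0], infeas_after[0]
        for _ in range(20):
            midp = 0.5 * (a + b)
            tm = f(midp)
            if tm is None:
                b = midp
            else:
                a = midp
                feas.append((midp, tm))
        feas.sort()
    if len(feas) < 2:
        raise CalibrationError(
            "objective infeasible on nearly the whole NGAM bracket")
    lo, t_lo = feas[0]
    hi, t_hi = feas[-1]
    seq = [t for _, t in feas]
    span = max(abs(t) for t in seq) or 1.0
    slack = 1e-6 * span
    decreasing = all(b <= a + slack for a, b in zip(seq, seq[1:]))
    increasing = all(b >= a - slack for a, b in zip(seq, seq[1:]))
    if not (decreasing or increasing):
        raise CalibrationError(
            f"total storage is not monotone in NGAM on {bracket}; probes "
            f"{[round(t, 6) for t in seq]}")
    t_min, t_max = min(t_lo, t_hi), max(t_lo, t_hi)
    span_rel = (t_max - t_min) / (abs(t_max) or 1.0)
    outside = not (t_min - slack <= measured_total <= t_max + slack)
    if outside or span_rel < 1e-6:
        raise CalibrationRangeError(measured_total, t_min, t_max)

    a, b = lo, hi
    fa = t_lo
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = f(mid)
        if fm is None:
            b = mid  # infeasible side only appears at high NGAM
            continue
        if abs(fm - measured_total) <= rel_tol * abs(measured_total) \
                or (b - a) <= ngam_tol:
            return mid, fm
        same_side = (fa - measured_total) * (fm - measured_total) > 0
        if same_side:
            a, fa = mid, fm
        else:
            b = mid
    return mid, fm  # pragma: no cover - loop always converges earlier
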