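"""Bayesian discrimination among candidate objective functions.

Given measured storage yield fractions (glycogen / PHA / TAG per substrate,
with standard errors) and each objective function's predicted fractions, the
posterior probability share of objective j is

    P_j  proportional to  prior_j * prod_{s,c} N(y_sc ; yhat_jsc, SE_sc^2)

with independent Gaussian measurement errors per (substrate, compound) and a
uniform prior by default.  Computation is done in log space, so arbitrarily
poor predictions (discrepancies of 100 SE and more) do not underflow.

The likelihood model (independent Gaussians on yield fractions) is the
standard construction for objective-function discrimination; yields are
compared as COD-basis fractions of the total storage because the NGAM
calibration step has already matched the totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExperimentalYields", "posterior_shares"]

COMPOUNDS = ("glycogen", "pha", "tag")


@dataclass
class ExperimentalYields:
    """Measured storage yield fractions per substrate and compound.

    ``yields[substrate][compound]`` and ``se[substrate][compound]`` hold the
    measured fraction of total storage COD and its standard error.
    """

    yields: dict[str, dict[str, float]]
    se: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for sub, comp in self.yields.items():
            if sub not in self.se:
                raise ValueError(f"no SEs for substrate {sub!r}")
            for c, v in comp.items():
                if v < 0:
                    raise ValueError(f"negative yield {sub}/{c}")
                s = self.se[sub].get(c, 0.0)
                if s <= 0:
                    raise ValueError(f"SE for {sub}/{c} must be > 0")
            total = sum(comp.values())
            se3 = 3 * np.sqrt(sum(self.se[sub][c] ** 2 for c in comp))
            if total > 1.0 + se3:
                raise ValueError(
                    f"{sub} yield fractions sum to {total:.3f} > 1 + 3 SE")

    def items(self):
        for sub, comp in self.yields.items():
            for c, v in comp.items():
                yield sub, c, v, self.se[sub][c]


def posterior_shares(predictions: dict[str, dict[str, dict[str, float]]],
                     measurements: ExperimentalYields,
                     prior: dict[str, float] | None = None,
                     ) -> dict[str, float]:
    """Posterior probability share of each objective function.

    ``predictions[objective][substrate][compound]`` are predicted yield
    fractions.  Objectives missing a prediction for a measured (substrate,
    compound) pair are excluded with a warning (e.g. an infeasible
    simulation).  Shares sum to 1.
    """
    import warnings

    if not predictions:
        raise ValueError("no predictions supplied")
    log_post: dict[str, float] = {}
    for obj, pred in predictions.items():
        lp = np.log(prior[obj]) if prior else 0.0
        ok = True
        for sub, comp, y, se in measurements.items():
            try:
                yhat = pred[sub][comp]
            except KeyError:
                warnings.warn(f"objective {obj!r} lacks a prediction for "
                              f"{sub}/{comp}; excluded", stacklevel=2)
                ok = False
                break
            lp += -0.5 * ((y - yhat) / se) ** 2 - np.log(se) \
                - 0.5 * np.log(2 * np.pi)
        if ok:
            log_post[obj] = lp
    if not log_post:
        raise ValueError("every objective was excluded")
    keys = sorted(log_post)
    lp_arr = np.array([log_post[k] for k in keys])
    lp_arr -= lp_arr.max()
    w = np.exp(lp_arr)
    w /= w.sum()
    return dict(zip(keys, map(float, w)))
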