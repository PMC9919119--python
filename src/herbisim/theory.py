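"""Closed-form predictions of the fitness equations.

At l = 1 with certain damage (d = 1) and neutral inbreeding terms, two
scenarios bracket the attainable fitness:

* resistance scenario: the population keeps a single resistance allele
  (minimum investment r* = 1/4 under the two-gene architecture), which
  cancels herbivory damage and therefore also tolerance benefits; its
  maximum factor is w_RS = 1 - c_r * r*^l under both allocation models.
* non-resistance scenario: damage is certain and tolerance alone pays;
  under the multiplicative model the maximum of
  (1 - c_t t)(1 - c_h + b_t t) sits at the interior optimum
  t_h = (1/c_t - (1 - c_h)/b_t) / 2 (clipped to [0, 1]); under the
  additive model fitness is linear in t, so the optimum is a corner:
  t = 1 if b_t > c_t else 0.

The fitness ratio f_r = w_NRS / w_RS decides the favored scenario
(non-resistance iff f_r > 1).  Neither scenario supports a mixed defense
strategy: cost duplication plus the inducibility of tolerance create a
double trade-off.

Mutation-load equilibria (lethal recessives, per-gene mutation rate mu
over n unlinked genes): under random mating the equilibrium allele
frequency is q* = sqrt(mu), giving 2 n sqrt(mu) detrimental alleles per
zygote; under full selfing every new lethal is exposed and purged within
about one generation, leaving U = 2 n mu.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fitness import fitness_factor
from .params import Params

R_STAR = 0.25  # minimum non-zero resistance investment: one allele of four


@dataclasses.dataclass(frozen=True)
class ScenarioPrediction:
    """Scenario fitness maxima, optimal tolerance, and the favored strategy."""

    w_rs: float       # resistance-scenario maximum fitness factor
    w_nrs: float      # non-resistance-scenario maximum fitness factor
    t_opt: float      # optimal tolerance investment in the non-resistance scenario
    f_r: float        # fitness ratio w_nrs / w_rs
    favored: str      # "non_resistance" iff f_r > 1, else "resistance"
    w_nrs_linear: float  # linearized non-resistance maximum, for comparison


def optimal_tolerance(c_t: float, c_h: float, b_t: float) -> float:
    """Tolerance investment maximizing (1 - c_t t)(1 - c_h + b_t t), clipped.

    t_h = (1/c_t - (1 - c_h)/b_t) / 2 is the exact interior maximizer at
    l = 1 with certain damage; values outside [0, 1] are clipped to the
    nearest boundary.
    """
    if c_t <= 0.0 or b_t <= 0.0:
        raise ValueError("optimal_tolerance requires c_t > 0 and b_t > 0")
    t_h = 0.5 * (1.0 / c_t - (1.0 - c_h) / b_t)
    return float(min(1.0, max(0.0, t_h)))


def scenario_predictions(p: Params) -> ScenarioPrediction:
    """Evaluate both scenarios at ``p`` (stated at l = 1, d = 1)."""
    w_rs = 1.0 - p.c_r * R_STAR ** p.l
    if p.model == "multiplicative":
        t_opt = optimal_tolerance(p.c_t, p.c_h, p.b_t)
        w_nrs = (1.0 - p.c_t * t_opt) * (1.0 - p.c_h + p.b_t * t_opt)
    else:
        t_opt = 1.0 if p.b_t > p.c_t else 0.0
        w_nrs = 1.0 - p.c_t * t_opt - p.c_h + p.b_t * t_opt
    t_lin = t_opt
    w_nrs_linear = 1.0 - t_lin * (p.b_t - p.c_t) - p.c_h
    f_r = w_nrs / w_rs
    favored = "non_resistance" if f_r > 1.0 else "resistance"
    return ScenarioPrediction(w_rs, w_nrs, t_opt, f_r, favored, w_nrs_linear)


def curvature_class(base_sign: str, l: float) -> str:
    """Shape of a powered term k*a**l by the sign of k*a and the exponent l."""
    if base_sign not in ("positive", "negative"):
        raise ValueError(f"base_sign must be positive/negative, got {base_sign!r}")
    if l <= 0:
        raise ValueError("l must be positive")
    if l == 1.0:
        return "linear"
    if base_sign == "positive":
        return "convex" if l > 1.0 else "concave"
    return "concave" if l > 1.0 else "convex"


def load_equilibrium(mu: float, n_genes: int, regime: str) -> float:
    """Equilibrium detrimental alleles per individual for lethal recessives.

    outcrossing: mutation-selection balance q* = sqrt(mu), i.e. 2 n sqrt(mu);
    selfing: each new lethal is purged within ~1 selfed generation, leaving
    the genomic mutation rate U = 2 n mu.
    """
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must lie in [0, 1)")
    if regime == "outcrossing":
        return 2.0 * n_genes * float(np.sqrt(mu))
    if regime == "selfing":
        return 2.0 * n_genes * mu
    raise ValueError(f"unknown regime: {regime!r}")


_AXES = ("c_r", "c_t", "r", "t", "d", "l")


def fitness_surface_grid(p: Params, axes: dict[str, np.ndarray],
                         fixed: dict[str, float] | None = None) -> pd.DataFrame:
    """Long-format fitness surface over two named axes.

    Axes may be fitness inputs (``r``, ``t``, ``d``) or parameters
    (``c_r``, ``c_t``, ``l``).  Sweeping the tolerance-cost axis applies
    the companion convention b_t = 1 - c_t, so tolerance cost and benefit
    are assessed at once.  ``fixed`` overrides the default evaluation
    point r = t = d = 0, h_i = H, u_i = 0.
    """
    if len(axes) != 2:
        raise ValueError("exactly two axes are required")
    for name in axes:
        if name not in _AXES:
            raise ValueError(f"unknown axis name: {name!r} (use one of {_AXES})")
    point = {"r": 0.0, "t": 0.0, "d": 0.0, "h_i": p.H, "u_i": 0.0}
    if fixed:
        point.update(fixed)

    (name1, vals1), (name2, vals2) = axes.items()
    rows = []
    for v1 in np.asarray(vals1, dtype=float):
        for v2 in np.asarray(vals2, dtype=float):
            here = dict(point)
            pp = p
            for name, v in ((name1, v1), (name2, v2)):
                if name in ("r", "t", "d"):
                    here[name] = v
                elif name == "c_t":
                    pp = dataclasses.replace(pp, c_t=v, b_t=1.0 - v)
                else:
                    pp = dataclasses.replace(pp, **{name: v})
            f = float(fitness_factor(pp, here["r"], here["t"], here["d"],
                                     here["h_i"], here["u_i"], False))
            rows.append({name1: v1, name2: v2, "r": here["r"], "t": here["t"],
                         "d": here["d"], "h_i": here["h_i"], "u_i": here["u_i"],
                         "model": pp.model, "F": f})
    return pd.DataFrame(rows)
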