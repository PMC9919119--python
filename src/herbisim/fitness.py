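"""Individual plant fitness under multiplicative and additive cost allocation.

The fitness *factor* F rescales the base fitness w0 (expected seeds of an
unimpaired plant).  With

    RC = c_r * r**l              resistance cost
    TC = c_t * t**l              tolerance cost
    HD = c_h * d**l              herbivory damage cost
    TB = b_t * d**l * t**l       tolerance benefit (inducible: needs damage)
    O1 = (h_i / H)**k            overdominance ratio (multiplicative)
    O2 = k * (H - h_i)           overdominance penalty (additive)
    D  = (u_i * s)**l            dominance (mutation-load) cost
    I  = 0 if a load gene is detrimental-homozygous else 1

the two allocation models are

    multiplicative:  F = (1-RC) (1-TC) (1-HD+TB) O1 (1-D) I
    additive:        F = (1 - RC - TC - HD + TB - O2 - D) I

Each parenthesized factor (and the additive sum) is floored at zero:
fitness cannot be negative.  F may exceed 1 under the multiplicative model
when h_i > H.  O2 is a *penalty* for below-reference heterozygosity (a
bonus above it); the opposite sign convention is available behind
``o2_sign_verbatim``.

Realized seed numbers are Poisson with mean w0 * F: thinning a
Poisson(w0) base by the factor F is exactly Poisson(w0 * F), and the
same form extends to F > 1.
"""

from __future__ import annotations

import numpy as np

from .params import Params


def fitness_factor(p: Params, r, t, d, h_i, u_i, lethal) -> np.ndarray:
    """Fitness factor F for (arrays of) individuals; broadcasts its inputs.

    Parameters are the individual's resistance and tolerance investments
    ``r``, ``t`` in [0, 1], binary herbivory damage ``d``, load-genome
    heterozygosity ``h_i``, detrimental-allele count ``u_i``, and the
    homozygous-lethal flag.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    u_i = np.asarray(u_i, dtype=float)
    alive = 1.0 - np.asarray(lethal, dtype=float)

    rc = p.c_r * r ** p.l
    tc = p.c_t * t ** p.l
    hd = p.c_h * d ** p.l
    tb = p.b_t * d ** p.l * t ** p.l
    dom = (u_i * p.s) ** p.l

    if p.model == "multiplicative":
        o1 = (h_i / p.H) ** p.k
        f = (np.maximum(1.0 - rc, 0.0)
             * np.maximum(1.0 - tc, 0.0)
             * np.maximum(1.0 - hd + tb, 0.0)
             * o1
             * np.maximum(1.0 - dom, 0.0))
    else:
        o2 = p.k * (h_i - p.H) if p.o2_sign_verbatim else p.k * (p.H - h_i)
        f = np.maximum(1.0 - rc - tc - hd + tb - o2 - dom, 0.0)
    return f * alive


def realize_seeds(p: Params, factor, rng: np.random.Generator) -> np.ndarray:
    """Integer seed counts: Poisson draws with mean ``w0 * factor``."""
    lam = p.w0 * np.asarray(factor, dtype=float)
    return rng.poisson(lam)
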