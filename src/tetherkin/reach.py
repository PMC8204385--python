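"""Molecular-reach analysis of fitted local concentrations.

The fitted local concentration sigma* of a tethered reaction encodes the
combined molecular reach L = (sigma*)^(-1/3), which mixes the reach of
the two anchoring tethers and of the enzyme in quadrature:

    L^2 = L_tether^2 + L_tether^2 + L_enzyme^2.

For a PEG tether of N units, worm-like-chain statistics make L^2 linear
in N:

    L^2 = 4 * N * l_unit * l_p + L_enzyme^2,

so an ordinary least-squares regression of L^2 on N across a PEG-length
series yields the enzyme reach as the square root of the intercept.  A
receptor-tail reach is parsed from a combined reach by inverting the
quadrature sum: L_tail = sqrt((L^2 - L_enzyme^2) / 2).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import units

__all__ = [
    "table_from_sigma",
    "peg_regression",
    "parse_tether_reach",
    "combine_reach",
]


def table_from_sigma(replicates: dict) -> pd.DataFrame:
    """Per-PEG-length reach table from replicate sigma* values.

    Parameters
    ----------
    replicates:
        Mapping ``{n_peg: iterable of sigma* replicate values in uM}``.
        A single pooled (mean, sd, n) tuple is also accepted per key.

    Returns
    -------
    DataFrame with columns ``n_peg, sigma_star_mean, sigma_star_sd,
    n_replicates, L, L_squared, L_squared_err``.  The reach is computed
    from the *average* sigma*, and the sigma* spread is propagated to
    L^2 to first order: err(L^2) = (2/3) * L^2 / sigma* * sd.
    """
    rows = []
    for n_peg, values in sorted(replicates.items()):
        if isinstance(values, tuple) and len(values) == 3:
            mean, sd, n = float(values[0]), float(values[1]), int(values[2])
        else:
            arr = np.asarray(list(values), dtype=float)
            if arr.size == 0:
                raise ValueError(f"no replicates for n_peg={n_peg}")
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            n = arr.size
        if mean <= 0:
            warnings.warn(f"non-positive sigma* for n_peg={n_peg}; row rejected",
                          stacklevel=2)
            continue
        reach = units.reach_from_sigma_star(mean)
        l2 = reach**2
        rows.append(
            {
                "n_peg": int(n_peg),
                "sigma_star_mean": mean,
                "sigma_star_sd": sd,
                "n_replicates": n,
                "L": reach,
                "L_squared": l2,
                "L_squared_err": (2.0 / 3.0) * l2 / mean * sd,
            }
        )
    return pd.DataFrame(rows)


def peg_regression(table: pd.DataFrame, exclude: set = frozenset({0}),
                   weighted: bool = False) -> dict:
    """Enzyme reach from OLS of L^2 on the number of PEG units.

    ``exclude`` drops PEG lengths from the regression (by default PEG0,
    whose very short tether introduces steric artefacts).  Returns the
    intercept-root enzyme reach with a delta-method standard error, the
    slope (an estimate of 4 * l_unit * l_p) and fit diagnostics.
    """
    sub = table[~table["n_peg"].isin(exclude)]
    if len(sub) < 3:
        raise ValueError("need at least 3 PEG lengths after exclusion")
    X = sm.add_constant(sub["n_peg"].to_numpy(dtype=float))
    y = sub["L_squared"].to_numpy(dtype=float)
    if weighted:
        err = sub["L_squared_err"].to_numpy(dtype=float)
        if np.any(err <= 0):
            raise ValueError("weighted regression requires positive L^2 errors")
        model = sm.WLS(y, X, weights=1.0 / err**2)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    intercept = float(res.params[0])
    if intercept <= 0:
        raise ValueError(
            f"negative intercept {intercept:.3g} nm^2: no real enzyme reach "
            f"(slope {res.params[1]:.3g}, R^2 {res.rsquared:.3f})"
        )
    l_enzyme = math.sqrt(intercept)
    se_intercept = float(res.bse[0])
    return {
        "L_enzyme": l_enzyme,
        "L_enzyme_se": se_intercept / (2.0 * l_enzyme),
        "intercept": intercept,
        "intercept_se": se_intercept,
        "slope": float(res.params[1]),
        "slope_se": float(res.bse[1]),
        "r_squared": float(res.rsquared),
        "p_value": float(res.pvalues[1]),
        "n_points": int(len(sub)),
        "result": res,
    }


def parse_tether_reach(l_rxn: float, l_enzyme: float) -> float:
    """Receptor-tail reach sqrt((L^2 - L_enzyme^2) / 2), nm.

    Undefined when the combined reach does not exceed the enzyme reach.
    """
    if not l_rxn > l_enzyme:
        raise ValueError(
            f"combined reach ({l_rxn} nm) must exceed the enzyme reach "
            f"({l_enzyme} nm) for the tether contribution to be real"
        )
    return math.sqrt((l_rxn**2 - l_enzyme**2) / 2.0)


def combine_reach(components, multiplicities=None) -> float:
    """Root-sum-square combination of component reaches (nm).

    ``multiplicities`` counts how many times each component enters the
    quadrature sum (e.g. two tethers + one enzyme for the SPR geometry).
    """
    comps = np.asarray(list(components), dtype=float)
    if np.any(comps < 0):
        raise ValueError("component reaches must be non-negative")
    if multiplicities is None:
        mult = np.ones_like(comps)
    else:
        mult = np.asarray(list(multiplicities), dtype=float)
        if mult.shape != comps.shape:
            raise ValueError("multiplicities must match components")
    return float(np.sqrt(np.sum(mult * comps**2)))
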