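"""Aggregate-conformation stability analysis.

Chemical denaturation with guanidine hydrochloride dissolves aggregates but
not monomers, so the detected aggregate count decays exponentially with
denaturant concentration, ``N(c) = N0 * exp(-c / c_e)``; ``c_e`` is the
concentration at which counts fall to ``N0 / e`` (~0.4 of the untreated
sample).  Immunodepletion provides an orthogonal chemical-specificity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DenaturationFit", "fit_denaturation", "depletion_fraction"]


@dataclass
class DenaturationFit:
    """Exponential-decay fit of a denaturation series."""

    n0: float
    c_e: float            # M; fitted curve crosses n0/e here by construction
    r_squared: float
    decaying: bool        # False when counts do not decrease over the range
    zero_counts_offset: bool  # True when zero counts were replaced by 0.5

    def predict(self, conc):
        return self.n0 * np.exp(-np.asarray(conc, dtype=float) / self.c_e)


def fit_denaturation(
    concs,
    counts,
) -> DenaturationFit:
    """Fit ``N(c) = N0 * exp(-c/c_e)`` by least squares on log counts.

    The log-linear fit is robust at small counts; zero counts are replaced
    by 0.5 (continuity correction) and flagged.  A non-decaying series
    (fitted slope >= 0) is returned with ``decaying=False`` and ``c_e`` set
    to infinity rather than raising.
    """
    concs = np.asarray(concs, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if concs.size != counts.size or concs.size < 3:
        raise ValueError("need >= 3 matching (concentration, count) points")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    positive = counts > 0
    if positive.sum() < 3:
        raise ValueError("need >= 3 positive counts to fit a decay")
    offset = bool(np.any(~positive))
    y = np.log(np.where(positive, counts, 0.5))
    slope, intercept = np.polyfit(concs, y, 1)
    resid = y - (slope * concs + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    if slope >= 0:
        return DenaturationFit(n0=float(np.exp(intercept)), c_e=float("inf"),
                               r_squared=r2, decaying=False,
                               zero_counts_offset=offset)
    return DenaturationFit(n0=float(np.exp(intercept)), c_e=float(-1.0 / slope),
                           r_squared=r2, decaying=True,
                           zero_counts_offset=offset)


def fit_denaturation_curve(curve: pd.DataFrame) -> DenaturationFit:
    """Fit a ``conc_M, count_mean`` table (the CSV dialect of this module)."""
    return fit_denaturation(curve["conc_M"], curve["count_mean"])


def depletion_fraction(count_before: float, count_after: float) -> float:
    """Fraction of aggregates removed by immunodepletion, 1 - after/before.

    Clipped to [0, 1]; near 1 indicates the assay detects the targeted
    protein specifically.
    """
    if count_before <= 0:
        raise ValueError("count_before must be positive")
    return float(np.clip(1.0 - count_after / count_before, 0.0, 1.0))
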