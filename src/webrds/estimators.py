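"""RDSII (inverse network-size weighted) estimation.

Respondent-driven sampling recruits along social ties, so inclusion
probability is approximately proportional to personal network size
(degree).  The RDSII estimator of Volz and Heckathorn corrects this by
weighting each respondent i by the reciprocal of their reported degree d_i:

    p_hat_A = (sum_{i in A} 1/d_i) / (sum_i 1/d_i)

for the population proportion in category A, with the analogous weighted
mean for numeric answers.  The estimated population mean degree is the
harmonic mean of the reported degrees,

    d_hat = n / sum_i (1/d_i),

which under degree-proportional (size-biased) sampling recovers the
population's arithmetic mean degree.  Missing degrees are imputed with
d_hat computed from the non-missing reports; a reported degree of zero is
treated as missing, since a respondent recruited into the study has at
least one in-scope contact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NO_ANSWER = "no_answer"


@dataclass
class RdsEstimate:
    """An RDSII estimate for one variable.

    Exactly one of ``proportions`` (category -> estimated population
    proportion, summing to 1) and ``mean`` is populated.
    """

    variable: str
    n: int
    proportions: dict | None = None
    mean: float | None = None
    estimator: str = field(default="RDSII")


def _as_degrees(degrees) -> np.ndarray:
    d = np.asarray(degrees, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("degrees must be positive and non-missing; impute first")
    return d


def impute_network_size(degrees) -> np.ndarray:
    """Replace missing (NaN) or zero reported network sizes.

    Each missing entry is set to the RDSII-estimated average network size
    (the harmonic mean) of the valid entries; valid entries are unchanged.
    """
    d = np.asarray(degrees, dtype=float).copy()
    valid = np.isfinite(d) & (d > 0)
    if not valid.any():
        raise ValueError("all reported network sizes are missing or zero")
    d[~valid] = rdsii_mean_degree(d[valid])
    return d


def rdsii_mean_degree(degrees) -> float:
    """Estimated population mean network size: n / sum(1/d_i)."""
    d = _as_degrees(degrees)
    return d.size / float(np.sum(1.0 / d))


def rdsii_proportion(categories, degrees, variable: str = "") -> RdsEstimate:
    """Inverse-degree-weighted population proportions.

    Missing answers ("don't want to answer") form their own category,
    labelled ``no_answer``.  Proportions cover every observed category and
    sum to 1.
    """
    cats = pd.Series(list(categories))
    d = _as_degrees(degrees)
    if len(cats) != d.size:
        raise ValueError(f"{len(cats)} values but {d.size} degrees")
    cats = cats.where(~cats.isna(), NO_ANSWER).astype(str)
    w = 1.0 / d
    total = float(w.sum())
    props = {
        cat: float(w[(cats == cat).to_numpy()].sum()) / total
        for cat in sorted(cats.unique())
    }
    return RdsEstimate(variable=variable, n=d.size, proportions=props)


def rdsii_mean(values, degrees, variable: str = "") -> RdsEstimate:
    """Inverse-degree-weighted mean of a numeric variable.

    Missing values are dropped pairwise (with their degrees).
    """
    x = np.asarray(values, dtype=float)
    d = _as_degrees(degrees)
    if x.size != d.size:
        raise ValueError(f"{x.size} values but {d.size} degrees")
    keep = np.isfinite(x)
    x, d = x[keep], d[keep]
    if x.size == 0:
        raise ValueError("no non-missing values")
    w = 1.0 / d
    return RdsEstimate(
        variable=variable, n=int(x.size), mean=float(np.sum(x * w) / np.sum(w))
    )
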