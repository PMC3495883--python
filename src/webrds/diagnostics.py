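"""Equilibrium and convergence diagnostics for RDS recruitment chains.

RDS estimation assumes the recruitment process has run long enough that
the sample composition no longer depends on the seeds.  The standard check
models recruitment on a categorical variable as a first-order Markov chain
whose transition probabilities are the averaged recruiter-to-recruit
transition frequencies observed in the study's chains.  The chain's
stationary distribution is the composition "after an infinite number of
steps"; the waves-to-equilibrium statistic is the smallest number of steps
after which every starting composition is within a relative tolerance
(default 2%) of stationarity.  Complementary empirical checks plot the
running sample composition against sample size and compare the full-sample
estimate with the last k respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .estimators import rdsii_mean, rdsii_proportion
from .forest import RecruitmentForest

__all__ = [
    "RecruitmentForest",
    "TransitionMatrix",
    "estimate_transition_matrix",
    "stationary_distribution",
    "waves_to_equilibrium",
    "running_composition",
    "last_k_comparison",
    "wave_stats",
    "cross_group_recruitment_fraction",
]


@dataclass
class TransitionMatrix:
    """Recruiter-category -> recruit-category transition matrix.

    ``counts[j, k]`` is the number of recruitment events from a category-j
    recruiter to a category-k recruit; ``probs`` is the row-normalised
    (row-stochastic) version.  The state space is restricted to categories
    observed at least once as a recruiter; categories appearing only as
    recruits are listed in ``dropped_states``.
    """

    variable: str
    states: list
    counts: np.ndarray
    probs: np.ndarray = field(init=False)
    dropped_states: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        rowsums = self.counts.sum(axis=1, keepdims=True)
        if np.any(rowsums == 0):
            bad = [s for s, r in zip(self.states, rowsums[:, 0]) if r == 0]
            raise ValueError(f"states with no outgoing events: {bad}")
        self.probs = self.counts / rowsums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.states, columns=self.states)


def estimate_transition_matrix(
    forest: RecruitmentForest, records: pd.DataFrame, variable: str
) -> TransitionMatrix:
    """Average the recruiter->recruit transitions over all recruitment events.

    Events whose recruiter or recruit has a missing value on ``variable``
    are dropped.  Raises if no usable recruitment event exists.
    """
    values = records.set_index("id")[variable]
    events = []
    for recruiter, recruit in forest.recruitment_events():
        a, b = values.get(recruiter), values.get(recruit)
        if a is None or b is None or pd.isna(a) or pd.isna(b):
            continue
        events.append((str(a), str(b)))
    if not events:
        raise ValueError(f"no recruitment events with observed {variable!r}")
    recruiter_cats = sorted({a for a, _ in events})
    all_cats = sorted({c for ab in events for c in ab})
    dropped = [c for c in all_cats if c not in recruiter_cats]
    index = {c: i for i, c in enumerate(recruiter_cats)}
    counts = np.zeros((len(recruiter_cats), len(recruiter_cats)))
    for a, b in events:
        if b in index:  # transitions into dropped states leave the chain
            counts[index[a], index[b]] += 1
    if np.any(counts.sum(axis=1) == 0):
        bad = [c for c in recruiter_cats if counts[index[c]].sum() == 0]
        raise ValueError(
            f"variable {variable!r}: categories {bad} recruit only into "
            "categories never observed as recruiters; chain undefined"
        )
    return TransitionMatrix(
        variable=variable, states=recruiter_cats, counts=counts, dropped_states=dropped
    )


def _check_ergodic(tm: TransitionMatrix) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(range(len(tm.states)))
    for j, k in zip(*np.nonzero(tm.probs > 0)):
        g.add_edge(int(j), int(k))
    if not nx.is_strongly_connected(g):
        comps = [
            sorted(tm.states[i] for i in c)
            for c in nx.strongly_connected_components(g)
        ]
        raise ValueError(
            f"transition matrix for {tm.variable!r} is reducible; "
            f"communicating classes: {comps}"
        )
    if not nx.is_aperiodic(g):
        raise ValueError(
            f"transition matrix for {tm.variable!r} is periodic on states {tm.states}"
        )


def stationary_distribution(tm: TransitionMatrix) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1 for an irreducible aperiodic chain."""
    _check_ergodic(tm)
    P = tm.probs
    k = P.shape[0]
    a = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.max(np.abs(pi @ P - pi)))
    if resid > 1e-10:
        raise ValueError(f"stationary solve residual {resid:.2e} exceeds 1e-10")
    return pi


def waves_to_equilibrium(
    tm: TransitionMatrix,
    tolerance: float = 0.02,
    start=None,
    max_iter: int = 500_000,
) -> int:
    """Waves until the chain is within ``tolerance`` relative difference of
    its stationary composition.

    By default the criterion is worst-case over all degenerate starts
    (every chain begun in a single category), the reading under which the
    statistic certifies seed-independence: the smallest n such that
    |(e_j P^n)_c - pi_c| / pi_c < tolerance for every start j and category
    c.  Pass ``start`` (a probability vector over the states) to evaluate a
    specific starting composition instead.
    """
    pi = stationary_distribution(tm)
    if np.any(pi <= 0):
        zero = [s for s, p in zip(tm.states, pi) if p <= 0]
        raise ValueError(
            f"stationary probability is zero for {zero}; relative difference undefined"
        )
    P = tm.probs
    if start is not None:
        current = np.atleast_2d(np.asarray(start, dtype=float))
        if current.shape[1] != P.shape[0] or abs(current.sum() - 1) > 1e-9:
            raise ValueError("start must be a probability vector over the chain's states")
    else:
        current = np.eye(P.shape[0])
    for n in range(1, max_iter + 1):
        current = current @ P
        if np.max(np.abs(current - pi) / pi) < tolerance:
            return n
    raise ValueError(f"no convergence within {max_iter} iterations")


def running_composition(
    records: pd.DataFrame, degrees, variable: str, step: int = 25
) -> pd.DataFrame:
    """Sample composition and RDSII estimate as the sample accumulates.

    Records must be time-ordered (ties broken by id).  Estimates are
    recomputed on the first m records for m = step, 2*step, ..., n; the
    final point is always the full sample, so the curve's endpoint equals
    the full-sample estimate exactly.
    """
    if step < 1:
        raise ValueError("step must be at least 1")
    order = records.sort_values(["timestamp", "id"], kind="mergesort")
    d = np.asarray(degrees, dtype=float)[
        records.reset_index(drop=True)
        .sort_values(["timestamp", "id"], kind="mergesort")
        .index
    ]
    n = len(order)
    sizes = sorted(set(list(range(step, n + 1, step)) + [n]))
    rows = []
    values = order[variable]
    for m in sizes:
        head = values.iloc[:m]
        est = rdsii_proportion(head, d[:m], variable=variable)
        raw = head.fillna("no_answer").astype(str).value_counts(normalize=True)
        for cat, p in est.proportions.items():
            rows.append(
                {
                    "sample_size": m,
                    "variable": variable,
                    "category": cat,
                    "sample_proportion": float(raw.get(cat, 0.0)),
                    "rdsii_estimate": p,
                }
            )
    return pd.DataFrame(rows)


def last_k_comparison(
    records: pd.DataFrame,
    degrees,
    variables,
    numeric_variables=(),
    k: int = 200,
) -> pd.Series:
    """Stability check: full-sample RDSII estimates versus the last k
    respondents.

    For categorical variables, the maximum over categories of the absolute
    difference in estimated proportions; for numeric variables, the
    absolute difference of the weighted means.  A small value indicates the
    late sample no longer drifts.
    """
    n = len(records)
    if n <= k:
        raise ValueError(f"need more than k={k} records, have {n}")
    order = records.sort_values(["timestamp", "id"], kind="mergesort")
    d = np.asarray(degrees, dtype=float)[
        records.reset_index(drop=True)
        .sort_values(["timestamp", "id"], kind="mergesort")
        .index
    ]
    tail, d_tail = order.iloc[-k:], d[-k:]
    out = {}
    for var in variables:
        full = rdsii_proportion(order[var], d, variable=var).proportions
        last = rdsii_proportion(tail[var], d_tail, variable=var).proportions
        cats = set(full) | set(last)
        out[var] = max(abs(full.get(c, 0.0) - last.get(c, 0.0)) for c in cats)
    for var in numeric_variables:
        full = rdsii_mean(order[var], d, variable=var).mean
        last = rdsii_mean(tail[var], d_tail, variable=var).mean
        out[var] = abs(full - last)
    return pd.Series(out, name="max_abs_difference")


def wave_stats(forest: RecruitmentForest, wave_threshold: int = 5) -> dict:
    """Recruitment-structure summary from the parent map and timestamps.

    Returns per-chain sizes and maximum wave numbers, the overall maximum
    wave, the number of chains exceeding ``wave_threshold`` waves, and the
    cumulative number of submissions per (integer) day.
    """
    chain_of = {v: forest.root_of(v) for v in forest.nodes}
    chain_sizes: dict = {}
    chain_max_wave: dict = {}
    for v, root in chain_of.items():
        chain_sizes[root] = chain_sizes.get(root, 0) + 1
        chain_max_wave[root] = max(chain_max_wave.get(root, 0), forest.wave[v])
    cumulative = {}
    if forest.timestamp:
        days = sorted(int(np.floor(t)) for t in forest.timestamp.values())
        total = 0
        for day in range(days[0], days[-1] + 1):
            total += sum(1 for d in days if d == day)
            cumulative[day] = total
    return {
        "n_chains": len(chain_sizes),
        "chain_sizes": chain_sizes,
        "chain_max_wave": chain_max_wave,
        "max_wave": max(chain_max_wave.values()) if chain_max_wave else 0,
        "n_chains_exceeding_threshold": sum(
            1 for w in chain_max_wave.values() if w > wave_threshold
        ),
        "wave_threshold": wave_threshold,
        "cumulative_submissions_by_day": cumulative,
    }


def cross_group_recruitment_fraction(
    forest: RecruitmentForest, records: pd.DataFrame, attribute: str
) -> float:
    """Fraction of recruitment events joining differing attribute values,
    e.g. the share of recruitments crossing province boundaries."""
    values = records.set_index("id")[attribute]
    events = forest.recruitment_events()
    if not events:
        raise ValueError("forest contains no recruitment events")
    missing = [
        (a, b) for a, b in events
        if a not in values.index or b not in values.index
        or pd.isna(values[a]) or pd.isna(values[b])
    ]
    if missing:
        raise ValueError(
            f"attribute {attribute!r} missing for {len(missing)} recruitment events"
        )
    differing = sum(1 for a, b in events if values[a] != values[b])
    return differing / len(events)
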