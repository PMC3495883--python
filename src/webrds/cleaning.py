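"""Submission validity flags and progressively stricter inclusion levels.

Web-based RDS collects submissions without face-to-face verification, so a
share of records is invalid: stated ages below the eligibility threshold,
repeated contact identifiers (one person answering several times for extra
rewards), shared IP tokens, implausibly fast completions, and improbable
answers.  This module flags those records and builds nested analysis
samples for sensitivity comparison:

* **L0** — non-seed submissions with valid stated age (the baseline);
* **L1** — L0 minus repeated phone/email/chat tokens (the *cleaned sample*);
* **L2** — L1 minus repeated IP tokens;
* **L3** — L2 minus fast completions (< 3 minutes), no-education answers
  and six-month partner counts above 1,000.

Seeds are always excluded from analysis samples, as is customary in RDS.
"Previously registered" is interpreted chronologically: the earliest bearer
of a token is never flagged, later bearers are.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .forest import RecruitmentForest

ADULT_AGE = 18
FAST_MINUTES = 3.0
EXTREME_PARTNERS = 1000

INCLUSION_LEVELS = ("L0", "L1", "L2", "L3")
FLAG_COLUMNS = (
    "underage",
    "duplicate_contact",
    "duplicate_ip",
    "fast_completion",
    "no_education",
    "extreme_partners",
)

_CONTACT_COLUMNS = ("phone_token", "email_token", "chat_token")
_NON_DIGITS = re.compile(r"\D")


def normalize_token(token, kind: str = "generic"):
    """Canonicalise an identity token; idempotent.

    Trims whitespace and lowercases; phone numbers are additionally reduced
    to their digits.  Empty or missing tokens normalise to ``None``.
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip().lower()
    if kind == "phone":
        s = _NON_DIGITS.sub("", s)
    return s or None


def flag_invalid(records: pd.DataFrame) -> pd.DataFrame:
    """Compute per-record validity flags.

    Returns a boolean DataFrame indexed like ``records`` with columns
    ``underage``, ``duplicate_contact``, ``duplicate_ip``,
    ``fast_completion``, ``no_education`` and ``extreme_partners``.  A
    repeated contact or IP token flags every bearer except the
    chronologically first (ties broken by record id).
    """
    if records["id"].duplicated().any():
        dupes = records.loc[records["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate submission ids: {dupes[:5]}")
    flags = pd.DataFrame(False, index=records.index, columns=list(FLAG_COLUMNS))
    flags["underage"] = records["stated_age"] < ADULT_AGE
    flags["fast_completion"] = records["completion_minutes"] < FAST_MINUTES
    if "education" in records:
        flags["no_education"] = records["education"] == "none"
    if "partners_6mo" in records:
        flags["extreme_partners"] = records["partners_6mo"] > EXTREME_PARTNERS

    order = records.sort_values(["timestamp", "id"], kind="mergesort").index
    for cols, out in ((_CONTACT_COLUMNS, "duplicate_contact"), (("ip_token",), "duplicate_ip")):
        seen: dict = {c: set() for c in cols}
        for idx in order:
            is_dup = False
            for c in cols:
                if c not in records:
                    continue
                kind = "phone" if c == "phone_token" else "generic"
                tok = normalize_token(records.at[idx, c], kind)
                if tok is None:
                    continue
                if tok in seen[c]:
                    is_dup = True
                else:
                    seen[c].add(tok)
            flags.at[idx, out] = is_dup
    return flags


def _level_mask(records: pd.DataFrame, flags: pd.DataFrame, level: str) -> pd.Series:
    if level not in INCLUSION_LEVELS:
        raise ValueError(f"unknown inclusion level {level!r}; expected one of {INCLUSION_LEVELS}")
    mask = ~records["is_seed"].astype(bool) & ~flags["underage"]
    if level >= "L1":
        mask &= ~flags["duplicate_contact"]
    if level >= "L2":
        mask &= ~flags["duplicate_ip"]
    if level >= "L3":
        mask &= ~(flags["fast_completion"] | flags["no_education"] | flags["extreme_partners"])
    return mask


def apply_inclusion(records: pd.DataFrame, flags: pd.DataFrame, level: str) -> pd.DataFrame:
    """Return the records passing the cumulative criteria of ``level``."""
    return records.loc[_level_mask(records, flags, level)]


def cleaning_summary(records: pd.DataFrame, flags: pd.DataFrame) -> dict:
    """Headline cleaning arithmetic on the full submission set.

    ``invalid`` counts non-seed records that are underage or bear a
    repeated contact token; percentages use all submissions (seeds
    included) as denominator.  ``excluded`` additionally counts the seeds,
    matching the construction of the cleaned sample.
    """
    n = len(records)
    n_seeds = int(records["is_seed"].sum())
    nonseed = ~records["is_seed"].astype(bool)
    invalid = nonseed & (flags["underage"] | flags["duplicate_contact"])
    n_invalid = int(invalid.sum())
    n_excluded = n_seeds + n_invalid
    return {
        "n_submissions": n,
        "n_seeds": n_seeds,
        "n_invalid": n_invalid,
        "invalid_pct": 100.0 * n_invalid / n,
        "n_excluded": n_excluded,
        "excluded_pct": 100.0 * n_excluded / n,
        "level_sizes": {
            lvl: int(_level_mask(records, flags, lvl).sum()) for lvl in INCLUSION_LEVELS
        },
    }


def reattach_orphans(forest: RecruitmentForest, excluded) -> RecruitmentForest:
    """Drop excluded nodes, re-parenting descendants to their nearest
    retained ancestor (or promoting them to pseudo-seeds), and recompute
    waves.  Chain repair is diagnostic-only: RDSII ignores tree structure.
    """
    excluded = set(excluded)
    unknown = excluded - set(forest.parent)
    if unknown:
        raise ValueError(f"excluded ids not in forest: {sorted(unknown, key=repr)[:5]}")
    new_parent = {}
    for node in forest.nodes:
        if node in excluded:
            continue
        anc = forest.parent[node]
        while anc is not None and anc in excluded:
            anc = forest.parent[anc]
        new_parent[node] = anc
    return RecruitmentForest(
        parent=new_parent,
        timestamp={v: forest.timestamp[v] for v in new_parent} if forest.timestamp else {},
        person={v: forest.person[v] for v in new_parent},
    )


def sensitivity_report(
    records: pd.DataFrame,
    flags: pd.DataFrame,
    variables,
    levels=INCLUSION_LEVELS,
) -> pd.DataFrame:
    """RDSII estimates per inclusion level per variable, with the absolute
    difference of each estimate from its L0 (baseline) value.

    Network sizes are re-imputed within each level from that level's
    non-missing reports, mirroring an analysis that only ever sees the
    included records.
    """
    from .estimators import impute_network_size, rdsii_proportion

    rows = []
    baseline: dict = {}
    for level in levels:
        sub = apply_inclusion(records, flags, level)
        if sub.empty:
            raise ValueError(f"inclusion level {level} retains no records")
        degrees = impute_network_size(sub["reported_network_size"].to_numpy(float))
        for var in variables:
            est = rdsii_proportion(sub[var], degrees, variable=var)
            for cat, p in est.proportions.items():
                if level == levels[0]:
                    baseline[(var, cat)] = p
                rows.append(
                    {
                        "level": level,
                        "variable": var,
                        "category": cat,
                        "n": est.n,
                        "rdsii_estimate": p,
                        "abs_diff_vs_baseline": abs(p - baseline.get((var, cat), 0.0)),
                    }
                )
    return pd.DataFrame(rows)
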