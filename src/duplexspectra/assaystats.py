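"""Reporter-assay statistics: mutant frequencies, fold changes and the
exact Mann-Whitney U test.

The mutant frequency of one animal is the ratio of its total
6-thioguanine-resistant colony count to its mean chloramphenicol-resistant
(titer) colony count.  Group comparisons use the *exact* two-sided
Mann-Whitney U test by full enumeration of labelings — at the small group
sizes of animal studies (n around 5) the exact null distribution is what
produces the familiar printed p-values (0.0079 for complete separation of
two groups of five, 0.0159 for a single crossing); a normal approximation
would not.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_MAX_EXACT = 12  # per-group bound for full enumeration


@dataclass
class GptAssayCounts:
    animal: str
    group: str
    tg_resistant: int
    cm_resistant_mean: float


def mutant_frequency(counts) -> float:
    """6-TG-resistant colonies over mean titer colonies.

    Accepts a :class:`GptAssayCounts` or any object/row with
    ``tg_resistant`` and ``cm_resistant_mean`` attributes.
    """
    tg = counts.tg_resistant
    cm = counts.cm_resistant_mean
    if tg < 0:
        raise ValueError("negative colony count")
    if cm <= 0:
        raise ValueError("titer (cm_resistant_mean) must be positive")
    return tg / cm


def fold_change(treated, control) -> float:
    """Ratio of group mean mutant frequencies (treated over control)."""
    treated = np.asarray(list(treated), dtype=float)
    control = np.asarray(list(control), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("empty group")
    cm = control.mean()
    if cm <= 0:
        raise ValueError("control mean must be positive")
    return float(treated.mean() / cm)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test for two small samples.

    Ties are handled by midranks; the p-value is computed by enumerating
    all C(na+nb, na) assignments of the pooled observations, with
    two-sided = 2 x min(lower tail, upper tail), capped at 1 (tails include
    the observed statistic).  Returns ``(U, p)`` with ``U = min(U1, U2)``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("empty group")
    if na > _MAX_EXACT or nb > _MAX_EXACT:
        raise ValueError(
            f"exact enumeration supports at most {_MAX_EXACT} observations per group"
        )
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:na].sum()
    u1 = r1 - na * (na + 1) / 2
    u2 = na * nb - u1

    total = comb(na + nb, na)
    eps = 1e-9
    n_le = 0
    n_ge = 0
    base = na * (na + 1) / 2
    for idx in combinations(range(na + nb), na):
        u = sum(ranks[i] for i in idx) - base
        if u <= u1 + eps:
            n_le += 1
        if u >= u1 - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return float(min(u1, u2)), p


def gpt_summary(
    table: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal mutant frequencies plus per-group means, fold changes
    relative to ``control_group`` and exact Mann-Whitney comparisons.

    ``table`` needs columns animal, group, tg_resistant, cm_resistant_mean.
    Returns ``(per_animal, per_group)`` frames; mutant frequencies are kept
    on the natural scale (multiply by 1e6 for the conventional unit).
    """
    required = {"animal", "group", "tg_resistant", "cm_resistant_mean"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)}")
    per_animal = table.copy()
    per_animal["mutant_frequency"] = (
        per_animal["tg_resistant"] / per_animal["cm_resistant_mean"]
    )
    if control_group not in set(per_animal["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    control_mf = per_animal.loc[
        per_animal["group"] == control_group, "mutant_frequency"
    ]
    rows = []
    for group, sub in per_animal.groupby("group", sort=False):
        mf = sub["mutant_frequency"]
        if group == control_group:
            fc, u, p = 1.0, np.nan, np.nan
        else:
            fc = fold_change(mf, control_mf)
            u, p = mann_whitney_exact(mf, control_mf)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "mean_mf": mf.mean(),
                "fold_change_vs_control": fc,
                "U": u,
                "p_two_sided": p,
            }
        )
    return per_animal, pd.DataFrame(rows)
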