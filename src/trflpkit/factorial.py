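"""Two-factor factorial ANOVA with Tukey–Kramer letters.

The engine behind treatment-comparison tables: a fixed-effects two-way
ANOVA with interaction in a completely randomized design, followed by
Tukey–Kramer pairwise comparisons of the cell means and a compact letter
display (two groups share a letter iff their comparison is not significant
at alpha).

Sums of squares come from least-squares model comparison, which reduces to
the classical balanced decomposition when cell sizes are equal and to
Type-II sums of squares otherwise.  Tukey–Kramer p-values use the
studentized range distribution with the unequal-n correction
q = |m_i - m_j| / sqrt(MS_error (1/n_i + 1/n_j) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """ANOVA table, cell means, and (after tukey_kramer) letter groups."""

    table: pd.DataFrame       # index A, B, A:B, Residual; sum_sq df mean_sq F p
    cell_means: pd.DataFrame  # index "a:b"; columns factor_a, factor_b, mean, n, se
    ms_error: float
    df_error: int
    factor_a: str
    factor_b: str
    response: str
    letters: dict[str, str] | None = None
    pairwise: pd.DataFrame | None = None


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def two_way_anova(data: pd.DataFrame, factor_a: str, factor_b: str,
                  response: str) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    ``data`` is a long table with one row per observation.  Every A x B
    cell must be observed and the residual degrees of freedom must be at
    least 1 (>= 2 replicates in at least one cell).  A constant response
    yields F = 0, p = 1 for every term.
    """
    df = data[[factor_a, factor_b, response]].dropna()
    y = df[response].to_numpy(float)
    a_codes, a_levels = pd.factorize(df[factor_a], sort=True)
    b_codes, b_levels = pd.factorize(df[factor_b], sort=True)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = pd.crosstab(a_codes, b_codes)
    if cells.shape != (na, nb) or (cells.to_numpy() == 0).any():
        raise ValueError("incomplete design: empty cell")
    n = y.size
    df_err = n - na * nb
    if df_err < 1:
        raise ValueError("no residual degrees of freedom")

    ones = np.ones((n, 1))
    da = _dummies(a_codes, na)
    db = _dummies(b_codes, nb)
    dab = np.einsum("ij,ik->ijk", da, db).reshape(n, -1)
    x_full = np.hstack([ones, da, db, dab])
    x_ab = np.hstack([ones, da, db])
    x_a = np.hstack([ones, da])
    x_b = np.hstack([ones, db])

    # center the response: RSS of intercept models is unchanged, and a
    # constant response becomes exactly zero everywhere (all F = 0)
    yc = y - y.mean()
    rss_full = _rss(x_full, yc)
    rss_ab = _rss(x_ab, yc)
    ss = {
        "A": _rss(x_b, yc) - rss_ab,   # Type II: A after B
        "B": _rss(x_a, yc) - rss_ab,   # Type II: B after A
        "A:B": rss_ab - rss_full,
    }
    dof = {"A": na - 1, "B": nb - 1, "A:B": (na - 1) * (nb - 1)}
    ms_error = rss_full / df_err

    rows = []
    for term in ("A", "B", "A:B"):
        s = max(ss[term], 0.0)
        ms = s / dof[term]
        if ms_error > 0:
            f = ms / ms_error
            p = float(stats.f.sf(f, dof[term], df_err))
        else:
            f, p = (0.0, 1.0) if s <= 1e-12 else (np.inf, 0.0)
        rows.append({"term": term, "sum_sq": s, "df": dof[term],
                     "mean_sq": ms, "F": f, "p": p})
    rows.append({"term": "Residual", "sum_sq": rss_full, "df": df_err,
                 "mean_sq": ms_error, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")

    means = (df.groupby([factor_a, factor_b])[response]
             .agg(["mean", "count"]).reset_index()
             .rename(columns={"count": "n"}))
    means["se"] = np.sqrt(ms_error / means["n"])
    means.index = [f"{a}:{b}" for a, b in zip(means[factor_a], means[factor_b])]
    return AnovaResult(table=table, cell_means=means, ms_error=ms_error,
                       df_error=df_err, factor_a=factor_a, factor_b=factor_b,
                       response=response)


def tukey_pairwise(means: np.ndarray, ns: np.ndarray, ms_error: float,
                   df_error: int, labels: list[str]) -> pd.DataFrame:
    """All pairwise Tukey–Kramer comparisons among ``len(means)`` groups."""
    if df_error < 1:
        raise ValueError("no residual df")
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        se = np.sqrt(ms_error * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
        if se > 0:
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_error))
        else:
            q = 0.0 if diff <= 1e-12 else np.inf
            p = 1.0 if diff <= 1e-12 else 0.0
        rows.append({"group1": labels[i], "group2": labels[j],
                     "diff": means[i] - means[j], "q": q, "p": p})
    return pd.DataFrame(rows)


def compact_letters(labels: list[str], significant: set[tuple[str, str]],
                    order: list[str] | None = None) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one class holding all groups; every significant pair splits
    each class containing both; classes that become subsets of another are
    absorbed.  Two groups share a letter iff their pair is not in
    ``significant``.  Letters are named a, b, c... in ``order`` of the
    groups (default: input order).
    """
    classes: list[set[str]] = [set(labels)]
    for g1, g2 in significant:
        new: list[set[str]] = []
        for cls in classes:
            if g1 in cls and g2 in cls:
                new.extend([cls - {g1}, cls - {g2}])
            else:
                new.append(cls)
        classes = [c for c in new if c]
        # absorb classes contained in another
        classes = [c for i, c in enumerate(classes)
                   if not any(i != j and c < other or (c == other and i > j)
                              for j, other in enumerate(classes))]
    rank = {g: i for i, g in enumerate(order or labels)}
    classes.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in labels}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_kramer(result: AnovaResult, alpha: float = 0.05,
                 scope: str = "cells") -> AnovaResult:
    """Tukey–Kramer comparisons of cell means with letter assignment.

    ``scope="cells"`` letters all A x B cells jointly (as in treatment
    tables spanning every time x treatment combination);
    ``scope="within_a"`` runs a separate comparison family within each
    level of factor A.  Returns the result with ``pairwise`` and
    ``letters`` filled in; cell_means gains a ``letter`` column ordered so
    that 'a' marks the class containing the highest mean.
    """
    cm = result.cell_means
    letters: dict[str, str] = {}
    frames = []
    if scope == "cells":
        groups = [cm]
    elif scope == "within_a":
        groups = [sub for _, sub in cm.groupby(result.factor_a, sort=True)]
    else:
        raise ValueError("scope must be 'cells' or 'within_a'")
    for sub in groups:
        pw = tukey_pairwise(sub["mean"].to_numpy(), sub["n"].to_numpy(),
                            result.ms_error, result.df_error, list(sub.index))
        sig = {(r.group1, r.group2) for r in pw.itertuples() if r.p <= alpha}
        sig |= {(b, a) for a, b in sig}
        order = list(sub.sort_values("mean", ascending=False).index)
        letters.update(compact_letters(list(sub.index), sig, order=order))
        frames.append(pw)
    result.pairwise = pd.concat(frames, ignore_index=True)
    result.letters = letters
    result.cell_means = cm.assign(letter=[letters[g] for g in cm.index])
    return result
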