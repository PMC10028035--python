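"""Class-characteristic comparisons: contingency tests and rank tests.

Categorical covariates are compared across latent classes with a Pearson
chi-square (no continuity correction) by default or Fisher's exact test;
continuous covariates with Kruskal-Wallis (t-test selectable for the
two-group case).  The exact r x c Fisher test enumerates all tables with
the observed margins when that enumeration is small enough, and otherwise
falls back to a seeded Monte-Carlo p-value over tables drawn with fixed
margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import QoLPanel, ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    """Covariate levels x classes count table."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts.astype(int))
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape must match labels")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")

    @classmethod
    def from_labels(cls, rows, cols) -> "ContingencyTable":
        ct = pd.crosstab(pd.Series(np.asarray(rows)), pd.Series(np.asarray(cols)))
        return cls(tuple(ct.index), tuple(ct.columns), ct.to_numpy())


def _log_table_prob(tab: np.ndarray, logfact) -> float:
    """Log probability of a table under fixed margins (hypergeometric)."""
    r = tab.sum(axis=1)
    c = tab.sum(axis=0)
    n = tab.sum()
    return float(logfact[r].sum() + logfact[c].sum() - logfact[n] - logfact[tab].sum())


def _enumerate_fisher(counts: np.ndarray, max_tables: int = 200_000) -> float | None:
    """Exact Fisher p by branch enumeration; None if the space is too large."""
    rows, cols = counts.shape
    rmarg = counts.sum(axis=1)
    cmarg = counts.sum(axis=0)
    n = int(counts.sum())
    logfact = np.append(0.0, np.cumsum(np.log(np.arange(1, n + 1))))
    obs_lp = _log_table_prob(counts, logfact)
    tol = 1e-10
    total = 0.0
    n_seen = 0

    def rec(i, remaining_cols, acc_rows):
        nonlocal total, n_seen
        if n_seen > max_tables:
            raise OverflowError
        if i == rows - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            tab = np.vstack(acc_rows + [last])
            n_seen += 1
            lp = _log_table_prob(tab, logfact)
            if lp <= obs_lp + tol:
                total += np.exp(lp)
            return
        # enumerate compositions of rmarg[i] over the columns within margins
        def comp(j, left, row):
            if j == cols - 1:
                if left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.append(row, left), acc_rows + [np.append(row, left)])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                comp(j + 1, left - v, np.append(row, v))

        comp(0, int(rmarg[i]), np.empty(0, dtype=int))

    try:
        rec(0, cmarg.copy(), [])
    except OverflowError:
        return None
    return min(total, 1.0)


def contingency_test(
    table: ContingencyTable,
    method: str = "chi2",
    n_mc: int = 20_000,
    seed: int = 0,
) -> tuple[float | None, float]:
    """Association test on a contingency table; returns (statistic, p).

    ``chi2`` is the Pearson statistic without continuity correction;
    ``fisher`` is exact (2x2 and enumerable r x c) or Monte-Carlo with the
    given seed.  The statistic is None for Fisher.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("test requires at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero row/column margin: test undefined")
    if method == "chi2":
        res = stats.chi2_contingency(counts, correction=False)
        return float(res.statistic), float(res.pvalue)
    if method != "fisher":
        raise ValidationError("method must be 'chi2' or 'fisher'")
    if counts.shape == (2, 2):
        return None, float(stats.fisher_exact(counts).pvalue)
    p = _enumerate_fisher(counts)
    if p is not None:
        return None, p
    # Monte-Carlo fall-back with fixed margins
    rng = np.random.default_rng(seed)
    dist = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    n = int(counts.sum())
    logfact = np.append(0.0, np.cumsum(np.log(np.arange(1, n + 1))))
    obs_lp = _log_table_prob(counts, logfact)
    draws = dist.rvs(n_mc, random_state=rng).astype(int)
    lps = np.array([_log_table_prob(t, logfact) for t in draws])
    p_mc = (1 + (lps <= obs_lp + 1e-10).sum()) / (n_mc + 1)
    return None, float(p_mc)


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; returns (H, df, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("every group must be non-empty")
    if np.ptp(values) == 0:
        raise ValidationError("all values identical: H undefined (tie correction is zero)")
    res = stats.kruskal(*samples)
    return float(res.statistic), len(levels) - 1, float(res.pvalue)


def class_characteristics_report(
    panel: QoLPanel,
    classes,
    categorical: tuple[str, ...] = ("sex", "ecog"),
    continuous: tuple[str, ...] = ("age",),
    categorical_test: str = "chi2",
    continuous_test: str = "kruskal",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-covariate class comparison table with the configured tests.

    Categorical rows report ``count (percent)`` per class; continuous rows
    report ``median (min, max)``.  With a single class the descriptives are
    emitted and the test column reads ``skipped``.
    """
    classes = np.asarray(classes)
    if classes.shape != (panel.n_subjects,):
        raise ValidationError("class labels must align with panel subjects")
    levels = sorted(pd.unique(classes))
    single = len(levels) < 2
    rows = []
    cov = panel.covariates
    for name in categorical:
        if name not in cov.columns:
            continue
        vals = cov[name]
        if single:
            p_txt = "skipped"
        else:
            tab = ContingencyTable.from_labels(vals, classes)
            try:
                _, p = contingency_test(tab, method=categorical_test, seed=seed)
                p_txt = f"{p:.4g} ({categorical_test})"
            except ValidationError as exc:
                p_txt = f"untestable: {exc}"
        for lev in sorted(pd.unique(vals)):
            row = {"covariate": name, "level": str(lev), "test_p": p_txt}
            for k in levels:
                sel = classes == k
                cnt = int(((vals == lev) & sel).sum())
                row[f"class_{k}"] = f"{cnt} ({100*cnt/max(sel.sum(),1):.0f})"
            rows.append(row)
    for name in continuous:
        if name not in cov.columns:
            continue
        vals = pd.to_numeric(cov[name], errors="raise").to_numpy(float)
        if single:
            p_txt = "skipped"
        elif continuous_test == "kruskal":
            try:
                _, _, p = kruskal_wallis(vals, classes)
                p_txt = f"{p:.4g} (kruskal)"
            except ValidationError as exc:
                p_txt = f"untestable: {exc}"
        elif continuous_test == "ttest":
            if len(levels) != 2:
                p_txt = "untestable: t-test needs exactly 2 groups"
            else:
                g0, g1 = (vals[classes == k] for k in levels)
                p_txt = f"{stats.ttest_ind(g0, g1).pvalue:.4g} (ttest)"
        else:
            raise ValidationError("continuous_test must be 'kruskal' or 'ttest'")
        row = {"covariate": name, "level": "median (min, max)", "test_p": p_txt}
        for k in levels:
            v = vals[classes == k]
            row[f"class_{k}"] = f"{np.median(v):.1f} ({v.min():.1f}, {v.max():.1f})"
        rows.append(row)
    return pd.DataFrame(rows)
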