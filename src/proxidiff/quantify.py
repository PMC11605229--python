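"""Protein-level normalization and group-vs-group contrasts.

The contrast is a plain two-sample pooled-variance t-test on log2
intensities: ``log2FC = mean_A - mean_B``, ``df = n_A + n_B - 2``, with
Benjamini–Hochberg adjustment across the proteins testable in that
contrast.  Proteins with fewer than ``min_obs`` observed values in either
group are reported with ``testable = False`` and excluded from the BH pool
rather than imputed.  The same engine serves as the two-group expression
differential-expression step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .simulate import IntensityTable


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    q at sorted rank i is ``min_{j >= i} min(1, p_(j) * m / j)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def normalize_median(table):
    """Equalize sample medians (over observed values) in log2 space.

    Every column is shifted so its median equals the median of the
    pre-normalization column medians; missing cells stay missing.  Accepts
    an :class:`~proxidiff.simulate.IntensityTable` or a bare DataFrame and
    returns the same kind.
    """
    values = table.values if isinstance(table, IntensityTable) else table
    if not isinstance(values, pd.DataFrame):
        raise ValidationError("normalize_median expects an IntensityTable or DataFrame")
    n_obs = values.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValidationError(
            f"sample(s) with no observed values: {', '.join(map(str, empty))}"
        )
    medians = values.median(axis=0, skipna=True)
    target = medians.median()
    shifted = values + (target - medians)
    if isinstance(table, IntensityTable):
        return IntensityTable(values=shifted, design=table.design.copy())
    return shifted


def _contrast_groups(table, design, group_a, group_b):
    if isinstance(table, IntensityTable):
        values, design = table.values, table.design
    else:
        values = table
        if design is None:
            raise ValidationError("a design is required when passing a bare DataFrame")
    for group in (group_a, group_b):
        if group not in set(design):
            raise ValidationError(f"condition {group!r} not present in the design")
    cols_a = [s for s in values.columns if design.get(s) == group_a]
    cols_b = [s for s in values.columns if design.get(s) == group_b]
    return values, cols_a, cols_b


def contrast(
    table,
    group_a: str,
    group_b: str,
    *,
    design: pd.Series | None = None,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Two-sample pooled-t contrast of ``group_a`` minus ``group_b``.

    Returns one row per protein: ``log2fc``, ``t``, ``df``, ``p``, ``q``
    (BH over testable proteins only), ``n_a``, ``n_b``, ``testable``.
    Untestable proteins (fewer than ``min_obs`` observed values in either
    group) carry NaN statistics.
    """
    if min_obs < 2:
        raise ValidationError("min_obs must be >= 2")
    values, cols_a, cols_b = _contrast_groups(table, design, group_a, group_b)

    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= min_obs) & (n_b >= min_obs)
    if not testable.any():
        raise ValidationError(
            f"no protein has >= {min_obs} observed values in both groups"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)

    log2fc = mean_a - mean_b
    df = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
        t = log2fc / se

    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))

    # zero-variance degenerates: equal constants -> t = 0, p = 1; unequal
    # constants -> smallest representable positive p, with a warning
    degenerate = testable & (se == 0)
    equal = degenerate & (log2fc == 0)
    t[equal] = 0.0
    p[equal] = 1.0
    unequal = degenerate & (log2fc != 0)
    if unequal.any():
        warnings.warn(
            f"{int(unequal.sum())} protein(s) have zero within-group variance but "
            "unequal group means; p set to the machine minimum",
            stacklevel=2,
        )
        t[unequal] = np.sign(log2fc[unequal]) * np.inf
        p[unequal] = np.nextafter(0, 1)

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df.astype(float),
            "p": p,
            "q": np.nan,
            "n_a": n_a,
            "n_b": n_b,
            "testable": testable,
        },
        index=values.index,
    )
    result.loc[~testable, ["log2fc", "t", "df", "p"]] = np.nan
    result.loc[testable, "q"] = adjust_bh(result.loc[testable, "p"].to_numpy())
    return result
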