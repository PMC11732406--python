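"""SES decile stratification and stratified summaries of mobility change.

Scores are stratified into *local* decile bands, per city: within each city
the origins are ranked (average rank for ties) and the ranks cut at the
10%, 20%, ..., 90% empirical quantiles, so decile 1 holds the lowest-scoring
tenth.  Deciles therefore depend only on the score ordering, never on the
score scale.  Summaries offered: per-decile medians of lambda_mob, the joint
10x10 ER-by-EO median grid (with a companion counts grid), and letter-value
summaries (median, fourths, eighths, ... by the halved-depth recursion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError

_LETTER_LABELS = "MFEDCBAZYXWVUTS"


def assign_deciles(scores: pd.Series, city: pd.Series | None = None) -> pd.Series:
    """Local decile band (1-10) for one score column, per city.

    ``city`` groups origins into separately-stratified cities; a single city
    is assumed when omitted.  Requires >= 10 origins per city and a non-
    degenerate score distribution (not all values tied).
    """
    scores = scores.astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise InputError("scores must be finite")
    if city is None:
        city = pd.Series("city", index=scores.index)
    out = pd.Series(0, index=scores.index, dtype=int)
    for label, group in scores.groupby(city):
        n = len(group)
        if n < 10:
            raise InputError(f"city {label!r} has {n} origins; >= 10 required for deciles")
        if np.ptp(group.to_numpy()) == 0:
            raise InputError(f"city {label!r}: degenerate stratification (all scores equal)")
        ranks = rankdata(group.to_numpy(), method="average")
        dec = np.ceil(10.0 * ranks / n).astype(int)
        out.loc[group.index] = np.clip(dec, 1, 10)
    return out


def decile_assignment(seifa: pd.DataFrame) -> pd.DataFrame:
    """ER and EO decile bands for a SES table (er_score, eo_score, city)."""
    return pd.DataFrame(
        {
            "er_decile": assign_deciles(seifa["er_score"], seifa["city"]),
            "eo_decile": assign_deciles(seifa["eo_score"], seifa["city"]),
        },
        index=seifa.index,
    )


def decile_medians(lam: pd.Series, deciles: pd.Series) -> np.ndarray:
    """Median lambda_mob within each decile band, ordered decile 1 -> 10.

    ``lam`` may be defined for a subset of origins; every decile must retain
    at least one origin with defined lambda.
    """
    common = lam.index.intersection(deciles.index)
    lam = lam.loc[common]
    dec = deciles.loc[common]
    medians = np.full(10, np.nan)
    grouped = lam.groupby(dec).median()
    for d in range(1, 11):
        if d not in grouped.index or np.isnan(grouped.loc[d]):
            raise InputError(f"decile {d} has no origins with defined lambda_mob")
        medians[d - 1] = grouped.loc[d]
    return medians


def joint_median_grid(lam: pd.Series, er_deciles: pd.Series, eo_deciles: pd.Series):
    """10x10 grids of median lambda (NaN where empty) and of member counts.

    Rows are ER deciles, columns EO deciles.  Empty cells are legal and
    reported as missing, never interpolated.
    """
    common = lam.index.intersection(er_deciles.index).intersection(eo_deciles.index)
    df = pd.DataFrame(
        {
            "lam": lam.loc[common],
            "er": er_deciles.loc[common],
            "eo": eo_deciles.loc[common],
        }
    )
    idx = pd.Index(range(1, 11), name="er_decile")
    cols = pd.Index(range(1, 11), name="eo_decile")
    med = df.pivot_table(index="er", columns="eo", values="lam", aggfunc="median")
    cnt = df.pivot_table(index="er", columns="eo", values="lam", aggfunc="count")
    med = med.reindex(index=idx, columns=cols)
    cnt = cnt.reindex(index=idx, columns=cols).fillna(0).astype(int)
    med.index.name = cnt.index.name = "er_decile"
    med.columns.name = cnt.columns.name = "eo_decile"
    return med, cnt


def letter_values(values) -> pd.DataFrame:
    """Letter-value summary: median, fourths, eighths, ... by halved depths.

    Depth recursion: d1 = (1+n)/2 and d_{k+1} = (1 + floor(d_k))/2; the value
    at depth d averages the order statistics at floor(d) and ceil(d), counted
    from each end.  A new level is added only while the observations outside
    the current letter-value pair number at least 5 (both tails combined), so
    a sample of 8 stops at the fourths and a single value yields the median
    only.  Columns: label, depth, lower, upper (lower == upper for M).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise InputError("letter_values requires at least one observation")

    def at_depth(d: float):
        lo_i = int(np.floor(d)) - 1
        hi_i = int(np.ceil(d)) - 1
        lower = (x[lo_i] + x[hi_i]) / 2.0
        upper = (x[n - 1 - lo_i] + x[n - 1 - hi_i]) / 2.0
        return lower, upper

    rows = []
    d = (1 + n) / 2.0
    med_lo, _ = at_depth(d)
    rows.append(("M", d, med_lo, med_lo))
    level = 1
    while 2 * int(np.floor(d)) >= 5 and level < len(_LETTER_LABELS):
        d = (1 + np.floor(d)) / 2.0
        lower, upper = at_depth(d)
        rows.append((_LETTER_LABELS[level], d, lower, upper))
        level += 1
        if d <= 1:
            break
    return pd.DataFrame(rows, columns=["label", "depth", "lower", "upper"])
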