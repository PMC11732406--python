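"""The coverage-normalised log-ratio mobility-change statistic.

For each origin region the statistic is

    lambda_mob = ln(A / B),   A = V_test / C_test,   B = V_base / C_base,

where V is the mean daily outbound visit count summed over non-excluded
destination zones and C is the sample coverage (device-panel proxy) in the
same period.  Both numerator and denominator are mean-per-day quantities;
because lambda is a ratio of ratios over the same windows, per-day means and
period totals give identical values.  Natural log throughout.

Origins where the statistic is undefined — no coverage container, zero
coverage, or zero outflow in either period — are omitted with a reason code
rather than patched with pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .ingest import ExclusionSet

REASON_NO_COVERAGE = "no_coverage"
REASON_ZERO_COVERAGE = "zero_coverage"
REASON_ZERO_OUTFLOW_TEST = "zero_outflow_test"
REASON_ZERO_OUTFLOW_BASE = "zero_outflow_base"


@dataclass
class MobilityChange:
    """Per-origin lambda_mob with its components and the omission log.

    ``table``: indexed by origin_id with columns A, B, lambda_mob.
    ``exclusions``: origin_id, reason for every omitted origin.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lambda_mob(self) -> pd.Series:
        return self.table["lambda_mob"]


def aggregate_outflow(
    visits: pd.DataFrame,
    excluded: ExclusionSet,
    period: str,
    origins=None,
) -> pd.Series:
    """Total mean daily visits per origin over non-excluded destinations.

    ``origins`` optionally fixes the output index (missing origins map to 0);
    by default the origins appearing in the edge list for the period are used.
    """
    sub = visits[visits["period"] == period]
    if sub.empty:
        raise InputError(f"period {period!r} absent from the visit edge list")
    if len(excluded):
        pairs = pd.MultiIndex.from_frame(sub[["origin_id", "destination_id"]])
        drop = pairs.isin(excluded.pairs)
        sub = sub[~drop]
    out = sub.groupby("origin_id")["mean_daily_visits"].sum()
    universe = pd.Index(
        origins if origins is not None else visits.loc[visits["period"] == period, "origin_id"].unique(),
        name="origin_id",
    )
    return out.reindex(universe, fill_value=0.0).astype(float)


def compute_lambda(
    outflow_test: pd.Series,
    outflow_base: pd.Series,
    coverage: pd.DataFrame,
    period_test: str = "test",
    period_base: str = "baseline",
) -> MobilityChange:
    """lambda_mob = ln((V_test/C_test) / (V_base/C_base)) per origin.

    Both outflow series must come from the same exclusion set.  Origins with
    undefined coverage in either period, zero coverage, or zero outflow in
    either period are omitted and logged with a reason code.
    """
    origins = outflow_test.index.union(outflow_base.index)
    cov = coverage.pivot(index="origin_id", columns="period", values="coverage")
    for per in (period_test, period_base):
        if per not in cov.columns:
            cov[per] = np.nan
    cov = cov.reindex(origins)
    c_test = cov[period_test]
    c_base = cov[period_base]
    v_test = outflow_test.reindex(origins)
    v_base = outflow_base.reindex(origins)

    reasons = pd.Series(pd.NA, index=origins, dtype="object")
    # precedence: missing coverage, zero coverage, zero outflow (test then base)
    reasons[(v_base.isna()) | (v_base <= 0)] = REASON_ZERO_OUTFLOW_BASE
    reasons[(v_test.isna()) | (v_test <= 0)] = REASON_ZERO_OUTFLOW_TEST
    reasons[(c_test == 0) | (c_base == 0)] = REASON_ZERO_COVERAGE
    reasons[c_test.isna() | c_base.isna()] = REASON_NO_COVERAGE

    ok = reasons.isna().to_numpy()
    a = v_test[ok] / c_test[ok]
    b = v_base[ok] / c_base[ok]
    table = pd.DataFrame(
        {"A": a, "B": b, "lambda_mob": np.log(a) - np.log(b)}, index=origins[ok]
    )
    table.index.name = "origin_id"
    exclusions = (
        reasons[~ok]
        .rename("reason")
        .rename_axis("origin_id")
        .reset_index()
        .astype({"reason": str})
    )
    return MobilityChange(table=table, exclusions=exclusions)


def lambda_summary(change: MobilityChange, bin_width: float = 0.1):
    """Median, count and fixed-width histogram of lambda_mob.

    Bins are aligned to zero with the given width; returns
    ``(median, count, bin_edges, bin_counts)``.
    """
    lam = change.lambda_mob.to_numpy()
    if lam.size == 0:
        raise InputError("no origins with defined lambda_mob")
    if bin_width <= 0:
        raise InputError("bin_width must be > 0")
    lo = np.floor(lam.min() / bin_width) * bin_width
    hi = np.ceil(lam.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(lam, bins=edges)
    return float(np.median(lam)), int(lam.size), edges, counts
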