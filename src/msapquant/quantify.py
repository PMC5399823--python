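"""Relative quantitative methylation characteristics from code counts.

Given per-sample counts of the sixteen four-bit codes and the per-code
event weights, each event total is

    total(event) = sum over codes of  count(code) * weight(code, event)

and the per-sample denominator is the total number of elementary events
over all explanations of all scored codes,

    denominator = sum over codes of  4 * n_explanations(code) * count(code).

Each characteristic is the event total expressed as a percentage of the
denominator.  Because the denominator counts every explanation of every
code, samples differing only in marker yield remain directly comparable —
the characteristics are invariant under rescaling a sample's counts.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd

from .site_model import (
    ALL_CODES,
    EVENT_COLUMNS,
    WeightTable,
    build_weight_table,
)

__all__ = [
    "event_totals",
    "characteristics",
    "group_summary",
    "round_half_up",
    "CHARACTERISTIC_COLUMNS",
]

#: Report column order for characteristic tables.
CHARACTERISTIC_COLUMNS: tuple[str, ...] = (
    "NMSP%", "MSP%", "DM%", "DNM%", "M%", "NM%",
    "DM-CG%", "DM-CHG%", "DNM-CG%", "DNM-CHG%",
)

_EVENT_TO_PCT = {
    "NMSP%": "NMSP", "MSP%": "MSP", "DM%": "DM", "DNM%": "DNM",
    "M%": "M", "NM%": "NM", "DM-CG%": "DM-CG", "DM-CHG%": "DM-CHG",
    "DNM-CG%": "DNM-CG", "DNM-CHG%": "DNM-CHG",
}


def round_half_up(values, ndigits: int = 2):
    """Round half away from zero (the convention of printed report tables,
    as opposed to numpy's round-half-to-even)."""
    q = decimal.Decimal(1).scaleb(-ndigits)

    def _one(x: float) -> float:
        return float(decimal.Decimal(repr(float(x))).quantize(
            q, rounding=decimal.ROUND_HALF_UP))

    if isinstance(values, pd.DataFrame):
        return values.map(_one)
    if isinstance(values, pd.Series):
        return values.map(_one)
    if np.isscalar(values):
        return _one(values)
    return np.vectorize(_one)(np.asarray(values, dtype=float))


def event_totals(counts: pd.DataFrame, weights: WeightTable | None = None,
                 include_0000: bool = True) -> pd.DataFrame:
    """Per-sample event totals implied by code counts.

    Parameters
    ----------
    counts
        16 x n_samples (or fewer rows; missing codes count 0) integer
        DataFrame indexed by four-bit code.
    weights
        Event weight table; derived from the enzyme model when omitted.
    include_0000
        Whether markers absent from all four tracks contribute.  Such
        fragments are only identifiable with replicated stressed samples,
        so some designs exclude them.

    Returns
    -------
    DataFrame
        n_samples rows, columns ``DM, DNM, MSP, NMSP, M, NM, DNM-CHG,
        DNM-CG, DM-CHG, DM-CG, Total`` — ``Total`` being the per-sample
        event denominator.
    """
    if weights is None:
        weights = build_weight_table()
    counts = counts.reindex(list(ALL_CODES), fill_value=0)
    arr = counts.to_numpy()
    if np.isnan(arr.astype(float)).any():
        raise ValueError("code counts contain missing values")
    if (arr < 0).any():
        raise ValueError("code counts must be non-negative")
    if not include_0000:
        counts = counts.copy()
        counts.loc["0000"] = 0
    w = weights.to_frame()  # index code, columns n_explanations + events
    c = counts.to_numpy(dtype=np.int64)  # 16 x samples
    totals = pd.DataFrame(
        w[list(EVENT_COLUMNS)].to_numpy().T @ c,
        index=list(EVENT_COLUMNS), columns=counts.columns.copy(deep=True),
        dtype=np.int64,
    ).T
    totals["Total"] = (4 * w["n_explanations"].to_numpy() @ c)
    if (totals["Total"] == 0).any():
        empty = totals.index[totals["Total"] == 0].tolist()
        import logging
        logging.getLogger("msapquant").warning(
            "event_totals: samples with no scoreable markers: %s", empty)
    totals.index.name = "sample"
    return totals


def characteristics(totals: pd.DataFrame) -> pd.DataFrame:
    """Normalise event totals to percentages of the per-sample denominator.

    Values are kept at full precision; apply :func:`round_half_up` for
    report tables.  Raises ``ValueError`` when a sample has denominator 0.
    """
    if (totals["Total"] == 0).any():
        empty = totals.index[totals["Total"] == 0].tolist()
        raise ValueError(f"no scoreable markers for samples {empty}")
    den = totals["Total"].to_numpy(dtype=float)
    out = pd.DataFrame(index=totals.index, columns=list(CHARACTERISTIC_COLUMNS),
                       dtype=float)
    for pct_col, ev_col in _EVENT_TO_PCT.items():
        out[pct_col] = 100.0 * totals[ev_col].to_numpy(dtype=float) / den
    out.index.name = "sample"
    return out


def group_summary(table: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation of each characteristic per
    group, computed on unrounded values.

    Returns a DataFrame with a (group, statistic) column MultiIndex, where
    statistic is ``mean`` or ``sd``; ``sd`` is NaN for singleton groups
    (flagged with a warning).
    """
    grouping = grouping.reindex(table.index)
    if grouping.isna().any():
        missing = table.index[grouping.isna()].tolist()
        raise ValueError(f"samples without group assignment: {missing}")
    pieces = {}
    for group, sub in table.groupby(grouping, sort=True):
        mean = sub.mean()
        if len(sub) >= 2:
            sd = sub.std(ddof=1)
        else:
            import logging
            logging.getLogger("msapquant").warning(
                "group_summary: group %r has a single sample; SD undefined",
                group)
            sd = pd.Series(np.nan, index=table.columns)
        pieces[(group, "mean")] = mean
        pieces[(group, "sd")] = sd
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["group", "statistic"])
    return out
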