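"""Device-vs-reference agreement statistics.

Pooled Pearson correlation and Lin's concordance correlation coefficient
(CCC), Bland-Altman bias and 95 % limits of agreement on the
inter-device difference (device minus reference), and per-participant
MAE / MAPE / MdAPE with the conventional < 10 % acceptability bound on
the percentage errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ACCEPTABLE_MDAPE_PCT = 10.0
LOA_Z = 1.96


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments):

        2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    Measures deviation of the relationship from the identity line, so a
    pure location shift lowers CCC while leaving Pearson r at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return float("nan")
    vx = np.var(x)
    vy = np.var(y)
    dm = np.mean(x) - np.mean(y)
    denom = vx + vy + dm * dm
    if denom == 0:
        return float("nan")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / denom)


def bland_altman(device, reference) -> tuple[float, float, float]:
    """Bias and 95 % limits of agreement of d = device - reference.

    bias = mean(d); limits = bias +/- 1.96 * SD(d) with the sample
    (n - 1) standard deviation.
    """
    d = np.asarray(device, dtype=float) - np.asarray(reference, dtype=float)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, bias - LOA_Z * sd, bias + LOA_Z * sd


def error_metrics(device, reference) -> tuple[float, float, float, int]:
    """MAE, MAPE (%), MdAPE (%) of device against reference.

    MAE uses all pairs. Pairs with a zero reference value are excluded
    from the percentage errors; the count of exclusions is returned.
    MdAPE is the median of the absolute percentage errors.
    """
    device = np.asarray(device, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ad = np.abs(device - reference)
    mae = float(np.mean(ad))
    nonzero = reference != 0
    n_excluded = int((~nonzero).sum())
    if nonzero.any():
        ape = 100.0 * ad[nonzero] / np.abs(reference[nonzero])
        mape = float(np.mean(ape))
        mdape = float(np.median(ape))
    else:
        mape = mdape = float("nan")
    return mae, mape, mdape, n_excluded


@dataclass
class AgreementSummary:
    group: str
    level: str
    metric: str
    threshold: float
    n_pairs: int
    r: float
    ccc: float
    bias: float
    loa_low: float
    loa_high: float
    mae: float
    mape: float
    mdape: float

    @property
    def acceptable(self) -> bool:
        return self.mdape < ACCEPTABLE_MDAPE_PCT


PAIRED_COLUMNS = [
    "participant_id",
    "group",
    "level",
    "metric",
    "threshold",
    "window_idx",
    "device_value",
    "reference_value",
]


def summarize_cell(
    paired: pd.DataFrame, group: str, level: str, metric: str, threshold: float
) -> AgreementSummary:
    """Pooled agreement over all pairs in one group/level/metric/threshold
    cell (pooled over windows and participants, as in a pooled scatter)."""
    x = paired["device_value"].to_numpy(dtype=float)
    y = paired["reference_value"].to_numpy(dtype=float)
    bias, lo, hi = bland_altman(x, y) if x.size else (float("nan"),) * 3
    mae, mape, mdape, _ = (
        error_metrics(x, y) if x.size else (float("nan"),) * 3 + (0,)
    )
    return AgreementSummary(
        group=group,
        level=level,
        metric=metric,
        threshold=threshold,
        n_pairs=int(x.size),
        r=pearson_r(x, y),
        ccc=ccc(x, y),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        mae=mae,
        mape=mape,
        mdape=mdape,
    )


def summarize(paired: pd.DataFrame) -> pd.DataFrame:
    """Agreement summary per group x level x metric x threshold, plus
    pooled rows over both groups (group = "all")."""
    frames = [paired, paired.assign(group="all")]
    rows = []
    for df in frames:
        for (group, level, metric, thr), cell in df.groupby(
            ["group", "level", "metric", "threshold"], sort=True
        ):
            s = summarize_cell(cell, group, level, metric, thr)
            rows.append({**s.__dict__, "acceptable": s.acceptable})
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "level", "metric", "threshold"]).reset_index(
        drop=True
    )


def participant_errors(paired: pd.DataFrame) -> pd.DataFrame:
    """Per-participant MAE/MAPE/MdAPE per level x metric x threshold."""
    rows = []
    keys = ["participant_id", "group", "level", "metric", "threshold"]
    for key_vals, cell in paired.groupby(keys, sort=True):
        mae, mape, mdape, n_excl = error_metrics(
            cell["device_value"].to_numpy(), cell["reference_value"].to_numpy()
        )
        rows.append(
            dict(
                zip(keys, key_vals),
                n_pairs=len(cell),
                mae=mae,
                mape=mape,
                mdape=mdape,
                n_zero_reference_excluded=n_excl,
            )
        )
    return pd.DataFrame(rows)


def mdape_heatmap(
    errors: pd.DataFrame, level: str = "5min", metric: str | None = None
) -> pd.DataFrame:
    """Participant x threshold MdAPE matrix at one level, rows sorted in
    descending order of each participant's mean MdAPE across thresholds
    (and across metrics unless one metric is selected)."""
    df = errors[errors["level"] == level]
    if metric is not None:
        df = df[df["metric"] == metric]
    table = df.pivot_table(
        index=["group", "participant_id"],
        columns=["metric", "threshold"],
        values="mdape",
    )
    order = table.mean(axis=1).sort_values(ascending=False).index
    return table.loc[order]
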