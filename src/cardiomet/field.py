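"""In-roost field analysis: stream synchronization, torpor flags, regressions.

Heart-rate, body-temperature and ambient-temperature streams arrive at
different cadences (continuous-to-10-min f_H, 1-to-10-min T_b, 15-min T_a).
Each body-temperature observation is paired with the trailing 60-s mean
heart rate and the nearest ambient reading; records are then summarized by
hour of day, classified into low-energy (torpor-like) states by the pooled
10% heart-rate quantile, and fed to the same random-intercept machinery
used for the laboratory calibration (no second fitting path).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration
from .detection import HeartRateSeries

__all__ = [
    "sync_streams",
    "classify_low_state",
    "hourly_summary",
    "scotophase_annotation",
    "field_regressions",
    "predict_field_expenditure",
    "LOW_STATE_QUANTILE",
]

LOW_STATE_QUANTILE = 0.10  # lowest 10% of observed heart rates (~<90 bpm)

DEFAULT_DUSK = "18:15"  # approximate local dusk/dawn, Gamboa, Panama
DEFAULT_DAWN = "06:15"


def _as_seconds(ts: pd.Series) -> np.ndarray:
    return ts.astype("int64").to_numpy() / 1e9


def scotophase_annotation(
    timestamps, dusk: str = DEFAULT_DUSK, dawn: str = DEFAULT_DAWN
) -> np.ndarray:
    """True during the dark phase (dusk→dawn wrap-around interval).

    Closed at dusk, open at dawn: the dusk instant itself is scotophase.
    """
    if dusk == dawn:
        raise ValueError("dusk and dawn must differ")
    idx = pd.DatetimeIndex(timestamps)
    minutes = idx.hour * 60 + idx.minute + idx.second / 60.0
    h1, m1 = map(int, dusk.split(":"))
    h2, m2 = map(int, dawn.split(":"))
    d, a = h1 * 60 + m1, h2 * 60 + m2
    if d > a:  # usual wrap-around night
        return np.asarray((minutes >= d) | (minutes < a))
    return np.asarray((minutes >= d) & (minutes < a))


def sync_streams(
    hr: pd.DataFrame,
    tb: pd.DataFrame,
    ta: pd.DataFrame,
    smooth_window_s: float = 60.0,
    ta_rule: str = "nearest",
    dusk: str = DEFAULT_DUSK,
    dawn: str = DEFAULT_DAWN,
) -> pd.DataFrame:
    """One record per body-temperature observation.

    ``hr``: columns timestamp, individual, bpm.  ``tb``: timestamp,
    individual, t_b.  ``ta``: timestamp, t_a (one shared station).  Heart
    rate is the trailing mean over ``smooth_window_s`` before each T_b
    timestamp; ambient temperature is matched by ``ta_rule`` ("nearest"
    15-min reading or "interpolate").  Observations with no heart-rate data
    in the window keep a missing f_H rather than being dropped.  Records
    where the body reads below ambient are retained and flagged.
    """
    for df, cols in ((hr, {"timestamp", "individual", "bpm"}),
                     (tb, {"timestamp", "individual", "t_b"}),
                     (ta, {"timestamp", "t_a"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {missing}")
    t_lo = max(hr["timestamp"].min(), tb["timestamp"].min())
    t_hi = min(hr["timestamp"].max(), tb["timestamp"].max())
    if t_lo > t_hi:
        raise ValueError("zero temporal overlap between heart-rate and T_b streams")

    ta_sorted = ta.sort_values("timestamp")
    ta_t = _as_seconds(ta_sorted["timestamp"])
    ta_v = ta_sorted["t_a"].to_numpy(dtype=float)

    out = []
    for ind, tb_grp in tb.groupby("individual"):
        tb_grp = tb_grp.sort_values("timestamp")
        hr_grp = hr[hr["individual"] == ind].sort_values("timestamp")
        tb_s = _as_seconds(tb_grp["timestamp"])
        if len(hr_grp):
            series = HeartRateSeries(
                _as_seconds(hr_grp["timestamp"]), hr_grp["bpm"].to_numpy(dtype=float)
            )
            from .detection import smooth_rate

            fh = smooth_rate(series, window=smooth_window_s, at=tb_s).bpm
        else:
            fh = np.full(tb_s.size, np.nan)
        if ta_rule == "interpolate":
            t_a = np.interp(tb_s, ta_t, ta_v)
        elif ta_rule == "nearest":
            pos = np.clip(np.searchsorted(ta_t, tb_s), 1, ta_t.size - 1)
            left_closer = (tb_s - ta_t[pos - 1]) <= (ta_t[pos] - tb_s)
            t_a = ta_v[np.where(left_closer, pos - 1, pos)]
        else:
            raise ValueError(f"unknown ta_rule {ta_rule!r}")
        grp = pd.DataFrame(
            {
                "timestamp": tb_grp["timestamp"].to_numpy(),
                "individual": ind,
                "f_h": fh,
                "t_b": tb_grp["t_b"].to_numpy(dtype=float),
                "t_a": t_a,
            }
        )
        out.append(grp)
    rec = pd.concat(out, ignore_index=True).sort_values(["individual", "timestamp"])
    rec["t_diff"] = rec["t_b"] - rec["t_a"]
    rec["below_ambient"] = rec["t_b"] < rec["t_a"]
    rec["scotophase"] = scotophase_annotation(rec["timestamp"], dusk, dawn)
    return rec.reset_index(drop=True)


def classify_low_state(
    records: pd.DataFrame,
    quantile: float = LOW_STATE_QUANTILE,
    per_individual: bool = False,
):
    """Flag low-energy-state records by the heart-rate quantile threshold.

    The threshold is the pooled (default) or per-individual ``quantile`` of
    observed f_H; records at or below it are flagged.  Returns the flagged
    records frame (new ``low_state`` column), the threshold(s), and the
    sorted hours of day containing at least one flagged record.
    """
    fh = records["f_h"].dropna()
    if len(fh) < 10:
        raise ValueError("need at least 10 heart-rate records")
    rec = records.copy()
    if per_individual:
        thr = records.groupby("individual")["f_h"].quantile(quantile)
        rec["low_state"] = rec["f_h"] <= rec["individual"].map(thr)
        threshold = thr
    else:
        threshold = float(np.quantile(fh, quantile))
        rec["low_state"] = rec["f_h"] <= threshold
    rec.loc[rec["f_h"].isna(), "low_state"] = False
    hours = sorted(pd.DatetimeIndex(rec.loc[rec["low_state"], "timestamp"]).hour.unique())
    return rec, threshold, hours


def hourly_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, s.d. and n of f_H and T_b per hour of day (0–23).

    Hours with no records are reported as empty (NaN means, n = 0), never
    as zero.  When a ``low_state`` column is present the flagged fraction
    per hour is included.
    """
    if records.empty:
        raise ValueError("no records")
    rec = records.copy()
    rec["hour"] = pd.DatetimeIndex(rec["timestamp"]).hour
    rows = []
    for h in range(24):
        grp = rec[rec["hour"] == h]
        row = {"hour": h}
        for col in ("f_h", "t_b"):
            vals = grp[col].dropna() if col in grp else pd.Series(dtype=float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{col}_n"] = int(len(vals))
        if "low_state" in rec.columns:
            sub = grp.dropna(subset=["f_h"])
            row["low_fraction"] = sub["low_state"].mean() if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("hour")


def field_regressions(records: pd.DataFrame) -> pd.DataFrame:
    """The three in-roost random-intercept regressions.

    t_b ~ t_a, f_h ~ t_b and f_h ~ t_diff, each on its own listwise-complete
    rows (so n differs per model, as with mixed field cadences), fit through
    the calibration module.  Reports slope, χ² and p against the
    intercept-only model, R²m/R²c and n.
    """
    specs = [("t_b", "t_a"), ("f_h", "t_b"), ("f_h", "t_diff")]
    rows = []
    for response, predictor in specs:
        sub = records.dropna(subset=[response, predictor])
        fit = calibration.fit_random_intercept(sub, (predictor,), response=response)
        null = calibration.fit_random_intercept(sub, (), response=response)
        chi2, df, p = calibration.lr_test(null, fit)
        rows.append(
            {
                "model": f"{response} ~ {predictor}",
                "slope": fit.beta[predictor],
                "intercept": fit.beta["intercept"],
                "chi2": chi2,
                "df": df,
                "p": p,
                "r2m": fit.r2m,
                "r2c": fit.r2c,
                "n": fit.n_obs,
                "aicc": fit.aicc,
            }
        )
    return pd.DataFrame(rows)


def predict_field_expenditure(
    records: pd.DataFrame,
    fit=None,
    unit: str | None = "kJ/day",
    max_gap_factor: float = 3.0,
    unreliable_gap: float = 0.5,
):
    """Per-record energy expenditure and daily totals from field heart rate.

    Each record's rate comes from the calibration prediction (population
    level).  Daily totals integrate rate over the observed coverage only:
    each record covers its cadence interval (gaps longer than
    ``max_gap_factor`` x the median cadence are not imputed), and a day
    whose gap fraction exceeds ``unreliable_gap`` is flagged unreliable.
    """
    rec = records.dropna(subset=["f_h"]).copy()
    rec["expenditure_rate"] = calibration.predict_expenditure(
        rec["f_h"].to_numpy(), fit, unit=unit
    )
    totals = []
    for (ind, date), grp in rec.groupby(
        ["individual", pd.DatetimeIndex(rec["timestamp"]).date]
    ):
        t = _as_seconds(grp.sort_values("timestamp")["timestamp"])
        if t.size < 2:
            coverage_s = 0.0
        else:
            dt = np.diff(t)
            cadence = np.median(dt)
            coverage_s = float(np.sum(np.minimum(dt, max_gap_factor * cadence))) + cadence
        gap_fraction = 1.0 - min(coverage_s / 86400.0, 1.0)
        # rate x covered time in the rate's own unit = energy over the span
        per_unit_s = 3600.0 if unit == "kJ/h" else 86400.0
        total = float(grp["expenditure_rate"].mean() * coverage_s / per_unit_s)
        totals.append(
            {
                "individual": ind,
                "date": date,
                "total_kj": total,
                "coverage_h": coverage_s / 3600.0,
                "gap_fraction": gap_fraction,
                "unreliable": gap_fraction > unreliable_gap,
            }
        )
    return rec, pd.DataFrame(totals)
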