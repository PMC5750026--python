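"""Open-flow respirometry: gas fractions to metabolic rates.

Carbon-dioxide production drives the energy estimate.  The implementation
carries two forms of the flow equation:

* ``"printed"`` (default): V̇CO2 = (FeCO2 − FiCO2)·FR / (1 − FeCO2·(1 − (1 − RER))),
  i.e. denominator 1 − FeCO2·RER, exactly as published;
* ``"textbook"``: the standard Lighton flow-through form with denominator
  1 − FeCO2·(1 − 1/RER).

At bat-scale excurrent concentrations the two differ by FeCO2·(RER + 1/RER
− 1) relatively — about 0.1% at typical FeCO2 and 0.5% at the 0.005
extreme; both are retained because the published denominator may
contain a transcription slip and neither reading can be confirmed from the
text.  Energy conversion uses 25.0 J per ml CO2.

Oxygen consumption follows the CO2-scrubbed configuration (CO2 absorbed
before the O2 analyzer): V̇O2 = FR·(FiO2 − FeO2)/(1 − FiO2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detection import HeartRateSeries, smooth_rate

logger = logging.getLogger(__name__)

__all__ = [
    "RespirometryTrace",
    "AlignedRecords",
    "baseline_correct",
    "compute_vco2",
    "compute_vo2",
    "compute_rer",
    "vco2_to_power",
    "metabolic_series",
    "align_measures",
    "minimum_states",
    "steady_state_mask",
    "percent_of_bmr",
    "JOULES_PER_ML_CO2",
    "DEFAULT_MASS_G",
    "PUBLISHED_BMR_W_G",
]

JOULES_PER_ML_CO2 = 25.0
DEFAULT_MASS_G = 10.5  # study-animal mean body mass, g
PUBLISHED_BMR_W_G = 0.008044  # previously measured basal rate, W g^-1


@dataclass
class RespirometryTrace:
    """1-Hz gas-analyzer trace.

    Fractions are dimensionless concentrations in [0, 1]; ``fr`` is the
    STP-corrected flow in ml min^-1; ``baseline_mask`` marks samples during
    which the analyzers read the empty reference chamber.
    """

    time: np.ndarray  # s, strictly increasing
    feco2: np.ndarray
    fico2: np.ndarray
    feo2: np.ndarray
    fio2: np.ndarray
    fr: np.ndarray
    chamber_temp: np.ndarray
    rh: np.ndarray
    baseline_mask: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("feco2", "fico2", "feo2", "fio2", "fr", "chamber_temp", "rh"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.baseline_mask = np.asarray(self.baseline_mask, dtype=bool)
        if np.any(self.fr <= 0):
            raise ValueError("flow rate must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "feco2": self.feco2,
                "fico2": self.fico2,
                "feo2": self.feo2,
                "fio2": self.fio2,
                "flow_ml_min": self.fr,
                "chamber_temp_c": self.chamber_temp,
                "rh_pct": self.rh,
                "baseline": self.baseline_mask.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column_map: dict | None = None) -> "RespirometryTrace":
        cm = {
            "time_s": "time_s", "feco2": "feco2", "fico2": "fico2",
            "feo2": "feo2", "fio2": "fio2", "flow_ml_min": "flow_ml_min",
            "chamber_temp_c": "chamber_temp_c", "rh_pct": "rh_pct",
            "baseline": "baseline",
        }
        cm.update(column_map or {})
        return cls(
            time=df[cm["time_s"]].to_numpy(),
            feco2=df[cm["feco2"]].to_numpy(),
            fico2=df[cm["fico2"]].to_numpy(),
            feo2=df[cm["feo2"]].to_numpy(),
            fio2=df[cm["fio2"]].to_numpy(),
            fr=df[cm["flow_ml_min"]].to_numpy(),
            chamber_temp=df[cm["chamber_temp_c"]].to_numpy(),
            rh=df[cm["rh_pct"]].to_numpy(),
            baseline_mask=df[cm["baseline"]].to_numpy().astype(bool),
        )


def _contiguous_periods(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def baseline_correct(
    trace: RespirometryTrace,
    fixed_incurrent: tuple | None = None,
) -> RespirometryTrace:
    """Replace nominal incurrent fractions by baseline-derived estimates.

    The mean excurrent reading within each reference (baseline) period
    estimates the incurrent fraction at that period's midpoint; incurrent
    fractions over animal periods are interpolated linearly between those
    means, removing linear analyzer drift.  With a single baseline period a
    constant baseline is assumed (logged).  With none, ``fixed_incurrent``
    = (FiCO2, FiO2) must be supplied.
    """
    periods = _contiguous_periods(trace.baseline_mask)
    if not periods:
        if fixed_incurrent is None:
            raise ValueError(
                "no baseline periods: supply fixed_incurrent=(fico2, fio2)"
            )
        fico2 = np.full(trace.time.size, fixed_incurrent[0])
        fio2 = np.full(trace.time.size, fixed_incurrent[1])
    else:
        centers = np.array([(trace.time[a] + trace.time[b - 1]) / 2 for a, b in periods])
        co2_means = np.array([trace.feco2[a:b].mean() for a, b in periods])
        o2_means = np.array([trace.feo2[a:b].mean() for a, b in periods])
        if len(periods) == 1:
            logger.info("single baseline period: assuming zero drift")
            fico2 = np.full(trace.time.size, co2_means[0])
            fio2 = np.full(trace.time.size, o2_means[0])
        else:
            fico2 = np.interp(trace.time, centers, co2_means)
            fio2 = np.interp(trace.time, centers, o2_means)
    return replace(trace, fico2=fico2, fio2=fio2)


def compute_vco2(feco2, fico2, fr, rer: float = 0.8, formula_variant: str = "printed"):
    """CO2 production in ml min^-1 from excurrent/incurrent fractions.

    ``formula_variant="printed"`` uses denominator 1 − FeCO2·RER (the
    published equation verbatim); ``"textbook"`` uses the standard
    1 − FeCO2·(1 − 1/RER).
    """
    if not 0.7 < rer <= 1.0:
        raise ValueError("rer must be in (0.7, 1.0]")
    feco2 = np.asarray(feco2, dtype=float)
    fico2 = np.asarray(fico2, dtype=float)
    fr = np.asarray(fr, dtype=float)
    if formula_variant == "printed":
        denom = 1.0 - feco2 * (1.0 - (1.0 - rer))
    elif formula_variant == "textbook":
        denom = 1.0 - feco2 * (1.0 - 1.0 / rer)
    else:
        raise ValueError(f"unknown formula_variant {formula_variant!r}")
    if np.any(denom <= 0):
        raise ValueError("non-positive denominator in gas-exchange equation")
    logger.debug("compute_vco2 variant=%s rer=%s", formula_variant, rer)
    return (feco2 - fico2) * fr / denom


def compute_vo2(feo2, fio2, fr):
    """O2 consumption (ml min^-1), CO2-scrubbed configuration."""
    feo2 = np.asarray(feo2, dtype=float)
    fio2 = np.asarray(fio2, dtype=float)
    if np.any(fio2 >= 1):
        raise ValueError("FiO2 must be < 1")
    return np.asarray(fr, dtype=float) * (fio2 - feo2) / (1.0 - fio2)


def compute_rer(vco2, vo2, method: str = "mean-of-ratios", mask=None) -> float:
    """Respiratory exchange ratio V̇CO2:V̇O2 over valid (steady-state) samples."""
    vco2 = np.asarray(vco2, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if mask is not None:
        vco2, vo2 = vco2[mask], vo2[mask]
    ok = vo2 > 0
    if not np.any(ok):
        raise ValueError("no samples with positive V̇O2")
    if method == "mean-of-ratios":
        return float(np.mean(vco2[ok] / vo2[ok]))
    if method == "ratio-of-means":
        return float(np.mean(vco2[ok]) / np.mean(vo2[ok]))
    raise ValueError(f"unknown method {method!r}")


def vco2_to_power(vco2, mass_g: float | None = None):
    """Convert CO2 production to energy: (kJ h^-1, W g^-1).

    kJ h^-1 = V̇CO2 · 25.0 · 60 / 1000; W g^-1 = kJ h^-1 / 3.6 / mass.
    When no mass is given the mass-specific rate is NaN.
    """
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vco2 < -1e-12):
        raise ValueError("vco2 must be non-negative")
    kj_h = vco2 * JOULES_PER_ML_CO2 * 60.0 / 1000.0
    if mass_g is None:
        w_g = np.full_like(kj_h, np.nan)
    else:
        if mass_g <= 0:
            raise ValueError("mass must be positive")
        w_g = kj_h / 3.6 / mass_g
    return kj_h, w_g


def metabolic_series(
    trace: RespirometryTrace,
    rer: float = 0.8,
    mass_g: float | None = DEFAULT_MASS_G,
    formula_variant: str = "printed",
    sample_period_s: float = 300.0,
) -> pd.DataFrame:
    """Per-sample metabolic rates from a baseline-corrected trace.

    The 1-Hz trace is averaged into ``sample_period_s`` respirometry samples
    (5 min by default); baseline samples are excluded.  Columns: time (s,
    period end), vco2, vo2 (ml min^-1), mr_kj_h, mr_w_g.
    """
    vco2 = compute_vco2(trace.feco2, trace.fico2, trace.fr, rer, formula_variant)
    vo2 = compute_vo2(trace.feo2, trace.fio2, trace.fr)
    df = pd.DataFrame(
        {"time": trace.time, "vco2": vco2, "vo2": vo2, "animal": ~trace.baseline_mask}
    )
    df = df[df["animal"]]
    bins = np.floor(df["time"] / sample_period_s).astype(int)
    agg = df.groupby(bins).agg(vco2=("vco2", "mean"), vo2=("vo2", "mean"), n=("vco2", "size"))
    agg["time"] = (agg.index + 1) * sample_period_s
    kj_h, w_g = vco2_to_power(np.clip(agg["vco2"], 0, None), mass_g)
    agg["mr_kj_h"] = kj_h
    agg["mr_w_g"] = w_g
    return agg.reset_index(drop=True)[["time", "vco2", "vo2", "n", "mr_kj_h", "mr_w_g"]]


@dataclass
class AlignedRecords:
    """Two granularities of the aligned physiology table.

    ``per_tb``: one row per body-temperature timestamp with the trailing
    60-s mean heart rate.  ``per_sample``: one row per gas sample with the
    means of its constituent (T_b, f_H) pairs (five per 5-min sample at
    1-min T_b cadence) plus the sample's metabolic rate.
    """

    per_tb: pd.DataFrame
    per_sample: pd.DataFrame


def align_measures(
    tb_series: pd.DataFrame,
    hr_series: HeartRateSeries,
    met: pd.DataFrame,
    t_a: float | np.ndarray | None = None,
    individual: str = "bat00",
    fh_window_s: float = 60.0,
    sample_period_s: float = 300.0,
) -> AlignedRecords:
    """Pair 1-min body temperature, smoothed heart rate and gas samples.

    ``tb_series`` needs columns ``time`` (s) and ``t_b``; ``met`` is the
    output of :func:`metabolic_series`.  Heart rate at each T_b timestamp is
    the mean over the preceding ``fh_window_s``.  Each gas sample covering
    ``(t − period, t]`` receives the mean of the T_b/f_H pairs inside it,
    with the actual pair count reported (not forced to five).
    """
    tb_t = tb_series["time"].to_numpy(dtype=float)
    if tb_t.size == 0 or met.shape[0] == 0:
        raise ValueError("empty input series")
    if tb_t.max() < met["time"].min() - sample_period_s or tb_t.min() > met["time"].max():
        raise ValueError("no temporal overlap between T_b and gas samples")
    fh = smooth_rate(hr_series, window=fh_window_s, at=tb_t)
    ta_arr = np.full(tb_t.size, np.nan) if t_a is None else np.broadcast_to(
        np.asarray(t_a, dtype=float), tb_t.shape
    ).copy()
    per_tb = pd.DataFrame(
        {
            "time": tb_t,
            "individual": individual,
            "f_h": fh.bpm,
            "t_b": tb_series["t_b"].to_numpy(dtype=float),
            "t_a": ta_arr,
        }
    )
    per_tb["t_diff"] = per_tb["t_b"] - per_tb["t_a"]

    rows = []
    for _, s in met.iterrows():
        t1 = s["time"]
        t0 = t1 - sample_period_s
        sel = per_tb[(per_tb["time"] > t0) & (per_tb["time"] <= t1)]
        rows.append(
            {
                "time": t1,
                "individual": individual,
                "n_pairs": len(sel),
                "f_h": sel["f_h"].mean(),
                "t_b": sel["t_b"].mean(),
                "t_a": sel["t_a"].mean(),
                "mr_kj_h": s["mr_kj_h"],
                "mr_w_g": s["mr_w_g"],
            }
        )
    per_sample = pd.DataFrame(rows)
    per_sample["t_diff"] = per_sample["t_b"] - per_sample["t_a"]
    counts = per_sample["n_pairs"].value_counts()
    if len(counts) > 1:
        logger.info("variable T_b pairs per gas sample: %s", dict(counts))
    return AlignedRecords(per_tb, per_sample)


def minimum_states(
    aligned: pd.DataFrame,
    quantile: float = 0.10,
    mr_col: str = "mr_kj_h",
    extra_quantile: float = 0.30,
    min_records: int = 10,
):
    """Per-individual minimum metabolic states.

    Selects, for each individual, the records whose metabolic rate lies at
    or below that individual's ``quantile`` (linear-interpolation, "type 7")
    quantile, and summarizes their mean MR, f_H and T_b.  Also reports the
    mean over the ``extra_quantile`` (30%) subset used for comparison with
    published basal rates.  Individuals with fewer than ``min_records``
    records are skipped with a warning.
    """
    summaries, selected = [], []
    for ind, grp in aligned.groupby("individual", sort=True):
        grp = grp.dropna(subset=[mr_col])
        if len(grp) < min_records:
            warnings.warn(f"individual {ind}: only {len(grp)} records, skipped", stacklevel=2)
            continue
        mr = grp[mr_col].to_numpy()
        thr = np.quantile(mr, quantile)  # numpy default = linear (type 7)
        thr30 = np.quantile(mr, extra_quantile)
        low = grp[grp[mr_col] <= thr]
        low30 = grp[grp[mr_col] <= thr30]
        summaries.append(
            {
                "individual": ind,
                "n": len(grp),
                "n_low": len(low),
                "threshold": thr,
                "mean_mr": low[mr_col].mean(),
                "mean_f_h": low["f_h"].mean() if "f_h" in low else np.nan,
                "mean_t_b": low["t_b"].mean() if "t_b" in low else np.nan,
                f"mean_mr_q{int(extra_quantile * 100)}": low30[mr_col].mean(),
            }
        )
        selected.append(low)
    if not summaries:
        raise ValueError("no individual has enough records")
    sel = pd.concat(selected).sort_values(["individual", "time"] if "time" in aligned else ["individual"])
    return pd.DataFrame(summaries), sel.reset_index(drop=True)


def steady_state_mask(
    met: pd.DataFrame,
    window: int = 4,
    cv_threshold: float = 0.10,
    mr_col: str = "mr_kj_h",
) -> np.ndarray:
    """Mark samples whose rolling coefficient of variation is below threshold.

    Defaults: 4 consecutive 5-min samples (20 min) with CV < 10%.
    """
    if window < 3:
        raise ValueError("window must cover at least 3 samples")
    s = met[mr_col]
    # partial windows (>= 2 samples) at the series edges still get a CV, so a
    # fully steady record is marked throughout
    roll = s.rolling(window, center=True, min_periods=2)
    cv = roll.std(ddof=1) / roll.mean().abs()
    return (cv < cv_threshold).fillna(False).to_numpy()


def percent_of_bmr(mr_w_g: float, bmr_w_g: float = PUBLISHED_BMR_W_G) -> float:
    """Mass-specific metabolic rate as a percentage of a basal reference."""
    if bmr_w_g <= 0:
        raise ValueError("reference BMR must be positive")
    return 100.0 * mr_w_g / bmr_w_g
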