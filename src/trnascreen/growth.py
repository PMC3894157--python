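"""Growth-parameter extraction from OD600 time series.

Two fitness parameters per well: the maximal specific growth rate (the
steepest sustained slope of log OD during exponential phase) and the
growth yield (population density on entry into stationary phase). Each
strain is then normalized to the mean of the wild-type wells on its own
plate, which cancels plate- and day-level effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .simulate import BLANK, WT

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "GrowthConfig",
    "read_plate_table",
    "preprocess_curve",
    "extract_growth_params",
    "normalize_to_wildtype",
    "fit_plate",
    "fit_library",
]


@dataclass
class GrowthCurve:
    """One well's OD trajectory (blank-subtracted after preprocessing)."""

    well: str
    times: np.ndarray
    od: np.ndarray
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if len(self.times) < 8:
            raise ValueError("curve needs at least 8 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"non-monotone time axis in well {self.well}")


@dataclass
class GrowthParams:
    """Extracted per-well parameters.

    ``rate`` in 1/h, ``yield_`` in OD units; both 0 with ``lethal`` set
    when the culture never clears the lethality threshold.
    """

    rate: float
    yield_: float
    rate_window: tuple[float, float] | None = None
    lethal: bool = False
    truncated: bool = False


@dataclass(frozen=True)
class GrowthConfig:
    """Extraction settings.

    rate_window: points per sliding log-linear fit for the rate.
    detection_floor: OD below which points are ignored for the rate fit.
    eps_floor: additive floor inside the log to avoid log(0).
    plateau_frac: derivative threshold (fraction of max) defining
        stationary phase; plateau_persistence: minimum suffix length.
    lethal_threshold: max OD below this (blank-subtracted) = no growth.
    smooth_window: running-median width for preprocessing (odd).
    """

    rate_window: int = 5
    detection_floor: float = 0.01
    eps_floor: float = 1e-4
    plateau_frac: float = 0.05
    plateau_persistence: int = 3
    lethal_threshold: float = 0.05
    smooth_window: int = 3


def read_plate_table(
    path, plate_map_path
) -> tuple[dict[tuple[str, int, str], GrowthCurve], float]:
    """Read a long-format plate CSV plus its plate map.

    Returns curves keyed by ``(strain, bio_rep, well)`` and the blank OD
    estimate (mean over all readings of BLANK wells; falls back to the
    per-plate minimum of each well's first three readings when no blanks
    are present). Wells listed in the map but absent from the reads are
    flagged missing rather than fabricated.
    """
    reads = pd.read_csv(path)
    plate_map = pd.read_csv(plate_map_path)
    for col in ("time_h", "well", "od"):
        if col not in reads.columns:
            raise ValueError(f"plate table missing required column {col!r}")
    for col in ("well", "strain", "bio_rep"):
        if col not in plate_map.columns:
            raise ValueError(f"plate map missing required column {col!r}")
    return curves_from_frames(reads, plate_map)


def curves_from_frames(
    reads: pd.DataFrame, plate_map: pd.DataFrame
) -> tuple[dict[tuple[str, int, str], GrowthCurve], float]:
    """Group a long-format reads table into per-well curves (see
    :func:`read_plate_table`)."""
    mapped = dict(zip(plate_map["well"], plate_map["strain"]))
    bio_of = dict(zip(plate_map["well"], plate_map["bio_rep"]))
    unmapped = set(reads["well"]) - set(mapped)
    if unmapped:
        raise ValueError(f"wells absent from plate map: {sorted(unmapped)}")
    if reads.duplicated(subset=["well", "time_h"]).any():
        dup = reads[reads.duplicated(subset=["well", "time_h"])]["well"].iloc[0]
        raise ValueError(f"duplicate (well, time) readings in well {dup}")

    curves: dict[tuple[str, int, str], GrowthCurve] = {}
    blank_readings = []
    for well, grp in reads.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        strain = mapped[well]
        if strain == BLANK:
            blank_readings.append(grp["od"].to_numpy())
            continue
        curve = GrowthCurve(
            well=well, times=grp["time_h"].to_numpy(), od=grp["od"].to_numpy()
        )
        curves[(strain, int(bio_of[well]), well)] = curve
    for well in set(mapped) - set(reads["well"]):
        if mapped[well] == BLANK:
            continue
        # listed but never read: placeholder flagged missing
        curves[(mapped[well], int(bio_of[well]), well)] = GrowthCurve(
            well=well,
            times=np.arange(8, dtype=float),
            od=np.zeros(8),
            flags={"missing"},
        )

    if blank_readings:
        blank = float(np.mean(np.concatenate(blank_readings)))
    else:
        firsts = [c.od[:3].min() for c in curves.values() if "missing" not in c.flags]
        blank = float(np.mean(firsts)) if firsts else 0.0
    return curves, blank


def preprocess_curve(
    raw: GrowthCurve, blank: float, smooth_window: int = 3
) -> GrowthCurve:
    """Blank-subtract, clip negatives, running-median smooth.

    A window of 1 is the identity. A blank at or above the curve's maximum
    marks the well no_growth instead of raising.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    od = np.maximum(raw.od - blank, 0.0)
    flags = set(raw.flags)
    if blank >= raw.od.max():
        flags.add("no_growth")
    if smooth_window > 1:
        od = median_filter(od, size=smooth_window, mode="nearest")
    return GrowthCurve(well=raw.well, times=raw.times.copy(), od=od, flags=flags)


def extract_growth_params(
    curve: GrowthCurve, config: GrowthConfig | None = None
) -> GrowthParams:
    """Extract (rate, yield) from a preprocessed curve.

    Yield: mean OD over the stationary plateau — the maximal suffix where
    the smoothed derivative stays at or below ``plateau_frac`` of its
    maximum — falling back to max(od) with the truncated flag when the
    culture never plateaus.

    Rate: maximal specific growth rate from sliding-window least-squares
    slopes of ln(od + eps_floor) versus time over detectable points. The
    exponential region is located by the maximum of the smoothed window
    slopes; within it each window's slope is divided by the logistic
    depletion factor (1 - od_center/K), K taken from the detected
    plateau, which removes the downward curvature bias of a finite
    window, and the region's corrected slopes are combined by a
    precision-weighted mean (weights follow the inverse variance of a
    log-slope under additive OD noise). Without a plateau the raw
    windowed slopes are used, which is exact for a pure exponential.

    A curve that never clears ``lethal_threshold`` is called lethal
    (rate = yield = 0).
    """
    if config is None:
        config = GrowthConfig()
    if "missing" in curve.flags:
        return GrowthParams(rate=np.nan, yield_=np.nan, lethal=False)
    od = curve.od
    t = curve.times
    if od.max() < config.lethal_threshold or "no_growth" in curve.flags:
        return GrowthParams(rate=0.0, yield_=0.0, lethal=True)

    yield_, truncated = _plateau_yield(od, t, config)
    K_hat = yield_ if not truncated else None

    detect = od > config.detection_floor
    idx = np.flatnonzero(detect)
    w = config.rate_window
    if len(idx) < w:
        return GrowthParams(rate=0.0, yield_=0.0, lethal=True)
    log_od = np.log(od + config.eps_floor)
    slopes, od_means, od_centers, starts = [], [], [], []
    for j in range(len(idx) - w + 1):
        sel = idx[j : j + w]
        if sel[-1] - sel[0] != w - 1:  # require contiguity in time
            continue
        slopes.append(_ls_slope(t[sel], log_od[sel]))
        od_means.append(od[sel].mean())
        od_centers.append(od[sel[w // 2]])
        starts.append(sel[0])
    if not slopes:
        return GrowthParams(rate=0.0, yield_=0.0, lethal=True)
    slopes = np.asarray(slopes)
    od_means = np.asarray(od_means)
    od_centers = np.asarray(od_centers)

    if K_hat is not None and K_hat > 0:
        factor = np.clip(1.0 - od_centers / K_hat, 0.5, 1.0)
        corrected = slopes / factor
        # windows too close to saturation carry unreliable corrections
        eligible = od_means <= 0.25 * K_hat
        if not eligible.any():
            eligible = np.ones(len(slopes), dtype=bool)
    else:
        factor = np.ones(len(slopes))
        corrected = slopes
        eligible = np.ones(len(slopes), dtype=bool)

    m = min(5, len(slopes))
    smoothed = np.convolve(slopes, np.ones(m) / m, mode="same")
    region = eligible & (smoothed >= 0.5 * smoothed[eligible].max())
    if not region.any():
        region = eligible
    weights = (od_means[region] * factor[region]) ** 2
    if weights.sum() <= 0:
        rate = float(max(corrected[region].max(), 0.0))
    else:
        rate = float(max(np.sum(weights * corrected[region]) / weights.sum(), 0.0))

    first = int(np.flatnonzero(region)[0])
    sel0 = starts[first]
    best_win = (float(t[sel0]), float(t[min(sel0 + w - 1, len(t) - 1)]))
    return GrowthParams(
        rate=rate, yield_=yield_, rate_window=best_win, truncated=truncated
    )


def _plateau_yield(
    od: np.ndarray, t: np.ndarray, config: GrowthConfig
) -> tuple[float, bool]:
    """Derivative-threshold plateau detection (see extract_growth_params)."""
    if len(od) >= 5 and np.allclose(np.diff(t), t[1] - t[0]):
        # least-squares 5-point derivative over distinct windows only:
        # each estimate covers od[i-2..i+2], robust to read noise
        dt = float(t[1] - t[0])
        kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / (10.0 * dt)
        deriv = np.convolve(od, kernel, mode="valid")
        pad = 2  # first interior estimate sits at time index 2
    else:
        deriv = np.gradient(od, t)
        pad = 0
    dmax = deriv.max()
    if dmax <= 0:
        return float(od.max()), True
    flat = deriv <= config.plateau_frac * dmax
    # maximal suffix of flat windows, tolerating isolated noise flips: a
    # break requires two consecutive above-threshold derivatives
    suffix_start = len(flat)
    i = len(flat) - 1
    while i >= 0:
        if flat[i]:
            suffix_start = i
            i -= 1
        elif i >= 1 and flat[i - 1]:
            suffix_start = i - 1
            i -= 2
        else:
            break
    # the suffix extends over the trailing points the edge windows cover
    n_plateau = len(od) - (suffix_start + pad)
    if suffix_start < len(flat) and n_plateau >= config.plateau_persistence:
        return float(od[suffix_start + pad :].mean()), False
    return float(od.max()), True


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc, y - y.mean()) / denom)


def normalize_to_wildtype(
    params: dict[tuple[str, int, str], GrowthParams],
    plate_map: pd.DataFrame,
    condition: str = "",
    plate_id: int = 0,
) -> pd.DataFrame:
    """Normalize per-well parameters to the plate's wild-type mean.

    Technical replicates of a strain on the plate are averaged to one row
    per (strain, bio_rep). Output columns:
    strain, condition, bio_rep, plate, rel_rate, rel_yield, lethal, missing.
    Wild-type rel values average to 1.0 per plate by construction.
    """
    wt_rates = [
        p.rate
        for (strain, _, _), p in params.items()
        if strain == WT and not p.lethal and not np.isnan(p.rate)
    ]
    wt_yields = [
        p.yield_
        for (strain, _, _), p in params.items()
        if strain == WT and not p.lethal and not np.isnan(p.yield_)
    ]
    if not any(strain == WT for (strain, _, _) in params):
        raise ValueError("plate lacks wild-type reference")
    if not wt_rates:
        raise ValueError("all wild-type wells lethal; plate cannot be normalized")
    wt_rate = float(np.mean(wt_rates))
    wt_yield = float(np.mean(wt_yields))
    if wt_rate <= 0 or wt_yield <= 0:
        raise ValueError("degenerate wild-type reference (zero mean)")

    rows = []
    for (strain, bio_rep, well), p in params.items():
        rows.append(
            (
                strain,
                bio_rep,
                well,
                p.rate / wt_rate if not p.lethal else 0.0,
                p.yield_ / wt_yield if not p.lethal else 0.0,
                p.lethal,
                bool(np.isnan(p.rate)),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["strain", "bio_rep", "well", "rel_rate", "rel_yield", "lethal",
                 "missing"],
    )
    # average technical replicates of deletion strains; wild-type wells
    # stay one row per well — they carry the spread of the reference
    # distribution, which plate-level aggregation would collapse to 1.0.
    # A strain is lethal/missing on this plate only if every well is.
    wt_df = df[df["strain"] == WT].drop(columns="well")
    del_df = df[df["strain"] != WT]
    agg = (
        del_df.groupby(["strain", "bio_rep"], as_index=False)
        .agg(
            rel_rate=("rel_rate", _mean_of_scored),
            rel_yield=("rel_yield", _mean_of_scored),
            lethal=("lethal", "all"),
            missing=("missing", "all"),
        )
    )
    agg = pd.concat([agg, wt_df], ignore_index=True)
    agg.insert(1, "condition", condition)
    agg.insert(3, "plate", plate_id)
    agg.loc[agg["lethal"] | agg["missing"], ["rel_rate", "rel_yield"]] = 0.0
    return agg


def _mean_of_scored(s: pd.Series) -> float:
    vals = s[(s > 0) & s.notna()]
    return float(vals.mean()) if len(vals) else 0.0


def fit_plate(
    reads: pd.DataFrame,
    plate_map: pd.DataFrame,
    config: GrowthConfig | None = None,
    condition: str = "",
    plate_id: int = 0,
) -> pd.DataFrame:
    """reads + map → per-(strain, bio_rep) relative parameters."""
    if config is None:
        config = GrowthConfig()
    curves, blank = curves_from_frames(reads, plate_map)
    params = {
        key: extract_growth_params(
            preprocess_curve(c, blank, config.smooth_window), config
        )
        for key, c in curves.items()
    }
    return normalize_to_wildtype(params, plate_map, condition, plate_id)


def fit_library(
    plates_by_condition: dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]],
    config: GrowthConfig | None = None,
) -> pd.DataFrame:
    """Fit every plate of every condition; concatenated RelativeParams table."""
    frames = []
    for condition, plates in plates_by_condition.items():
        for plate_id, (reads, plate_map) in enumerate(plates):
            frames.append(fit_plate(reads, plate_map, config, condition, plate_id))
    return pd.concat(frames, ignore_index=True)
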