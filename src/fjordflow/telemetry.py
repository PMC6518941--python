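"""Acoustic-telemetry behavioural metrics.

Turns raw receiver detections into the behavioural traits and fate/fitness
variables of a tagged-fish study: false-detection filtering, post-mortem
truncation, 30-min centres of activity (COA), diel vertical migration
(DVM, day-minus-night depth), monthly mean daytime depth, monthly 95% KUD
home-range area, fate classification (alive / dispersed / dead) and
relative longevity.

Calendar-day and month bucketing use a configurable local time zone
(default Europe/Oslo); day/night uses solar elevation at the array centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import classify_daynight

DEFAULT_TZ = "Europe/Oslo"
M_PER_DEG_LAT = 111_320.0

#: chi-square(2 df) quantile: expected 95% KUD area of a bivariate normal
#: with isotropic sigma is pi * CHI2_95 * sigma^2
CHI2_95 = 5.99146


@dataclass
class FateRecord:
    fish_id: str
    fate: str  # alive | dispersed | dead
    last_valid_timestamp: pd.Timestamp
    days_survived: float
    relative_longevity: float | None = None


# ---------------------------------------------------------------------------
# detection cleaning


def filter_false_detections(det: pd.DataFrame, tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Drop detections on fish-days with fewer than 2 detections.

    Code collisions and false detections appear as isolated single hits; a
    minimum of two detections per local calendar day per fish is required.
    """
    local_day = det["timestamp"].dt.tz_convert(tz).dt.date
    counts = det.groupby(["fish_id", local_day], sort=False)["timestamp"].transform("size")
    return det[counts >= 2].reset_index(drop=True)


def truncate_post_mortem(
    det: pd.DataFrame,
    depth_sd_threshold: float = 0.5,
    window_h: float = 24.0,
) -> tuple[pd.DataFrame, dict[str, pd.Timestamp | None]]:
    """Remove constant-depth tails (transmissions after death).

    For each fish, finds the earliest time t* after which every trailing
    ``window_h``-hour window of depths has standard deviation below
    ``depth_sd_threshold`` through the end of the record; detections after
    t* are removed and the fish flagged as a candidate "dead" (mapping
    fish_id -> t*, or None when no truncation applies).  A quiet tail
    shorter than one window is not truncated.
    """
    flags: dict[str, pd.Timestamp | None] = {}
    kept = []
    window = pd.Timedelta(hours=window_h)
    for fish, sub in det.groupby("fish_id", sort=False):
        sub = sub.sort_values("timestamp")
        s = pd.Series(sub["depth_m"].to_numpy(), index=pd.DatetimeIndex(sub["timestamp"]))
        if len(s) < 3 or (s.index[-1] - s.index[0]) < window:
            flags[fish] = None
            kept.append(sub)
            continue
        roll_sd = s.rolling(window).std()
        # trailing window at time t covers (t - window, t]; it lies fully
        # after t* iff t - window >= t*
        noisy = roll_sd >= depth_sd_threshold
        valid = s.index >= (s.index[0] + window)  # full windows only
        noisy_times = s.index[noisy.to_numpy() & valid]
        if len(noisy_times) == 0:
            t_star = s.index[0]
        else:
            t_last_bad = noisy_times[-1]
            if t_last_bad == s.index[-1] or (s.index[-1] - t_last_bad) < window:
                flags[fish] = None  # still moving at record end (or tail too short)
                kept.append(sub)
                continue
            t_star = t_last_bad - window
        flags[fish] = t_star
        kept.append(sub[sub["timestamp"] <= t_star])
    out = pd.concat(kept, ignore_index=True) if kept else det.iloc[0:0]
    return out, flags


# ---------------------------------------------------------------------------
# centres of activity


def compute_coa(det: pd.DataFrame, bin_min: int = 30) -> pd.DataFrame:
    """Centres of activity: mean detecting-receiver position per time bin.

    Receivers are implicitly weighted by their detection counts (the mean
    runs over detections, not distinct receivers).  Columns: fish_id,
    bin_start (UTC, aligned to the bin grid), lon, lat, depth_m,
    n_detections.
    """
    bin_start = det["timestamp"].dt.floor(f"{bin_min}min")
    coa = (
        det.assign(bin_start=bin_start)
        .groupby(["fish_id", "bin_start"], sort=True)
        .agg(
            lon=("lon", "mean"),
            lat=("lat", "mean"),
            depth_m=("depth_m", "mean"),
            n_detections=("timestamp", "size"),
        )
        .reset_index()
    )
    return coa


# ---------------------------------------------------------------------------
# monthly behavioural traits


def _with_daynight_and_day(coa: pd.DataFrame, lat: float, lon: float, tz: str) -> pd.DataFrame:
    out = coa.copy()
    out["daynight"] = classify_daynight(out["bin_start"], lat, lon)
    local = out["bin_start"].dt.tz_convert(tz)
    out["local_date"] = local.dt.date
    out["year_month"] = local.dt.tz_localize(None).dt.to_period("M")
    return out


def monthly_dvm(
    coa: pd.DataFrame, lat: float, lon: float, tz: str = DEFAULT_TZ
) -> pd.DataFrame:
    """Monthly diel vertical migration per fish: mean over days of
    (day mean depth - night mean depth); positive = deeper by day."""
    df = _with_daynight_and_day(coa, lat, lon, tz)
    daily = (
        df.groupby(["fish_id", "year_month", "local_date", "daynight"])["depth_m"]
        .mean()
        .unstack("daynight")
    )
    if "day" not in daily.columns or "night" not in daily.columns:
        return pd.DataFrame(columns=["fish_id", "year_month", "dvm_m"])
    daily = daily.dropna(subset=["day", "night"])
    daily["dvm"] = daily["day"] - daily["night"]
    out = daily.groupby(["fish_id", "year_month"])["dvm"].mean().reset_index()
    return out.rename(columns={"dvm": "dvm_m"})


def monthly_mean_daytime_depth(
    coa: pd.DataFrame, lat: float, lon: float, tz: str = DEFAULT_TZ
) -> pd.DataFrame:
    """Monthly mean daytime depth per fish: days weighted equally."""
    df = _with_daynight_and_day(coa, lat, lon, tz)
    day = df[df["daynight"] == "day"]
    daily = day.groupby(["fish_id", "year_month", "local_date"])["depth_m"].mean()
    out = daily.groupby(["fish_id", "year_month"]).mean().reset_index()
    return out.rename(columns={"depth_m": "daytime_depth_m"})


def project_local_m(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to metres about (lon0, lat0)."""
    x = (np.asarray(lon) - lon0) * M_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    y = (np.asarray(lat) - lat0) * M_PER_DEG_LAT
    return x, y


def kud_area_km2(
    x_m: np.ndarray,
    y_m: np.ndarray,
    prob: float = 0.95,
    grid_n: int = 256,
    pad_bw: float = 3.0,
) -> float:
    """Area of the smallest region holding ``prob`` of a 2-D Gaussian KDE.

    Reference ("href") bandwidth per axis: h = sigma * n^(-1/6).  The
    utilization distribution is evaluated on a ``grid_n`` x ``grid_n`` grid
    padded by ``pad_bw`` bandwidths; the area is the total area of the
    highest-density cells that accumulate ``prob`` of the UD mass.
    """
    x = np.asarray(x_m, dtype=float)
    y = np.asarray(y_m, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 positions")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate positions: zero variance")
    hx = sx * n ** (-1.0 / 6.0)
    hy = sy * n ** (-1.0 / 6.0)

    gx = np.linspace(x.min() - pad_bw * hx, x.max() + pad_bw * hx, grid_n)
    gy = np.linspace(y.min() - pad_bw * hy, y.max() + pad_bw * hy, grid_n)
    # separable Gaussian kernels -> density = A @ B with A (grid x n), B (n x grid)
    ax = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    by = np.exp(-0.5 * ((y[:, None] - gy[None, :]) / hy) ** 2)
    dens = (ax @ by) / (n * 2.0 * np.pi * hx * hy)

    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(dens.ravel())[::-1]
    mass = np.cumsum(flat) * cell
    total = mass[-1]
    k = int(np.searchsorted(mass, prob * total) + 1)
    return k * cell / 1e6


def monthly_home_range(
    coa: pd.DataFrame,
    prob: float = 0.95,
    min_days: int = 20,
    min_coas: int = 30,
    tz: str = DEFAULT_TZ,
) -> pd.DataFrame:
    """Monthly KUD home-range area (km²) per fish.

    A fish-month needs ``min_days`` distinct local days of presence and
    ``min_coas`` COAs; otherwise the month is skipped (missing).
    """
    local = coa["bin_start"].dt.tz_convert(tz)
    df = coa.assign(year_month=local.dt.tz_localize(None).dt.to_period("M"), local_date=local.dt.date)
    lon0 = coa["lon"].mean()
    lat0 = coa["lat"].mean()
    rows = []
    for (fish, ym), sub in df.groupby(["fish_id", "year_month"], sort=True):
        if sub["local_date"].nunique() < min_days or len(sub) < min_coas:
            continue
        x, y = project_local_m(sub["lon"].to_numpy(), sub["lat"].to_numpy(), lon0, lat0)
        try:
            area = kud_area_km2(x, y, prob=prob)
        except ValueError:
            continue
        rows.append({"fish_id": fish, "year_month": ym, "home_range_km2": area,
                     "days_present": sub["local_date"].nunique()})
    return pd.DataFrame(rows, columns=["fish_id", "year_month", "home_range_km2", "days_present"])


def monthly_traits(
    det: pd.DataFrame,
    lat: float,
    lon: float,
    tz: str = DEFAULT_TZ,
    min_days: int = 20,
) -> pd.DataFrame:
    """Full monthly trait table: home range, daytime depth, DVM, presence."""
    coa = compute_coa(det)
    hr = monthly_home_range(coa, min_days=min_days, tz=tz)
    dd = monthly_mean_daytime_depth(coa, lat, lon, tz=tz)
    dvm = monthly_dvm(coa, lat, lon, tz=tz)
    local = coa["bin_start"].dt.tz_convert(tz)
    days = (
        coa.assign(year_month=local.dt.tz_localize(None).dt.to_period("M"), local_date=local.dt.date)
        .groupby(["fish_id", "year_month"])["local_date"]
        .nunique()
        .reset_index(name="days_present")
    )
    out = days.merge(dd, how="left", on=["fish_id", "year_month"])
    out = out.merge(dvm, how="left", on=["fish_id", "year_month"])
    out = out.merge(
        hr[["fish_id", "year_month", "home_range_km2"]], how="left", on=["fish_id", "year_month"]
    )
    return out


# ---------------------------------------------------------------------------
# fate and fitness


def classify_fate(
    det: pd.DataFrame,
    receiver_positions: pd.DataFrame,
    battery_end: pd.Timestamp,
    tagging_dates: dict[str, pd.Timestamp] | None = None,
    depth_sd_threshold: float = 0.5,
    window_h: float = 24.0,
    k_last_coas: int = 10,
    silence_days: float = 7.0,
) -> list[FateRecord]:
    """Classify each fish as alive / dispersed / dead from its detections.

    dead: a persistent constant-depth tail (post-mortem truncation fires),
    or transmissions stop well before battery end while the last COAs are
    interior.  dispersed: distance to the array centroid trends outward
    over the last ``k_last_coas`` COAs (a clear majority of increments
    positive and a net outward displacement), the final detections come
    from an outermost receiver, and the fish then falls silent.  Otherwise
    alive.  COA positions are biased inward near the array edge (detecting
    receivers all lie inward of the fish), so the "ends at an outermost
    receiver" condition is judged on the raw detecting receivers of the
    final hour, not on COA radii.

    days_survived runs from tagging (first detection when no tagging date
    given) to the last valid detection; for alive fish, to battery end.
    """
    rec_lon0 = receiver_positions["lon"].mean()
    rec_lat0 = receiver_positions["lat"].mean()
    rx, ry = project_local_m(
        receiver_positions["lon"].to_numpy(), receiver_positions["lat"].to_numpy(),
        rec_lon0, rec_lat0,
    )
    rec_radius = pd.Series(np.hypot(rx, ry), index=receiver_positions["receiver_id"].to_numpy())
    outer_radius = float(np.quantile(rec_radius, 0.8))

    truncated, dead_flags = truncate_post_mortem(det, depth_sd_threshold, window_h)
    records: list[FateRecord] = []
    for fish, sub in truncated.groupby("fish_id", sort=False):
        sub = sub.sort_values("timestamp")
        coa = compute_coa(sub)
        t_tag = (
            tagging_dates[fish]
            if tagging_dates and fish in tagging_dates
            else sub["timestamp"].iloc[0]
        )
        t_last = sub["timestamp"].iloc[-1]
        silent_for = battery_end - t_last

        x, y = project_local_m(coa["lon"].to_numpy(), coa["lat"].to_numpy(), rec_lon0, rec_lat0)
        r = np.hypot(x, y)
        k = min(k_last_coas, len(r))
        tail_r = r[-k:]
        day_mask = (coa["bin_start"] > t_last - pd.Timedelta(hours=24)).to_numpy()
        day_r = r[day_mask] if day_mask.any() else tail_r
        last_hour = sub[sub["timestamp"] > t_last - pd.Timedelta(hours=1)]
        end_rec_radius = rec_radius.reindex(last_hour["receiver_id"]).max()
        outward = (
            k >= 3
            # track ends at its outermost point, up to COA positional noise
            and tail_r[-1] >= tail_r.max() - 0.1 * outer_radius
            # clear outward run over the final day (COA radii saturate near
            # the array edge, so the run is judged on a longer horizon)
            and (tail_r.max() - day_r.min()) > 0.25 * outer_radius
            and float(end_rec_radius) >= outer_radius
            and silent_for > pd.Timedelta(days=silence_days)
        )

        if dead_flags.get(fish) is not None:
            fate = "dead"
        elif outward:
            fate = "dispersed"
        elif silent_for > pd.Timedelta(days=silence_days):
            fate = "dead"  # stopped transmitting while interior
        else:
            fate = "alive"

        end = battery_end if fate == "alive" else t_last
        records.append(
            FateRecord(
                fish_id=fish,
                fate=fate,
                last_valid_timestamp=t_last,
                days_survived=float((end - t_tag) / pd.Timedelta(days=1)),
            )
        )
    return records


def relative_longevity(fates: list[FateRecord]) -> dict[str, float]:
    """S = days survived / mean days survived, dispersed fish excluded.

    mean(S) over included fish is exactly 1.  Mutates the ``relative_longevity``
    field of the included records and returns fish_id -> S.
    """
    included = [f for f in fates if f.fate != "dispersed"]
    if not included:
        raise ValueError("all fish dispersed; relative longevity undefined")
    mean_days = float(np.mean([f.days_survived for f in included]))
    out = {}
    for f in included:
        f.relative_longevity = f.days_survived / mean_days
        out[f.fish_id] = f.relative_longevity
    return out
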