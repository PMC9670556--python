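"""Turn raw tracks into regularized, covariate-annotated step series.

Pipeline: :func:`segment_bouts` splits a track at long gaps and drops
data-sparse bouts, :func:`interpolate_gaps` restores the regular 2-h grid
(linear or continuous-time correlated-random-walk interpolation),
:func:`compute_steps` derives step speeds and turning angles, and
:func:`annotate_covariates` attaches flow-relative angles and environmental
covariates sampled at each step's starting fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._geometry import bearing, wrap_angle
from .fields import DEFAULT_LONLAT_ORIGIN, FlowField, ScalarField, Track, \
    local_lonlat

NOMINAL_DT_H = 2.0
MS_PER_KMH = 1.0 / 3.6

#: jitter bound for zero-length steps (km); the gamma density excludes 0
ZERO_STEP_JITTER_KM = 1e-3


@dataclass
class Bout:
    """Contiguous sub-track with no gap longer than the interpolation limit."""

    animal_id: str
    data: pd.DataFrame
    attributes: dict = field(default_factory=dict)
    nominal_dt_h: float = NOMINAL_DT_H

    def __len__(self):
        return len(self.data)

    @property
    def span_h(self) -> float:
        t = pd.DatetimeIndex(self.data["timestamp"])
        return (t[-1] - t[0]).total_seconds() / 3600.0


@dataclass
class StepSeries:
    """Per-step observations: the HMM observation unit.

    One row per step; ``speed_kmh`` is the step length divided by its
    duration, ``turn_rad`` the change in bearing (ccw positive, NaN on the
    first step of a bout), ``psi_wind``/``psi_tide`` the stimulus directions
    relative to the previous step's bearing and ``r_tide`` the tidal speed.
    """

    animal_id: str
    data: pd.DataFrame
    attributes: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    def to_csv(self, path):
        out = self.data.copy()
        out.insert(0, "animal_id", self.animal_id)
        out.to_csv(path, index=False)


class SegmentationResult(NamedTuple):
    bouts: list
    n_split: int
    n_dropped_short: int
    n_dropped_sparse: int


def segment_bouts(track: Track, max_gap_h=6.0, min_span_h=24.0, min_locs=8,
                  nominal_dt_h=NOMINAL_DT_H) -> SegmentationResult:
    """Split a track at gaps of missing fixes spanning more than ``max_gap_h``
    and drop bouts shorter than ``min_span_h`` or with fewer than
    ``min_locs`` locations.

    A gap is the span of *missing* fixes: with a 2-h nominal interval, three
    consecutive missing fixes are a 6-h gap (consecutive observed fixes 8 h
    apart) and are still interpolable; anything longer splits the bout.
    """
    t = pd.DatetimeIndex(track.data["timestamp"])
    if len(t) > 1:
        dt = np.diff(t.asi8) / 3.6e12
        if np.any(dt <= 0):
            raise ValueError("track timestamps must be strictly increasing")
    else:
        dt = np.array([])
    split_after = np.where(dt - nominal_dt_h > max_gap_h + 1e-9)[0]
    pieces = np.split(np.arange(len(t)), split_after + 1)
    n_short = n_sparse = 0
    bouts = []
    for idx in pieces:
        sub = track.data.iloc[idx].reset_index(drop=True)
        b = Bout(track.animal_id, sub, dict(track.attributes), nominal_dt_h)
        if len(b) < min_locs:
            n_sparse += 1
            continue
        if b.span_h < min_span_h:
            n_short += 1
            continue
        bouts.append(b)
    return SegmentationResult(bouts, len(pieces) - 1, n_short, n_sparse)


# ---------------------------------------------------------------------------
# gap interpolation


def _ctcrw_system(beta, sigma, dt):
    """Per-axis CTCRW (integrated Ornstein-Uhlenbeck) discrete system.

    ``beta -> 0`` degenerates to the integrated random walk (constant
    velocity under zero process noise); that limit is handled exactly.
    """
    if beta < 1e-10:
        F = np.array([[1.0, dt], [0.0, 1.0]])
        s2 = sigma ** 2
        Q = s2 * np.array([[dt ** 3 / 3.0, dt ** 2 / 2.0],
                           [dt ** 2 / 2.0, dt]])
        return F, Q
    a = np.exp(-beta * dt)
    F = np.array([[1.0, (1.0 - a) / beta], [0.0, a]])
    s2 = sigma ** 2
    q_vv = s2 * (1.0 - a ** 2) / (2.0 * beta)
    q_pv = s2 * (1.0 - a) ** 2 / (2.0 * beta ** 2)
    q_pp = s2 / beta ** 2 * (dt - 2.0 * (1.0 - a) / beta
                             + (1.0 - a ** 2) / (2.0 * beta))
    Q = np.array([[q_pp, q_pv], [q_pv, q_vv]])
    return F, Q


def _kalman(z, obs, dt, beta, sigma, tau=1e-4, smooth=True):
    """Kalman filter/RTS smoother for one axis on a regular grid.

    ``z`` observed positions (NaN where missing per ``obs``); returns
    (smoothed positions, log-likelihood of the observed values).
    """
    n = len(z)
    F, Q = _ctcrw_system(beta, sigma, dt)
    R = tau ** 2
    first = int(np.argmax(obs))
    m = np.array([z[first], 0.0])
    # diffuse velocity prior: the zero-process-noise limit must still be
    # able to learn a constant velocity from the data
    P = np.diag([R, 1e4])
    ms = np.zeros((n, 2)); Ps = np.zeros((n, 2, 2))
    mp = np.zeros((n, 2)); Pp = np.zeros((n, 2, 2))
    ll = 0.0
    for t in range(n):
        if t > 0:
            m = F @ m
            P = F @ P @ F.T + Q
        mp[t], Pp[t] = m, P
        if obs[t]:
            S = P[0, 0] + R
            y = z[t] - m[0]
            ll += -0.5 * (np.log(2 * np.pi * S) + y * y / S)
            K = P[:, 0] / S
            m = m + K * y
            P = P - np.outer(K, P[0, :])
        ms[t], Ps[t] = m, P
    if not smooth:
        return ms[:, 0], ll
    xs = ms.copy()
    Psm = Ps.copy()
    for t in range(n - 2, -1, -1):
        C = Ps[t] @ F.T @ np.linalg.inv(Pp[t + 1])
        xs[t] = ms[t] + C @ (xs[t + 1] - mp[t + 1])
        Psm[t] = Ps[t] + C @ (Psm[t + 1] - Pp[t + 1]) @ C.T
    return xs[:, 0], ll


def _fit_ctcrw(x, y, obs, dt):
    """ML estimate of (beta, sigma) pooled over both axes."""

    def nll(w):
        beta, sigma = np.exp(w)
        if not (1e-4 < beta < 1e3 and 1e-6 < sigma < 1e3):
            return 1e10
        _, lx = _kalman(x, obs, dt, beta, sigma, smooth=False)
        _, ly = _kalman(y, obs, dt, beta, sigma, smooth=False)
        out = -(lx + ly)
        return out if np.isfinite(out) else 1e10

    res = minimize(nll, np.log([0.5, 1.0]), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    return tuple(np.exp(res.x))


def interpolate_gaps(bout: Bout, method="linear", nominal_dt_h=None,
                     max_missing=3, ctcrw_params=None) -> Bout:
    """Restore the regular time grid inside a bout.

    ``method`` is ``"linear"`` or ``"ctcrw"`` (continuous-time correlated
    random walk: Kalman smoother of an integrated Ornstein-Uhlenbeck velocity
    process, parameters estimated by ML unless ``ctcrw_params=(beta, sigma)``
    is given). Interpolated fixes are flagged in an ``interpolated`` column.
    """
    dt_h = nominal_dt_h or bout.nominal_dt_h
    t = pd.DatetimeIndex(bout.data["timestamp"])
    grid = pd.date_range(t[0], t[-1], freq=pd.Timedelta(hours=dt_h))
    if not set(t).issubset(set(grid)):
        raise ValueError("bout timestamps do not sit on the nominal grid")
    df = bout.data.set_index("timestamp").reindex(grid)
    obs = df["x_km"].notna().to_numpy()
    runs = np.diff(np.flatnonzero(np.concatenate(([True], obs, [True]))))
    gap_lengths = runs[runs > 1] - 1 if len(runs) else np.array([])
    if np.any(~obs):
        longest = int(np.max(np.diff(np.flatnonzero(obs)))) - 1
        if longest > max_missing:
            raise ValueError(
                f"gap of {longest} missing fixes exceeds the interpolation "
                f"limit of {max_missing}; split the bout first")
    x = df["x_km"].to_numpy(dtype=float)
    y = df["y_km"].to_numpy(dtype=float)
    if np.any(~obs):
        if method == "linear":
            xs = pd.Series(x).interpolate("linear").to_numpy()
            ys = pd.Series(y).interpolate("linear").to_numpy()
        elif method == "ctcrw":
            beta, sigma = ctcrw_params or _fit_ctcrw(x, y, obs, dt_h)
            xs, _ = _kalman(x, obs, dt_h, beta, sigma)
            ys, _ = _kalman(y, obs, dt_h, beta, sigma)
            xs = np.where(obs, x, xs)
            ys = np.where(obs, y, ys)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
    else:
        xs, ys = x, y
    out = pd.DataFrame({"timestamp": grid, "x_km": xs, "y_km": ys,
                        "interpolated": ~obs})
    return Bout(bout.animal_id, out, dict(bout.attributes), dt_h)


# ---------------------------------------------------------------------------
# step geometry


def compute_steps(bout: Bout, jitter_seed=0) -> StepSeries:
    """Step speeds, bearings and turning angles from a regularized bout.

    A bout of n locations yields n-1 steps; the first step's turning angle is
    undefined (NaN) and contributes only its step-length density downstream.
    Zero-length steps get a seeded uniform jitter on (0, 1 m] with a uniform
    random direction, because the gamma density excludes zero.
    """
    if len(bout) < 3:
        raise ValueError("need at least 3 locations to compute turning angles")
    df = bout.data
    t = pd.DatetimeIndex(df["timestamp"])
    dt_h = np.diff(t.asi8) / 3.6e12
    x = df["x_km"].to_numpy(dtype=float)
    y = df["y_km"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    dist = np.hypot(dx, dy)
    zero = dist <= 0
    if np.any(zero):
        rng = np.random.default_rng(jitter_seed)
        r = rng.uniform(0.0, ZERO_STEP_JITTER_KM, zero.sum())
        r = np.where(r == 0.0, ZERO_STEP_JITTER_KM, r)
        th = rng.uniform(-np.pi, np.pi, zero.sum())
        dx[zero] = r * np.cos(th)
        dy[zero] = r * np.sin(th)
        dist = np.hypot(dx, dy)
    brg = bearing(dx, dy)
    turn = np.full(len(dist), np.nan)
    turn[1:] = wrap_angle(np.diff(brg))
    data = pd.DataFrame({
        "timestamp": t[:-1], "x0_km": x[:-1], "y0_km": y[:-1],
        "x1_km": x[1:], "y1_km": y[1:], "dt_h": dt_h,
        "step_km": dist, "speed_kmh": dist / dt_h,
        "bearing_rad": brg, "turn_rad": turn,
    })
    if "interpolated" in df.columns:
        data["interpolated"] = df["interpolated"].to_numpy()[:-1]
    return StepSeries(bout.animal_id, data, dict(bout.attributes))


def relative_stimulus_angle(prev_bearing, stimulus_u, stimulus_v):
    """Direction and magnitude of a stimulus relative to the previous bearing.

    Returns (psi, r): psi = wrap(stimulus_direction - prev_bearing) in
    (-pi, pi], ccw positive; a zero stimulus gives (0, 0) by convention (bias
    terms vanish when multiplied by r).
    """
    u = np.asarray(stimulus_u, dtype=float)
    v = np.asarray(stimulus_v, dtype=float)
    r = np.hypot(u, v)
    psi = np.where(r > 0.0,
                   wrap_angle(np.arctan2(v, u) - np.asarray(prev_bearing)),
                   0.0)
    if psi.ndim == 0:
        return float(psi), float(r)
    return psi, r


# ---------------------------------------------------------------------------
# solar position (NOAA/Spencer approximation)


def sun_altitude(timestamps_utc, lon_deg, lat_deg) -> np.ndarray:
    """Sun altitude in degrees from a standard low-precision solar formula."""
    t = pd.DatetimeIndex(timestamps_utc)
    doy = t.dayofyear.to_numpy(dtype=float)
    hour = (t.hour + t.minute / 60.0 + t.second / 3600.0).to_numpy(dtype=float)
    g = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g)
                       - 0.032077 * np.sin(g) - 0.014615 * np.cos(2 * g)
                       - 0.040849 * np.sin(2 * g))
    tst = hour * 60.0 + eqtime + 4.0 * np.asarray(lon_deg, dtype=float)
    ha = np.deg2rad(tst / 4.0 - 180.0)
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    alt = np.arcsin(np.sin(lat) * np.sin(decl)
                    + np.cos(lat) * np.cos(decl) * np.cos(ha))
    return np.degrees(alt)


# ---------------------------------------------------------------------------
# covariate annotation


def annotate_covariates(steps, wind: FlowField = None, tide: FlowField = None,
                        scalar_fields: dict = None, attributes: dict = None,
                        utc_offset_h=-5, lonlat_origin=DEFAULT_LONLAT_ORIGIN,
                        origin_time=None, clamp=False) -> StepSeries:
    """Attach flow-relative angles and covariates to a step series.

    Gridded fields are interpolated bilinearly in space and linearly in time
    at each step's starting fix. Clock covariates: ``hour`` is local standard
    time (UTC ``utc_offset_h``), ``ordinal_date`` the day of year and
    ``sun_altitude`` from the solar-position formula. ``scalar_fields`` maps
    covariate names to :class:`ScalarField` rasters; ``attributes`` (e.g.
    age) are broadcast per animal. Accepts a Bout (steps are computed first).
    """
    if isinstance(steps, Bout):
        steps = compute_steps(steps)
    df = steps.data.copy()
    ref = wind or tide
    if origin_time is None:
        origin_time = ref.origin_time if ref is not None \
            else np.datetime64("2020-01-05T00:00:00")
    t = pd.DatetimeIndex(df["timestamp"])
    th = (t - pd.Timestamp(origin_time)).total_seconds().to_numpy() / 3600.0
    x0 = df["x0_km"].to_numpy()
    y0 = df["y0_km"].to_numpy()
    prev_bearing = np.concatenate(([np.nan], df["bearing_rad"].to_numpy()[:-1]))
    pb = np.where(np.isfinite(prev_bearing), prev_bearing, 0.0)

    if wind is not None:
        wu, wv = wind.sample(th, x0, y0, clamp=clamp)
        psi_w, r_w = relative_stimulus_angle(pb, wu, wv)
        df["psi_wind"] = np.where(np.isfinite(prev_bearing), psi_w, 0.0)
        df["wind_speed"] = r_w / 3.6  # km/h -> m/s
    else:
        df["psi_wind"] = 0.0
        df["wind_speed"] = 0.0
    if tide is not None:
        tu, tv = tide.sample(th, x0, y0, clamp=clamp)
        psi_t, r_t = relative_stimulus_angle(pb, tu, tv)
        df["psi_tide"] = np.where(np.isfinite(prev_bearing), psi_t, 0.0)
        df["r_tide"] = r_t
    else:
        df["psi_tide"] = 0.0
        df["r_tide"] = 0.0

    local = t + pd.Timedelta(hours=utc_offset_h)
    df["hour"] = (local.hour + local.minute / 60.0).to_numpy(dtype=float)
    df["ordinal_date"] = local.dayofyear.to_numpy(dtype=float)
    lon, lat = local_lonlat(x0, y0, lonlat_origin)
    df["sun_altitude"] = sun_altitude(t, lon, lat)
    for name, fld in (scalar_fields or {}).items():
        df[name] = fld.sample(th, x0, y0, clamp=clamp)
    for name, value in (attributes or {}).items():
        df[name] = value
    for name, value in steps.attributes.items():
        if name not in df.columns:
            df[name] = value
    return StepSeries(steps.animal_id, df, dict(steps.attributes))
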