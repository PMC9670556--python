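"""Wind-forced sea-ice drift: BCRW calibration on passive drifters and
subtraction of predicted drift from bear tracks.

The drift model is a single-state biased correlated random walk with the same
emission family as the behavioral HMM: step speed ~ gamma with mean
``intercept + slope * flow_speed`` (floored at a small epsilon), turning
angle ~ von Mises whose mean trades persistence against bias along the flow
(``a1``) and 90 deg anti-clockwise of it (``a2``). Candidate flow predictors
(e.g. hourly wind vs daily ice vectors) are compared by AIC and the winner is
used to predict, and subtract, the wind-driven component of ice motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._geometry import bearing, wrap_angle
from .fields import FlowField, Track
from .hmm import STEP_MEAN_FLOOR, bias_turn_mean, gamma_logpdf_meansd, \
    numerical_hessian, vonmises_logpdf
from .preprocess import Bout, StepSeries, compute_steps, \
    relative_stimulus_angle


@dataclass
class DriftModel:
    """Fitted BCRW linking passive-drifter motion to a flow field."""

    flow_kind: str
    intercept: float        # km/h
    slope: float            # drifter speed per unit flow speed
    sigma: float            # gamma sd, km/h
    kappa: float            # turning concentration
    a1: float               # bias along the flow
    a2: float               # bias 90 deg anti-clockwise of the flow
    loglik: float
    n_params: int
    aic: float
    n_steps: int = 0
    converged: bool = True
    cov: np.ndarray | None = None
    flags: list = field(default_factory=list)

    @property
    def bias_angle_deg(self) -> float:
        """Bias direction relative to the flow, ccw positive."""
        return float(np.degrees(np.arctan2(self.a2, self.a1)))

    @property
    def deflection_deg(self) -> float:
        """Deflection clockwise (to the right) of the flow direction."""
        return -self.bias_angle_deg

    def slope_ci95(self):
        if self.cov is None:
            return (np.nan, np.nan)
        se = float(np.sqrt(max(self.cov[1, 1], 0.0)))
        return (self.slope - 1.96 * se, self.slope + 1.96 * se)

    def to_json(self, path):
        obj = {"flow_kind": self.flow_kind,
               "intercept_kmh": self.intercept, "slope": self.slope,
               "sigma_kmh": self.sigma, "kappa": self.kappa,
               "a1_along_flow": self.a1, "a2_left_of_flow": self.a2,
               "bias_angle_deg": self.bias_angle_deg,
               "loglik": self.loglik, "aic": self.aic,
               "n_params": self.n_params, "n_steps": self.n_steps,
               "converged": self.converged, "flags": self.flags}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            o = json.load(fh)
        return cls(flow_kind=o["flow_kind"], intercept=o["intercept_kmh"],
                   slope=o["slope"], sigma=o["sigma_kmh"], kappa=o["kappa"],
                   a1=o["a1_along_flow"], a2=o["a2_left_of_flow"],
                   loglik=o["loglik"], n_params=o["n_params"],
                   aic=o["aic"], n_steps=o.get("n_steps", 0),
                   converged=o.get("converged", True),
                   flags=list(o.get("flags", [])))


def drifter_step_series(track: Track, flow: FlowField, clamp=True
                        ) -> StepSeries:
    """Steps of a drifter track annotated with flow-relative angle/magnitude.

    Adds columns ``psi_flow`` (flow direction relative to the previous step's
    bearing; NaN on the first step) and ``r_flow`` (flow speed, km/h) sampled
    at each step's starting fix.
    """
    bout = Bout(track.animal_id, track.data[["timestamp", "x_km", "y_km"]],
                dict(track.attributes))
    steps = compute_steps(bout)
    df = steps.data
    th = (pd.DatetimeIndex(df["timestamp"])
          - pd.Timestamp(flow.origin_time)).total_seconds().to_numpy() / 3600.0
    u, v = flow.sample(th, df["x0_km"].to_numpy(), df["y0_km"].to_numpy(),
                      clamp=clamp)
    prev = np.concatenate(([np.nan], df["bearing_rad"].to_numpy()[:-1]))
    pb = np.where(np.isfinite(prev), prev, 0.0)
    psi, r = relative_stimulus_angle(pb, u, v)
    df = df.copy()
    df["psi_flow"] = np.where(np.isfinite(prev), psi, np.nan)
    df["r_flow"] = r
    df["flow_u"] = u
    df["flow_v"] = v
    return StepSeries(steps.animal_id, df, dict(steps.attributes))


def _drift_nll_data(series_list):
    speed = np.concatenate([s.data["speed_kmh"].to_numpy()
                            for s in series_list])
    turn = np.concatenate([s.data["turn_rad"].to_numpy()
                           for s in series_list])
    psi = np.concatenate([s.data["psi_flow"].to_numpy()
                          for s in series_list])
    r = np.concatenate([s.data["r_flow"].to_numpy() for s in series_list])
    ok = np.isfinite(turn) & np.isfinite(psi)
    return speed, turn, psi, r, ok


def _drift_nll(theta, speed, turn, psi, r, ok, bias):
    c0, c1, lsig, lkap = theta[:4]
    a1, a2 = (theta[4], theta[5]) if bias else (0.0, 0.0)
    sigma, kappa = np.exp(lsig), np.exp(lkap)
    if not (1e-8 < sigma < 1e3 and 1e-8 < kappa < 1e4):
        return 1e12
    mu = np.maximum(c0 + c1 * r, STEP_MEAN_FLOOR)
    ll = gamma_logpdf_meansd(speed, mu, sigma).sum()
    mphi = bias_turn_mean(psi[ok], a1, a2)
    ll += vonmises_logpdf(turn[ok], mphi, kappa).sum()
    return -ll if np.isfinite(ll) else 1e12


def fit_drift_bcrw(drifters, flow: FlowField = None, bias=True,
                   compute_hessian=True) -> DriftModel:
    """Maximum-likelihood BCRW fit to passive-drifter step series.

    ``drifters`` is a list of :class:`StepSeries` carrying ``psi_flow`` /
    ``r_flow`` columns (see :func:`drifter_step_series`) or a list of
    :class:`Track` (``flow`` then required). ``bias=False`` fits the
    persistence-only null model (a1 = a2 = 0).
    """
    if drifters and isinstance(drifters[0], Track):
        if flow is None:
            raise ValueError("flow field required to annotate raw tracks")
        drifters = [drifter_step_series(t, flow) for t in drifters]
    data = _drift_nll_data(drifters)
    speed, turn, psi, r, ok = data
    if len(speed) < 2:
        raise ValueError("need at least 2 steps to fit the drift model")
    flags = []
    if np.all(r < 1e-12):
        flags.append("all-zero flow: slope unidentifiable")
    # starting values: least-squares speed-on-flow regression
    A = np.column_stack([np.ones_like(r), r])
    c, *_ = np.linalg.lstsq(A, speed, rcond=None)
    resid_sd = max(np.std(speed - A @ c), 1e-3)
    x0 = [c[0], c[1], np.log(resid_sd), 0.0]
    if bias:
        x0 += [0.3, 0.0]
    x0 = np.asarray(x0, dtype=float)

    def nll(th):
        return _drift_nll(th, *data, bias)

    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 500})
    th = res.x
    a1, a2 = (th[4], th[5]) if bias else (0.0, 0.0)
    k = len(th)
    ll = -res.fun
    cov = None
    if compute_hessian:
        H = numerical_hessian(nll, th, step=1e-5)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
    kind = flow.kind if flow is not None else "wind"
    if not res.success:
        flags.append(f"optimizer: {res.message}")
    return DriftModel(flow_kind=kind, intercept=th[0], slope=th[1],
                      sigma=float(np.exp(th[2])), kappa=float(np.exp(th[3])),
                      a1=a1, a2=a2, loglik=ll, n_params=k,
                      aic=2 * k - 2 * ll, n_steps=len(speed),
                      converged=bool(res.success), cov=cov, flags=flags)


def compare_drift_predictors(drifter_tracks, candidates) -> list:
    """Fit one DriftModel per candidate flow field and rank them by AIC.

    ``candidates`` is a list of (label, FlowField) pairs or FlowFields.
    Returns a list of (label, DriftModel | Exception) pairs sorted by AIC
    (failed fits sort last); the first entry is the winner.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate flow field")
    results = []
    for i, cand in enumerate(candidates):
        label, flow = cand if isinstance(cand, tuple) else (f"cand{i}", cand)
        try:
            series = [drifter_step_series(t, flow) for t in drifter_tracks]
            results.append((label, fit_drift_bcrw(series, flow,
                                                  compute_hessian=False)))
        except Exception as exc:  # keep ranking the other candidates
            results.append((label, exc))
    results.sort(key=lambda kv: kv[1].aic
                 if isinstance(kv[1], DriftModel) else np.inf)
    return results


def predict_drift(model: DriftModel, flow_u, flow_v, prev_bearing=None):
    """Expected drift velocity (km/h) for one step.

    The predicted speed is ``max(intercept + slope*flow_speed, 0)`` and the
    direction is the model's mean-turn blend of the previous bearing and the
    flow bias. Without a previous bearing (first step of a track) the
    direction falls back to the flow direction rotated by the fitted bias
    angle.
    """
    r = float(np.hypot(flow_u, flow_v))
    spd = max(model.intercept + model.slope * r, 0.0)
    flow_dir = float(np.arctan2(flow_v, flow_u))
    if prev_bearing is None:
        direction = flow_dir + np.arctan2(model.a2, model.a1)
    else:
        psi = wrap_angle(flow_dir - prev_bearing)
        direction = prev_bearing + float(bias_turn_mean(psi, model.a1,
                                                        model.a2))
    return np.array([spd * np.cos(direction), spd * np.sin(direction)])


def correct_track(track: Track, flow: FlowField, model: DriftModel,
                  clamp=True) -> Track:
    """Subtract the predicted wind-driven drift from a track.

    Each displacement is reduced by the predicted drift velocity times the
    step duration, then positions are rebuilt cumulatively from the first
    fix. The subtracted displacements are stored in ``drift_dx_km`` /
    ``drift_dy_km`` columns, so the correction is exactly invertible; the
    original track is untouched.
    """
    t = pd.DatetimeIndex(track.data["timestamp"])
    th = (t - pd.Timestamp(flow.origin_time)).total_seconds() \
        .to_numpy() / 3600.0
    xy = track.xy
    n = len(track)
    disp = np.diff(xy, axis=0)
    dt_h = np.diff(t.asi8) / 3.6e12
    brg = bearing(disp[:, 0], disp[:, 1])
    drift = np.zeros_like(disp)
    for k in range(n - 1):
        u, v = flow.sample(th[k], xy[k, 0], xy[k, 1], clamp=clamp)
        prev = brg[k - 1] if k > 0 else None
        drift[k] = predict_drift(model, float(u), float(v), prev) * dt_h[k]
    corrected = disp - drift
    pos = np.vstack([xy[0], xy[0] + np.cumsum(corrected, axis=0)])
    out = pd.DataFrame({"timestamp": t, "x_km": pos[:, 0],
                        "y_km": pos[:, 1],
                        "drift_dx_km": np.concatenate(([0.0], drift[:, 0])),
                        "drift_dy_km": np.concatenate(([0.0], drift[:, 1]))})
    return Track(track.animal_id, out, dict(track.attributes))


def apply_correction(track: Track, flow: FlowField = None,
                     model: DriftModel = None, mode="wind-bcrw",
                     clamp=True) -> Track:
    """Apply one of the configurable ice-motion correction modes.

    ``"none"`` returns an untouched copy; ``"wind-bcrw"`` subtracts the
    drift predicted by a drifter-calibrated :class:`DriftModel` (the default
    analysis path); ``"direct-field-subtraction"`` subtracts the sampled
    flow velocity itself (the conventional satellite-ice-vector correction,
    which assumes the flow field is unbiased).
    """
    if mode == "none":
        return Track(track.animal_id, track.data.copy(),
                     dict(track.attributes))
    if flow is None:
        raise ValueError(f"mode {mode!r} requires a flow field")
    if mode == "wind-bcrw":
        if model is None:
            raise ValueError("wind-bcrw correction requires a DriftModel")
        return correct_track(track, flow, model, clamp=clamp)
    if mode == "direct-field-subtraction":
        t = pd.DatetimeIndex(track.data["timestamp"])
        th = (t - pd.Timestamp(flow.origin_time)).total_seconds() \
            .to_numpy() / 3600.0
        xy = track.xy
        dt_h = np.diff(t.asi8) / 3.6e12
        u, v = flow.sample(th[:-1], xy[:-1, 0], xy[:-1, 1], clamp=clamp)
        drift = np.column_stack([u, v]) * dt_h[:, None]
        corrected = np.diff(xy, axis=0) - drift
        pos = np.vstack([xy[0], xy[0] + np.cumsum(corrected, axis=0)])
        out = pd.DataFrame({
            "timestamp": t, "x_km": pos[:, 0], "y_km": pos[:, 1],
            "drift_dx_km": np.concatenate(([0.0], drift[:, 0])),
            "drift_dy_km": np.concatenate(([0.0], drift[:, 1]))})
        return Track(track.animal_id, out, dict(track.attributes))
    raise ValueError(f"unknown correction mode {mode!r}")


def uncorrect_track(corrected: Track) -> Track:
    """Invert :func:`correct_track` using the stored drift displacements."""
    df = corrected.data
    disp = np.diff(df[["x_km", "y_km"]].to_numpy(), axis=0)
    drift = df[["drift_dx_km", "drift_dy_km"]].to_numpy()[1:]
    pos = np.vstack([df[["x_km", "y_km"]].to_numpy()[0],
                     df[["x_km", "y_km"]].to_numpy()[0]
                     + np.cumsum(disp + drift, axis=0)])
    out = pd.DataFrame({"timestamp": df["timestamp"], "x_km": pos[:, 0],
                        "y_km": pos[:, 1]})
    return Track(corrected.animal_id, out, dict(corrected.attributes))
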