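"""Four-state menotactic hidden Markov model for sea-ice telemetry.

States (fixed order): ``D`` (stationary drift on the ice), ``ARS``
(area-restricted search), ``OL``/``OR`` (olfactory search biased left/right of
the wind). Step speeds follow a gamma distribution in mean/sd parameterization;
turning angles follow a von Mises distribution whose mean trades off
directional persistence against bias relative to an external flow:

* drift: bias toward the tidal-current direction, weighted by tidal speed,
  and a tidal-speed slope on the mean step;
* ARS: zero mean turn (plain correlated random walk);
* olfactory search: menotactic bias at an unknown angle relative to wind,
  parameterized by a downwind coefficient ``alpha1`` and a crosswind
  coefficient ``alpha2`` (90 deg anti-clockwise of the wind); the left and
  right states mirror each other and share all other parameters.

Transition probabilities are multinomial-logit functions of environmental
covariates; the two olfactory states share transition parameters. Fitting is
by direct numerical maximization of the pooled forward log-likelihood across
animals (all coefficients shared among individuals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e

STATES = ("D", "ARS", "OL", "OR")
N_STATES = 4
D, ARS, OL, OR = 0, 1, 2, 3

#: floor applied to gamma step means so the density stays proper when the
#: identity-link mean goes non-positive
STEP_MEAN_FLOOR = 1e-6

LOG_2PI = np.log(2.0 * np.pi)

# ---------------------------------------------------------------------------
# emission densities


def gamma_logpdf_meansd(x, mu, sigma):
    """Gamma log-density in mean/sd parameterization (shape=mu^2/sd^2)."""
    x = np.asarray(x, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), STEP_MEAN_FLOOR)
    sigma = np.asarray(sigma, dtype=float)
    shape = mu ** 2 / sigma ** 2
    rate = mu / sigma ** 2
    return (shape * np.log(rate) - gammaln(shape)
            + (shape - 1.0) * np.log(x) - rate * x)


def vonmises_logpdf(phi, mu, kappa):
    """von Mises log-density; log I0 via the exponentially scaled Bessel."""
    phi = np.asarray(phi, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    log_i0 = np.log(i0e(kappa)) + kappa
    return kappa * np.cos(phi - mu) - LOG_2PI - log_i0


def bias_turn_mean(psi, a1, a2):
    """Mean turning angle of a BCRW biased relative to a stimulus.

    ``psi`` is the stimulus direction relative to the previous bearing;
    ``a1`` weights bias along the stimulus, ``a2`` bias 90 deg anti-clockwise
    of it; the constant 1 is the directional-persistence weight.
    """
    num = a1 * np.sin(psi) + a2 * np.cos(psi)
    den = 1.0 + a1 * np.cos(psi) - a2 * np.sin(psi)
    return np.arctan2(num, den)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class EmissionParams:
    """Natural-scale emission parameters (speeds km/h, angles rad).

    ``mu_step``/``sigma_step``/``kappa`` are length-3 arrays over the merged
    state groups (D, ARS, O); the two olfactory states share them.
    """

    mu_step: np.ndarray
    sigma_step: np.ndarray
    kappa: np.ndarray
    beta_tide: float = 0.0      # tidal-speed slope on D's mean step
    alpha1_drift: float = 0.0   # along-tide bias weight of D (times r_tide)
    alpha1_olf: float = 0.0     # downwind bias of olfactory search
    alpha2_olf: float = 0.0     # crosswind (90 deg ccw) bias of O(L)

    def __post_init__(self):
        self.mu_step = np.asarray(self.mu_step, dtype=float)
        self.sigma_step = np.asarray(self.sigma_step, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.sigma_step <= 0) or np.any(self.kappa <= 0):
            raise ValueError("sigma and kappa must be positive")
        if not (self.mu_step[0] < self.mu_step[1] < self.mu_step[2]):
            raise ValueError("step means must satisfy mu_D < mu_ARS < mu_O")


# Shared off-diagonal transition slots; OL/OR share all transition parameters
# and transitions into olfactory search are split evenly between OL and OR.
TRANSITION_SLOTS = (
    "D->ARS", "D->O", "ARS->D", "ARS->O", "O->D", "O->ARS", "O->O'",
)
_SLOT_CELLS = {
    0: [(D, ARS)],
    1: [(D, OL), (D, OR)],
    2: [(ARS, D)],
    3: [(ARS, OL), (ARS, OR)],
    4: [(OL, D), (OR, D)],
    5: [(OL, ARS), (OR, ARS)],
    6: [(OL, OR), (OR, OL)],
}

COSINOR_PERIOD = 24.0


def _form_ncols(form):
    return {"linear": 1, "quadratic": 2, "cosinor": 2}[form]


@dataclass
class TransitionModel:
    """Multinomial-logit transition model with shared olfactory parameters.

    ``covariates`` is a sequence of (name, form) pairs with
    form in {linear, quadratic, cosinor}; ``coef`` has shape
    (7 slots, 1 + design columns). Linear/quadratic covariates are
    standardized using ``centers`` (name -> (mean, sd)).
    """

    covariates: tuple = ()
    coef: np.ndarray | None = None
    centers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.covariates = tuple((str(n), str(f)) for n, f in self.covariates)
        if self.coef is None:
            self.coef = np.zeros((len(TRANSITION_SLOTS), self.n_columns))
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(TRANSITION_SLOTS), self.n_columns):
            raise ValueError("transition coefficient shape mismatch")

    @property
    def n_columns(self):
        return 1 + sum(_form_ncols(f) for _, f in self.covariates)

    def design(self, cov: pd.DataFrame) -> np.ndarray:
        """Design matrix (T, n_columns) from a covariate frame."""
        T = len(cov)
        cols = [np.ones(T)]
        for name, form in self.covariates:
            v = np.asarray(cov[name], dtype=float)
            if form == "cosinor":
                w = 2.0 * np.pi * v / COSINOR_PERIOD
                cols += [np.cos(w), np.sin(w)]
            else:
                m, s = self.centers.get(name, (0.0, 1.0))
                z = (v - m) / s
                cols.append(z)
                if form == "quadratic":
                    cols.append(z ** 2)
        return np.column_stack(cols)


def eta_matrix(slot_values) -> np.ndarray:
    """Expand 7 shared slot values into a 4x4 log-odds matrix (diagonal 0)."""
    slot_values = np.asarray(slot_values, dtype=float)
    eta = np.zeros(slot_values.shape[:-1] + (N_STATES, N_STATES))
    for s, cells in _SLOT_CELLS.items():
        for (i, j) in cells:
            eta[..., i, j] = slot_values[..., s]
    return eta


def softmax_rows(eta):
    """Row-wise multinomial logit with the diagonal as reference (eta_ii=0)."""
    e = np.exp(eta - eta.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def transition_matrices(X, coef) -> np.ndarray:
    """Stack of 4x4 transition matrices for design rows X (T, p)."""
    slots = X @ np.asarray(coef, dtype=float).T   # (T, 7)
    return softmax_rows(eta_matrix(slots))


def transition_matrix(covariate_row, model: TransitionModel) -> np.ndarray:
    """Single transition matrix at one covariate row (mapping or Series)."""
    cov = pd.DataFrame([dict(covariate_row)]) if covariate_row else \
        pd.DataFrame(index=[0])
    X = model.design(cov)
    return transition_matrices(X, model.coef)[0]


@dataclass
class HMMSpec:
    """Full model specification: emissions + covariate-linked transitions."""

    emission: EmissionParams
    transition: TransitionModel = field(default_factory=TransitionModel)


# ---------------------------------------------------------------------------
# state-level emission helpers (Eq.-style case functions)


def step_mean(state, r_tide, params: EmissionParams):
    """Mean step speed: D gets the tidal slope, all others their intercept."""
    r_tide = np.asarray(r_tide, dtype=float)
    group = {D: 0, ARS: 1, OL: 2, OR: 2}[state]
    mu = np.full_like(r_tide, params.mu_step[group], dtype=float)
    if state == D:
        mu = params.mu_step[0] + params.beta_tide * r_tide
    return np.maximum(mu, STEP_MEAN_FLOOR)


def turn_mean(state, psi_wind, psi_tide, r_tide, params: EmissionParams):
    """Mean turning angle by state.

    Drift is biased along the tide with weight ``alpha1_drift * r_tide``;
    ARS has zero mean turn; the olfactory states are menotactic relative to
    wind, with OR the mirror image of OL (crosswind sign flipped).
    """
    if state == ARS:
        return np.zeros(np.broadcast(np.asarray(psi_wind),
                                     np.asarray(r_tide)).shape)
    if state == D:
        w = params.alpha1_drift * np.asarray(r_tide, dtype=float)
        return bias_turn_mean(psi_tide, w, 0.0)
    a2 = params.alpha2_olf if state == OL else -params.alpha2_olf
    return bias_turn_mean(psi_wind, params.alpha1_olf, a2)


def emission_logdensity(l, phi, state, covariates, spec: HMMSpec):
    """Log emission density of one observation in one state.

    ``covariates`` needs keys psi_wind, psi_tide, r_tide. A missing turning
    angle (NaN; the first step of a bout) contributes the step term only.
    """
    p = spec.emission
    group = {D: 0, ARS: 1, OL: 2, OR: 2}[state]
    mu = step_mean(state, covariates.get("r_tide", 0.0), p)
    out = gamma_logpdf_meansd(l, mu, p.sigma_step[group])
    if phi is not None and np.all(np.isfinite(phi)):
        mphi = turn_mean(state, covariates.get("psi_wind", 0.0),
                         covariates.get("psi_tide", 0.0),
                         covariates.get("r_tide", 0.0), p)
        out = out + vonmises_logpdf(phi, mphi, p.kappa[group])
    return out


_STATE_GROUP = {D: 0, ARS: 1, OL: 2, OR: 2}


def emission_logcolumn(state, speed, turn0, have_turn, psi_wind, psi_tide,
                       r_tide, params: EmissionParams) -> np.ndarray:
    """Log emission density of every step in one state (turn NaNs already
    replaced by 0 in ``turn0`` and masked via ``have_turn``)."""
    group = _STATE_GROUP[state]
    mu = step_mean(state, r_tide, params)
    lb = gamma_logpdf_meansd(speed, mu, params.sigma_step[group])
    mphi = turn_mean(state, psi_wind, psi_tide, r_tide, params)
    lturn = vonmises_logpdf(turn0, mphi, params.kappa[group])
    return lb + np.where(have_turn, lturn, 0.0)


def emission_logmatrix(speed, turn, psi_wind, psi_tide, r_tide,
                       params: EmissionParams) -> np.ndarray:
    """(T, 4) log emission densities; NaN turns contribute step terms only."""
    speed = np.asarray(speed, dtype=float)
    T = speed.shape[0]
    logB = np.empty((T, N_STATES))
    have_turn = np.isfinite(np.asarray(turn, dtype=float))
    turn0 = np.where(have_turn, turn, 0.0)
    for state in range(N_STATES):
        logB[:, state] = emission_logcolumn(state, speed, turn0, have_turn,
                                            psi_wind, psi_tide, r_tide,
                                            params)
    return logB


# ---------------------------------------------------------------------------
# numba kernels: scaled forward recursion and Viterbi


@njit(cache=False)
def _forward_ll(logB, Gammas, delta):
    T, N = logB.shape
    m = logB[0].max()
    phi = np.empty(N)
    for j in range(N):
        phi[j] = delta[j] * np.exp(logB[0, j] - m)
    c = phi.sum()
    ll = np.log(c) + m
    for j in range(N):
        phi[j] /= c
    for t in range(1, T):
        v = np.zeros(N)
        for i in range(N):
            pi = phi[i]
            for j in range(N):
                v[j] += pi * Gammas[t, i, j]
        m = logB[t].max()
        c = 0.0
        for j in range(N):
            v[j] *= np.exp(logB[t, j] - m)
            c += v[j]
        ll += np.log(c) + m
        for j in range(N):
            phi[j] = v[j] / c
    return ll


@njit(cache=False)
def _viterbi_path(logB, logGammas, logdelta):
    T, N = logB.shape
    score = np.empty((T, N))
    back = np.zeros((T, N), dtype=np.int64)
    for j in range(N):
        score[0, j] = logdelta[j] + logB[0, j]
    for t in range(1, T):
        for j in range(N):
            best = -np.inf
            arg = 0
            for i in range(N):
                s = score[t - 1, i] + logGammas[t, i, j]
                if s > best:
                    best = s
                    arg = i
            score[t, j] = best + logB[t, j]
            back[t, j] = arg
    path = np.zeros(T, dtype=np.int64)
    best = -np.inf
    for j in range(N):
        if score[T - 1, j] > best:
            best = score[T - 1, j]
            path[T - 1] = j
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def forward_loglik_matrices(logB, Gammas, delta) -> float:
    """Scaled-forward log-likelihood from precomputed matrices.

    ``Gammas[t]`` governs the transition into step ``t`` (evaluated at the
    covariates of step t's starting fix); ``Gammas[0]`` is unused beyond the
    initial distribution ``delta``.
    """
    return float(_forward_ll(np.ascontiguousarray(logB, dtype=float),
                             np.ascontiguousarray(Gammas, dtype=float),
                             np.ascontiguousarray(delta, dtype=float)))


# ---------------------------------------------------------------------------
# stationary distribution


def stationary_distribution(Gamma) -> np.ndarray:
    """Solve pi Gamma = pi, sum(pi) = 1 for a row-stochastic matrix."""
    Gamma = np.asarray(Gamma, dtype=float)
    n = Gamma.shape[0]
    A = np.vstack([Gamma.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-8):
        raise ValueError("chain appears reducible or periodic; no proper "
                         "stationary distribution")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# data preparation

_REQUIRED = ("speed_kmh", "turn_rad", "psi_wind", "psi_tide", "r_tide")


def _series_frame(series) -> pd.DataFrame:
    df = getattr(series, "data", series)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"step series missing columns {missing}")
    return df


def _prepare(series_list, spec: HMMSpec):
    """Per-bout (logB, Gammas, delta) triples for the likelihood kernels."""
    out = []
    for series in series_list:
        df = _series_frame(series)
        logB = emission_logmatrix(df["speed_kmh"].to_numpy(),
                                  df["turn_rad"].to_numpy(),
                                  df["psi_wind"].to_numpy(),
                                  df["psi_tide"].to_numpy(),
                                  df["r_tide"].to_numpy(), spec.emission)
        X = spec.transition.design(df)
        Gammas = transition_matrices(X, spec.transition.coef)
        delta = stationary_distribution(Gammas[0])
        out.append((logB, Gammas, delta))
    return out


def forward_loglik(series, spec: HMMSpec) -> float:
    """Pooled forward log-likelihood of one or several step series."""
    if not isinstance(series, (list, tuple)):
        series = [series]
    return sum(forward_loglik_matrices(*triple)
               for triple in _prepare(series, spec))


def viterbi(series, spec_or_fit) -> np.ndarray:
    """Most likely state path (global decoding) for one step series."""
    spec = getattr(spec_or_fit, "spec", spec_or_fit)
    (logB, Gammas, delta), = _prepare([series], spec)
    with np.errstate(divide="ignore"):
        lG = np.log(Gammas)
        ld = np.log(delta)
    return np.asarray(_viterbi_path(np.ascontiguousarray(logB),
                                    np.ascontiguousarray(lG),
                                    np.ascontiguousarray(ld)))


def decode(series, spec_or_fit):
    """Return a copy of the step series with Viterbi-decoded ``state`` and
    ``state_name`` columns appended (ready to write as CSV)."""
    path = viterbi(series, spec_or_fit)
    df = _series_frame(series).copy()
    df["state"] = path
    df["state_name"] = [STATES[s] for s in path]
    if hasattr(series, "data"):
        out = type(series)(series.animal_id, df,
                           dict(getattr(series, "attributes", {})))
        return out
    return df


# ---------------------------------------------------------------------------
# working-scale parameter vector

# emission block: [log mu_D, log d1, log d2, beta_tide, log sigma (3),
#                  log kappa (3), alpha1_drift, alpha1_olf, alpha2_olf]
N_EMISSION_WORKING = 13


def pack_params(spec: HMMSpec) -> np.ndarray:
    e = spec.emission
    mu = e.mu_step
    w = [np.log(mu[0]), np.log(mu[1] - mu[0]), np.log(mu[2] - mu[1]),
         e.beta_tide, *np.log(e.sigma_step), *np.log(e.kappa),
         e.alpha1_drift, e.alpha1_olf, e.alpha2_olf]
    return np.concatenate([w, spec.transition.coef.ravel()])


def unpack_params(theta, template: HMMSpec) -> HMMSpec:
    theta = np.asarray(theta, dtype=float)
    w = theta[:N_EMISSION_WORKING]
    mu_d = np.exp(w[0])
    mu = np.array([mu_d, mu_d + np.exp(w[1]), mu_d + np.exp(w[1]) + np.exp(w[2])])
    em = EmissionParams(mu_step=mu, sigma_step=np.exp(w[4:7]),
                        kappa=np.exp(w[7:10]), beta_tide=w[3],
                        alpha1_drift=w[10], alpha1_olf=w[11], alpha2_olf=w[12])
    tm = template.transition
    coef = theta[N_EMISSION_WORKING:].reshape(tm.coef.shape)
    return HMMSpec(em, replace(tm, coef=coef))


def param_names(spec: HMMSpec):
    names = ["log_mu_D", "log_dmu_ARS", "log_dmu_O", "beta_tide",
             "log_sigma_D", "log_sigma_ARS", "log_sigma_O",
             "log_kappa_D", "log_kappa_ARS", "log_kappa_O",
             "alpha1_drift", "alpha1_olf", "alpha2_olf"]
    cols = ["icpt"]
    for name, form in spec.transition.covariates:
        if form == "cosinor":
            cols += [f"{name}_cos", f"{name}_sin"]
        elif form == "quadratic":
            cols += [name, f"{name}^2"]
        else:
            cols.append(name)
    for slot in TRANSITION_SLOTS:
        for c in cols:
            names.append(f"gamma[{slot}]:{c}")
    return names


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HMMFit:
    spec: HMMSpec
    theta: np.ndarray
    loglik: float
    n_params: int
    aic: float
    converged: bool
    n_steps: int
    names: list
    cov: np.ndarray | None = None
    message: str = ""

    def summary(self) -> pd.DataFrame:
        rows = {"name": self.names, "working_value": list(self.theta)}
        df = pd.DataFrame(rows)
        if self.cov is not None:
            df["working_se"] = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return df

    def to_json(self, path):
        e = self.spec.emission
        obj = {
            "states": list(STATES),
            "emission": {
                "mu_step_kmh": e.mu_step.tolist(),
                "sigma_step_kmh": e.sigma_step.tolist(),
                "kappa": e.kappa.tolist(),
                "beta_tide": e.beta_tide,
                "alpha1_drift": e.alpha1_drift,
                "alpha1_olf": e.alpha1_olf,
                "alpha2_olf": e.alpha2_olf,
            },
            "transition": {
                "covariates": list(map(list, self.spec.transition.covariates)),
                "coef": self.spec.transition.coef.tolist(),
                "centers": {k: list(v)
                            for k, v in self.spec.transition.centers.items()},
            },
            "loglik": self.loglik, "aic": self.aic,
            "n_params": self.n_params, "converged": self.converged,
            "working_names": self.names,
            "working_values": self.theta.tolist(),
            "covariance": None if self.cov is None else self.cov.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def default_start(series_list, transition_covariates=(), centers=None
                  ) -> HMMSpec:
    """Data-driven starting values: step-speed quantiles, mild persistence."""
    speeds = np.concatenate([_series_frame(s)["speed_kmh"].to_numpy()
                             for s in series_list])
    q = np.maximum(np.quantile(speeds, [0.2, 0.5, 0.85]), 1e-3)
    q = np.maximum.accumulate(q) + np.array([0.0, 1e-3, 2e-3])
    em = EmissionParams(mu_step=q, sigma_step=np.maximum(q * 0.6, 1e-3),
                        kappa=np.array([1.5, 1.0, 1.5]), beta_tide=0.1,
                        alpha1_drift=0.5, alpha1_olf=0.05, alpha2_olf=0.2)
    tm = TransitionModel(covariates=tuple(transition_covariates),
                         centers=centers or {})
    tm.coef[:, 0] = -1.8
    return HMMSpec(em, tm)


def compute_centers(series_list, transition_covariates) -> dict:
    """Mean/sd standardization constants for linear/quadratic covariates."""
    centers = {}
    for name, form in transition_covariates:
        if form == "cosinor":
            continue
        v = np.concatenate([np.asarray(_series_frame(s)[name], dtype=float)
                            for s in series_list])
        sd = float(np.std(v))
        centers[name] = (float(np.mean(v)), sd if sd > 0 else 1.0)
    return centers


#: states whose emission column depends on each emission working parameter
#: (the cumulative-increment mean construction couples mu_D into all means)
_EMISSION_AFFECTS = (
    (D, ARS, OL, OR),  # log mu_D
    (ARS, OL, OR),     # log dmu_ARS
    (OL, OR),          # log dmu_O
    (D,),              # beta_tide
    (D,), (ARS,), (OL, OR),     # log sigma
    (D,), (ARS,), (OL, OR),     # log kappa
    (D,),              # alpha1_drift
    (OL, OR),          # alpha1_olf
    (OL, OR),          # alpha2_olf
)

_BAD = 1e12


def _safe_delta(Gamma):
    try:
        return stationary_distribution(Gamma)
    except ValueError:
        return np.full(Gamma.shape[0], 1.0 / Gamma.shape[0])


class _Objective:
    """Pooled negative log-likelihood with a structured finite-difference
    gradient: emission partials rebuild only the affected emission columns,
    transition partials only the multinomial-logit matrices."""

    def __init__(self, series_list, template: HMMSpec, fd_step=1e-6):
        frames = [_series_frame(s) for s in series_list]
        self.obs = []
        for df in frames:
            speed = df["speed_kmh"].to_numpy(dtype=float)
            turn = df["turn_rad"].to_numpy(dtype=float)
            have = np.isfinite(turn)
            self.obs.append((speed, np.where(have, turn, 0.0), have,
                             df["psi_wind"].to_numpy(dtype=float),
                             df["psi_tide"].to_numpy(dtype=float),
                             df["r_tide"].to_numpy(dtype=float)))
        self.designs = [template.transition.design(df) for df in frames]
        self.template = template
        self.coef_shape = template.transition.coef.shape
        self.fd_step = fd_step

    # -- component computation -------------------------------------------
    def _logB(self, em, k):
        speed, turn0, have, pw, pt, rt = self.obs[k]
        logB = np.empty((len(speed), N_STATES))
        for state in range(N_STATES):
            logB[:, state] = emission_logcolumn(state, speed, turn0, have,
                                                pw, pt, rt, em)
        return logB

    def _value(self, theta, want_components=False):
        try:
            spec = unpack_params(theta, self.template)
        except (ValueError, FloatingPointError, OverflowError):
            return (_BAD, None) if want_components else _BAD
        total = 0.0
        comps = []
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for k, X in enumerate(self.designs):
                logB = self._logB(spec.emission, k)
                Gammas = transition_matrices(X, spec.transition.coef)
                if not (np.all(np.isfinite(logB))
                        and np.all(np.isfinite(Gammas))):
                    return (_BAD, None) if want_components else _BAD
                delta = _safe_delta(Gammas[0])
                total += forward_loglik_matrices(logB, Gammas, delta)
                comps.append((logB, Gammas, delta))
        if not np.isfinite(total):
            return (_BAD, None) if want_components else _BAD
        return (-total, (spec, comps)) if want_components else -total

    def __call__(self, theta):
        return self._value(theta)

    # -- value + gradient -------------------------------------------------
    def value_and_grad(self, theta):
        f0, state = self._value(theta, want_components=True)
        if state is None:
            return _BAD, np.zeros_like(theta)
        spec, comps = state
        h = self.fd_step
        grad = np.zeros_like(theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            # emission block: perturb, rebuild only the affected columns
            for i, states in enumerate(_EMISSION_AFFECTS):
                tp = theta.copy()
                tp[i] += h
                try:
                    em_p = unpack_params(tp, self.template).emission
                except (ValueError, FloatingPointError, OverflowError):
                    tp[i] -= 2 * h
                    em_p = unpack_params(tp, self.template).emission
                fp = 0.0
                for k, (logB, Gammas, delta) in enumerate(comps):
                    speed, turn0, have, pw, pt, rt = self.obs[k]
                    logB_p = logB.copy()
                    for s in states:
                        logB_p[:, s] = emission_logcolumn(s, speed, turn0,
                                                          have, pw, pt, rt,
                                                          em_p)
                    fp += forward_loglik_matrices(logB_p, Gammas, delta)
                grad[i] = (-fp - f0) / (tp[i] - theta[i])
            # transition block: perturb one coefficient, rebuild Gammas only
            n_em = N_EMISSION_WORKING
            coef0 = spec.transition.coef
            for j in range(theta.size - n_em):
                r, c = divmod(j, self.coef_shape[1])
                coef_p = coef0.copy()
                coef_p[r, c] += h
                fp = 0.0
                for k, (logB, _, _) in enumerate(comps):
                    Gammas_p = transition_matrices(self.designs[k], coef_p)
                    delta_p = _safe_delta(Gammas_p[0])
                    fp += forward_loglik_matrices(logB, Gammas_p, delta_p)
                grad[n_em + j] = (-fp - f0) / h
        if not np.all(np.isfinite(grad)):
            grad = np.where(np.isfinite(grad), grad, 0.0)
        return f0, grad


def _nll_factory(series_list, template: HMMSpec):
    return _Objective(series_list, template)


def numerical_hessian(fun, x, step=1e-5):
    """Central-difference Hessian (symmetrized)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step ** 2
            else:
                fpp = fun(x + ei + ej); fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej); fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
    return H


def transition_columns(covariates):
    """Slices of the transition design columns, keyed by covariate name
    (the intercept is column 0)."""
    out = {}
    col = 1
    for name, form in covariates:
        n = _form_ncols(form)
        out[(name, form)] = slice(col, col + n)
        col += n
    return out


def warm_start_spec(base: "HMMSpec | HMMFit", covariates) -> HMMSpec:
    """Starting spec for a new covariate set, reusing a previous fit.

    Emission parameters are copied; transition intercepts and the columns of
    covariates shared with the base model are carried over, new covariates
    start at zero.
    """
    spec = getattr(base, "spec", base)
    covariates = tuple(covariates)
    tm = TransitionModel(covariates)
    tm.coef[:, 0] = spec.transition.coef[:, 0]
    old = transition_columns(spec.transition.covariates)
    new = transition_columns(covariates)
    for key, sl in new.items():
        if key in old:
            tm.coef[:, sl] = spec.transition.coef[:, old[key]]
    tm.centers = dict(spec.transition.centers)
    return HMMSpec(spec.emission, tm)


def fit_hmm(series_list, transition_covariates=(), *, start: HMMSpec = None,
            n_restarts=3, seed=0, maxiter=500, ftol=None,
            compute_hessian=True, hessian_step=1e-4) -> HMMFit:
    """Maximum-likelihood fit pooled over animals.

    Quasi-Newton (L-BFGS-B) on the working scale with seeded jittered
    restarts; the step-mean ordering mu_D < mu_ARS < mu_O is enforced by the
    cumulative-increment working transform. Covariance is the inverse of the
    central-difference Hessian (optional; costly on large data).
    """
    if not isinstance(series_list, (list, tuple)):
        series_list = [series_list]
    transition_covariates = tuple(transition_covariates)
    centers = compute_centers(series_list, transition_covariates)
    if start is None:
        start = default_start(series_list, transition_covariates, centers)
    else:
        tm = start.transition
        if tm.covariates != transition_covariates:
            start = HMMSpec(start.emission,
                            TransitionModel(transition_covariates))
    # standardization is always data-driven and consistent across warm starts
    start.transition.centers = centers
    template = start
    nll = _nll_factory(series_list, template)
    theta0 = pack_params(start)
    rng = np.random.default_rng(seed)

    options = {"maxiter": maxiter, "maxfun": 10 ** 6}
    if ftol is not None:
        options["ftol"] = ftol
    best = None
    for k in range(max(1, int(n_restarts))):
        t0 = theta0 if k == 0 else theta0 + rng.normal(0, 0.25, theta0.shape)
        res = minimize(nll.value_and_grad, t0, jac=True, method="L-BFGS-B",
                       options=options)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    loglik = -best.fun
    # alpha2 -> -alpha2 is an exact label swap of O(L)/O(R); canonicalize to
    # alpha2 >= 0 so O(L) is genuinely the left-of-wind state
    if theta[12] < 0:
        theta = theta.copy()
        theta[12] = -theta[12]
    spec = unpack_params(theta, template)
    k_free = len(theta)
    cov = None
    if compute_hessian:
        H = numerical_hessian(nll, theta, step=hessian_step)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
    n_steps = sum(len(_series_frame(s)) for s in series_list)
    return HMMFit(spec=spec, theta=theta, loglik=loglik, n_params=k_free,
                  aic=2 * k_free - 2 * loglik, converged=bool(best.success),
                  n_steps=n_steps, names=param_names(template), cov=cov,
                  message=str(best.message))


# ---------------------------------------------------------------------------
# derived quantities


def scaled_attraction(alpha1, alpha2) -> float:
    """Scaled magnitude of attraction M* in [0, 1).

    M* -> 0 is a plain correlated random walk; M* -> 1 a fully biased walk.
    """
    m = np.hypot(alpha1, alpha2)
    return float(m / (1.0 + m))


def attraction_angle(alpha1, alpha2, degrees=False) -> float:
    """Angle of attraction relative to the stimulus, atan2(alpha2, alpha1)."""
    if alpha1 == 0.0 and alpha2 == 0.0:
        raise ValueError("attraction angle undefined for zero bias")
    th = float(np.arctan2(alpha2, alpha1))
    return float(np.degrees(th)) if degrees else th


def stationary_with_ci(fit: HMMFit, covariate_grid: pd.DataFrame,
                       level=0.95, fd_step=1e-5) -> pd.DataFrame:
    """Stationary state probabilities over a covariate grid with delta-method
    confidence intervals propagated through the stationary solve."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    template = fit.spec
    rows = []
    for _, row in covariate_grid.iterrows():
        cov = row.to_dict()

        def pi_of(theta):
            spec = unpack_params(theta, template)
            return stationary_distribution(transition_matrix(cov,
                                                             spec.transition))

        pi = pi_of(fit.theta)
        if fit.cov is not None:
            J = np.empty((N_STATES, len(fit.theta)))
            for i in range(len(fit.theta)):
                e = np.zeros(len(fit.theta)); e[i] = fd_step
                J[:, i] = (pi_of(fit.theta + e) - pi_of(fit.theta - e)) \
                    / (2 * fd_step)
            var = np.einsum("ij,jk,ik->i", J, fit.cov, J)
            se = np.sqrt(np.clip(var, 0, None))
        else:
            se = np.full(N_STATES, np.nan)
        for s, name in enumerate(STATES):
            rows.append({**cov, "state": name, "prob": pi[s],
                         "lo": max(pi[s] - z * se[s], 0.0),
                         "hi": min(pi[s] + z * se[s], 1.0)})
    return pd.DataFrame(rows)
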