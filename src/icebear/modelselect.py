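"""Transition-covariate selection: functional forms, collinearity filtering
and bidirectional stepwise AIC.

Candidate covariates enter the transition model in a restricted set of
forms — linear or quadratic for smoothly varying drivers (ordinal date, sun
altitude, wind speed, solar radiation, ice concentration), a cosinor pair
(cos, sin of 2*pi*hour/24) for hour of day, linear otherwise. The form for
each covariate is chosen by fitting single-covariate models and taking the
lowest AIC; covariates correlated above a threshold compete and only the
lower-AIC member is retained; the final set is chosen by forward and
backward stepwise AIC, which are run independently and compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hmm import HMMFit, fit_hmm, warm_start_spec

#: allowed functional forms per covariate; anything absent is linear-only
FORM_RULES = {
    "ordinal_date": ("linear", "quadratic"),
    "sun_altitude": ("linear", "quadratic"),
    "wind_speed": ("linear", "quadratic"),
    "solar_radiation": ("linear", "quadratic"),
    "ice_conc": ("linear", "quadratic"),
    "hour": ("cosinor",),
}

#: AIC margin inside which the simpler model wins
AIC_TIE = 2.0


def allowed_forms(name: str) -> tuple:
    return FORM_RULES.get(name, ("linear",))


@dataclass
class CovariateCatalog:
    """Candidate covariates, their allowed forms and pairwise correlations."""

    names: tuple
    forms: dict = field(default_factory=dict)
    correlations: pd.DataFrame | None = None

    def __post_init__(self):
        self.names = tuple(self.names)
        for n in self.names:
            self.forms.setdefault(n, allowed_forms(n))


def covariate_correlations(series_list, names) -> pd.DataFrame:
    """Pairwise Pearson correlations over the pooled analysis rows."""
    pooled = pd.concat([s.data[list(names)] for s in series_list],
                       ignore_index=True)
    return pooled.corr()


class FormSelection(NamedTuple):
    covariate: str
    chosen_form: str
    aic_by_form: dict
    fits: dict


def select_form(series_list, covariate, *, fit_kwargs=None) -> FormSelection:
    """Choose the functional form of one covariate by single-covariate AIC.

    Fits one HMM per allowed form (the covariate alone on the transitions)
    and returns the form with the lowest AIC; a failed fit is skipped with a
    warning entry in ``aic_by_form``.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_restarts", 1)
    fit_kwargs.setdefault("compute_hessian", False)
    aics, fits = {}, {}
    for form in allowed_forms(covariate):
        try:
            f = fit_hmm(series_list, [(covariate, form)], **fit_kwargs)
            aics[form] = f.aic
            fits[form] = f
        except Exception as exc:
            aics[form] = np.inf
            fits[form] = exc
    ok = {k: v for k, v in aics.items() if np.isfinite(v)}
    if not ok:
        raise RuntimeError(f"all form fits failed for {covariate!r}")
    chosen = min(ok, key=ok.get)
    return FormSelection(covariate, chosen, aics, fits)


def filter_collinear(correlations: pd.DataFrame, aic_by_covariate: dict,
                     threshold=0.5) -> list:
    """Within each pair correlated above ``threshold``, keep the lower-AIC
    covariate.

    Pairs are resolved greedily in descending |r| so that chained
    correlations (a~b~c) give a deterministic, documented outcome.
    """
    names = [n for n in correlations.columns if n in aic_by_covariate]
    retained = set(names)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = abs(float(correlations.loc[a, b]))
            if r > threshold:
                pairs.append((r, a, b))
    for _, a, b in sorted(pairs, reverse=True):
        if a in retained and b in retained:
            drop = a if aic_by_covariate[a] > aic_by_covariate[b] else b
            retained.discard(drop)
    return [n for n in names if n in retained]


class StepwiseResult(NamedTuple):
    forward_set: tuple
    backward_set: tuple
    agree: bool
    trace: pd.DataFrame
    fit: HMMFit


def _fit_with(series_list, covs, base_fit, fit_kwargs):
    """Fit with a covariate set, warm-started from a previous fit's spec."""
    kw = dict(fit_kwargs)
    start = warm_start_spec(base_fit, covs) if base_fit is not None else None
    return fit_hmm(series_list, tuple(covs), start=start, **kw)


def stepwise_aic(series_list, candidates: Sequence, *, fit_kwargs=None
                 ) -> StepwiseResult:
    """Forward and backward stepwise AIC over transition covariates.

    ``candidates`` is a sequence of (name, form) pairs (forms already chosen
    via :func:`select_form`). Both directions are run and reported; ties
    within ``AIC_TIE`` are resolved toward the simpler model. The returned
    fit is the forward top model (refit if the backward set differs and wins
    on AIC).
    """
    candidates = [tuple(c) for c in candidates]
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_restarts", 1)
    fit_kwargs.setdefault("compute_hessian", False)
    trace = []

    base = _fit_with(series_list, [], None, fit_kwargs)
    trace.append({"direction": "forward", "action": "start",
                  "covariate": "", "aic": base.aic})

    # forward pass
    current, cur_fit = [], base
    while True:
        remaining = [c for c in candidates if c not in current]
        if not remaining:
            break
        trials = []
        for c in remaining:
            f = _fit_with(series_list, current + [c], cur_fit, fit_kwargs)
            trials.append((f.aic, c, f))
            trace.append({"direction": "forward", "action": "try-add",
                          "covariate": c[0], "aic": f.aic})
        aic, c, f = min(trials, key=lambda t: t[0])
        if aic < cur_fit.aic - AIC_TIE:
            current.append(c)
            cur_fit = f
            trace.append({"direction": "forward", "action": "add",
                          "covariate": c[0], "aic": aic})
        else:
            break
    forward_set, forward_fit = tuple(current), cur_fit

    # backward pass
    full = _fit_with(series_list, candidates, base, fit_kwargs) \
        if candidates else base
    trace.append({"direction": "backward", "action": "start",
                  "covariate": "", "aic": full.aic})
    current, cur_fit = list(candidates), full
    while current:
        trials = []
        for c in current:
            reduced = [d for d in current if d != c]
            f = _fit_with(series_list, reduced, cur_fit, fit_kwargs)
            trials.append((f.aic, c, f))
            trace.append({"direction": "backward", "action": "try-drop",
                          "covariate": c[0], "aic": f.aic})
        aic, c, f = min(trials, key=lambda t: t[0])
        if aic < cur_fit.aic + AIC_TIE:  # simpler model wins ties
            current.remove(c)
            cur_fit = f
            trace.append({"direction": "backward", "action": "drop",
                          "covariate": c[0], "aic": aic})
        else:
            break
    backward_set, backward_fit = tuple(current), cur_fit

    agree = set(forward_set) == set(backward_set)
    final = forward_fit if forward_fit.aic <= backward_fit.aic else \
        backward_fit
    return StepwiseResult(forward_set, backward_set, agree,
                          pd.DataFrame(trace), final)
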