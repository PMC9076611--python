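"""Dose-response models for saturation photoincorporation data.

Three model families cover the binding behaviors seen in the labeling
experiments:

* ``hyperbolic`` -- one-site isotherm ``PI_max x / (EC50 + x)``,
* ``hill`` -- cooperative isotherm ``PI_max x^n / (K_A^n + x^n)``,
* ``two_site`` -- a tight hyperbolic site plus a much weaker component,
  modeled as a linear term ``weak_slope * x`` (a dual-hyperbola variant is
  available via ``weak_model="hyperbolic"``).

Fits are (weighted) least squares via scipy's trust-region solver with
asymptotic standard errors from the Jacobian; an optional seeded bootstrap
is provided for small-sample uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["BindingFit", "eval_model", "fit_binding"]

_PARAM_NAMES = {
    "hyperbolic": ("pi_max", "ec50"),
    "hill": ("pi_max", "k_a", "n"),
    "two_site": ("pi_max", "ec50", "weak_slope"),
    "two_site_hyperbolic": ("pi_max", "ec50", "weak_max", "weak_ec50"),
}


def _as_tuple(model_kind: str, params) -> tuple[float, ...]:
    names = _PARAM_NAMES[model_kind]
    if isinstance(params, dict):
        return tuple(float(params[name]) for name in names)
    return tuple(float(v) for v in params)


def eval_model(model_kind: str, params, concentration):
    """Evaluate a dose-response model at the given concentrations (µM)."""
    x = np.asarray(concentration, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    if model_kind == "hyperbolic":
        pi_max, ec50 = _as_tuple(model_kind, params)
        return pi_max * x / (ec50 + x)
    if model_kind == "hill":
        pi_max, k_a, n = _as_tuple(model_kind, params)
        with np.errstate(divide="ignore"):
            xn = np.power(x, n)
        return pi_max * xn / (k_a**n + xn)
    if model_kind == "two_site":
        pi_max, ec50, weak_slope = _as_tuple(model_kind, params)
        return pi_max * x / (ec50 + x) + weak_slope * x
    if model_kind == "two_site_hyperbolic":
        pi_max, ec50, weak_max, weak_ec50 = _as_tuple(model_kind, params)
        return pi_max * x / (ec50 + x) + weak_max * x / (weak_ec50 + x)
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class BindingFit:
    """Result of a dose-response fit."""

    model_kind: str
    params: dict[str, float]
    ses: dict[str, float]
    rss: float
    converged: bool
    n_obs: int
    fixed: dict[str, float] = field(default_factory=dict)

    def predict(self, concentration):
        return eval_model(self.model_kind, {**self.params, **self.fixed}, concentration)


def _default_init(model_kind: str, x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    pi_max = float(np.max(y)) if np.max(y) > 0 else 1.0
    half = pi_max / 2.0
    positive = x[x > 0]
    # concentration nearest half-max response
    if positive.size:
        idx = int(np.argmin(np.abs(y - half)))
        ec50 = float(x[idx]) if x[idx] > 0 else float(np.median(positive))
    else:
        ec50 = 1.0
    init = {"pi_max": pi_max, "ec50": ec50, "k_a": ec50, "n": 2.0}
    if model_kind == "two_site":
        init["weak_slope"] = max(1e-6, 0.1 * pi_max / max(float(np.max(x)), 1.0))
    if model_kind == "two_site_hyperbolic":
        init["weak_max"] = 0.5 * pi_max
        init["weak_ec50"] = 10.0 * ec50
    return init


def _default_bounds(model_kind: str, x: np.ndarray, y: np.ndarray) -> dict[str, tuple[float, float]]:
    positive = x[x > 0]
    lo_c = float(np.min(positive)) / 10.0 if positive.size else 1e-6
    hi_c = 10.0 * float(np.max(x)) if np.max(x) > 0 else 1e6
    ymax = float(np.max(y)) if np.max(y) > 0 else 1.0
    bounds = {
        "pi_max": (1e-12, 10.0 * ymax),
        "ec50": (lo_c, hi_c),
        "k_a": (lo_c, hi_c),
        "n": (0.3, 6.0),
        "weak_slope": (0.0, np.inf),
        "weak_max": (0.0, 10.0 * ymax),
        "weak_ec50": (lo_c, 100.0 * hi_c),
    }
    return bounds


def fit_binding(
    dataset: pd.DataFrame,
    model_kind: str,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    fix: dict[str, float] | None = None,
    weights=None,
    bootstrap: int = 0,
    seed: int = 0,
) -> BindingFit:
    """Fit a dose-response model to a (concentration_uM, signal) table.

    Parameters listed in ``fix`` are held constant (e.g. ``fix={"n": 1.0}``
    turns the Hill model into the hyperbolic one). Requires at least
    (number of free parameters + 1) distinct concentrations. If
    ``bootstrap`` > 0, parameter standard errors are replaced by the SD over
    that many seeded case resamples.
    """
    if model_kind not in _PARAM_NAMES:
        raise ValueError(f"unknown model kind {model_kind!r}")
    x = dataset["concentration_uM"].to_numpy(dtype=float)
    y = dataset["signal"].to_numpy(dtype=float)
    fix = dict(fix or {})
    names = [p for p in _PARAM_NAMES[model_kind] if p not in fix]
    n_distinct = np.unique(x).size
    if n_distinct < len(names) + 1:
        raise ValueError(
            f"underdetermined design: {model_kind} with {len(names)} free parameters "
            f"needs >= {len(names) + 1} distinct concentrations, got {n_distinct}"
        )
    init_all = {**_default_init(model_kind, x, y), **(init or {})}
    bounds_all = {**_default_bounds(model_kind, x, y), **(bounds or {})}
    p0 = [np.clip(init_all[p], *bounds_all[p]) for p in names]
    lo = [bounds_all[p][0] for p in names]
    hi = [bounds_all[p][1] for p in names]
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))

    def f(xv, *theta):
        return eval_model(model_kind, {**dict(zip(names, theta)), **fix}, xv)

    def solve(xv, yv):
        return curve_fit(
            f, xv, yv, p0=p0, bounds=(lo, hi), sigma=sigma, maxfev=20000, full_output=True
        )

    try:
        popt, pcov, _info, _msg, ier = solve(x, y)
        converged = bool(1 <= ier <= 4) and np.all(np.isfinite(popt))
    except RuntimeError:
        popt = np.array(p0)
        pcov = np.full((len(names), len(names)), np.nan)
        converged = False

    resid = y - f(x, *popt)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        ses = dict(zip(names, np.sqrt(np.diag(pcov))))

    if bootstrap > 0 and converged:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(bootstrap):
            idx = rng.integers(0, x.size, size=x.size)
            try:
                bopt, *_ = curve_fit(f, x[idx], y[idx], p0=popt, bounds=(lo, hi), maxfev=20000)
                draws.append(bopt)
            except RuntimeError:
                continue
        if draws:
            ses = dict(zip(names, np.std(np.asarray(draws), axis=0, ddof=1)))

    return BindingFit(
        model_kind=model_kind,
        params=dict(zip(names, (float(v) for v in popt))),
        ses={k: float(v) for k, v in ses.items()},
        rss=rss,
        converged=converged,
        n_obs=int(x.size),
        fixed=fix,
    )
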