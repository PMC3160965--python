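"""Photophysical reaction schemes of GFP, tdEos and Dronpa and ensemble-decay fitting.

Under continuous illumination the ensemble fluorescence of a photoswitchable
probe decays through a small linear reaction network:

* GFP: first-order photobleaching, ``F -> B`` with rate ``k_b``.
* tdEos: green-to-red photoswitching followed by bleaching of the red state,
  ``G -(k_ps)-> R -(k_b)-> B``; the observed signal under 561 nm illumination
  is the red-state occupancy ``R(t)``.
* Dronpa: reversible photoactivation ``I <-> A`` (rates ``k_pa``, ``k_pda``)
  with irreversible bleaching from the active state, ``A -(k_b)-> B``; the
  observed signal is the active-state occupancy ``A(t)``.

All forward models are closed-form solutions of the corresponding linear ODEs,
peak-normalized on the evaluation grid because measured ensemble traces are
normalized to their maximum. Degenerate (equal-rate) cases use their analytic
``t·exp`` limits rather than numerical perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecayTrace",
    "TdEosKinetics",
    "DronpaKinetics",
    "FitResult",
    "RateSeries",
    "model_gfp",
    "model_tdeos",
    "model_dronpa",
    "fit_decay",
    "compare_models",
    "rate_vs_intensity",
]

_SCHEMES = ("gfp", "tdeos", "dronpa")


@dataclass
class DecayTrace:
    """Normalized ensemble fluorescence under continuous illumination."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    intensity: float = 1.0  # illumination power, arbitrary units
    wavelength_nm: float = float("nan")
    probe: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.size < 5:
            raise ValueError("decay trace needs at least 5 points")
        if self.time_s.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)) or np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be finite and non-negative")


@dataclass
class TdEosKinetics:
    k_ps: float
    k_b: float
    g0: float = 0.5
    r0: float = 0.5

    def __post_init__(self) -> None:
        if self.k_ps < 0 or self.k_b < 0:
            raise ValueError("rate constants must be non-negative")
        if self.g0 < 0 or self.r0 < 0:
            raise ValueError("initial fractions must be non-negative")


@dataclass
class DronpaKinetics:
    k_pa: float
    k_pda: float
    k_b: float
    i0: float = 0.0
    a0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_pa, self.k_pda, self.k_b) < 0:
            raise ValueError("rate constants must be non-negative")
        if self.i0 < 0 or self.a0 < 0:
            raise ValueError("initial fractions must be non-negative")


@dataclass
class FitResult:
    scheme: str
    params: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_params: int

    @property
    def n_points(self) -> int:
        return int(self.residuals.size)


@dataclass
class RateSeries:
    """Fitted rate constants across illumination intensities with an OLS line."""

    intensities: np.ndarray
    rates: np.ndarray
    rate_stderr: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    intercept_stderr: float = field(init=False)
    nonzero_intercept: bool = field(init=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.rate_stderr = np.asarray(self.rate_stderr, dtype=float)
        if self.intensities.size < 3:
            raise ValueError("regression needs at least 3 intensity levels")
        if np.unique(self.intensities).size < 2:
            raise ValueError("degenerate regression: a single intensity value")
        res = stats.linregress(self.intensities, self.rates)
        self.slope = float(res.slope)
        self.intercept = float(res.intercept)
        self.intercept_stderr = float(res.intercept_stderr)
        self.nonzero_intercept = bool(
            self.intercept > 2.0 * self.intercept_stderr and self.intercept > 0
        )


def _normalize_peak(y: np.ndarray) -> np.ndarray:
    peak = float(np.max(y))
    if peak <= 0:
        # all-dark model (e.g. r0 = 0, k_ps = 0): return as-is, avoids 0/0
        return y
    return y / peak


def model_gfp(t: np.ndarray, k_b: float) -> np.ndarray:
    """Single-exponential photobleaching decay, peak-normalized."""
    if k_b < 0:
        raise ValueError("k_b must be non-negative")
    t = np.asarray(t, dtype=float)
    return _normalize_peak(np.exp(-k_b * t))


def tdeos_red_state(t: np.ndarray, p: TdEosKinetics) -> np.ndarray:
    """Un-normalized red-state occupancy R(t) of G -> R -> B.

    R(t) = r0·e^{-k_b t} + g0·k_ps·(e^{-k_ps t} − e^{-k_b t})/(k_b − k_ps),
    with the k_ps = k_b limit  r0·e^{-kt} + g0·k·t·e^{-kt}.
    """
    t = np.asarray(t, dtype=float)
    if math.isclose(p.k_ps, p.k_b, rel_tol=1e-12, abs_tol=1e-15):
        k = 0.5 * (p.k_ps + p.k_b)
        return (p.r0 + p.g0 * k * t) * np.exp(-k * t)
    transfer = p.g0 * p.k_ps * (np.exp(-p.k_ps * t) - np.exp(-p.k_b * t)) / (p.k_b - p.k_ps)
    return p.r0 * np.exp(-p.k_b * t) + transfer


def model_tdeos(t: np.ndarray, p: TdEosKinetics) -> np.ndarray:
    """Peak-normalized tdEos red fluorescence."""
    return _normalize_peak(tdeos_red_state(t, p))


def dronpa_states(t: np.ndarray, p: DronpaKinetics) -> tuple[np.ndarray, np.ndarray]:
    """Un-normalized (I(t), A(t)) for  I <->(k_pa, k_pda) A -(k_b)-> B.

    The 2×2 system  d/dt [I, A] = M [I, A]  with
    M = [[-k_pa, k_pda], [k_pa, -(k_pda + k_b)]]  is solved by
    eigen-decomposition; the discriminant (trace² − 4·det) is non-negative for
    non-negative rates, so both eigenvalues are real.
    """
    t = np.asarray(t, dtype=float)
    s = p.k_pa + p.k_pda + p.k_b  # -trace
    det = p.k_pa * p.k_b
    disc = s * s - 4.0 * det
    disc = max(disc, 0.0)
    root = math.sqrt(disc)
    lam1 = 0.5 * (-s + root)  # slow eigenvalue (closer to 0)
    lam2 = 0.5 * (-s - root)
    if root < 1e-12 * max(s, 1.0):
        # defective/near-degenerate case: fall back to t·exp form via expm-like
        # limit. A'' term: use first-order expansion around lam1 == lam2.
        lam = 0.5 * (lam1 + lam2)
        e = np.exp(lam * t)
        i_t = e * (p.i0 + t * (-p.k_pa * p.i0 + p.k_pda * p.a0 - lam * p.i0))
        a_t = e * (p.a0 + t * (p.k_pa * p.i0 - (p.k_pda + p.k_b) * p.a0 - lam * p.a0))
        return i_t, a_t
    # project initial state onto eigenvectors; for eigenvalue lam the
    # eigenvector satisfies (−k_pa − lam)·v_I + k_pda·v_A = 0.
    e1 = np.exp(lam1 * t)
    e2 = np.exp(lam2 * t)
    # Solve [v1 v2] c = x0 with v_k = (k_pda, lam_k + k_pa) (valid also when
    # k_pda = 0 since then lam_k + k_pa != 0 for one of them; handle k_pda = 0
    # by the decoupled closed form).
    if p.k_pda == 0.0:
        # I decays alone; A is the tdEos-type cascade I -(k_pa)-> A -(k_b)-> B
        i_t = p.i0 * np.exp(-p.k_pa * t)
        a_t = tdeos_red_state(t, TdEosKinetics(k_ps=p.k_pa, k_b=p.k_b, g0=p.i0, r0=p.a0))
        return i_t, a_t
    v1 = np.array([p.k_pda, lam1 + p.k_pa])
    v2 = np.array([p.k_pda, lam2 + p.k_pa])
    denom = v1[0] * v2[1] - v2[0] * v1[1]
    c1 = (p.i0 * v2[1] - p.a0 * v2[0]) / denom
    c2 = (p.a0 * v1[0] - p.i0 * v1[1]) / denom
    i_t = c1 * v1[0] * e1 + c2 * v2[0] * e2
    a_t = c1 * v1[1] * e1 + c2 * v2[1] * e2
    return i_t, a_t


def model_dronpa(t: np.ndarray, p: DronpaKinetics) -> np.ndarray:
    """Peak-normalized Dronpa active-state fluorescence."""
    _, a_t = dronpa_states(t, p)
    return _normalize_peak(a_t)


# ---------------------------------------------------------------------------
# fitting


def _model_curve(scheme: str, t: np.ndarray, theta: np.ndarray, fixed: dict) -> np.ndarray:
    # theta[0] is a free amplitude multiplying the peak-normalized forward
    # model: it absorbs the bias introduced by re-normalizing a noisy trace
    # to its (noisy) maximum, which would otherwise pin the model to 1 at an
    # arbitrary sample and distort nested-model comparisons.
    amp = theta[0]
    if scheme == "gfp":
        return amp * model_gfp(t, theta[1])
    if scheme == "tdeos":
        if "g0" in fixed:
            g0, r0 = fixed["g0"], fixed["r0"]
        else:
            g0, r0 = theta[3], 1.0 - theta[3]
        return amp * model_tdeos(t, TdEosKinetics(k_ps=theta[1], k_b=theta[2], g0=g0, r0=r0))
    if scheme == "dronpa":
        if "a0" in fixed:
            a0, i0 = fixed["a0"], fixed["i0"]
        else:
            a0, i0 = theta[4], 1.0 - theta[4]
        return amp * model_dronpa(
            t, DronpaKinetics(k_pa=theta[1], k_pda=theta[2], k_b=theta[3], i0=i0, a0=a0)
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def _param_layout(scheme: str, fix_fractions: bool) -> list[str]:
    if scheme == "gfp":
        return ["amp", "k_b"]
    if scheme == "tdeos":
        return ["amp", "k_ps", "k_b"] if fix_fractions else ["amp", "k_ps", "k_b", "g0"]
    if scheme == "dronpa":
        return (
            ["amp", "k_pa", "k_pda", "k_b"]
            if fix_fractions
            else ["amp", "k_pa", "k_pda", "k_b", "a0"]
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def fit_decay(
    trace: DecayTrace,
    scheme: str,
    initial_guess: dict[str, float] | None = None,
    fixed_fractions: dict[str, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Nonlinear least squares of a photophysical forward model to a trace.

    Parameters are bounded below by 0 (fractions additionally by 1 above).
    ``fixed_fractions`` pins the initial state fractions (e.g. ``{"g0": 0.5,
    "r0": 0.5}`` for tdEos or ``{"a0": 1.0, "i0": 0.0}`` for Dronpa); when
    absent, the occupied fraction is fitted as one free parameter (the
    complement goes to the other state), which removes the normalization
    scale degeneracy.

    The optimizer is restarted ``n_restarts`` times from random multiplicative
    perturbations of the initial guess; the best residual sum wins, ties going
    to the first. Non-convergence is reported via ``converged``, not raised.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    fixed = dict(fixed_fractions or {})
    names = _param_layout(scheme, bool(fixed))
    t, y = trace.time_s, trace.fluorescence
    if t.size <= len(names):
        raise ValueError("fewer data points than free parameters")

    guess = {"amp": 1.0, "k_ps": 0.1, "k_b": 0.1, "k_pa": 0.1, "k_pda": 0.1,
             "g0": 0.5, "a0": 0.9}
    guess.update(initial_guess or {})
    theta0 = np.array([guess[n] for n in names], dtype=float)
    lo = np.zeros(len(names))
    hi = np.array([1.0 if n in ("g0", "a0") else np.inf for n in names])
    theta0 = np.clip(theta0, lo + 1e-12, np.where(np.isinf(hi), theta0 + 1.0, hi - 1e-12))

    def resid(theta: np.ndarray) -> np.ndarray:
        return _model_curve(scheme, t, theta, fixed) - y

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        start = theta0 if restart == 0 else np.clip(
            theta0 * rng.lognormal(0.0, 0.5, size=theta0.size), lo + 1e-12, hi - 1e-12
        )
        try:
            sol = optimize.least_squares(resid, start, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1] - 1e-15:
            best = (sol, rss)
    if best is None:
        raise RuntimeError("all optimizer restarts failed")
    sol, rss = best

    # standard errors from the Gauss-Newton covariance (J^T J)^-1 * s^2
    dof = max(t.size - len(names), 1)
    s2 = rss / dof
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)

    params = {n: float(v) for n, v in zip(names, sol.x)}
    if scheme == "tdeos" and "g0" in params:
        params["r0"] = 1.0 - params["g0"]
    if scheme == "dronpa" and "a0" in params:
        params["i0"] = 1.0 - params["a0"]
    params.update(fixed)
    return FitResult(
        scheme=scheme,
        params=params,
        stderr={n: float(v) for n, v in zip(names, se)},
        residuals=sol.fun.copy(),
        rss=rss,
        converged=bool(sol.success),
        n_params=len(names),
    )


@dataclass
class ModelComparison:
    scheme: str
    rss_single: float
    rss_full: float
    f_stat: float
    p_value: float
    df_num: int
    df_den: int


def compare_models(
    trace: DecayTrace,
    scheme: str,
    initial_guess: dict[str, float] | None = None,
    seed: int = 0,
) -> ModelComparison:
    """Nested F-test: single-exponential bleaching vs the full multi-rate scheme.

    The single-exponential model is nested in both the tdEos scheme
    (k_ps = 0, r0 = 1) and the Dronpa scheme (k_pa = k_pda = 0, a0 = 1), so the
    classical extra-sum-of-squares F-test applies.
    """
    if scheme == "gfp":
        raise ValueError("compare_models contrasts a multi-rate scheme against gfp")
    single = fit_decay(trace, "gfp", initial_guess={"k_b": 0.1}, seed=seed)
    full = fit_decay(trace, scheme, initial_guess=initial_guess, seed=seed)
    n = trace.time_s.size
    p1, p2 = single.n_params, full.n_params
    df_num, df_den = p2 - p1, n - p2
    rss1, rss2 = single.rss, full.rss
    if rss2 <= 0 or df_den <= 0:
        f = np.inf if rss1 > rss2 else 0.0
        p = 0.0 if rss1 > rss2 else 1.0
    else:
        f = ((rss1 - rss2) / df_num) / (rss2 / df_den)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, df_num, df_den))
    return ModelComparison(scheme, rss1, rss2, float(f), p, df_num, df_den)


def rate_vs_intensity(
    fits: list[tuple[float, FitResult]], rate_name: str
) -> RateSeries:
    """OLS regression of a fitted rate constant on illumination intensity.

    A non-zero intercept (> 2 standard errors above zero) is flagged; for
    photoswitching rates it indicates spontaneous (illumination-independent)
    activation.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 intensity levels")
    intens = np.array([i for i, _ in fits], dtype=float)
    rates = np.array([f.params[rate_name] for _, f in fits], dtype=float)
    se = np.array([f.stderr.get(rate_name, np.nan) for _, f in fits], dtype=float)
    return RateSeries(intens, rates, se)
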