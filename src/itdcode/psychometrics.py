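"""Nonlinear mixed-effects (NLME) psychometric model of perceived laterality.

The lateralization data are continuous responses in [-1, 1] collected over
a balanced ITD x sensation-level grid from several listeners.  The model
is a sigmoid in (normalized) ITD whose amplitude depends on (normalized)
sound intensity and on the listener's pure-tone-average threshold (PTA),
with per-listener random effects for the perceived midline and for the
maximal extent of lateralization:

    response = A / (1 + exp(-eta)) - 0.5                       ("ratio" form)
    A   = ay2 * PTA + ay1 * intensity + by0_listener
    eta = ax2 * intensity + ax1 * (ITD - ax0 - bx0_listener)

``by0`` is Gaussian across listeners with a free mean (the population
lateralization amplitude) and ``bx0`` is mean-zero Gaussian.  The printed
equation is typographically ambiguous about the scope of the numerator;
the literal reading above is the default, and the alternative
``A * (logistic - 0.5)`` reading is available as ``form="scaled"``.

Fitting is penalized nonlinear least squares over fixed and random effects
jointly, alternating with variance-component updates (a Lindstrom-Bates
style approximation of the marginal likelihood); standard errors come from
the marginal generalized-least-squares information, and the residual
degrees of freedom follow the grouped-data convention
``df = n_obs - n_listeners - n_within_fixed_effects`` (PTA, constant
within listener, is a between-listener effect, so 4 of the 5 fixed effects
count as within).

ITD and intensity are z-scored before fitting; PTA enters in raw dB HL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .stimuli import ParameterError

__all__ = [
    "FixedEffects",
    "NormalizationSpec",
    "NLMEFit",
    "ConvergenceError",
    "TRIAL_COLUMNS",
    "load_trials",
    "normalize_predictors",
    "predict_laterality",
    "fit_nlme",
    "variance_explained",
    "wald_table",
    "criterion_correlation",
    "fisher_power",
    "monte_carlo_power",
]

#: Canonical trial schema; the external-data adapter maps onto these.
TRIAL_COLUMNS = ["listener_id", "experiment", "itd_us", "sl_db", "pta_db",
                 "response"]

FIXED_NAMES = ("ax0", "ax1", "ax2", "ay1", "ay2")
#: Effects whose predictor varies within a listener (ITD / intensity terms).
WITHIN_EFFECTS = ("ax0", "ax1", "ax2", "ay1")


class ConvergenceError(RuntimeError):
    """NLME optimization failed after bounded restarts; carries the trace."""

    def __init__(self, msg: str, trace: list):
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class FixedEffects:
    """Population-level coefficients of the lateralization model."""

    ax0: float = 0.0   # midline intercept, normalized-ITD units
    ax1: float = 1.0   # laterality slope per normalized ITD
    ax2: float = 0.0   # slope change per normalized intensity
    ay1: float = 0.0   # amplitude change per normalized intensity
    ay2: float = 0.0   # amplitude change per dB PTA

    def as_array(self) -> np.ndarray:
        return np.array([self.ax0, self.ax1, self.ax2, self.ay1, self.ay2])

    @classmethod
    def from_array(cls, a) -> "FixedEffects":
        return cls(*map(float, a))


@dataclass(frozen=True)
class NormalizationSpec:
    """Z-scoring constants for the ITD and intensity predictors."""

    itd_mean: float
    itd_sd: float
    intensity_mean: float
    intensity_sd: float

    def normalize_itd(self, itd_us):
        return (np.asarray(itd_us, float) - self.itd_mean) / self.itd_sd

    def normalize_intensity(self, sl_db):
        return (np.asarray(sl_db, float) - self.intensity_mean) / self.intensity_sd

    def denormalize_itd(self, z):
        return np.asarray(z, float) * self.itd_sd + self.itd_mean

    def denormalize_intensity(self, z):
        return np.asarray(z, float) * self.intensity_sd + self.intensity_mean


def load_trials(path, mapping: dict[str, str] | str | None = None) -> pd.DataFrame:
    """Read a trial CSV, optionally mapping foreign column names.

    ``mapping`` maps canonical names to the file's column names (a dict or
    a path to a YAML file with such a dict) — the adapter for externally
    deposited datasets.  Missing ``experiment`` defaults to ``"flat"``.
    """
    df = pd.read_csv(path)
    if mapping is not None:
        if not isinstance(mapping, dict):
            import yaml
            with open(mapping) as fh:
                mapping = yaml.safe_load(fh)
        df = df.rename(columns={v: k for k, v in mapping.items()})
    if "experiment" not in df.columns:
        df["experiment"] = "flat"
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"trial table missing columns {missing}")
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def normalize_predictors(trials: pd.DataFrame
                         ) -> tuple[pd.DataFrame, NormalizationSpec]:
    """Z-score ITD and intensity columns (zero mean, unit variance).

    Returns a copy with ``itd_norm`` / ``intensity_norm`` columns and the
    :class:`NormalizationSpec` to undo or reapply the transform.
    """
    out = trials.copy()
    stats_ = {}
    for col, key in (("itd_us", "itd"), ("sl_db", "intensity")):
        x = out[col].to_numpy(float)
        mu, sd = x.mean(), x.std()   # population sd -> unit variance exactly
        if sd == 0:
            raise ParameterError(f"column {col} has zero variance")
        stats_[key] = (mu, sd)
    spec = NormalizationSpec(*stats_["itd"], *stats_["intensity"])
    out["itd_norm"] = spec.normalize_itd(out["itd_us"])
    out["intensity_norm"] = spec.normalize_intensity(out["sl_db"])
    return out, spec


def predict_laterality(fixed: FixedEffects, bx0, by0, pta_db, itd_norm,
                       intensity_norm, form: str = "ratio"):
    """Model-predicted laterality for (arrays of) normalized predictors.

    ``by0`` is the listener's full amplitude term (population mean plus
    random deviation); ``bx0`` the listener's midline shift.  ``form``
    selects the reading of the printed equation: ``"ratio"`` (default,
    literal) or ``"scaled"`` (amplitude multiplies the centred logistic).
    """
    itd_norm = np.asarray(itd_norm, float)
    a_amp = (fixed.ay2 * np.asarray(pta_db, float)
             + fixed.ay1 * np.asarray(intensity_norm, float) + by0)
    eta = (fixed.ax2 * np.asarray(intensity_norm, float)
           + fixed.ax1 * (itd_norm - fixed.ax0 - bx0))
    s = special.expit(eta)
    if form == "ratio":
        return a_amp * s - 0.5
    if form == "scaled":
        return a_amp * (s - 0.5)
    raise ParameterError(f"unknown model form {form!r}")


# --------------------------------------------------------------------------
# Fitting


@dataclass
class NLMEFit:
    """Fitted NLME model: point estimates, inference table inputs, fit stats."""

    fixed: FixedEffects
    amplitude_mean: float                  # population mean of by0
    random: pd.DataFrame                   # index: listener_id; bx0, by0
    sigma_x0: float
    sigma_y0: float
    sigma_resid: float
    se: np.ndarray                         # per fixed effect, FIXED_NAMES order
    t: np.ndarray
    p: np.ndarray
    df: int
    var_explained: float
    form: str
    norm_spec: NormalizationSpec
    n_obs: int
    n_listeners: int
    converged: bool = True
    trace: list = field(default_factory=list)

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        """Predictions including each listener's random effects."""
        df = trials.copy()
        if "itd_norm" not in df.columns:
            df["itd_norm"] = self.norm_spec.normalize_itd(df["itd_us"])
            df["intensity_norm"] = self.norm_spec.normalize_intensity(df["sl_db"])
        bx0 = df["listener_id"].map(self.random["bx0"]).to_numpy(float)
        by0 = df["listener_id"].map(self.random["by0"]).to_numpy(float)
        return predict_laterality(self.fixed, bx0, by0,
                                  df["pta_db"].to_numpy(float),
                                  df["itd_norm"].to_numpy(float),
                                  df["intensity_norm"].to_numpy(float),
                                  self.form)


def residual_df(n_obs: int, n_listeners: int,
                n_within: int = len(WITHIN_EFFECTS)) -> int:
    """Grouped-data residual df: n_obs - n_listeners - n_within_effects.

    Depends only on the design; PTA counts as a between-listener effect
    and is excluded from ``n_within``.
    """
    return n_obs - n_listeners - n_within


def _model_arrays(trials: pd.DataFrame):
    df, spec = normalize_predictors(trials)
    listeners = np.sort(df["listener_id"].unique())
    li = pd.Categorical(df["listener_id"], categories=listeners).codes
    return (df["response"].to_numpy(float), df["itd_norm"].to_numpy(float),
            df["intensity_norm"].to_numpy(float),
            df["pta_db"].to_numpy(float), np.asarray(li), listeners, spec)


def _predict_raw(p, itdn, intn, pta, li, n_l, form):
    ax0, ax1, ax2, ay1, ay2, mu = p[:6]
    bx0 = p[6:6 + n_l][li]
    dy0 = p[6 + n_l:6 + 2 * n_l][li]
    a_amp = ay2 * pta + ay1 * intn + mu + dy0
    eta = ax2 * intn + ax1 * (itdn - ax0 - bx0)
    s = special.expit(eta)
    if form == "ratio":
        return a_amp * s - 0.5, a_amp, s
    return a_amp * (s - 0.5), a_amp, s


def _jacobian(p, itdn, intn, pta, li, n_l, form):
    """Analytic d(pred)/d(params): columns [6 fixed, bx0 block, dy0 block]."""
    ax0, ax1, ax2, ay1, ay2, mu = p[:6]
    bx0 = p[6:6 + n_l][li]
    dy0 = p[6 + n_l:6 + 2 * n_l][li]
    a_amp = ay2 * pta + ay1 * intn + mu + dy0
    u = itdn - ax0 - bx0
    s = special.expit(ax2 * intn + ax1 * u)
    ds = a_amp * s * (1.0 - s)
    sa = s if form == "ratio" else s - 0.5
    n = itdn.size
    J = np.zeros((n, 6 + 2 * n_l))
    J[:, 0] = -ax1 * ds
    J[:, 1] = u * ds
    J[:, 2] = intn * ds
    J[:, 3] = intn * sa
    J[:, 4] = pta * sa
    J[:, 5] = sa
    rows = np.arange(n)
    J[rows, 6 + li] = -ax1 * ds
    J[rows, 6 + n_l + li] = sa
    return J


def _initial_params(y, itdn, intn, pta, li, n_l, form, seed):
    """Coarse start: scan ax1, solve the amplitude by linear least squares."""
    best = None
    for ax1 in (0.5, 1.0, 2.0, 3.0, 5.0):
        s = special.expit(ax1 * itdn)
        basis = s if form == "ratio" else s - 0.5
        target = y + 0.5 if form == "ratio" else y
        denom = float(basis @ basis)
        amp = float(basis @ target) / denom if denom > 0 else 1.0
        ss = float(np.sum((target - amp * basis) ** 2))
        if best is None or ss < best[0]:
            best = (ss, ax1, amp)
    _, ax1, amp = best
    p0 = np.zeros(6 + 2 * n_l)
    p0[1], p0[5] = ax1, amp
    return p0


def fit_nlme(trials: pd.DataFrame, start: FixedEffects | None = None,
             seed: int = 0, form: str = "ratio", n_outer: int = 4,
             max_restarts: int = 3) -> NLMEFit:
    """Fit the lateralization NLME model to a trial table.

    Penalized nonlinear least squares over the five fixed effects, the
    amplitude mean and the per-listener random effects, with the random
    effects ridge-penalized by the current variance components; variance
    components are re-estimated between optimizer passes (EM-flavoured
    Lindstrom-Bates approximation).  Deterministic given data and start.

    Raises :class:`ConvergenceError` after ``max_restarts`` jittered
    restarts, carrying the optimization trace.
    """
    y, itdn, intn, pta, li, listeners, spec = _model_arrays(trials)
    n_l = listeners.size
    n = y.size
    if n_l < 2:
        raise ParameterError("need at least 2 listeners")
    counts = np.bincount(li)
    if counts.min() < 20:
        raise ParameterError("need at least 20 trials per listener")
    pta_by_listener = np.array(
        [pta[li == i][0] for i in range(n_l)])

    p0 = _initial_params(y, itdn, intn, pta, li, n_l, form, seed)
    if start is not None:
        p0[:5] = start.as_array()

    rng = np.random.default_rng(seed)
    trace: list = []
    result = None
    for attempt in range(max_restarts + 1):
        p = p0.copy()
        if attempt:
            p[:6] += rng.normal(0, 0.2, 6) * np.maximum(np.abs(p[:6]), 0.5)
        sig, sx, sy = 0.2, 0.2, 0.2
        ok = True
        for outer in range(n_outer):
            wx = min(sig / max(sx, 1e-9), 1e6)
            wy = min(sig / max(sy, 1e-9), 1e6)

            def resid(pv):
                pred, _, _ = _predict_raw(pv, itdn, intn, pta, li, n_l, form)
                return np.concatenate([
                    pred - y, wx * pv[6:6 + n_l], wy * pv[6 + n_l:6 + 2 * n_l]])

            def jac(pv):
                J = _jacobian(pv, itdn, intn, pta, li, n_l, form)
                P = np.zeros((2 * n_l, J.shape[1]))
                P[np.arange(n_l), 6 + np.arange(n_l)] = wx
                P[n_l + np.arange(n_l), 6 + n_l + np.arange(n_l)] = wy
                return np.vstack([J, P])

            sol = optimize.least_squares(resid, p, jac=jac, method="lm",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                         max_nfev=4000)
            p = sol.x
            pred, _, _ = _predict_raw(p, itdn, intn, pta, li, n_l, form)
            ss = float(np.sum((pred - y) ** 2))
            sig = max(np.sqrt(ss / max(n - 6, 1)), 1e-9)
            bx = p[6:6 + n_l]
            dy = p[6 + n_l:6 + 2 * n_l]
            # EM-style variance update incl. conditional (posterior) spread
            J = _jacobian(p, itdn, intn, pta, li, n_l, form)
            pv_x = pv_y = 0.0
            for i in range(n_l):
                m = li == i
                Zi = J[np.ix_(m, [6 + i, 6 + n_l + i])]
                G = Zi.T @ Zi + sig**2 * np.diag(
                    [1 / max(sx, 1e-9) ** 2, 1 / max(sy, 1e-9) ** 2])
                C = sig**2 * np.linalg.inv(G)
                pv_x += C[0, 0]
                pv_y += C[1, 1]
            sx = max(np.sqrt(np.mean(bx**2) + pv_x / n_l), 1e-9)
            sy = max(np.sqrt(np.mean(dy**2) + pv_y / n_l), 1e-9)
            trace.append({"attempt": attempt, "outer": outer, "ss": ss,
                          "sigma": sig, "sigma_x0": sx, "sigma_y0": sy,
                          "status": sol.status})
            if not sol.success and sol.status <= 0:
                ok = False
                break
        if ok and np.all(np.isfinite(p)):
            result = (p, sig, sx, sy)
            break
    if result is None:
        raise ConvergenceError("NLME fit did not converge", trace)

    p, sig, sx, sy = result
    fixed = FixedEffects.from_array(p[:5])
    mu = float(p[5])
    bx = p[6:6 + n_l]
    dy = p[6 + n_l:6 + 2 * n_l]
    random = pd.DataFrame({"bx0": bx, "by0": mu + dy},
                          index=pd.Index(listeners, name="listener_id"))

    # Marginal (GLS) information for the fixed-effect standard errors:
    # V_i = sigma^2 I + Z_i D Z_i'; info = sum_i X_i' V_i^-1 X_i.
    J = _jacobian(p, itdn, intn, pta, li, n_l, form)
    D = np.diag([sx**2, sy**2])
    info = np.zeros((6, 6))
    for i in range(n_l):
        m = li == i
        Xi = J[m][:, :6]
        Zi = J[np.ix_(m, [6 + i, 6 + n_l + i])]
        # Woodbury: V^-1 = (I - Z (sig^2 D^-1 + Z'Z)^-1 Z') / sig^2
        core = np.linalg.inv(sig**2 * np.linalg.inv(D) + Zi.T @ Zi)
        XtVX = (Xi.T @ Xi - (Xi.T @ Zi) @ core @ (Zi.T @ Xi)) / sig**2
        info += XtVX
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov)[:5], 0.0))
    df = residual_df(n, n_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, fixed.as_array() / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    pval[tval == 0] = 1.0

    pred, _, _ = _predict_raw(p, itdn, intn, pta, li, n_l, form)
    ve = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)

    return NLMEFit(fixed=fixed, amplitude_mean=mu, random=random,
                   sigma_x0=float(sx), sigma_y0=float(sy),
                   sigma_resid=float(sig), se=se, t=tval, p=pval, df=df,
                   var_explained=float(ve), form=form, norm_spec=spec,
                   n_obs=n, n_listeners=n_l, converged=True, trace=trace)


def variance_explained(fit: NLMEFit, trials: pd.DataFrame) -> float:
    """1 - SS_resid / SS_total with random-effect-aware predictions."""
    y = trials["response"].to_numpy(float)
    pred = fit.predict(trials)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ParameterError("responses have zero variance")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def wald_table(fit: NLMEFit) -> pd.DataFrame:
    """Per-effect inference table: estimate, SE, t, two-sided p, df."""
    return pd.DataFrame({
        "estimate": fit.fixed.as_array(),
        "se": fit.se,
        "t": fit.t,
        "p": fit.p,
        "df": fit.df,
    }, index=pd.Index(FIXED_NAMES, name="effect"))


# --------------------------------------------------------------------------
# Training power criterion


def fisher_power(r: float, n: int, alpha: float = 0.01,
                 two_sided: bool = True) -> float:
    """Power of the Fisher-z test of H0: rho=0 at true correlation ``r``.

    Uses the finite-sample mean of the z statistic, ``atanh(r) +
    r/(2(n-1))`` (Hotelling's correction); without it the analytic power
    is visibly optimistic-biased at small n such as 11.
    """
    if n <= 3:
        raise ParameterError("need n > 3 for the Fisher-z approximation")
    zcrit = stats.norm.ppf(1 - alpha / (2 if two_sided else 1))
    mu = (np.arctanh(r) + r / (2 * (n - 1))) * np.sqrt(n - 3)
    power = stats.norm.sf(zcrit - mu)
    if two_sided:
        power += stats.norm.cdf(-zcrit - mu)
    return float(power)


def criterion_correlation(n: int, alpha: float = 0.01, power: float = 0.95,
                          two_sided: bool = True) -> float:
    """Smallest population correlation detectable at the stated n/alpha/power.

    Inverts the Fisher-z power function: the r whose test against rho=0
    with ``n`` pairs reaches the requested power at significance ``alpha``.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ParameterError("alpha and power must be in (0, 1)")
    return float(optimize.brentq(
        lambda r: fisher_power(r, n, alpha, two_sided) - power,
        1e-6, 1 - 1e-12, xtol=1e-10))


def monte_carlo_power(r: float, n: int, alpha: float = 0.01,
                      n_sim: int = 10_000, seed: int = 0,
                      two_sided: bool = True) -> float:
    """Simulated power of the Fisher-z test: bivariate-normal samples.

    Independent oracle for :func:`criterion_correlation`; draws ``n_sim``
    samples of ``n`` correlated pairs and counts rejections.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sim, n))
    ynoise = rng.standard_normal((n_sim, n))
    yv = r * x + np.sqrt(1 - r**2) * ynoise
    xc = x - x.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    rhat = (xc * yc).sum(axis=1) / np.sqrt(
        (xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    z = np.arctanh(np.clip(rhat, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1 - alpha / (2 if two_sided else 1))
    reject = np.abs(z) > zcrit if two_sided else z > zcrit
    return float(reject.mean())
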