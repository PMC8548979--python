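"""Activation statistics for the thermal-QST phase.

First level (per subject, per channel): a generalized linear model with
AR-prewhitening and robust (Tukey bisquare) least squares,

    W y = W x beta + W eps

where ``x`` is the design matrix (condition boxcars convolved with a
canonical hemodynamic response function peaking at 6 s, plus intercept and
linear drift), and ``W`` is the whitening filter built from an AR(p) model
of the residuals (order chosen by AIC).  Robust weighting and AR estimation
are alternated until the coefficients stabilise.

Group level (per channel): a linear mixed-effects model on the first-level
coefficients,

    Y_g = X_g B + Z_g theta + eps

with a subject random intercept fit by REML, followed by a two-tailed
t-test  t = c'B / sqrt(c' Cov_group c)  per channel and Benjamini-Hochberg
FDR control across the channel map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from nirspain.preprocess import HemoglobinTimeSeries
from nirspain.probe import EventDesign

TUKEY_C = 4.685  # 95% efficiency at the normal model


# ---------------------------------------------------------------------------
# HRF and design
# ---------------------------------------------------------------------------


def canonical_hrf(rate: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma canonical hemodynamic response, unit peak at t = 6 s.

    Positive gamma lobe with mode 6 s, undershoot lobe with mode 16 s at
    1/6 amplitude; sampled over ``duration_s`` at ``rate``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = np.arange(0.0, duration_s, 1.0 / rate)
    peak = stats.gamma.pdf(t, a=7.0, scale=1.0)      # mode (a-1)*scale = 6 s
    under = stats.gamma.pdf(t, a=17.0, scale=1.0)    # mode 16 s
    h = peak - under / 6.0
    return h / np.max(h)


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named columns."""

    X: np.ndarray
    names: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X must be (n_times, n_regressors) matching names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> int:
        return self.names.index(name)


def build_design(
    events: EventDesign,
    n_samples: int,
    rate: float,
    drift: bool = True,
) -> DesignMatrix:
    """Condition regressors (boxcar * canonical HRF) plus intercept and drift.

    Each condition contributes one column: the sum of per-trial boxcars over
    ``[onset, onset + duration)`` convolved with the canonical HRF.  Raises
    on rank deficiency, naming the collinear columns.
    """
    hrf = canonical_hrf(rate)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in events.conditions:
        box = np.zeros(n_samples)
        for onset, dur, lab in zip(events.onsets, events.durations, events.labels):
            if lab != cond:
                continue
            i0 = int(np.ceil(onset * rate - 1e-9))
            i1 = int(np.ceil((onset + dur) * rate - 1e-9))
            if i0 >= n_samples:
                raise ValueError(f"event at {onset} s is outside the data")
            box[i0:min(i1, n_samples)] = 1.0
        # dt scaling approximates the continuous-time convolution, so the
        # regressor (and hence beta) is invariant to the sampling rate
        cols.append(np.convolve(box, hrf)[:n_samples] / rate)
        names.append(cond)
    cols.append(np.ones(n_samples))
    names.append("intercept")
    if drift:
        cols.append(np.linspace(-0.5, 0.5, n_samples))
        names.append("drift")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending columns by pairwise correlation
        c = np.corrcoef(X.T - X.mean(axis=0, keepdims=True).T)
        bad = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(c[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    return DesignMatrix(X=X, names=names, sampling_rate=rate)


# ---------------------------------------------------------------------------
# AR model selection and whitening
# ---------------------------------------------------------------------------


def select_ar(resid: np.ndarray, max_order: int,
              method: str = "burg") -> np.ndarray:
    """AR coefficients minimising AIC over orders 0..max_order.

    ``method='burg'`` (default) estimates reflection coefficients from
    forward and backward prediction errors; it is substantially less biased
    than Yule-Walker for strongly autocorrelated broadband series, which
    matters for GLM whitening (under-whitening inflates the type-I error).
    ``method='yw'`` (Levinson-Durbin on the sample autocovariance) is
    stability-biased: its poles shrink away from the unit circle, which is
    the safe choice when prewhitening *band-limited* series whose Burg fits
    are marginally stable and amplify out-of-band leakage.
    """
    x = np.asarray(resid, dtype=float)
    x = x - x.mean()
    n = len(x)
    max_order = min(max_order, n // 4)
    sigma2 = np.dot(x, x) / n
    if sigma2 <= 0:
        return np.array([])
    best_aic = n * np.log(max(sigma2, 1e-300))
    best = np.array([])
    coefs = np.zeros(0)
    if method == "yw":
        acov = np.array(
            [np.dot(x[: n - k], x[k:]) / n for k in range(max_order + 1)]
        )
    f = x.copy()
    b = x.copy()
    for k in range(1, max_order + 1):
        if method == "burg":
            fk = f[1:]
            bk = b[:-1]
            denom = np.dot(fk, fk) + np.dot(bk, bk)
            rc = 2 * np.dot(fk, bk) / denom if denom > 0 else 0.0
            f = fk - rc * bk
            b = bk - rc * fk
        elif method == "yw":
            num = acov[k] - np.dot(coefs, acov[1:k][::-1])
            rc = num / sigma2 if sigma2 > 0 else 0.0
        else:
            raise ValueError(f"unknown AR method {method!r}")
        new = np.empty(k)
        new[: k - 1] = coefs - rc * coefs[::-1]
        new[k - 1] = rc
        coefs = new
        sigma2 = sigma2 * max(1 - rc**2, 1e-12)
        aic = n * np.log(max(sigma2, 1e-300)) + 2 * k
        if aic < best_aic:
            best_aic = aic
            best = coefs.copy()
    return best


def ar_whiten(x: np.ndarray, ar_coefs: np.ndarray) -> np.ndarray:
    """Apply the whitening filter [1, -a1, ..., -ap] along the last axis."""
    if len(ar_coefs) == 0:
        return np.asarray(x, dtype=float)
    b = np.concatenate([[1.0], -np.asarray(ar_coefs, dtype=float)])
    return sps.lfilter(b, [1.0], np.asarray(x, dtype=float), axis=-1)




# ---------------------------------------------------------------------------
# Robust (Tukey bisquare) weighted least squares
# ---------------------------------------------------------------------------


def _tukey_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def _irls(X: np.ndarray, y: np.ndarray, c: float = TUKEY_C,
          max_iter: int = 30, tol: float = 1e-8,
          beta0: np.ndarray | None = None):
    """Tukey bisquare IRLS; returns (beta, weights, scale)."""
    if beta0 is not None:
        beta = beta0
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones_like(y)
    scale = 1.0
    for _ in range(max_iter):
        e = y - X @ beta
        mad = np.median(np.abs(e - np.median(e)))
        scale = 1.4826 * mad if mad > 0 else float(np.std(e))
        if scale == 0:  # perfect fit
            return beta, np.ones_like(y), 0.0
        u = e / (c * scale)
        w = _tukey_weights(u)
        if w.sum() < X.shape[1]:  # pathological: nearly all downweighted
            w = np.ones_like(y)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta, w, scale


def _hac_cov(X: np.ndarray, e: np.ndarray, lags: int) -> np.ndarray:
    """Coefficient covariance from the residuals, optionally HAC-corrected.

    ``lags = 0`` is the classical homoskedastic form s^2 (X'X)^-1.  With
    ``lags > 0`` a Newey-West (Bartlett-weighted) estimate of the score
    covariance absorbs the short-range autocorrelation that AR whitening
    of strongly band-limited noise leaves behind.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    if lags <= 0:
        s2 = np.dot(e, e) / (n - p)
        return s2 * xtx_inv
    U = X * e[:, None]
    S = U.T @ U
    for l in range(1, min(lags, n - 1) + 1):
        g = U[l:].T @ U[:-l]
        S += (1 - l / (lags + 1)) * (g + g.T)
    return xtx_inv @ S @ xtx_inv * n / (n - p)


# ---------------------------------------------------------------------------
# First level
# ---------------------------------------------------------------------------


@dataclass
class FirstLevelResult:
    """Per-channel GLM coefficients and whitening description."""

    subject: str
    names: list[str]
    beta: np.ndarray                  # (n_channels, p)
    cov: np.ndarray                   # (n_channels, p, p)
    resid_var: np.ndarray             # (n_channels,)
    ar_coefs: list[np.ndarray]        # per channel
    weight_mean: np.ndarray           # mean robust weight per channel
    dof: np.ndarray                   # per channel
    converged: np.ndarray             # bool per channel
    group: str = ""
    visit: int = 0

    def tvalues(self, name: str) -> np.ndarray:
        j = self.names.index(name)
        se = np.sqrt(self.cov[:, j, j])
        return self.beta[:, j] / se

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in range(self.beta.shape[0]):
            row = {"channel": ch + 1, "subject": self.subject,
                   "group": self.group, "visit": self.visit,
                   "dof": self.dof[ch], "ar_order": len(self.ar_coefs[ch]),
                   "converged": bool(self.converged[ch])}
            for j, name in enumerate(self.names):
                row[f"beta_{name}"] = self.beta[ch, j]
                row[f"se_{name}"] = np.sqrt(self.cov[ch, j, j])
            rows.append(row)
        return pd.DataFrame(rows)


class FirstLevelGLM(BaseEstimator):
    """AR-prewhitened robust GLM, one fit per channel.

    Iterates (a) Tukey-bisquare robust regression, (b) AR(p) fit to the
    unwhitened residuals with AIC order selection (max order = 12 s of
    lags, enough to whiten the slow vasomotor fluctuations that overlap
    the trial frequency), (c) whitening of data and design by the AR
    filter with the filter warm-up samples dropped (conditional
    treatment), until the coefficient change falls below ``tol`` or
    ``max_iter`` alternations.

    Parameters
    ----------
    robust : bool
        Tukey bisquare reweighting (default).  ``False`` gives prewhitened
        ordinary least squares, an oracle-friendly reduction.
    max_ar_order : int or None
        Cap on the AR model order; ``None`` uses 12 s of lags (rate x 12).
    hac_lags : int or None
        Newey-West window (in samples) applied to the whitened residuals
        when forming coefficient standard errors; ``None`` uses 3 s of
        lags.  Set 0 for the classical homoskedastic covariance (the
        ordinary-least-squares oracle).
    tol, max_iter
        Alternation stopping rule; channels that do not converge are
        flagged in ``converged_`` and keep their last iterate.
    """

    def __init__(self, robust: bool = True, max_ar_order: int | None = None,
                 hac_lags: int | None = None, tol: float = 1e-6,
                 max_iter: int = 10):
        self.robust = robust
        self.max_ar_order = max_ar_order
        self.hac_lags = hac_lags
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, design: DesignMatrix, data: HemoglobinTimeSeries | np.ndarray,
            subject: str = "", group: str = "", visit: int = 0) -> "FirstLevelGLM":
        if isinstance(data, HemoglobinTimeSeries):
            Y = data.hbo
            if not np.isclose(data.sampling_rate, design.sampling_rate):
                raise ValueError(
                    f"data rate {data.sampling_rate} Hz != design rate "
                    f"{design.sampling_rate} Hz"
                )
        else:
            Y = np.atleast_2d(np.asarray(data, dtype=float))
        X = design.X
        if Y.shape[1] != X.shape[0]:
            raise ValueError(
                f"data has {Y.shape[1]} samples but design has {X.shape[0]}"
            )
        max_order = (
            int(round(design.sampling_rate * 12))
            if self.max_ar_order is None
            else self.max_ar_order
        )
        hac = (
            int(round(design.sampling_rate * 3))
            if self.hac_lags is None
            else self.hac_lags
        )
        self._hac = hac
        n_ch = Y.shape[0]
        p = X.shape[1]
        beta = np.zeros((n_ch, p))
        cov = np.zeros((n_ch, p, p))
        resid_var = np.zeros(n_ch)
        dof = np.zeros(n_ch)
        wmean = np.ones(n_ch)
        converged = np.zeros(n_ch, dtype=bool)
        ar_list: list[np.ndarray] = []
        for ch in range(n_ch):
            b, V, rv, ar, wm, conv, df = self._fit_channel(X, Y[ch], max_order)
            beta[ch] = b
            cov[ch] = V
            resid_var[ch] = rv
            wmean[ch] = wm
            converged[ch] = conv
            dof[ch] = df
            ar_list.append(ar)
        if not converged.all():
            warnings.warn(
                f"{int((~converged).sum())} channel(s) did not reach the "
                f"coefficient tolerance in {self.max_iter} alternations; "
                "last iterates returned",
                RuntimeWarning,
                stacklevel=2,
            )
        self.result_ = FirstLevelResult(
            subject=subject, names=list(design.names), beta=beta, cov=cov,
            resid_var=resid_var, ar_coefs=ar_list, weight_mean=wmean,
            dof=dof, converged=converged, group=group, visit=visit,
        )
        self.coef_ = beta
        self.cov_ = cov
        self.converged_ = converged
        return self

    def _fit_channel(self, X: np.ndarray, y: np.ndarray, max_order: int):
        Xw, yw = X, y
        ar = np.array([])
        beta_prev = None
        conv = False
        beta, w, scale = None, np.ones_like(y), 0.0
        for _ in range(self.max_iter):
            if self.robust:
                # warm-start from the previous alternation's coefficients
                beta, w, scale = _irls(Xw, yw, tol=self.tol / 10,
                                       beta0=beta_prev)
            else:
                beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
                w = np.ones_like(yw)
            resid = y - X @ beta
            ar = select_ar(resid, max_order)
            Xw = ar_whiten(X.T, ar).T
            yw = ar_whiten(y, ar)
            if len(ar):
                # the causal whitening filter needs `order` past samples;
                # its warm-up outputs are mis-scaled, so condition on the
                # first `order` observations and drop them
                Xw = Xw[len(ar):]
                yw = yw[len(ar):]
            if beta_prev is not None and np.max(np.abs(beta - beta_prev)) < self.tol:
                conv = True
                break
            beta_prev = beta
        # final estimate and covariance in the whitened domain
        if self.robust:
            beta, w, scale = _irls(Xw, yw, tol=self.tol / 10, beta0=beta)
        else:
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        e = yw - Xw @ beta
        V = _hac_cov(Xw, e, self._hac)
        rv = float(np.dot(e, e) / max(len(e) - X.shape[1], 1))
        df = len(yw) - X.shape[1]
        return beta, V, rv, ar, float(np.mean(w)), conv, df


def fit_first_level(hbo: HemoglobinTimeSeries | np.ndarray, design: DesignMatrix,
                    **kwargs) -> FirstLevelResult:
    """Functional wrapper over :class:`FirstLevelGLM`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("subject", "group", "visit")
                  if k in kwargs}
    est = FirstLevelGLM(**kwargs)
    est.fit(design, hbo, **fit_kwargs)
    return est.result_


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------


@dataclass
class GroupActivationResult:
    """Per-channel group fixed effect, t, p and FDR-adjusted q."""

    effect: np.ndarray
    se: np.ndarray
    random_var: np.ndarray
    tvalues: np.ndarray
    dof: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    contrast: str
    fallback: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def cov_diag(self) -> np.ndarray:
        return self.se**2

    def to_frame(self, region_of: dict[int, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "channel": np.arange(1, len(self.effect) + 1),
                "beta": self.effect,
                "se": self.se,
                "t": self.tvalues,
                "dof": self.dof,
                "p": self.pvalues,
                "q": self.qvalues,
            }
        )
        if region_of:
            df.insert(1, "region", [region_of.get(c, "other") for c in df["channel"]])
        return df


def _balanced_random_intercept(values: np.ndarray, subjects: np.ndarray):
    """Closed-form REML for ``y ~ 1 + (1 | subject)`` with balanced replicates.

    The fixed intercept estimate is the grand mean of subject means; in the
    interior of the parameter space its REML variance equals the sampling
    variance of the mean of subject means, so the t statistic reduces to a
    one-sample t on subject means with n_subjects - 1 dof.  When the
    random-intercept variance estimate hits the zero boundary, REML refits
    with a single pooled residual variance.  Exact under balance; verified
    against brute-force GLS in the test-suite.
    """
    uniq = np.unique(subjects)
    means = np.array([values[subjects == s].mean() for s in uniq])
    n = len(uniq)
    m = len(values) / n
    grand = float(means.mean())
    var_means = float(np.var(means, ddof=1))
    within = float(
        np.mean([np.var(values[subjects == s], ddof=1) for s in uniq])
    ) if m > 1 else 0.0
    tau2 = var_means - within / m
    if tau2 >= 0 or m == 1:
        se = np.sqrt(var_means / n)
        dof = n - 1
    else:  # boundary: independent-errors model with pooled variance
        tau2 = 0.0
        pooled = float(np.var(values, ddof=1))
        se = np.sqrt(pooled / len(values))
        dof = len(values) - 1
    return grand, se, max(tau2, 0.0), dof


class GroupActivation(BaseEstimator):
    """Channel-wise linear mixed-effects model over first-level coefficients.

    ``fixed='1'`` (default) estimates the group-mean response per channel
    with a subject random intercept; ``fixed='group'`` adds a two-group
    contrast (second level group difference).  Balanced intercept-only
    designs use the exact closed-form REML solution; anything else goes
    through statsmodels MixedLM, with a fixed-effects-only (OLS) fallback
    when the random-effects fit is singular.
    """

    def __init__(self, condition: str = "tqst_trial", fixed: str = "1",
                 fdr_q: float = 0.05):
        self.condition = condition
        self.fixed = fixed
        self.fdr_q = fdr_q

    def fit(self, first_levels: list[FirstLevelResult], y=None) -> "GroupActivation":
        if len({fl.subject for fl in first_levels}) < 3:
            raise ValueError("need at least 3 subjects for a group model")
        j = first_levels[0].names.index(self.condition)
        n_ch = first_levels[0].beta.shape[0]
        subjects = np.array([fl.subject for fl in first_levels])
        groups = np.array([fl.group for fl in first_levels])
        effect = np.zeros(n_ch)
        se = np.zeros(n_ch)
        tau2 = np.zeros(n_ch)
        tval = np.zeros(n_ch)
        dof = np.zeros(n_ch)
        pval = np.zeros(n_ch)
        fallback = np.zeros(n_ch, dtype=bool)
        for ch in range(n_ch):
            values = np.array([fl.beta[ch, j] for fl in first_levels])
            if self.fixed == "1" and _is_balanced(subjects):
                b, s, t2, df = _balanced_random_intercept(values, subjects)
            else:
                b, s, t2, df, fb = _mixedlm_fit(values, subjects, groups, self.fixed)
                fallback[ch] = fb
            effect[ch] = b
            se[ch] = s
            tau2[ch] = t2
            dof[ch] = df
            # zero between-subject scatter: a nonzero effect is exact
            tval[ch] = b / s if s > 0 else (np.inf * np.sign(b) if b else 0.0)
            pval[ch] = 2 * stats.t.sf(abs(tval[ch]), df)
        qval, _ = fdr_correct(pval, self.fdr_q)
        self.result_ = GroupActivationResult(
            effect=effect, se=se, random_var=tau2, tvalues=tval, dof=dof,
            pvalues=pval, qvalues=qval,
            contrast=self.fixed if self.fixed != "1" else self.condition,
            fallback=fallback,
        )
        self.effect_ = effect
        self.tvalues_ = tval
        self.pvalues_ = pval
        self.qvalues_ = qval
        return self


def _is_balanced(subjects: np.ndarray) -> bool:
    _, counts = np.unique(subjects, return_counts=True)
    return len(set(counts)) == 1


def _mixedlm_fit(values: np.ndarray, subjects: np.ndarray, groups: np.ndarray,
                 fixed: str):
    """statsmodels MixedLM with subject random intercept; OLS fallback."""
    import statsmodels.api as sm

    df = pd.DataFrame({"y": values, "subject": subjects, "group": groups})
    formula = "y ~ 1" if fixed == "1" else "y ~ C(group)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(formula, groups="subject", data=df)
            res = model.fit(reml=True, method="lbfgs")
        idx = -1  # last fixed-effect term: intercept or group contrast
        b = float(np.asarray(res.fe_params)[idx])
        s = float(np.asarray(res.bse_fe)[idx])
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        dof = len(np.unique(subjects)) - (1 if fixed == "1" else 2)
        if not np.isfinite(s) or s == 0:
            raise ValueError("singular mixed fit")
        return b, s, tau2, max(dof, 1), False
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X = (
                np.ones((len(values), 1))
                if fixed == "1"
                else np.column_stack(
                    [np.ones(len(values)), (groups == "VRB").astype(float)]
                )
            )
            res = sm.OLS(values, X).fit()
        b = float(res.params[-1])
        s = float(res.bse[-1])
        return b, s, 0.0, max(len(values) - X.shape[1], 1), True


def fit_group(first_levels: list[FirstLevelResult], condition: str = "tqst_trial",
              fixed: str = "1", fdr_q: float = 0.05) -> GroupActivationResult:
    """Functional wrapper over :class:`GroupActivation`."""
    est = GroupActivation(condition=condition, fixed=fixed, fdr_q=fdr_q)
    est.fit(first_levels)
    return est.result_


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (adjusted q-values, reject flags)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return qvals, reject
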