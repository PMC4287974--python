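"""Survival machinery: Kaplan-Meier, weighted log-rank tests, univariate
Cox regression, and the single-hit Poisson limiting-dilution estimator.

All estimators here are implemented from first principles. The Cox model
follows the statsmodels convention: a model object is built from data and
``fit()`` returns a results object carrying the estimate, its standard
error, Wald inference and a ``summary()`` table.

Conventions
-----------
* Kaplan-Meier uses the standard product-limit estimator
  ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``; censorings recorded at an
  event time leave the risk set *after* the events at that time.
* The two-sample "Wilcoxon" test is the Gehan-Breslow generalized
  Wilcoxon: a weighted log-rank statistic with weight ``w_i = n_i`` (total
  number at risk). The unweighted log-rank (``w_i = 1``) is available via
  ``method="logrank"``.
* Cox ties are handled by the Efron correction by default (Breslow
  selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "SurvTestResult",
    "gehan_wilcoxon",
    "logrank",
    "two_sample_test",
    "CoxPH",
    "CoxResult",
    "cox_univariate",
    "SingleHitModel",
    "LDResult",
    "limiting_dilution_mle",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the sorted distinct times at which at least one
    event occurred; ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``at_risk[i]`` and ``n_events[i]`` are the risk-set size and event
    count at that time. ``S = 1`` before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_step_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )

    def plot(self, ax=None, label=None, **kwargs):
        """Step plot of the curve (matplotlib optional dependency)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label, **kwargs)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival fraction")
        ax.set_ylim(-0.02, 1.02)
        return ax


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate from right-censored data."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = time.size

    event_times, survival, at_risk, n_events = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += event[j]
            j += 1
        n_at_risk = n - i  # everyone with time >= t, censored-after-events convention
        if d > 0:
            s *= 1.0 - d / n_at_risk
            event_times.append(t)
            survival.append(s)
            at_risk.append(n_at_risk)
            n_events.append(d)
        i = j
    return KMCurve(
        event_times=np.asarray(event_times),
        survival=np.asarray(survival),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        n_total=n,
    )


# ---------------------------------------------------------------------------
# weighted log-rank two-sample tests
# ---------------------------------------------------------------------------


@dataclass
class SurvTestResult:
    """Chi-square (1 df) two-sample survival test result."""

    statistic: float
    p: float
    method: str
    observed_a: float = float("nan")
    expected_a: float = float("nan")


def _weighted_logrank(time_a, event_a, time_b, event_b, weight: str) -> SurvTestResult:
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        import logging

        logging.getLogger("sigrank").warning("no events in either group; p set to 1")
        return SurvTestResult(0.0, 1.0, weight)

    num = 0.0  # sum w_i (d_Ai - E_Ai)
    den = 0.0  # sum w_i^2 V_i
    obs_a = 0.0
    exp_a = 0.0
    for t in event_times:
        at_risk = times >= t
        n_i = int(at_risk.sum())
        n_ai = int((at_risk & (group == 0)).sum())
        dead = (times == t) & (events == 1)
        d_i = int(dead.sum())
        d_ai = int((dead & (group == 0)).sum())
        e_ai = d_i * n_ai / n_i
        if n_i > 1:
            v_i = d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / (n_i - 1)
        else:
            v_i = 0.0
        w = float(n_i) if weight == "gehan_wilcoxon" else 1.0
        num += w * (d_ai - e_ai)
        den += w * w * v_i
        obs_a += d_ai
        exp_a += e_ai

    if den <= 0:
        return SurvTestResult(0.0, 1.0, weight, obs_a, exp_a)
    chi2 = num * num / den
    p = float(stats.chi2.sf(chi2, df=1))
    return SurvTestResult(float(chi2), p, weight, obs_a, exp_a)


def gehan_wilcoxon(time_a, event_a, time_b, event_b) -> SurvTestResult:
    """Gehan-Breslow generalized Wilcoxon test (weight = number at risk).

    Emphasizes early survival differences; this is the "Wilcoxon method"
    of classical survival packages.
    """
    return _weighted_logrank(time_a, event_a, time_b, event_b, "gehan_wilcoxon")


def logrank(time_a, event_a, time_b, event_b) -> SurvTestResult:
    """Unweighted log-rank (Mantel-Cox) test."""
    return _weighted_logrank(time_a, event_a, time_b, event_b, "logrank")


def two_sample_test(time_a, event_a, time_b, event_b, method: str = "gehan_wilcoxon") -> SurvTestResult:
    if method not in ("gehan_wilcoxon", "logrank"):
        raise ValueError(f"unknown test method {method!r}")
    return _weighted_logrank(time_a, event_a, time_b, event_b, method)


# ---------------------------------------------------------------------------
# univariate Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Fitted univariate Cox model.

    ``beta`` is the log hazard ratio per unit of the covariate;
    ``hr = exp(beta)``; ``se`` is sqrt of the inverse observed information.
    """

    beta: float
    hr: float
    se: float
    wald_p: float
    iterations: int
    converged: bool
    ties_method: str
    loglik: float
    n: int
    n_events: int
    separation: bool = False

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald CI for the hazard ratio."""
        z = stats.norm.ppf(1 - alpha / 2)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Univariate Cox proportional hazards",
            "===================================",
            f"n = {self.n}, events = {self.n_events}, ties = {self.ties_method}",
            f"beta (log HR) = {self.beta: .4f}  (SE {self.se:.4f})",
            f"HR            = {self.hr: .4f}  [95% CI {lo:.4f}, {hi:.4f}]",
            f"Wald p        = {self.wald_p:.4g}",
            f"log partial likelihood = {self.loglik:.4f}",
            f"converged = {self.converged} ({self.iterations} iterations)"
            + ("  [monotone likelihood / separation]" if self.separation else ""),
        ]
        return "\n".join(lines)


class CoxPH:
    """Univariate Cox proportional-hazards model for right-censored data.

    Maximizes the partial likelihood by Newton-Raphson with analytic
    gradient and Hessian. Tied event times use the Efron correction by
    default (``ties="breslow"`` selectable). Monotone partial likelihood
    (risk-set separation) is detected when ``|beta|`` exceeds 15 during
    iteration; the result is then flagged non-converged with beta capped.

    Examples
    --------
    >>> res = CoxPH(time, event, group_indicator).fit()
    >>> res.hr, res.conf_int()
    """

    MAX_ABS_BETA = 15.0
    TOL = 1e-9
    MAX_ITER = 50

    def __init__(self, time, event, covariate, ties: str = "efron"):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.x = np.asarray(covariate, dtype=float)
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.ties = ties
        if not (self.time.size == self.event.size == self.x.size):
            raise ValueError("time, event and covariate must have equal length")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        if np.ptp(self.x) == 0:
            raise ValueError("covariate is constant; hazard ratio undefined")
        # sort by time ascending; group tied event times
        order = np.argsort(self.time, kind="stable")
        self.time = self.time[order]
        self.event = self.event[order]
        self.x = self.x[order]

    # partial log-likelihood and derivatives at beta
    def _loglik_grad_hess(self, beta: float) -> tuple[float, float, float]:
        t, e, x = self.time, self.event, self.x
        eta = beta * x
        # stabilize exp
        w = np.exp(eta - eta.max())
        scale = eta.max()
        n = t.size
        ll = 0.0
        grad = 0.0
        hess = 0.0
        # iterate distinct event times; risk set = time >= t_k
        # cumulative sums from the end give risk-set aggregates
        cw = np.cumsum(w[::-1])[::-1]
        cwx = np.cumsum((w * x)[::-1])[::-1]
        cwx2 = np.cumsum((w * x * x)[::-1])[::-1]
        i = 0
        while i < n:
            tk = t[i]
            j = i
            while j < n and t[j] == tk:
                j += 1
            dead = np.arange(i, j)[e[i:j] == 1]
            d = dead.size
            if d > 0:
                s0r, s1r, s2r = cw[i], cwx[i], cwx2[i]
                xd = x[dead]
                wd = w[dead]
                s0d, s1d, s2d = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
                ll += beta * xd.sum() - d * scale  # numerator terms (scale restored below)
                for l in range(d):
                    frac = l / d if self.ties == "efron" else 0.0
                    a0 = s0r - frac * s0d
                    a1 = s1r - frac * s1d
                    a2 = s2r - frac * s2d
                    ll -= np.log(a0)
                    mu = a1 / a0
                    grad += xd.sum() / d - mu if self.ties == "efron" else 0.0
                    hess -= a2 / a0 - mu * mu
                if self.ties == "breslow":
                    mu = s1r / s0r
                    grad += xd.sum() - d * mu
            i = j
        # for efron the per-l grad above used mean x of deaths each step
        return ll, grad, hess

    def loglik(self, beta: float) -> float:
        return self._loglik_grad_hess(beta)[0]

    def fit(self, start: float = 0.0) -> CoxResult:
        beta = float(start)
        converged = False
        separation = False
        it = 0
        for it in range(1, self.MAX_ITER + 1):
            ll, grad, hess = self._loglik_grad_hess(beta)
            if abs(grad) < self.TOL:
                converged = True
                break
            if hess >= 0:  # should not happen away from degenerate data
                hess = -1e-8
            step = -grad / hess
            # dampen huge steps
            if abs(step) > 5.0:
                step = np.sign(step) * 5.0
            beta += step
            if abs(beta) > self.MAX_ABS_BETA:
                beta = np.sign(beta) * self.MAX_ABS_BETA
                separation = True
                break
        ll, grad, hess = self._loglik_grad_hess(beta)
        if abs(grad) < self.TOL and not separation:
            converged = True
        info = -hess
        se = float(np.sqrt(1.0 / info)) if info > 0 else float("inf")
        z = beta / se if se > 0 and np.isfinite(se) else 0.0
        wald_p = float(2 * stats.norm.sf(abs(z)))
        if separation:
            import logging

            logging.getLogger("sigrank").warning(
                "Cox fit: monotone partial likelihood (separation); |beta| capped at %.1f",
                self.MAX_ABS_BETA,
            )
        return CoxResult(
            beta=float(beta),
            hr=float(np.exp(beta)),
            se=se,
            wald_p=wald_p,
            iterations=it,
            converged=converged and not separation,
            ties_method=self.ties,
            loglik=float(ll),
            n=self.time.size,
            n_events=int(self.event.sum()),
            separation=separation,
        )


def cox_univariate(time, event, covariate, ties: str = "efron") -> CoxResult:
    """Convenience wrapper: fit :class:`CoxPH` and return its result."""
    return CoxPH(time, event, covariate, ties=ties).fit()


# ---------------------------------------------------------------------------
# single-hit Poisson limiting dilution
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    """Limiting-dilution MLE under the single-hit Poisson model.

    ``frequency`` is tumor-initiating cells per cell; ``reciprocal`` the
    familiar "1 in N cells" form. The 95% CI is Wald on log(f) by default.
    """

    frequency: float
    reciprocal: float
    ci_low: float
    ci_high: float
    loglik: float
    n_doses: int
    boundary: str | None = None  # "all_negative" | "all_positive" | None

    def summary(self) -> str:
        recip = "inf" if self.frequency == 0 else f"1/{self.reciprocal:.1f}"
        lines = [
            "Single-hit Poisson limiting-dilution estimate",
            "=============================================",
            f"TIC frequency  = {self.frequency:.6g}  ({recip} cells)",
            f"95% CI (freq)  = [{self.ci_low:.6g}, {self.ci_high:.6g}]",
            f"log-likelihood = {self.loglik:.4f} over {self.n_doses} dose level(s)",
        ]
        if self.boundary:
            lines.append(f"boundary case: {self.boundary}")
        return "\n".join(lines)


class SingleHitModel:
    """Single-hit Poisson model for limiting-dilution transplantation.

    A graft at dose ``d`` cells is positive with probability
    ``1 - exp(-f d)`` where ``f`` is the tumor-initiating-cell frequency.
    The binomial log-likelihood over dose levels is maximized over ``f``;
    the default 95% CI is Wald on log(f), with a profile-likelihood CI
    behind ``ci="profile"``.
    """

    def __init__(self, doses, n_injected, n_positive):
        self.doses = np.asarray(doses, dtype=float)
        self.n_injected = np.asarray(n_injected, dtype=int)
        self.n_positive = np.asarray(n_positive, dtype=int)
        if not (self.doses.size == self.n_injected.size == self.n_positive.size):
            raise ValueError("doses, n_injected, n_positive must align")
        if self.doses.size < 1:
            raise ValueError("at least one dose level required")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(self.n_positive > self.n_injected) or np.any(self.n_positive < 0):
            raise ValueError("need 0 <= n_positive <= n_injected")

    def loglik(self, f: float) -> float:
        """Binomial log-likelihood at frequency f (constants dropped)."""
        d, n, k = self.doses, self.n_injected, self.n_positive
        p = 1.0 - np.exp(-f * d)
        ll = 0.0
        with np.errstate(divide="ignore"):
            pos = k > 0
            ll += float(np.sum(k[pos] * np.log(p[pos]))) if pos.any() else 0.0
            if np.any(p >= 1) and np.any((n - k)[p >= 1] > 0):
                return -np.inf
            ll += float(np.sum((n - k) * (-f * d)))
        return ll

    def fit(self, ci: str = "wald") -> LDResult:
        from scipy.optimize import brentq, minimize_scalar

        d, n, k = self.doses, self.n_injected, self.n_positive
        if k.sum() == 0:
            # f_hat = 0; one-sided 95% upper bound from L(f)/L(0) = exp(-f sum(n d))
            upper = -np.log(0.05) / float(np.sum(n * d))
            return LDResult(0.0, float("inf"), 0.0, upper, 0.0, d.size, "all_negative")
        if (k == n).all():
            # unbounded MLE; report a lower 95% bound at the largest f with
            # all-positive probability >= 0.05 relative likelihood
            # L(f) = prod (1-exp(-f d))^n, increasing in f -> sup at infinity
            def rel(fv):
                return self.loglik(fv) - 0.0  # sup loglik -> 0 as f -> inf

            lo = brentq(lambda fv: rel(fv) - np.log(0.05), 1e-12, 1e6)
            return LDResult(1.0, 1.0, lo, 1.0, self.loglik(1.0), d.size, "all_positive")

        res = minimize_scalar(
            lambda lf: -self.loglik(np.exp(lf)),
            bounds=(np.log(1e-9), np.log(10.0 / d.min())),
            method="bounded",
            options={"xatol": 1e-12},
        )
        log_f = float(res.x)
        f_hat = float(np.exp(log_f))
        ll = self.loglik(f_hat)

        # observed information on log f by central difference
        h = 1e-4
        d2 = (self.loglik(np.exp(log_f + h)) - 2 * ll + self.loglik(np.exp(log_f - h))) / h**2
        if ci == "wald":
            if d2 < 0:
                se_logf = np.sqrt(-1.0 / d2)
                lo = float(np.exp(log_f - 1.959963984540054 * se_logf))
                hi = float(np.exp(log_f + 1.959963984540054 * se_logf))
            else:
                lo, hi = 0.0, 1.0
        elif ci == "profile":
            drop = stats.chi2.ppf(0.95, df=1) / 2.0

            def g(lf):
                return self.loglik(np.exp(lf)) - (ll - drop)

            lo_b = np.log(1e-12)
            hi_b = np.log(10.0 / d.min())
            lo = float(np.exp(brentq(g, lo_b, log_f))) if g(lo_b) < 0 else 0.0
            hi = float(np.exp(brentq(g, log_f, hi_b))) if g(hi_b) < 0 else 1.0
        else:
            raise ValueError(f"unknown ci method {ci!r}")
        hi = min(hi, 1.0)
        return LDResult(f_hat, 1.0 / f_hat, lo, hi, float(ll), d.size)


def limiting_dilution_mle(doses, n_injected, n_positive, ci: str = "wald") -> LDResult:
    """Convenience wrapper: fit :class:`SingleHitModel` and return the result."""
    return SingleHitModel(doses, n_injected, n_positive).fit(ci=ci)
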