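"""Dose-response IC50 fitting and meta-analysis of IC50-activity correlations.

The dose-response model is the four-parameter logistic (4PL, log-logistic)

    y(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with viability decreasing in dose for hill > 0. Fitting is bounded least
squares with a multi-start over log-spaced IC50 initial values spanning the
dose range; a fit whose IC50 lands on a search bound, or whose response is
flat, is flagged unreliable.

Correlations of log10(IC50) with pathway activity are computed per
experiment and pooled on the Fisher-z scale (var(z) = 1/(n-3)) with a
DerSimonian-Laird random-effects estimate of the between-experiment
variance tau^2; fixed-effects pooling sets tau^2 = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

logger = logging.getLogger("sigrank")

__all__ = [
    "four_pl",
    "FourPL",
    "FourPLFit",
    "fit_4pl",
    "experiment_correlation",
    "CorrelationMeta",
    "MetaResult",
    "meta_correlation",
    "DoseResponsePanel",
]

BOUNDS_LO = np.array([-0.2, 0.5, 0.1, np.nan])  # bottom, top, hill, ic50 (ic50 set per fit)
BOUNDS_HI = np.array([0.5, 1.3, 10.0, np.nan])


def four_pl(dose, bottom: float, top: float, hill: float, ic50: float):
    """Four-parameter logistic viability at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass
class FourPLFit:
    """Fitted 4PL curve; ``ic50`` in the units of the input doses (uM)."""

    bottom: float
    top: float
    hill: float
    ic50: float
    rss: float
    converged: bool
    n_points: int
    reliable: bool = True
    note: str = ""

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.hill, self.ic50)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=========================================",
            f"IC50   = {self.ic50:.6g} uM",
            f"top    = {self.top:.4f}   bottom = {self.bottom:.4f}   hill = {self.hill:.4f}",
            f"RSS    = {self.rss:.6g} over {self.n_points} points",
            f"converged = {self.converged}, reliable = {self.reliable}"
            + (f" ({self.note})" if self.note else ""),
        ]
        return "\n".join(lines)

    def plot(self, doses=None, viabilities=None, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if doses is not None and viabilities is not None:
            ax.semilogx(doses, viabilities, "o", alpha=0.6)
        lo = self.ic50 / 100 if doses is None else min(doses)
        hi = self.ic50 * 100 if doses is None else max(doses)
        grid = np.geomspace(lo, hi, 200)
        ax.semilogx(grid, self.predict(grid), **kwargs)
        ax.set_xlabel("dose (uM)")
        ax.set_ylabel("viability fraction")
        return ax


class FourPL:
    """Bounded least-squares 4PL model for one dose-response curve.

    Requires >= 5 distinct doses. ``fit()`` runs a multi-start over
    log-spaced IC50 initial values spanning [min dose, max dose] and keeps
    the lowest-RSS solution within the bounds bottom in [-0.2, 0.5], top in
    [0.5, 1.3], hill in [0.1, 10], ic50 in [min dose / 10, max dose * 10].
    """

    def __init__(self, doses, viabilities):
        self.doses = np.asarray(doses, dtype=float)
        self.viabilities = np.asarray(viabilities, dtype=float)
        if self.doses.size != self.viabilities.size:
            raise ValueError("doses and viabilities must align")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.unique(self.doses).size < 5:
            raise ValueError("need >= 5 distinct doses for a 4PL fit")
        if not np.isfinite(self.viabilities).all():
            raise ValueError("viabilities must be finite")

    def fit(self, n_starts: int = 6) -> FourPLFit:
        d, y = self.doses, self.viabilities
        dmin, dmax = d.min(), d.max()
        lo = np.array([-0.2, 0.5, 0.1, dmin / 10.0])
        hi = np.array([0.5, 1.3, 10.0, dmax * 10.0])

        # data-driven IC50 guess: dose whose response is nearest the midpoint
        mid = (np.clip(y.max(), 0.5, 1.3) + np.clip(y.min(), -0.2, 0.5)) / 2.0
        guess = d[np.argmin(np.abs(y - mid))]
        starts = np.concatenate([[guess], np.geomspace(dmin, dmax, n_starts - 1)])

        best = None
        n_agree = 0
        for ic0 in starts:
            p0 = np.array([
                np.clip(y.min(), lo[0] + 1e-9, hi[0] - 1e-9),
                np.clip(y.max(), lo[1] + 1e-9, hi[1] - 1e-9),
                1.0,
                np.clip(ic0, lo[3], hi[3]),
            ])
            try:
                popt, _ = curve_fit(
                    four_pl, d, y, p0=p0, bounds=(lo, hi),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=5000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((four_pl(d, *popt) - y) ** 2))
            if best is not None and (
                abs(rss - best[1]) <= 1e-9 * max(best[1], 1e-12)
                and abs(popt[3] - best[0][3]) <= 1e-6 * best[0][3]
            ):
                n_agree += 1
            if best is None or rss < best[1]:
                best = (popt, rss)
                n_agree = 0
            # two independent starts landed on the same optimum: accept it
            if n_agree >= 1:
                break

        if best is None:
            return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, d.size, False, "optimizer failed")
        popt, rss = best
        bottom, top, hill, ic50 = (float(v) for v in popt)

        reliable, note = True, ""
        rel = 1e-6
        if ic50 <= lo[3] * (1 + 1e-6) or ic50 >= hi[3] * (1 - 1e-6):
            reliable, note = False, "IC50 at search bound"
        span = abs(top - bottom)
        y_range = np.ptp(y)
        if y_range < 0.05 or span < 0.05:
            reliable, note = False, "flat response, no dose effect"
        if not reliable:
            logger.warning("4PL fit flagged unreliable: %s", note)
        return FourPLFit(bottom, top, hill, ic50, rss, True, d.size, reliable, note)


def fit_4pl(doses, viabilities) -> FourPLFit:
    """Convenience wrapper: fit :class:`FourPL` and return the result."""
    return FourPL(doses, viabilities).fit()


# ---------------------------------------------------------------------------
# panels and correlations
# ---------------------------------------------------------------------------


@dataclass
class DoseResponsePanel:
    """Long-format viability records across experiments, lines and doses.

    Columns: experiment, line, drug, dose_uM, viability, replicate.
    """

    records: pd.DataFrame

    REQUIRED = ("experiment", "line", "drug", "dose_uM", "viability", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if (self.records["dose_uM"] <= 0).any():
            raise ValueError("doses must be positive")

    def fit_ic50s(self) -> pd.DataFrame:
        """Fit a 4PL per (experiment, line, drug); returns long IC50 table."""
        rows = []
        for (exp, line, drug), grp in self.records.groupby(["experiment", "line", "drug"]):
            fit = fit_4pl(grp["dose_uM"].to_numpy(), grp["viability"].to_numpy())
            rows.append(
                {
                    "experiment": exp,
                    "line": line,
                    "drug": drug,
                    "ic50": fit.ic50,
                    "reliable": fit.reliable,
                    "rss": fit.rss,
                }
            )
        return pd.DataFrame(rows)


def experiment_correlation(ic50s, activities, log_transform: bool = True) -> tuple[float, int]:
    """Pearson correlation of (log10) IC50 with pathway activity.

    IC50s are log10-transformed by default: correlation on raw uM would be
    dominated by scale. Requires >= 3 lines with both values.
    """
    ic50s = np.asarray(ic50s, dtype=float)
    activities = np.asarray(activities, dtype=float)
    keep = np.isfinite(ic50s) & np.isfinite(activities)
    ic50s, activities = ic50s[keep], activities[keep]
    if ic50s.size < 3:
        raise ValueError("need >= 3 lines with both IC50 and activity")
    x = np.log10(ic50s) if log_transform else ic50s
    if np.ptp(x) == 0 or np.ptp(activities) == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(stats.pearsonr(x, activities)[0])
    return r, int(ic50s.size)


@dataclass
class MetaResult:
    """Pooled correlation across experiments on the Fisher-z scale."""

    per_experiment: list[tuple[float, int]]
    pooled_r: float
    ci_low: float
    ci_high: float
    tau2: float
    method: str
    z_p: float

    def summary(self) -> str:
        lines = [
            f"Fisher-z meta-analysis of correlations ({self.method})",
            "=" * 50,
            f"k = {len(self.per_experiment)} experiments",
            f"pooled r = {self.pooled_r: .4f}  [95% CI {self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"tau^2 (z scale) = {self.tau2:.4f}",
            f"p (pooled z = 0) = {self.z_p:.4g}",
            "per experiment: " + ", ".join(f"r={r:.3f} (n={n})" for r, n in self.per_experiment),
        ]
        return "\n".join(lines)


class CorrelationMeta:
    """Fisher-z pooling of Pearson correlations across experiments.

    Each experiment contributes z_i = atanh(r_i) with within-experiment
    variance v_i = 1/(n_i - 3). ``method="dersimonian_laird"`` (default)
    adds the DL moment estimate of tau^2; ``method="fixed"`` sets tau^2=0.
    Every experiment must have n >= 4 so v_i is defined.
    """

    def __init__(self, per_experiment: list[tuple[float, int]], method: str = "dersimonian_laird"):
        if method not in ("fixed", "dersimonian_laird"):
            raise ValueError(f"unknown meta-analysis method {method!r}")
        if not per_experiment:
            raise ValueError("no experiments to pool")
        for i, (r, n) in enumerate(per_experiment):
            if n <= 3:
                raise ValueError(f"experiment {i} has n={n} <= 3; Fisher-z variance undefined")
            if not -1 < r < 1:
                raise ValueError(f"experiment {i} has |r| >= 1; z transform undefined")
        self.per_experiment = [(float(r), int(n)) for r, n in per_experiment]
        self.method = method

    def fit(self) -> MetaResult:
        r = np.array([x[0] for x in self.per_experiment])
        n = np.array([x[1] for x in self.per_experiment])
        z = np.arctanh(r)
        v = 1.0 / (n - 3)
        w = 1.0 / v
        k = z.size

        tau2 = 0.0
        if self.method == "dersimonian_laird" and k > 1:
            z_fixed = np.sum(w * z) / np.sum(w)
            q = float(np.sum(w * (z - z_fixed) ** 2))
            c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
            tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0

        w_star = 1.0 / (v + tau2)
        z_pooled = float(np.sum(w_star * z) / np.sum(w_star))
        se = float(np.sqrt(1.0 / np.sum(w_star)))
        zcrit = 1.959963984540054
        ci = (np.tanh(z_pooled - zcrit * se), np.tanh(z_pooled + zcrit * se))
        p = float(2 * stats.norm.sf(abs(z_pooled / se)))
        return MetaResult(
            per_experiment=self.per_experiment,
            pooled_r=float(np.tanh(z_pooled)),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            tau2=float(tau2),
            method=self.method,
            z_p=p,
        )


def meta_correlation(per_experiment: list[tuple[float, int]], method: str = "dersimonian_laird") -> MetaResult:
    """Convenience wrapper: pool (r, n) pairs with :class:`CorrelationMeta`."""
    return CorrelationMeta(per_experiment, method=method).fit()
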