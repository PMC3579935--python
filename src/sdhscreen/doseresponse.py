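"""Serial-dilution design and four-parameter log-logistic IC50 fitting.

Concentration–response data from whole-cell growth assays (maximal culture
saturation vs. compound concentration) and from enzyme assays (initial rate
vs. inhibitor concentration) are both modelled with the four-parameter
log-logistic ("4PL") family

    response(c) = bottom + (top - bottom) / (1 + (c / ic50) ** hill)

so that ``response(0) = top``, ``response(inf) = bottom`` and
``response(ic50)`` is halfway between the asymptotes.  The Hill slope may be
left free (the default) or fixed, e.g. at 1 for simple single-site binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DilutionSeries",
    "serial_dilution",
    "LogLogisticIC50",
    "DoseResponseFit",
    "fit_ic50",
    "ic50_ratio",
]


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric (fold) dilution series, highest concentration first.

    Parameters
    ----------
    top_conc_um : float
        Highest tested concentration in µM.
    fold : float
        Dilution factor between consecutive points; must exceed 1.
    n_points : int
        Number of concentrations (>= 2).
    """

    top_conc_um: float
    fold: float
    n_points: int

    def __post_init__(self) -> None:
        if self.top_conc_um <= 0:
            raise ValueError("top_conc_um must be positive")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def concentrations_um(self) -> np.ndarray:
        """Concentrations c_k = top / fold**k, k = 0..n_points-1 (µM)."""
        k = np.arange(self.n_points)
        return self.top_conc_um / self.fold ** k.astype(float)

    @property
    def bottom_conc_um(self) -> float:
        return float(self.concentrations_um[-1])


def serial_dilution(top_conc_um: float, fold: float, n_points: int) -> DilutionSeries:
    """Design an ``n_points``-point, ``fold``-fold serial dilution from ``top_conc_um``."""
    return DilutionSeries(top_conc_um, fold, n_points)


@dataclass
class DoseResponseFit:
    """Result container for a concentration–response fit."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    extrapolated: bool = False
    diagnostic: str = ""
    ci_ic50: tuple[float, float] | None = None
    n_obs: int = 0
    conc_span: tuple[float, float] = (np.nan, np.nan)
    per_run_ic50: dict = field(default_factory=dict)


def _four_pl(conc: np.ndarray, log10_ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    out = np.full_like(conc, top, dtype=float)
    pos = conc > 0
    # (c/ic50)**hill computed in log space for numerical stability
    ratio = np.exp(hill * (np.log(conc[pos]) - np.log(10.0) * log10_ic50))
    out[pos] = bottom + (top - bottom) / (1.0 + ratio)
    return out


class LogLogisticIC50(BaseEstimator, RegressorMixin):
    """Four-parameter log-logistic concentration–response estimator.

    Fits ``bottom + (top - bottom) / (1 + (c/ic50)**hill)`` to observed
    responses by bounded nonlinear least squares, multi-started across a grid
    of candidate IC50 values spanning the tested concentration range.

    Parameters
    ----------
    hill : "free" or float
        Hill slope treatment: estimate it (default) or fix it.
    n_starts : int
        Number of IC50 grid starts (log-spaced across the dilution span).
    bootstrap : int
        If > 0, number of case-resampling bootstrap replicates used for a
        95% percentile confidence interval on IC50.
    random_state : int
        Seed for the bootstrap resampler (fitting itself is deterministic).

    Attributes
    ----------
    ic50_, hill_, top_, bottom_ : float
        Fitted parameters (ic50 in the units of the supplied concentrations).
    rss_ : float
        Residual sum of squares.
    converged_ : bool
        False for degenerate (flat) input or optimizer failure.
    extrapolated_ : bool
        True when ic50_ falls outside the tested concentration span.
    ci_ic50_ : tuple or None
        95% bootstrap CI when ``bootstrap > 0``.
    """

    def __init__(
        self,
        hill: str | float = "free",
        n_starts: int = 7,
        bootstrap: int = 0,
        random_state: int = 0,
    ) -> None:
        self.hill = hill
        self.n_starts = n_starts
        self.bootstrap = bootstrap
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, conc, response) -> "LogLogisticIC50":
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape:
            raise ValueError("conc and response must have the same shape")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(response)):
            raise ValueError("responses must be finite")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations")

        pos = conc[conc > 0]
        self.conc_span_ = (float(pos.min()), float(pos.max()))
        rng = np.random.default_rng(self.random_state)

        span = float(response.max() - response.min())
        if span <= 1e-12 * max(1.0, abs(float(response.max()))):
            # Flat response: no dose dependence; nothing to estimate.
            self.ic50_ = np.nan
            self.hill_ = np.nan
            self.top_ = float(response.mean())
            self.bottom_ = float(response.mean())
            self.rss_ = float(np.sum((response - response.mean()) ** 2))
            self.converged_ = False
            self.diagnostic_ = "flat"
            self.extrapolated_ = False
            self.ci_ic50_ = None
            return self

        theta, rss = self._fit_once(conc, response)
        self.ic50_ = 10.0 ** theta[0]
        self.hill_ = theta[1]
        self.top_ = theta[2]
        self.bottom_ = theta[3]
        self.rss_ = rss
        self.converged_ = True
        self.diagnostic_ = ""
        self.extrapolated_ = not (
            self.conc_span_[0] <= self.ic50_ <= self.conc_span_[1]
        )

        # Non-monotonicity beyond noise is worth a warning but not a failure.
        mean_by_c = [response[conc == c].mean() for c in np.unique(conc)]
        diffs = np.diff(mean_by_c)
        noise_scale = max(np.sqrt(rss / max(len(conc) - 4, 1)), 1e-12)
        if np.any(diffs > 3 * noise_scale) and np.any(diffs < -3 * noise_scale):
            warnings.warn("non-monotone concentration-response beyond noise", stacklevel=2)

        self.ci_ic50_ = None
        if self.bootstrap > 0:
            boots = []
            n = len(conc)
            for _ in range(self.bootstrap):
                idx = rng.integers(0, n, n)
                if len(np.unique(conc[idx])) < 4:
                    continue
                try:
                    th, _ = self._fit_once(conc[idx], response[idx])
                    boots.append(10.0 ** th[0])
                except Exception:
                    continue
            if len(boots) >= 10:
                lo, hi = np.percentile(boots, [2.5, 97.5])
                self.ci_ic50_ = (float(lo), float(hi))
        return self

    # ------------------------------------------------------------------
    def _fit_once(self, conc: np.ndarray, response: np.ndarray):
        lo_c, hi_c = np.log10(self.conc_span_[0]), np.log10(self.conc_span_[1])
        grid = np.linspace(lo_c - 0.5, hi_c + 0.5, self.n_starts)
        top0 = float(response[conc == conc.min()].mean())
        bot0 = float(response[conc == conc.max()].mean())
        fixed_hill = None if self.hill == "free" else float(self.hill)

        r_lo, r_hi = float(response.min()), float(response.max())
        # asymptotes may lie well outside the observed response range when the
        # dilution series covers only part of the transition
        pad = 10.0 * (r_hi - r_lo)

        def residuals(theta):
            if fixed_hill is None:
                li, h, t, b = theta
            else:
                li, t, b = theta
                h = fixed_hill
            return _four_pl(conc, li, h, t, b) - response

        best = None
        for li0 in grid:
            if fixed_hill is None:
                x0 = [li0, 1.0, top0, bot0]
                lb = [lo_c - 3, 0.1, r_lo - pad, r_lo - pad]
                ub = [hi_c + 3, 10.0, r_hi + pad, r_hi + pad]
            else:
                x0 = [li0, top0, bot0]
                lb = [lo_c - 3, r_lo - pad, r_lo - pad]
                ub = [hi_c + 3, r_hi + pad, r_hi + pad]
            x0 = np.clip(x0, lb, ub)
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[1] - 1e-15:
                best = (sol.x, rss)
        if best is None:
            raise RuntimeError("IC50 fit failed from every start")
        x, rss = best
        if fixed_hill is None:
            theta = (float(x[0]), float(x[1]), float(x[2]), float(x[3]))
        else:
            theta = (float(x[0]), fixed_hill, float(x[1]), float(x[2]))
        # Enforce bottom <= top by swap (equivalent model with hill sign flip
        # cannot occur since hill > 0 and top is the zero-dose asymptote).
        return theta, rss

    # ------------------------------------------------------------------
    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if not getattr(self, "converged_", False):
            raise RuntimeError("model did not converge; nothing to predict")
        return _four_pl(conc, np.log10(self.ic50_), self.hill_, self.top_, self.bottom_)

    def result_(self) -> DoseResponseFit:
        """Package fitted attributes as a :class:`DoseResponseFit`."""
        return DoseResponseFit(
            ic50=getattr(self, "ic50_", np.nan),
            hill=getattr(self, "hill_", np.nan),
            top=getattr(self, "top_", np.nan),
            bottom=getattr(self, "bottom_", np.nan),
            rss=getattr(self, "rss_", np.nan),
            converged=getattr(self, "converged_", False),
            extrapolated=getattr(self, "extrapolated_", False),
            diagnostic=getattr(self, "diagnostic_", ""),
            ci_ic50=getattr(self, "ci_ic50_", None),
            conc_span=getattr(self, "conc_span_", (np.nan, np.nan)),
        )


def fit_ic50(
    conc,
    response,
    hill: str | float = "free",
    bootstrap: int = 0,
    random_state: int = 0,
) -> DoseResponseFit:
    """Fit a four-parameter log-logistic curve and return the IC50 summary."""
    est = LogLogisticIC50(hill=hill, bootstrap=bootstrap, random_state=random_state)
    est.fit(conc, response)
    out = est.result_()
    out.n_obs = len(np.asarray(conc))
    return out


def ic50_ratio(fit_ref: DoseResponseFit | float, fit_mut: DoseResponseFit | float) -> float:
    """Fold differential IC50_ref / IC50_mut; > 1 means the mutant is more sensitive."""

    def _val(f):
        if isinstance(f, (int, float, np.floating)):
            v = float(f)
        else:
            if not f.converged:
                raise ValueError("cannot form IC50 ratio from a non-converged fit")
            v = f.ic50
        if not np.isfinite(v) or v <= 0:
            raise ValueError("IC50 must be positive and finite")
        return v

    return _val(fit_ref) / _val(fit_mut)
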