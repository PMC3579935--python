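"""Mono- and biphasic growth-curve fitting for OD600 time series.

Yeast growing on a mixture of a fermentable and a non-fermentable carbon
source shows diauxic growth: a fast glycolytic phase, a plateau while the
culture retools for respiration, and a second respiratory phase.  Strains
without a functional TCA cycle stop at the plateau.  This module fits

    OD(t) = b + sum_i  K_i / (1 + exp(-r_i (t - m_i)))

to a high-resolution absorbance trace (one logistic component per growth
phase) and reports, per phase, the three parameters used for differential
scoring:

* saturation   ``S_i = K_i``         (OD attained by the phase),
* maximal rate ``R_i = r_i K_i / 4`` (steepest slope, OD/h),
* lag          ``L_i = m_i - 2/r_i`` (tangent-at-inflection intercept, h,
  clamped at zero).

The number of phases can be forced (1 or 2) or chosen automatically: a
derivative-based segmentation proposes a hypothesis and starting values,
both one- and two-phase models are fitted, and the small-sample corrected
AIC selects between them with a margin favouring the simpler model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

__all__ = ["PhaseFit", "GrowthFitResult", "GrowthCurveModel", "segment_phases", "fit_growth"]

_MIN_POINTS = 30


@dataclass(frozen=True)
class PhaseFit:
    """Fitted parameters for one growth phase."""

    lag_h: float          # tangent-intercept lag, clamped at 0
    max_rate: float       # maximal slope r*K/4, OD/h
    saturation: float     # phase asymptote increment K, OD
    inflection_h: float   # logistic midpoint m
    shape_rate: float     # logistic shape parameter r, 1/h


@dataclass
class GrowthFitResult:
    """Full fit summary for one curve (``no_growth`` curves carry no phases)."""

    n_phases: int
    baseline: float
    phases: tuple[PhaseFit, ...]
    rss: float
    converged: bool
    no_growth: bool = False
    aicc: float = np.nan

    @property
    def total_saturation(self) -> float:
        """Fitted asymptote: baseline + sum of phase saturations."""
        return self.baseline + sum(p.saturation for p in self.phases)


def _logistic_sum(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """theta = [b, K1, r1, m1, (K2, r2, m2)]."""
    out = np.full_like(t, theta[0], dtype=float)
    for i in range((len(theta) - 1) // 3):
        K, r, m = theta[1 + 3 * i: 4 + 3 * i]
        out += K / (1.0 + np.exp(np.clip(-r * (t - m), -500, 500)))
    return out


def _smooth(od: np.ndarray, window: int) -> np.ndarray:
    s = (
        pd.Series(od)
        .rolling(window, center=True, min_periods=1)
        .median()
        .rolling(window, center=True, min_periods=1)
        .mean()
    )
    return s.to_numpy()


def _validate_curve(times, od):
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.ndim != 1 or times.shape != od.shape:
        raise ValueError("times and od must be 1-D arrays of equal length")
    if len(times) < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points for growth fitting")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(od)) or np.any(od < 0):
        raise ValueError("od values must be finite and non-negative")
    return times, od


def segment_phases(
    times,
    od,
    smooth_window: int = 5,
    valley_frac: float = 0.3,
    od_floor: float = 0.05,
):
    """Propose a phase count and initial parameter guesses from the derivative.

    The OD trace is smoothed (moving median then mean), numerically
    differentiated, and scanned for growth-rate maxima.  Two phases are
    proposed when two separated derivative maxima flank a valley below
    ``valley_frac`` of the smaller maximum.  A curve whose dynamic range is
    below ``od_floor`` is declared "no growth".

    Returns
    -------
    (n_phases, guesses) where ``n_phases`` is 0 (no growth), 1 or 2 and
    ``guesses`` maps each hypothesis to a theta vector ``[b, K, r, m, ...]``.
    """
    times, od = _validate_curve(times, od)
    sm = _smooth(od, smooth_window)
    rng_od = float(sm.max() - sm.min())
    if rng_od < od_floor:
        return 0, {}

    deriv = np.gradient(sm, times)
    base = float(np.percentile(sm[: max(3, len(sm) // 20)], 50))
    top = float(sm[-len(sm) // 20:].mean()) if len(sm) >= 20 else float(sm[-1])

    # single-phase guess: one logistic spanning the whole rise
    i_pk = int(np.argmax(deriv))
    K1 = max(top - base, 1e-3)
    r1 = max(4.0 * deriv[i_pk] / K1, 1e-2)
    guess1 = np.array([base, K1, r1, times[i_pk]])

    peaks, props = find_peaks(deriv, height=0.05 * deriv.max(), distance=max(3, len(times) // 50))
    n_phases = 1
    guess2 = None
    if len(peaks) >= 2:
        # two tallest separated maxima
        order = np.argsort(props["peak_heights"])[::-1]
        p1, p2 = sorted(peaks[order[:2]])
        valley = float(deriv[p1:p2 + 1].min())
        smaller = min(deriv[p1], deriv[p2])
        if valley < valley_frac * smaller:
            n_phases = 2
            i_val = p1 + int(np.argmin(deriv[p1:p2 + 1]))
            plateau = float(sm[i_val])
            Ka = max(plateau - base, 1e-3)
            Kb = max(top - plateau, 1e-3)
            ra = max(4.0 * deriv[p1] / Ka, 1e-2)
            rb = max(4.0 * deriv[p2] / Kb, 1e-2)
            guess2 = np.array([base, Ka, ra, times[p1], Kb, rb, times[p2]])
    if guess2 is None:
        # fallback: split the rise in half around the single peak
        mid = base + K1 / 2
        i_half = int(np.argmin(np.abs(sm - mid)))
        guess2 = np.array(
            [base, K1 / 2, 2 * r1, times[max(i_pk - len(times) // 10, 1)],
             K1 / 2, 2 * r1, times[min(i_half + len(times) // 5, len(times) - 1)]]
        )
    return n_phases, {1: guess1, 2: guess2}


class GrowthCurveModel(BaseEstimator):
    """Sum-of-logistics growth-curve estimator.

    Parameters
    ----------
    n_phases : 1, 2 or "auto"
        Phase-count hypothesis.  ``"auto"`` fits both and selects by
        corrected AIC, preferring the simpler model unless the two-phase
        fit improves AICc by more than ``aicc_margin``.
    n_starts : int
        Multi-start count; starts beyond the first jitter the segmentation
        guess (deterministic given ``random_state``).
    od_floor : float
        Dynamic range below which a curve is declared "no growth".
    aicc_margin : float
        AICc improvement the two-phase model must achieve.

    Attributes
    ----------
    n_phases_ : int       0 for a no-growth curve.
    baseline_ : float
    phases_ : tuple of :class:`PhaseFit`, ordered by inflection time.
    rss_, aicc_ : float
    converged_, no_growth_ : bool
    """

    def __init__(
        self,
        n_phases: int | str = "auto",
        n_starts: int = 5,
        random_state: int = 0,
        smooth_window: int = 5,
        valley_frac: float = 0.3,
        od_floor: float = 0.05,
        aicc_margin: float = 2.0,
    ) -> None:
        self.n_phases = n_phases
        self.n_starts = n_starts
        self.random_state = random_state
        self.smooth_window = smooth_window
        self.valley_frac = valley_frac
        self.od_floor = od_floor
        self.aicc_margin = aicc_margin

    # ------------------------------------------------------------------
    def fit(self, times, od) -> "GrowthCurveModel":
        times, od = _validate_curve(times, od)
        if self.n_phases not in (1, 2, "auto"):
            raise ValueError("n_phases must be 1, 2 or 'auto'")
        hint, guesses = segment_phases(
            times, od, self.smooth_window, self.valley_frac, self.od_floor
        )
        if hint == 0:
            self.n_phases_ = 0
            self.baseline_ = float(np.median(od))
            self.phases_ = ()
            self.rss_ = float(np.sum((od - self.baseline_) ** 2))
            self.aicc_ = np.nan
            self.converged_ = True
            self.no_growth_ = True
            self._times = times
            return self

        rng = np.random.default_rng(self.random_state)
        candidates = [self.n_phases] if self.n_phases != "auto" else [1, 2]
        fits = {}
        for p in candidates:
            fits[p] = self._fit_hypothesis(times, od, guesses[p], rng)

        if self.n_phases == "auto":
            a1, a2 = fits[1][2], fits[2][2]
            chosen = 2 if (a2 < a1 - self.aicc_margin and fits[2][3]) else 1
            # fall back to whichever converged
            if not fits[chosen][3] and fits[3 - chosen][3]:
                chosen = 3 - chosen
        else:
            chosen = self.n_phases

        theta, rss, aicc, ok = fits[chosen]
        order = np.argsort(theta[3::3])  # sort phases by inflection m
        phases = []
        for i in order:
            K, r, m = theta[1 + 3 * i: 4 + 3 * i]
            phases.append(
                PhaseFit(
                    lag_h=max(m - 2.0 / r, 0.0),
                    max_rate=r * K / 4.0,
                    saturation=K,
                    inflection_h=m,
                    shape_rate=r,
                )
            )
        self.n_phases_ = chosen
        self.baseline_ = float(theta[0])
        self.phases_ = tuple(phases)
        self.rss_ = rss
        self.aicc_ = aicc
        self.converged_ = ok
        self.no_growth_ = False
        self._theta = theta
        self._times = times
        return self

    # ------------------------------------------------------------------
    def _fit_hypothesis(self, times, od, guess, rng):
        t_span = times[-1] - times[0]
        od_max = float(od.max())
        n_comp = (len(guess) - 1) // 3
        lb = [0.0] + [1e-4, 1e-2, times[0] - t_span] * n_comp
        ub = [max(od_max, 1e-3)] + [2.5 * max(od_max, 1e-3), 200.0, times[-1] + t_span] * n_comp

        def residuals(theta):
            return _logistic_sum(times, theta) - od

        starts = [np.asarray(guess, dtype=float)]
        for _ in range(self.n_starts - 1):
            jit = guess * np.exp(rng.normal(0, 0.2, size=len(guess)))
            jit[3::3] = guess[3::3] + rng.normal(0, 0.05 * t_span, size=n_comp)
            starts.append(jit)

        best = None
        for x0 in starts:
            x0 = np.clip(x0, lb, ub)
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[1] - 1e-15:
                best = (sol.x, rss, sol.status > 0)
        if best is None:
            return guess, np.inf, np.inf, False
        theta, rss, ok = best
        n, k = len(times), 1 + 3 * n_comp
        aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2.0 * k * (k + 1) / (n - k - 1)
        return theta, rss, aicc, ok

    # ------------------------------------------------------------------
    def predict(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if getattr(self, "no_growth_", False):
            return np.full_like(times, self.baseline_, dtype=float)
        return _logistic_sum(times, self._theta)

    def result_(self) -> GrowthFitResult:
        return GrowthFitResult(
            n_phases=self.n_phases_,
            baseline=self.baseline_,
            phases=self.phases_,
            rss=self.rss_,
            converged=self.converged_,
            no_growth=self.no_growth_,
            aicc=self.aicc_,
        )


def fit_growth(times, od, n_phases: int | str = "auto", random_state: int = 0, **kwargs) -> GrowthFitResult:
    """Fit a growth curve and return the phase-parameter summary."""
    model = GrowthCurveModel(n_phases=n_phases, random_state=random_state, **kwargs)
    model.fit(times, od)
    return model.result_()
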