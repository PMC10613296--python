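"""Psychometric quantification of fear/happy judgments.

The proportion of "fear" choices as a function of morph level x is
modeled as a three-parameter logistic

    P(x) = P_inf / (1 + exp(-alpha * (x - x_half)))

where ``x_half`` is the emotion-discrimination threshold (curve
midpoint, percent-fear units), ``alpha`` the sensitivity (steepness,
per percent) and ``P_inf`` the asymptote.  The curve is fitted by least
squares on the observed per-level choice proportions with multi-start
bounded optimization.

The module also derives the condition-level summaries used downstream:
the ambiguity grouping of morph levels, the (high - anchor)/anchor
modulation index of RT/confidence measures, and the raw RT difference
DeltaRT ("ambiguity sensitivity") that feeds the connectivity
prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._stats import cohens_d, rm_anova
from .datasets import BehavioralSession
from .design import group_ambiguity

__all__ = [
    "PsychometricRegression",
    "PsychometricFit",
    "ModulationIndex",
    "AmbiguitySensitivity",
    "fit_psychometric",
    "modulation_index",
    "ambiguity_sensitivity",
    "group_compare",
    "choice_proportions",
]

_BOUNDS_LO = np.array([1e-3, 0.0, 1e-4])   # p_inf, x_half, alpha
_BOUNDS_HI = np.array([1.05, 100.0, 5.0])


def logistic(x: np.ndarray, p_inf: float, x_half: float, alpha: float) -> np.ndarray:
    from scipy.special import expit

    return p_inf * expit(alpha * (np.asarray(x, dtype=float) - x_half))


def choice_proportions(session: BehavioralSession) -> pd.DataFrame:
    """Per-morph-level proportion of trials judged "fear"."""
    t = session.trials
    grp = t.groupby("morph_pct")["choice"]
    out = pd.DataFrame(
        {
            "n": grp.size(),
            "p_fear": grp.apply(lambda c: float(np.mean(c == "fear"))),
        }
    ).reset_index()
    return out


class PsychometricRegression(BaseEstimator):
    """Least-squares logistic psychometric curve.

    Fit on per-trial data: ``X`` is the morph level (percent fear,
    one column), ``y`` the binary choice (1/"fear" vs 0/"happy").
    Trials are aggregated into per-level proportions and the logistic
    parameters minimize the sum of squared proportion residuals.

    Parameters
    ----------
    n_starts : int
        Number of multi-start initializations (moment-based guess plus
        a coarse grid over threshold and slope).

    Attributes
    ----------
    p_inf_, x_half_, alpha_slope_ : float
        Fitted asymptote, threshold and sensitivity.
    rss_ : float
        Residual sum of squares on the proportions.
    converged_ : bool
        False when the slope is unidentifiable (all choices identical /
        constant proportions) or the optimizer failed.
    diagnostic_ : str
        Human-readable reason when not converged.
    """

    def __init__(self, n_starts: int = 12) -> None:
        self.n_starts = n_starts

    # -- sklearn plumbing ---------------------------------------------------
    def _as_xy(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.asarray(y).dtype.kind in "OSU":
            y = np.asarray([1.0 if c == "fear" else 0.0 for c in np.asarray(y)])
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        return x, y

    def fit(self, X, y) -> "PsychometricRegression":
        x, y = self._as_xy(X, y)
        levels, inv = np.unique(x, return_inverse=True)
        if levels.size < 2:
            raise ValueError("need at least 2 distinct morph levels")
        props = np.bincount(inv, weights=y) / np.bincount(inv)
        return self.fit_proportions(levels, props)

    def fit_proportions(self, levels, props) -> "PsychometricRegression":
        """Fit directly on per-level fear proportions."""
        levels = np.asarray(levels, dtype=float)
        props = np.asarray(props, dtype=float)
        self.levels_ = levels
        self.proportions_ = props
        self.converged_ = True
        self.diagnostic_ = ""
        if np.ptp(props) < 1e-12:
            # constant proportions: slope is unidentifiable
            self.p_inf_ = float(props[0])
            self.x_half_ = float(np.median(levels))
            self.alpha_slope_ = np.nan
            self.rss_ = 0.0
            self.converged_ = False
            self.diagnostic_ = "all choice proportions identical; slope unidentifiable"
            return self

        best = None
        for p0 in self._starts(levels, props):
            try:
                res = optimize.least_squares(
                    lambda th: logistic(levels, *th) - props,
                    p0,
                    bounds=(_BOUNDS_LO, _BOUNDS_HI),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:  # pragma: no cover - optimizer blow-up
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:  # pragma: no cover
            self.p_inf_ = self.x_half_ = self.alpha_slope_ = np.nan
            self.rss_ = np.nan
            self.converged_ = False
            self.diagnostic_ = "optimizer failed from every start"
            return self
        self.p_inf_, self.x_half_, self.alpha_slope_ = map(float, best.x)
        self.rss_ = float(2.0 * best.cost)
        return self

    def _starts(self, levels: np.ndarray, props: np.ndarray):
        p_inf0 = float(np.clip(props.max(), 0.05, 1.05))
        # threshold guess: level where proportions cross half the asymptote
        half = p_inf0 / 2.0
        idx = int(np.argmin(np.abs(props - half)))
        x0 = float(levels[idx])
        span = max(np.ptp(levels), 1.0)
        alpha0 = float(np.clip(4.0 * np.ptp(props) / span, 1e-3, 5.0))
        starts = [np.array([p_inf0, x0, alpha0])]
        grid_x = np.array([30.0, 50.0, 70.0])
        grid_a = np.array([0.05, 0.2, 1.0])
        for gx in grid_x:
            for ga in grid_a:
                starts.append(np.array([p_inf0, gx, ga]))
        return starts[: max(1, self.n_starts)]

    def predict(self, X) -> np.ndarray:
        """Fitted P(fear) at morph levels ``X``."""
        if not hasattr(self, "p_inf_"):
            raise AttributeError("PsychometricRegression is not fitted")
        return logistic(np.asarray(X, dtype=float).reshape(-1),
                        self.p_inf_, self.x_half_, self.alpha_slope_)


@dataclass(frozen=True)
class PsychometricFit:
    p_inf: float
    x_half: float
    alpha_slope: float
    rss: float
    converged: bool
    diagnostic: str = ""


def fit_psychometric(session: BehavioralSession, n_starts: int = 12) -> PsychometricFit:
    """Fit the logistic psychometric curve to one participant's choices."""
    t = session.trials
    est = PsychometricRegression(n_starts=n_starts).fit(
        t["morph_pct"].to_numpy(), t["choice"].to_numpy()
    )
    return PsychometricFit(
        p_inf=est.p_inf_,
        x_half=est.x_half_,
        alpha_slope=est.alpha_slope_,
        rss=est.rss_,
        converged=est.converged_,
        diagnostic=est.diagnostic_,
    )


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

_MEASURE_COLUMNS = {
    "rt": "rt_s",
    "confidence": "confidence",
    "confidence_rt": "confidence_rt_s",
}


@dataclass(frozen=True)
class ModulationIndex:
    measure: str
    value: float
    high_mean: float
    anchor_mean: float


@dataclass(frozen=True)
class AmbiguitySensitivity:
    delta_rt: float  # seconds, high-ambiguity mean RT minus anchor mean RT


def _condition_means(session: BehavioralSession, column: str) -> dict[str, float]:
    t = session.trials
    if column not in t.columns:
        raise ValueError(f"session has no {column!r} measure")
    levels = t["morph_pct"].map(group_ambiguity)
    vals = t[column]
    ok = vals.notna()
    means: dict[str, float] = {}
    for cond in ("anchor", "high"):
        sel = ok & (levels == cond)
        if not sel.any():
            raise ValueError(f"no non-missing {column!r} trials in condition {cond!r}")
        means[cond] = float(vals[sel].mean())
    return means


def modulation_index(session: BehavioralSession, measure: str) -> ModulationIndex:
    """(high - anchor) / anchor modulation of a behavioral measure.

    ``measure`` is one of ``"rt"``, ``"confidence"``, ``"confidence_rt"``.
    """
    try:
        column = _MEASURE_COLUMNS[measure]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r}; expected one of {sorted(_MEASURE_COLUMNS)}"
        ) from None
    means = _condition_means(session, column)
    if means["anchor"] == 0:
        raise ZeroDivisionError(
            f"anchor mean of {measure} is zero; modulation undefined"
        )
    value = (means["high"] - means["anchor"]) / means["anchor"]
    return ModulationIndex(measure, value, means["high"], means["anchor"])


def ambiguity_sensitivity(session: BehavioralSession) -> AmbiguitySensitivity:
    """DeltaRT = mean RT at high ambiguity minus mean RT at anchor, seconds."""
    means = _condition_means(session, "rt_s")
    return AmbiguitySensitivity(delta_rt=means["high"] - means["anchor"])


def group_compare(
    values_by_group: "dict[str, np.ndarray]", design: str = "independent"
) -> dict:
    """Compare a scalar measure across participant groups.

    Two independent groups: two-tailed two-sample t with Cohen's d.
    More than two groups: one-way ANOVA (repeated-measures when
    ``design="repeated"``, in which case groups are treated as
    within-participant conditions aligned by position).
    """
    if design not in ("independent", "repeated"):
        raise ValueError("design must be 'independent' or 'repeated'")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >=2 groups with >=2 values each")
    if len(groups) == 2 and design == "independent":
        (na, a), (nb, b) = groups.items()
        t, p = stats.ttest_ind(a, b)
        return {
            "test": "t",
            "statistic": float(t),
            "p_value": float(p),
            "effect_size": cohens_d(a, b),
            "df": a.size + b.size - 2,
        }
    if design == "repeated":
        sizes = {g.size for g in groups.values()}
        if len(sizes) != 1:
            raise ValueError("repeated-measures design requires equal group sizes")
        table = pd.DataFrame(groups)
        return rm_anova(table)
    f, p = stats.f_oneway(*groups.values())
    # eta^2 from sums of squares
    allv = np.concatenate(list(groups.values()))
    ss_between = sum(g.size * (g.mean() - allv.mean()) ** 2 for g in groups.values())
    ss_total = float(((allv - allv.mean()) ** 2).sum())
    return {
        "test": "anova",
        "statistic": float(f),
        "p_value": float(p),
        "effect_size": ss_between / ss_total if ss_total > 0 else 0.0,
        "df": (len(groups) - 1, allv.size - len(groups)),
    }
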