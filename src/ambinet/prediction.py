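"""Linear prediction of amygdala-dmPFC functional connectivity from
behavioral ambiguity sensitivity.

The model is the affine map

    y(connectivity) = a * DeltaRT(high - anchor) + b

with DeltaRT in seconds and constants fitted on neuroimaging data
(defaults a = 2.4739, b = -0.1329, dimensionless connectivity units).
Group comparisons of predicted connectivity against a control group use
two-tailed two-sample t-tests; because the map is affine, these are
numerically identical to t-tests on DeltaRT itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._stats import cohens_d

__all__ = ["ConnectivityPredictor", "predict_connectivity", "compare_groups"]

DEFAULT_A = 2.4739  # connectivity units per second of DeltaRT
DEFAULT_B = -0.1329


class ConnectivityPredictor(RegressorMixin, BaseEstimator):
    """Affine DeltaRT -> connectivity map.

    Usable without fitting (the published constants are the defaults);
    :meth:`fit` refits ``a`` and ``b`` by ordinary least squares from
    paired (DeltaRT, connectivity) observations.
    """

    def __init__(self, a: float = DEFAULT_A, b: float = DEFAULT_B):
        self.a = a
        self.b = b

    def fit(self, X, y) -> "ConnectivityPredictor":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 2:
            raise ValueError("need >= 2 paired observations")
        slope, intercept = np.polyfit(x, y, 1)
        self.a_ = float(slope)
        self.b_ = float(intercept)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("DeltaRT inputs must be finite")
        a = getattr(self, "a_", self.a)
        b = getattr(self, "b_", self.b)
        return a * x + b


def predict_connectivity(
    delta_rt, a: float = DEFAULT_A, b: float = DEFAULT_B
) -> np.ndarray:
    """y = a * DeltaRT + b, DeltaRT in seconds."""
    return ConnectivityPredictor(a, b).predict(delta_rt)


def compare_groups(
    delta_rt_by_group: "dict[str, np.ndarray]",
    control_label: str = "control",
    a: float = DEFAULT_A,
    b: float = DEFAULT_B,
) -> pd.DataFrame:
    """Predicted connectivity of each group versus the control group.

    Returns one row per non-control group with the two-tailed two-sample
    t statistic, p-value, Cohen's d, and the group's mean predicted
    connectivity normalized by subtracting the control-group mean.
    """
    if control_label not in delta_rt_by_group:
        raise ValueError(f"control group {control_label!r} missing")
    model = ConnectivityPredictor(a, b)
    preds = {
        g: model.predict(np.asarray(v, dtype=float).reshape(-1))
        for g, v in delta_rt_by_group.items()
    }
    if any(v.size < 2 for v in preds.values()):
        raise ValueError("every group needs >= 2 participants")
    control = preds[control_label]
    rows = []
    for g, y in preds.items():
        if g == control_label:
            continue
        t, p = stats.ttest_ind(y, control)
        rows.append(
            {
                "group": g,
                "n": y.size,
                "mean_y": float(y.mean()),
                "normalized_mean_y": float(y.mean() - control.mean()),
                "t": float(t),
                "p_value": float(p),
                "cohens_d": cohens_d(y, control),
                "df": y.size + control.size - 2,
            }
        )
    return pd.DataFrame(rows)
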