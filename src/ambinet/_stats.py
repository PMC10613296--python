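"""Small shared statistical helpers (effect sizes, RM-ANOVA wrapper)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def rm_anova(table: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    Rows are participants, columns the within-participant conditions.
    Returns the F statistic, p-value and generalized eta-squared.
    """
    import pingouin as pg

    if table.isna().any().any():
        raise ValueError("repeated-measures table has missing cells")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >=2 participants and >=2 conditions")
    long = table.reset_index(names="participant").melt(
        id_vars="participant", var_name="condition", value_name="value"
    )
    res = pg.rm_anova(
        data=long, dv="value", within="condition", subject="participant", detailed=True
    )
    row = res.iloc[0]
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return {
        "test": "rm_anova",
        "statistic": float(row["F"]),
        "p_value": float(row[p_col]),
        "effect_size": float(row["ng2"]),
        "df": (float(row["DF"]), float(res.iloc[1]["DF"])),
    }
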