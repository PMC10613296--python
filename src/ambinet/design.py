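"""Task-design constants for the fear-happy morph judgment task.

Stimuli are morphed fear-happy faces on a fixed grid of percent-fear
levels.  The seven morph levels collapse into three ordinal ambiguity
levels: unambiguous anchors (0/100%), intermediate morphs (30/70%) and
the most ambiguous morphs (40-60%).
"""

from __future__ import annotations

MORPH_GRID: tuple[int, ...] = (0, 30, 40, 50, 60, 70, 100)

AMBIGUITY_LEVELS: tuple[str, ...] = ("anchor", "intermediate", "high")

#: ordinal codes used in the trial-by-trial selection regression
LEVEL_CODES: dict[str, int] = {"anchor": 1, "intermediate": 2, "high": 3}

#: fractional ambiguity score used to interpolate condition effects
AMBIGUITY_SCORE: dict[str, float] = {"anchor": 0.0, "intermediate": 0.5, "high": 1.0}

_AMBIGUITY_OF_MORPH: dict[int, str] = {
    0: "anchor",
    100: "anchor",
    30: "intermediate",
    70: "intermediate",
    40: "high",
    50: "high",
    60: "high",
}


def group_ambiguity(morph_pct: int) -> str:
    """Map a percent-fear morph level to its ambiguity level.

    Parameters
    ----------
    morph_pct : int
        Morph level on the grid {0, 30, 40, 50, 60, 70, 100}.

    Returns
    -------
    str
        One of ``"anchor"``, ``"intermediate"``, ``"high"``.

    Raises
    ------
    ValueError
        If the morph level is off the grid.
    """
    try:
        return _AMBIGUITY_OF_MORPH[int(morph_pct)]
    except (KeyError, TypeError):
        raise ValueError(
            f"morph level {morph_pct!r} is not on the grid {MORPH_GRID}"
        ) from None
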