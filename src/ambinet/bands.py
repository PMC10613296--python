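"""Canonical EEG frequency-band edges.

Single source of truth shared by the synthetic-epoch generator, the
coherence analysis and the cross-frequency coupling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz
    hi: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.lo, self.hi)


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}

#: combined theta/alpha/low-beta range used for the Pz-seeded coherence map
COHERENCE_BAND: tuple[float, float] = (4.0, 23.0)

#: DTF analysis grid edges
DTF_BAND: tuple[float, float] = (1.0, 30.0)


def get_band(band: "str | BandDefinition | tuple[float, float]") -> BandDefinition:
    """Resolve a band name, tuple of edges, or BandDefinition."""
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    lo, hi = band
    return BandDefinition(f"{lo:g}-{hi:g}Hz", float(lo), float(hi))
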