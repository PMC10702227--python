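"""Canonical cortical LFP frequency bands.

Six bands are delineated throughout: delta (0.5-4 Hz), theta (4-8 Hz),
alpha (8-12 Hz), beta (15-30 Hz), low gamma (30-70 Hz) and high gamma
(70-120 Hz).  Band names are the single source of truth for every module
that filters, couples or locks to a band.
"""

from __future__ import annotations

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "low_gamma": (30.0, 70.0),
    "high_gamma": (70.0, 120.0),
}

BAND_ORDER = tuple(BANDS)

#: four behavioral states, in the order clusters are assigned to them
STATES = ("Move", "Rest", "REM", "NREM")


def band_edges(name: str) -> tuple[float, float]:
    """Return (low, high) edges in Hz for a canonical band name."""
    try:
        return BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; expected one of {sorted(BANDS)}"
        ) from None


def band_center(name: str) -> float:
    lo, hi = band_edges(name)
    return 0.5 * (lo + hi)


def band_pairs() -> list[tuple[str, str]]:
    """All 15 ordered (low, high) band pairs with low center < high center."""
    names = BAND_ORDER
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
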