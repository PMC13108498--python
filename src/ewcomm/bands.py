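"""Canonical frequency bands used throughout the analysis.

The five bands span the classic MEG rhythms analysed for routing principles:
theta (4-6 Hz), alpha (8-12 Hz), beta (14-24 Hz), low gamma (30-59 Hz) and
high gamma (60-80 Hz). Bands are non-overlapping and do not tile the
spectrum, so the five relative band powers sum to less than one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple


@dataclass(frozen=True)
class Band:
    """A closed frequency interval [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


DEFAULT_BANDS: Tuple[Band, ...] = (
    Band("theta", 4.0, 6.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 14.0, 24.0),
    Band("gamma_lo", 30.0, 59.0),
    Band("gamma_hi", 60.0, 80.0),
)

BAND_NAMES: Tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def validate_bands(bands: Sequence[Band]) -> Tuple[Band, ...]:
    """Check that bands are ordered, non-overlapping and strictly increasing."""
    bands = tuple(bands)
    if not bands:
        raise ValueError("need at least one band")
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.lo <= prev.hi:
            raise ValueError(f"bands {prev.name!r} and {nxt.name!r} overlap or are out of order")
    return bands


def band_index(bands: Sequence[Band], name: str) -> int:
    for i, b in enumerate(bands):
        if b.name == name:
            return i
    raise KeyError(f"unknown band {name!r}; have {[b.name for b in bands]}")
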