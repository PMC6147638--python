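"""Frequency band definitions."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with edges in Hz.

    Parameters
    ----------
    name : str
        Label used to tag layers and output files.
    low, high : float
        Band edges in Hz; ``0 < low < high`` is required.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, freq: float, strict: bool = True) -> bool:
        if strict:
            return self.low < freq < self.high
        return self.low <= freq <= self.high


THETA = FrequencyBand("theta", 3.0, 8.0)
ALPHA = FrequencyBand("alpha", 8.0, 12.0)
BETA = FrequencyBand("beta", 12.0, 30.0)
GAMMA = FrequencyBand("gamma", 30.0, 100.0)

#: The four canonical bands, in layer order.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (THETA, ALPHA, BETA, GAMMA)

_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def band_by_name(name: str) -> FrequencyBand:
    """Look up one of the canonical bands by its label."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known bands: {sorted(_BY_NAME)}"
        ) from None
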