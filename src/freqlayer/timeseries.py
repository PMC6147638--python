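"""Multichannel time-series container and plain-text I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from freqlayer.bands import FrequencyBand


@dataclass
class TimeSeriesSet:
    """A channels x samples matrix with sampling-rate metadata.

    Parameters
    ----------
    values : ndarray, shape (n_channels, n_samples)
        Real-valued signals, one row per channel. All values must be finite.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    channel_ids : sequence of str, optional
        Channel labels; defaults to ``ch000, ch001, ...``.
    band : FrequencyBand, optional
        Set when the signals have been band-pass filtered.
    """

    values: np.ndarray
    sampling_rate: float
    channel_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    band: FrequencyBand | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"values must be 2-D (channels x samples), got {self.values.ndim}-D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.values.shape[0])]
        else:
            self.channel_ids = list(self.channel_ids)
            if len(self.channel_ids) != self.values.shape[0]:
                raise ValueError(
                    f"{len(self.channel_ids)} channel ids for "
                    f"{self.values.shape[0]} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_values(self, values: np.ndarray, band: FrequencyBand | None = None) -> "TimeSeriesSet":
        """Copy of this set with new sample values (same metadata)."""
        return TimeSeriesSet(
            values=values,
            sampling_rate=self.sampling_rate,
            channel_ids=list(self.channel_ids),
            band=band if band is not None else self.band,
        )


def write_signals(ts: TimeSeriesSet, prefix: str | Path, extra_meta: dict | None = None) -> None:
    """Write signals as ``<prefix>.tsv`` (rows = channels) + JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), ts.values, delimiter="\t", fmt="%.17g")
    meta = {
        "sampling_rate": ts.sampling_rate,
        "channel_ids": list(ts.channel_ids),
        "band": None
        if ts.band is None
        else {"name": ts.band.name, "low": ts.band.low, "high": ts.band.high},
    }
    if extra_meta:
        meta.update(extra_meta)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_signals(prefix: str | Path) -> TimeSeriesSet:
    """Read signals written by :func:`write_signals`."""
    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    band = meta.get("band")
    return TimeSeriesSet(
        values=values,
        sampling_rate=meta["sampling_rate"],
        channel_ids=meta["channel_ids"],
        band=None if band is None else FrequencyBand(band["name"], band["low"], band["high"]),
    )
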