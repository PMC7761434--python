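"""EEG trial container and interval cropping."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["EEGTrial", "Interval", "crop"]


@dataclass(frozen=True)
class EEGTrial:
    """One trial of multichannel EEG.

    ``data`` is a ``(n_channels, n_samples)`` float matrix in µV, ``fs`` the
    sampling rate in Hz, ``channel_names`` the electrode labels (e.g. C3, C4)
    and ``label`` the motor-imagery class ("left"/"right") or ``None`` for
    unlabeled data.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple
    label: str | None = None

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.data, dtype=float))
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"trial data must be (channels, samples), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trial data contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.channel_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """The single-channel signal for an electrode label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in trial (has {list(self.channel_names)})"
            ) from None
        return self.data[idx]


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive sample interval [b, d]; its length is H = d - b + 1."""

    b: int
    d: int

    def __post_init__(self) -> None:
        if not (isinstance(self.b, (int, np.integer)) and isinstance(self.d, (int, np.integer))):
            raise ValueError("interval bounds must be integers")
        if not (1 <= self.b <= self.d):
            raise ValueError(f"need 1 <= b <= d, got b={self.b}, d={self.d}")

    @property
    def H(self) -> int:
        return self.d - self.b + 1

    def slice(self) -> slice:
        """The equivalent 0-based Python slice."""
        return slice(self.b - 1, self.d)


def crop(trial: EEGTrial, interval: Interval) -> EEGTrial:
    """Restrict every channel to the inclusive sample interval [b, d]."""
    if interval.d > trial.n_samples:
        raise ValueError(
            f"interval [{interval.b}, {interval.d}] exceeds trial length {trial.n_samples}"
        )
    return replace(trial, data=trial.data[:, interval.slice()])
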