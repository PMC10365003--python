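"""Core containers shared by every stage.

Units: echo times and T2* are always milliseconds; signal intensities are
arbitrary units (magnitude data, hence non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["EchoTrain", "EchoSeries", "ImageStack", "default_echo_train"]


@dataclass(frozen=True)
class EchoTrain:
    """An ordered schedule of echo times (ms).

    Must be strictly increasing, strictly positive, and hold at least
    three echoes (a two-parameter exponential needs three points for a
    non-trivial goodness of fit).
    """

    tes: np.ndarray

    def __init__(self, tes) -> None:
        tes = np.asarray(tes, dtype=float)
        if tes.ndim != 1 or tes.size < 3:
            raise InvalidInputError(
                f"echo train needs >= 3 echo times, got shape {tes.shape}"
            )
        if np.any(tes <= 0):
            raise InvalidInputError("echo times must be positive (ms)")
        if np.any(np.diff(tes) <= 0):
            raise InvalidInputError("echo times must be strictly increasing")
        tes.setflags(write=False)
        object.__setattr__(self, "tes", tes)

    def __len__(self) -> int:
        return int(self.tes.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, EchoTrain) and np.array_equal(self.tes, other.tes)

    def truncate(self, n: int) -> "EchoTrain":
        """Return the first ``n`` echoes."""
        return EchoTrain(self.tes[:n])


def default_echo_train(n_echoes: int = 10, first_te: float = 0.8,
                       spacing: float = 1.0) -> EchoTrain:
    """Liver-protocol echo schedule: first TE 0.8 ms, 1.0 ms spacing, 10 echoes."""
    return EchoTrain(first_te + spacing * np.arange(n_echoes))


@dataclass(frozen=True)
class EchoSeries:
    """Signal intensity sampled at each echo of one ROI (or one pixel)."""

    echo_train: EchoTrain
    signals: np.ndarray

    def __init__(self, echo_train: EchoTrain, signals) -> None:
        signals = np.asarray(signals, dtype=float)
        if signals.shape != (len(echo_train),):
            raise InvalidInputError(
                f"signals shape {signals.shape} does not match "
                f"{len(echo_train)} echoes"
            )
        if np.any(signals < 0):
            raise InvalidInputError("magnitude signals must be non-negative")
        signals.setflags(write=False)
        object.__setattr__(self, "echo_train", echo_train)
        object.__setattr__(self, "signals", signals)

    @property
    def tes(self) -> np.ndarray:
        return self.echo_train.tes

    def __len__(self) -> int:
        return len(self.echo_train)

    def truncate(self, n: int) -> "EchoSeries":
        return EchoSeries(self.echo_train.truncate(n), self.signals[:n])


@dataclass(frozen=True)
class ImageStack:
    """Multi-echo magnitude image stack: one 2-D image per echo time.

    ``data`` has shape ``(ny, nx, n_echoes)`` with echoes in the order of
    ``echo_train`` (ascending TE).
    """

    data: np.ndarray
    echo_train: EchoTrain

    def __init__(self, data, echo_train: EchoTrain) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise InvalidInputError(
                f"stack must be (ny, nx, n_echoes), got shape {data.shape}"
            )
        if data.shape[2] != len(echo_train):
            raise InvalidInputError(
                f"stack has {data.shape[2]} echo frames but the echo train "
                f"lists {len(echo_train)} TEs"
            )
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "echo_train", echo_train)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]
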