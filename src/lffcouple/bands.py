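"""Frequency bands for BOLD low-frequency fluctuation analysis.

The resting BOLD spectrum below ~0.1 Hz is conventionally split into
slow-5 (0.01-0.027 Hz) and slow-4 (0.027-0.073 Hz); their union is the
"full" low-frequency band analyzed here.  Band membership of discrete
FFT bins uses half-open intervals ``[f_low, f_high)`` except for bands
flagged ``closed_high``, whose top edge bin is included.  With slow-5
open at the top and slow-4 closed, the two sub-bands partition the
full band's bin set exactly, so band-limited quantities add up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrequencyBand", "FULL_BAND", "SLOW5", "SLOW4", "DEFAULT_BANDS", "get_band"]

# relative slack when comparing bin frequencies to band edges
_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval in Hz.

    Parameters
    ----------
    name :
        Short identifier (``"full"``, ``"slow5"``, ``"slow4"``).
    f_low, f_high :
        Band edges in Hz, ``0 < f_low < f_high``.
    closed_high :
        If True a discrete frequency bin falling exactly on ``f_high``
        belongs to this band; otherwise the interval is half-open.
    """

    name: str
    f_low: float
    f_high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    def validate_against(self, tr_seconds: float) -> None:
        """Raise if the band does not fit below the Nyquist frequency."""
        nyquist = 0.5 / tr_seconds
        if self.f_high > nyquist * (1.0 + _EDGE_RTOL):
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz exceeds "
                f"Nyquist {nyquist:.4g} Hz at TR={tr_seconds}s"
            )

    def bin_mask(self, n_timepoints: int, tr_seconds: float) -> np.ndarray:
        """Boolean mask over one-sided (rfft) frequency bins inside the band.

        The DC bin is never included.  Raises if no bin falls in the band.
        """
        self.validate_against(tr_seconds)
        freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
        tol = _EDGE_RTOL * self.f_high
        mask = (freqs >= self.f_low - tol) & (freqs < self.f_high - tol)
        if self.closed_high:
            mask |= np.abs(freqs - self.f_high) <= tol
        mask[0] = False
        if not mask.any():
            raise ValueError(
                f"band {self.name!r} [{self.f_low}, {self.f_high}] Hz contains "
                f"no FFT bin at n={n_timepoints}, TR={tr_seconds}s"
            )
        return mask


FULL_BAND = FrequencyBand("full", 0.01, 0.073, closed_high=True)
SLOW5 = FrequencyBand("slow5", 0.01, 0.027, closed_high=False)
SLOW4 = FrequencyBand("slow4", 0.027, 0.073, closed_high=True)

DEFAULT_BANDS: tuple[FrequencyBand, ...] = (FULL_BAND, SLOW5, SLOW4)

_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def get_band(name: str) -> FrequencyBand:
    """Look up one of the standard bands by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; available: {sorted(_BY_NAME)}"
        ) from None
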