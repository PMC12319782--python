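"""Band-limited views of EEG recordings.

Five canonical EEG bands plus the full analysis band, filtered with a
4th-order Butterworth applied forward-backward (zero phase).  Filtering is
the only place a transfer function enters the package; the synthetic
generator reuses these filters so that simulated sources and analyzed data
share one spectral definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import signal

__all__ = ["BandSet", "DEFAULT_BANDS", "EEGRecording", "bandpass", "band_decompose"]

CONDITIONS = ("rest", "S1", "S4", "S16", "S64", "S256")


class BandSet(dict):
    """Named frequency intervals in Hz; a dict of name -> (lo, hi)."""

    def __init__(self, intervals: Mapping[str, Tuple[float, float]]):
        super().__init__()
        for name, (lo, hi) in intervals.items():
            lo, hi = float(lo), float(hi)
            if not (0 < lo < hi):
                raise ValueError(f"band {name}: need 0 < lo < hi, got [{lo}, {hi}]")
            self[name] = (lo, hi)


#: Delta/Theta/Alpha/Beta/Gamma plus the preprocessing band.
DEFAULT_BANDS = BandSet({
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 12.0),
    "Beta": (12.0, 30.0),
    "Gamma": (30.0, 50.0),
    "Full": (1.0, 50.0),
})


@dataclass
class EEGRecording:
    """Condition-tagged multichannel time series.

    ``X`` is channels x time in microvolts; ``band`` is a band name once
    filtered, "broadband" otherwise.  ``good_mask`` marks usable channels;
    bad channels should be dropped before referencing.
    """

    X: np.ndarray
    fs: float
    condition: str = "rest"
    band: str = "broadband"
    subject: Optional[str] = None
    good_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] == 0:
            raise ValueError("X must be channels x time with T > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


def apply_good_mask(rec: EEGRecording) -> EEGRecording:
    """Drop channels flagged bad before referencing/analysis.

    Manual channel vetting itself is out of scope; this honors an
    externally supplied per-channel boolean mask.
    """
    if rec.good_mask is None:
        return rec
    mask = np.asarray(rec.good_mask, dtype=bool)
    if mask.shape != (rec.n_channels,):
        raise ValueError("good_mask must have one entry per channel")
    if mask.sum() < 2:
        raise ValueError("fewer than 2 good channels")
    return replace(rec, X=rec.X[mask], good_mask=None)


def _design(lo: float, hi: float, fs: float):
    return signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")


def bandpass(rec: EEGRecording, band: str, bands: BandSet = DEFAULT_BANDS) -> EEGRecording:
    """Zero-phase band-pass filter into a named band.

    Forward-backward 4th-order Butterworth with reflective padding; requires
    ``fs > 2*hi`` and at least ``6*fs/lo`` samples so the lowest period is
    well represented.
    """
    if band not in bands:
        raise ValueError(f"band {band!r} not in band set {sorted(bands)}")
    lo, hi = bands[band]
    if rec.fs <= 2 * hi:
        raise ValueError(f"fs={rec.fs} too low for band {band} (hi={hi})")
    min_T = int(6 * rec.fs / lo)
    if rec.n_samples < min_T:
        raise ValueError(f"insufficient samples for band {band}: {rec.n_samples} < {min_T}")
    sos = _design(lo, hi, rec.fs)
    padlen = min(rec.n_samples - 1, 3 * 2 * sos.shape[0] * 10)
    Y = signal.sosfiltfilt(sos, rec.X, axis=1, padtype="even", padlen=padlen)
    return replace(rec, X=Y, band=band)


def band_decompose(rec: EEGRecording, bands: BandSet = DEFAULT_BANDS) -> Dict[str, EEGRecording]:
    """Filter one recording into every band of a band set; order-independent."""
    return {name: bandpass(rec, name, bands) for name in bands}
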