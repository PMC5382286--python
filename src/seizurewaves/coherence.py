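"""Windowed multitaper coherence between electrode pairs.

Coherence is estimated per 10 s analysis window with discrete prolate
spheroidal (Slepian) tapers at a time-bandwidth product of 20 (half-bandwidth
2 Hz), using one taper less than the Shannon number (39 at defaults).  Bins
whose magnitude-squared coherence exceeds the theoretical null quantile are
flagged significant; the null for magnitude-squared coherence of independent
Gaussian signals averaged over K tapers is Beta(1, K-1), giving the
closed-form threshold ``1 - alpha**(1/(K-1))``.

Phase convention: the cross-spectrum is ``X * conj(Y)``, so a *positive*
phase slope versus frequency means the second channel lags the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.signal.windows import dpss

from .recordings import AnalysisWindow, Recording

__all__ = [
    "MultitaperParams",
    "CoherogramSet",
    "taper_count",
    "coherence_threshold",
    "multitaper_coherence",
    "band_average_coherence",
    "CoherenceEngine",
]


def taper_count(time_bandwidth: float) -> int:
    """Number of Slepian tapers: one less than the Shannon number ``2*TW``."""
    if time_bandwidth < 1:
        raise ValueError("time-bandwidth product must be >= 1")
    return int(np.floor(2 * time_bandwidth - 1))


def coherence_threshold(n_tapers: int, alpha: float = 0.005) -> float:
    """Null quantile of magnitude-squared coherence at level ``alpha``.

    Under independence the magnitude-squared coherence estimated with K
    tapers follows Beta(1, K-1); the upper-``alpha`` quantile is
    ``1 - alpha**(1/(K-1))``.  Returned on the magnitude-squared scale
    (take a square root for the magnitude scale).
    """
    if n_tapers < 2:
        raise ValueError("need at least 2 tapers for a non-degenerate null")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - alpha ** (1.0 / (n_tapers - 1))


@dataclass(frozen=True)
class MultitaperParams:
    """Multitaper estimation settings.

    ``n_tapers`` defaults to one less than the Shannon number.  ``max_freq``
    truncates the stored frequency axis; the rhythms analysed live below
    25 Hz.
    """

    window_length: float = 10.0
    time_bandwidth: float = 20.0
    n_tapers: int | None = None
    alpha: float = 0.005
    max_freq: float = 25.0

    @property
    def k(self) -> int:
        return self.n_tapers if self.n_tapers is not None else taper_count(
            self.time_bandwidth
        )

    @property
    def half_bandwidth(self) -> float:
        """Spectral half-bandwidth in Hz (TW / window length)."""
        return self.time_bandwidth / self.window_length

    @property
    def threshold(self) -> float:
        return coherence_threshold(self.k, self.alpha)


@dataclass
class CoherogramSet:
    """Window x frequency coherence magnitude, phase and significance mask."""

    pair: tuple[str, str]
    magnitude: np.ndarray      # (n_windows, n_freqs), in [0, 1]; NaN undefined
    phase: np.ndarray          # (n_windows, n_freqs), radians in (-pi, pi]
    sig_mask: np.ndarray       # (n_windows, n_freqs), bool
    freq_axis: np.ndarray      # (n_freqs,), Hz
    windows: list[AnalysisWindow] = field(default_factory=list)
    threshold: float = np.nan  # magnitude-squared significance threshold

    @property
    def n_windows(self) -> int:
        return self.magnitude.shape[0]


@lru_cache(maxsize=8)
def _tapers(n: int, tw: float, k: int) -> np.ndarray:
    return dpss(n, tw, Kmax=k)


def _tapered_fft(seg: np.ndarray, tapers: np.ndarray, n_keep: int) -> np.ndarray:
    """Tapered spectra of one demeaned segment: (k_tapers, n_keep) complex."""
    seg = seg - seg.mean()
    return np.fft.rfft(tapers * seg[None, :], axis=1)[:, :n_keep]


class CoherenceEngine:
    """Caches per-channel tapered spectra so many pairs reuse one FFT pass.

    All pairwise coherograms over the same recording and window sequence
    share the per-channel multitaper FFTs, which dominate the cost.
    """

    def __init__(
        self,
        rec: Recording,
        windows: Sequence[AnalysisWindow],
        params: MultitaperParams = MultitaperParams(),
    ) -> None:
        self.rec = rec
        self.windows = list(windows)
        self.params = params
        n = int(round(params.window_length * rec.rate))
        self._n = n
        self._tapers = _tapers(n, params.time_bandwidth, params.k)
        freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate)
        self._keep = int(np.searchsorted(freqs, params.max_freq, side="right"))
        self.freq_axis = freqs[: self._keep]
        self._spectra: dict[str, np.ndarray] = {}
        self._power: dict[str, np.ndarray] = {}

    def _compute_spectra(self, electrode_id: str) -> np.ndarray:
        ch = self.rec.layout.index(electrode_id)
        segs = np.empty((len(self.windows), self._n))
        for w, win in enumerate(self.windows):
            segs[w] = self.rec.segment(win.start, self.params.window_length)[
                :, ch
            ]
        segs = segs - segs.mean(axis=1, keepdims=True)
        return np.fft.rfft(
            segs[:, None, :] * self._tapers[None, :, :], axis=2
        )[:, :, : self._keep]

    def _channel_spectra(self, electrode_id: str, cache: bool = True):
        """(n_windows, k, n_freq) tapered spectra and per-window power.

        ``cache=False`` computes without storing (spectra are ~MBs per
        channel; a 100-electrode array would otherwise hold ~1 GB).
        """
        if electrode_id in self._spectra:
            return self._spectra[electrode_id], self._power[electrode_id]
        spec = self._compute_spectra(electrode_id)
        power = np.mean(np.abs(spec) ** 2, axis=1)
        if cache:
            self._spectra[electrode_id] = spec
            self._power[electrode_id] = power
        return spec, power

    def coherogram(
        self, a: str, b: str, cache_a: bool = True, cache_b: bool = True
    ) -> CoherogramSet:
        """Multitaper coherogram for the electrode pair ``(a, b)``."""
        sa, sxx = self._channel_spectra(a, cache_a)
        sb, syy = self._channel_spectra(b, cache_b)
        sxy = np.mean(sa * np.conj(sb), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            msc = np.abs(sxy) ** 2 / (sxx * syy)
        undefined = (sxx <= 0) | (syy <= 0)
        if undefined.any():
            warnings.warn(
                f"zero-variance window(s) in pair ({a}, {b}); bins marked "
                "undefined",
                stacklevel=2,
            )
            msc[undefined] = np.nan
        thr = self.params.threshold
        return CoherogramSet(
            pair=(a, b),
            magnitude=np.sqrt(np.clip(msc, 0.0, 1.0)),
            phase=np.angle(sxy),
            sig_mask=np.where(np.isnan(msc), False, msc > thr),
            freq_axis=self.freq_axis,
            windows=self.windows,
            threshold=thr,
        )


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    windows: Sequence[AnalysisWindow],
    params: MultitaperParams = MultitaperParams(),
    t0: float = 0.0,
    pair: tuple[str, str] = ("x", "y"),
) -> CoherogramSet:
    """Windowed multitaper coherence between two raw channel vectors.

    Convenience wrapper over :class:`CoherenceEngine` for a single pair; the
    engine is preferred when many pairs share windows.
    """
    from .recordings import ElectrodeLayout, Recording

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    layout = ElectrodeLayout(
        ids=pair, scale="micro", positions=np.array([[0.0, 0.0], [1.0, 0.0]])
    )
    dur = len(x) / rate
    # onset/offset are irrelevant for coherence itself; pick a valid pair
    rec = Recording(
        samples=np.column_stack([x, y]),
        rate=rate,
        onset=t0,
        offset=t0 + dur,
        layout=layout,
        t0=t0,
    )
    eng = CoherenceEngine(rec, windows, params)
    return eng.coherogram(*pair)


def band_average_coherence(
    cg: CoherogramSet, band: tuple[float, float] = (1.0, 13.0)
) -> np.ndarray:
    """Per-window mean coherence magnitude over a frequency band.

    Defaults to the 1-13 Hz band that captures the low-frequency rhythms
    dominating ictal coherence while excluding slow non-rhythmic trends.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("band upper edge must exceed lower edge")
    if lo > cg.freq_axis[-1] or hi < cg.freq_axis[0]:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside frequency axis "
            f"[{cg.freq_axis[0]}, {cg.freq_axis[-1]}] Hz"
        )
    sel = (cg.freq_axis >= lo) & (cg.freq_axis <= hi)
    if not sel.any():
        raise ValueError("no frequency bins inside band")
    return cg.magnitude[:, sel].mean(axis=1)
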