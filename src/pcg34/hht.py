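"""Hilbert-Huang transform: empirical mode decomposition + Hilbert spectra.

EMD iteratively sifts a signal into intrinsic mode functions (IMFs): at each
sift the mean of the upper and lower cubic-spline extrema envelopes is
subtracted until the candidate satisfies a Cauchy-type convergence criterion.
Each IMF is then Hilbert-transformed to obtain instantaneous amplitude, phase
and frequency; the per-sample maximal-amplitude component forms the frequency
ridge consumed by the diastolic S3/S4 detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .config import EmdConfig
from .exceptions import ParameterError


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the final residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    fs: float

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residual (identical to the input)."""
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out

    def __len__(self) -> int:
        return len(self.imfs)


@dataclass
class InstantaneousTrack:
    """Per-sample amplitude, unwrapped phase and frequency of one IMF."""

    amplitude: np.ndarray
    phase: np.ndarray
    freq_hz: np.ndarray
    fs: float
    n_clamped: int = 0  # negative-frequency samples clamped to zero


@dataclass
class RidgeTrack:
    """Frequency and magnitude of the maximal-amplitude component per sample."""

    freq_hz: np.ndarray
    magnitude: np.ndarray
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.freq_hz.size) / self.fs


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus yield their midpoints."""
    d = np.diff(x)
    # carry the sign of the last nonzero difference across plateaus
    sign = np.sign(d)
    nz = sign != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    idx = np.where(nz, np.arange(d.size), -1)
    np.maximum.accumulate(idx, out=idx)
    carried = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0.0)
    turn = np.nonzero((carried[:-1] != 0) & (sign[1:] != 0) & (sign[1:] != carried[:-1]))[0]
    maxima, minima = [], []
    for i in turn:
        # plateau spans from the end of the last nonzero step to i+1
        left = i
        while left > 0 and sign[left] == 0:
            left -= 1
        pos = (left + 1 + i + 1) // 2
        (maxima if carried[i] > 0 else minima).append(pos)
    return np.array(maxima, int), np.array(minima, int)


def _mirrored(idx: np.ndarray, vals: np.ndarray, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to ``k`` extrema beyond each end of the support [0, n-1]."""
    left_i = (-idx[:k])[::-1]
    left_v = vals[:k][::-1]
    right_i = (2 * (n - 1) - idx[-k:])[::-1]
    right_v = vals[-k:][::-1]
    pos = np.concatenate([left_i, idx, right_i])
    val = np.concatenate([left_v, vals, right_v])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return pos[keep], val[keep]


def envelope_mean(x: np.ndarray, boundary_extrema: int = 2) -> np.ndarray | None:
    """Mean of the upper and lower cubic-spline extrema envelopes.

    Returns ``None`` when the signal has fewer than two maxima or minima,
    which signals sift/EMD termination.  Extrema are mirror-extended past the
    record ends to suppress spline end swings; natural boundary conditions
    are used so an independent tridiagonal solve reproduces the envelopes.
    """
    imax, imin = find_extrema(x)
    if imax.size < 2 or imin.size < 2:
        return None
    grid = np.arange(x.size)
    pmax, vmax = _mirrored(imax, x[imax], x.size, boundary_extrema)
    pmin, vmin = _mirrored(imin, x[imin], x.size, boundary_extrema)
    upper = CubicSpline(pmax, vmax, bc_type="natural")(grid)
    lower = CubicSpline(pmin, vmin, bc_type="natural")(grid)
    return 0.5 * (upper + lower)


def sift(
    x: np.ndarray,
    sd_tol: float = 0.2,
    max_sifts: int = 100,
    boundary_extrema: int = 2,
) -> tuple[np.ndarray, bool]:
    """Extract one IMF candidate by iterative sifting.

    The loop stops when the normalised squared change between successive
    candidates, ``SD = sum((h_prev - h)^2) / sum(h_prev^2)``, falls below
    ``sd_tol``, or when the candidate runs out of extrema.  Returns the
    candidate and a convergence flag (False only if the iteration cap hit).
    """
    h = np.asarray(x, dtype=float).copy()
    for _ in range(max_sifts):
        m = envelope_mean(h, boundary_extrema)
        if m is None:
            return h, True
        denom = float(np.sum(h**2))
        if denom == 0.0:
            return h, True
        sd = float(np.sum(m**2)) / denom
        h -= m
        if sd < sd_tol:
            return h, True
    return h, False


def emd(x: np.ndarray, fs: float = 1.0, config: EmdConfig | None = None) -> IMFSet:
    """Empirical mode decomposition into IMFs plus a residual.

    Extraction stops when the residual has fewer than two extrema (monotonic
    or near-constant), when its energy is negligible relative to the input,
    or at the IMF cap.  By construction the IMFs and residual sum back to the
    input exactly.
    """
    cfg = config or EmdConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ParameterError("EMD needs at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("EMD input must be finite")
    energy0 = float(np.sum(x**2))
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        imax, imin = find_extrema(residual)
        if imax.size + imin.size < 2:
            break
        if energy0 > 0 and float(np.sum(residual**2)) < 1e-10 * energy0:
            break
        c, _ = sift(residual, cfg.sd_tol, cfg.max_sifts, cfg.boundary_extrema)
        if not np.any(c):
            break
        imfs.append(c)
        residual = residual - c
    return IMFSet(imfs=imfs, residual=residual, fs=fs)


def analytic_attrs(imf: np.ndarray, fs: float) -> InstantaneousTrack:
    """Instantaneous amplitude/phase/frequency of one IMF.

    The analytic signal's modulus gives the amplitude; its unwrapped phase is
    differentiated (central differences, one-sided at the ends) and scaled to
    Hz.  Negative frequency estimates - a boundary/low-amplitude artefact -
    are clamped to zero and counted.
    """
    z = sps.hilbert(np.asarray(imf, dtype=float))
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    n_clamped = int(np.sum(freq < 0))
    freq = np.maximum(freq, 0.0)
    return InstantaneousTrack(amplitude, phase, freq, fs, n_clamped)


def max_amplitude_ridge(tracks: list[InstantaneousTrack]) -> RidgeTrack:
    """Per-sample (frequency, magnitude) of the largest-amplitude component.

    Ties go to the lowest IMF index (the highest-frequency mode), which is
    what ``argmax`` returns.
    """
    if not tracks:
        raise ParameterError("need at least one instantaneous track")
    amps = np.vstack([t.amplitude for t in tracks])
    freqs = np.vstack([t.freq_hz for t in tracks])
    winner = np.argmax(amps, axis=0)
    cols = np.arange(amps.shape[1])
    return RidgeTrack(freqs[winner, cols], amps[winner, cols], tracks[0].fs)


def max_frequency_ridge(tracks: list[InstantaneousTrack]) -> RidgeTrack:
    """Per-sample (frequency, magnitude) of the highest-frequency component.

    Alternative ridge reading kept for comparison: selects, at each sample,
    the IMF with the largest instantaneous frequency rather than the largest
    amplitude.  High-order noise modes usually win under this rule, which is
    why the maximal-amplitude ridge is the default.
    """
    if not tracks:
        raise ParameterError("need at least one instantaneous track")
    amps = np.vstack([t.amplitude for t in tracks])
    freqs = np.vstack([t.freq_hz for t in tracks])
    winner = np.argmax(freqs, axis=0)
    cols = np.arange(amps.shape[1])
    return RidgeTrack(freqs[winner, cols], amps[winner, cols], tracks[0].fs)


def hilbert_spectrum_tracks(imfset: IMFSet) -> list[InstantaneousTrack]:
    """Instantaneous tracks for every IMF of a decomposition."""
    return [analytic_attrs(c, imfset.fs) for c in imfset.imfs]


def ridge_to_csv(ridge: RidgeTrack, path) -> None:
    """Diagnostic export: one row per sample (sample, time_s, freq_hz, magnitude)."""
    import pandas as pd

    pd.DataFrame(
        {
            "sample": np.arange(ridge.freq_hz.size),
            "time_s": ridge.times,
            "freq_hz": ridge.freq_hz,
            "magnitude": ridge.magnitude,
        }
    ).to_csv(path, index=False)
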