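"""Fourier shell correlation and frequency filtering.

Resolution of an average is read from the FSC between two half-set
averages at the 0.5 threshold: the first frequency where the shell-wise
correlation drops below 0.5, reported as a real-space distance in nm.
Real-space masks inflate FSC values, so callers are expected to log the
mask in use (the half-set split used here shares the alignment and splits
only at averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelVolume

__all__ = ["FSCCurve", "fsc", "resolution_at", "lowpass", "bandpass"]


@dataclass
class FSCCurve:
    frequencies: np.ndarray   # shell centers, 1/nm, ascending
    values: np.ndarray        # real part of normalized shell correlation
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frequencies) != len(self.values):
            raise ValueError("frequency/value length mismatch")


def _freq_grid(shape, voxel_size: float) -> np.ndarray:
    axes = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    FX, FY, FZ = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(FX**2 + FY**2 + FZ**2)


def fsc(a: VoxelVolume, b: VoxelVolume,
        shell_width: float | None = None) -> FSCCurve:
    """Per-shell normalized complex correlation (real part) of two volumes."""
    if a.data.shape != b.data.shape:
        raise ValueError("volumes must have equal shapes")
    if abs(a.voxel_size - b.voxel_size) > 1e-9:
        raise ValueError("volumes must share a voxel size")
    n = a.data.shape[0]
    if shell_width is None:
        shell_width = 1.0 / (n * a.voxel_size)
    Fa = np.fft.fftn(a.data)
    Fb = np.fft.fftn(b.data)
    freq = _freq_grid(a.data.shape, a.voxel_size)
    nyquist = 1.0 / (2.0 * a.voxel_size)
    nshell = int(np.floor(nyquist / shell_width))
    shell_idx = np.minimum((freq / shell_width).astype(int), nshell)
    num = np.zeros(nshell, dtype=np.complex128)
    pa = np.zeros(nshell)
    pb = np.zeros(nshell)
    flat = shell_idx.ravel()
    cross = (Fa * np.conj(Fb)).ravel()
    num = np.bincount(flat, weights=cross.real, minlength=nshell + 1)[:nshell] \
        + 1j * np.bincount(flat, weights=cross.imag, minlength=nshell + 1)[:nshell]
    pa = np.bincount(flat, weights=(np.abs(Fa)**2).ravel(),
                     minlength=nshell + 1)[:nshell]
    pb = np.bincount(flat, weights=(np.abs(Fb)**2).ravel(),
                     minlength=nshell + 1)[:nshell]
    # skip the DC shell
    freqs = (np.arange(1, nshell) + 0.5) * shell_width
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.real(num[1:]) / np.sqrt(pa[1:] * pb[1:])
    vals = np.nan_to_num(vals, nan=0.0)
    return FSCCurve(freqs, np.clip(vals, -1.0, 1.0))


def resolution_at(curve: FSCCurve, threshold: float = 0.5):
    """Resolution (nm) at the first downward threshold crossing.

    Linear interpolation between the bracketing shells.  If the curve
    never drops below the threshold the Nyquist distance is returned with
    ``crossed=False``.  Returns ``(resolution_nm, crossed)``.
    """
    f = curve.frequencies
    v = curve.values
    if len(f) == 0:
        raise ValueError("empty FSC curve")
    below = np.where(v < threshold)[0]
    if len(below) == 0 or below[0] == 0:
        if len(below) and below[0] == 0:
            return float(1.0 / f[0]), True
        nyq_freq = f[-1] + (f[1] - f[0]) / 2 if len(f) > 1 else f[-1]
        return float(1.0 / nyq_freq), False
    i = below[0]
    f0, f1 = f[i - 1], f[i]
    v0, v1 = v[i - 1], v[i]
    fc = f0 + (v0 - threshold) * (f1 - f0) / (v0 - v1)
    return float(1.0 / fc), True


def _radial_filter(vol: VoxelVolume, response) -> VoxelVolume:
    freq = _freq_grid(vol.data.shape, vol.voxel_size)
    out = np.fft.ifftn(np.fft.fftn(vol.data) * response(freq)).real
    return VoxelVolume(out.astype(np.float32), vol.voxel_size)


def _raised_cosine_low(freq, cutoff, width):
    """1 below cutoff-width, 0 above cutoff+width, cosine in between."""
    r = np.ones_like(freq)
    hi = freq >= cutoff + width
    mid = (freq > cutoff - width) & ~hi
    r[hi] = 0.0
    r[mid] = 0.5 * (1 + np.cos(np.pi * (freq[mid] - (cutoff - width))
                               / (2 * width)))
    return r


def lowpass(vol: VoxelVolume, cutoff_nm: float) -> VoxelVolume:
    """Low-pass at 1/cutoff_nm with a raised-cosine rolloff 2 shells wide.

    The zero-frequency term is untouched, so the mean value is preserved.
    """
    if cutoff_nm < 2 * vol.voxel_size:
        raise ValueError("cutoff below Nyquist distance")
    n = vol.data.shape[0]
    width = 2.0 / (n * vol.voxel_size)   # two frequency shells
    fc = 1.0 / cutoff_nm
    return _radial_filter(vol, lambda f: _raised_cosine_low(f, fc, width))


def bandpass(vol: VoxelVolume, lo_nm: float, hi_nm: float) -> VoxelVolume:
    """Band-pass keeping distances between hi_nm and lo_nm (lo_nm > hi_nm)."""
    if not lo_nm > hi_nm:
        raise ValueError("need lo_nm > hi_nm (distances, nm)")
    if hi_nm < 2 * vol.voxel_size:
        raise ValueError("high cutoff below Nyquist distance")
    n = vol.data.shape[0]
    width = 2.0 / (n * vol.voxel_size)
    f_lo = 1.0 / lo_nm
    f_hi = 1.0 / hi_nm

    def resp(f):
        return _raised_cosine_low(f, f_hi, width) * \
            (1.0 - _raised_cosine_low(f, f_lo, width))

    return _radial_filter(vol, resp)
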