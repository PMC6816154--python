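"""Linear operators for the CS + parallel-imaging forward model.

Conventions: the k-space arrays are centred (DC at index n//2, i.e. the
fftshifted layout), the DFT is orthonormal, and the undersampling mask is a
2D pattern over the two phase-encode axes (the last two array axes),
broadcast along the fully sampled readout axis.  With these choices the
forward operator A_n x = M F (CSM_n * x) has adjoint
A_n^H y = conj(CSM_n) * F^H (M y), and the normal operator has spectral
norm <= max RSS^2 = 1 for RSS-normalised coil maps.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["fft_c", "ifft_c", "SenseOperator", "WaveletTransform"]


def fft_c(x: np.ndarray) -> np.ndarray:
    """Orthonormal centred n-dimensional DFT."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def ifft_c(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_c` (also its adjoint)."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(y), norm="ortho"))


class SenseOperator:
    """Stacked multi-coil undersampled Fourier operator.

    forward:  x (image) -> y (n_coils, *shape) masked k-space
    adjoint:  y -> coil-combined image  sum_n conj(CSM_n) F^H(M y_n)
    """

    def __init__(self, maps: np.ndarray, mask2d: np.ndarray):
        self.maps = maps
        self.mask = np.asarray(mask2d, dtype=bool)
        self.shape = maps.shape[1:]
        if self.mask.shape != self.shape[-2:]:
            raise ValueError("mask must span the two trailing (phase-encode) axes")

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.empty(self.maps.shape, dtype=np.complex128)
        for n in range(self.maps.shape[0]):
            k = fft_c(self.maps[n] * x)
            k[..., ~self.mask] = 0.0
            y[n] = k
        return y

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        x = np.zeros(self.shape, dtype=np.complex128)
        for n in range(self.maps.shape[0]):
            k = y[n].copy()
            k[..., ~self.mask] = 0.0
            x += np.conj(self.maps[n]) * ifft_c(k)
        return x

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(x))

    def lipschitz(self, n_iter: int = 10, seed: int = 0) -> float:
        """Spectral norm of the normal operator by power iteration."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.shape) + 1j * rng.standard_normal(self.shape)
        v /= np.linalg.norm(v)
        lam = 1.0
        for _ in range(n_iter):
            w = self.normal(v)
            lam = float(np.linalg.norm(w))
            if lam == 0.0:
                return 1.0
            v = w / lam
        return lam


class WaveletTransform:
    """Orthogonal separable wavelet transform (flat coefficient vector).

    Uses periodization boundary handling so the transform is exactly
    orthonormal; the l1 proximal step in the transform domain is then the
    exact proximal operator of lambda * ||W x||_1.
    """

    def __init__(self, shape: tuple[int, ...], wavelet: str = "db4", levels: int = 3):
        self.wavelet = wavelet
        max_level = pywt.dwtn_max_level(shape, wavelet)
        self.levels = max(0, min(levels, max_level))
        self.shape = tuple(shape)
        if self.levels > 0:
            coeffs = pywt.wavedecn(
                np.zeros(self.shape), self.wavelet, mode="periodization", level=self.levels
            )
            arr, self._slices = pywt.coeffs_to_array(coeffs)
            self._arr_shape = arr.shape
        else:
            self._slices = None
            self._arr_shape = self.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.levels == 0:
            return np.array(x, copy=True)
        coeffs = pywt.wavedecn(x, self.wavelet, mode="periodization", level=self.levels)
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr

    def inverse(self, w: np.ndarray) -> np.ndarray:
        if self.levels == 0:
            return np.array(w, copy=True)
        coeffs = pywt.array_to_coeffs(w, self._slices, output_format="wavedecn")
        rec = pywt.waverecn(coeffs, self.wavelet, mode="periodization")
        return rec[tuple(slice(s) for s in self.shape)]

    def l1_norm(self, x: np.ndarray) -> float:
        return float(np.sum(np.abs(self.forward(x))))
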