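"""Compressed-sensing + parallel-imaging reconstruction.

The reconstruction minimises

    1/2 sum_n || y_n - F_u(CSM_n * x) ||_2^2  +  lambda * || W x ||_1

where y_n is the n-th coil's undersampled k-space, F_u the mask-restricted
orthonormal Fourier transform, CSM_n the coil sensitivity map, W an
orthogonal wavelet transform and lambda the regularisation weight trading
data fidelity against sparsity.  The solver is accelerated proximal
gradient (FISTA) with a monotone safeguard; because W is orthonormal the
proximal step is exact complex soft-thresholding in the wavelet domain.

The regularisation weight is interpreted on normalised data: k-space is
scaled so the zero-filled coil-combined image has unit peak magnitude, the
printed default lambda = 2e-3 applies on that scale, and the output image
is scaled back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operators import SenseOperator, WaveletTransform, fft_c, ifft_c
from .phantom import KSpaceAcquisition, SenseMaps

__all__ = [
    "ReconConfig",
    "ReconResult",
    "estimate_sensitivities",
    "objective",
    "soft_threshold",
    "reconstruct_cs",
    "reconstruct_reference",
    "zero_filled",
    "nrmse",
    "sweep_recon_params",
]


@dataclass
class ReconConfig:
    lam: float = 0.002
    iterations: int = 10
    wavelet: str = "db4"
    wavelet_levels: int = 3
    step_rule: str = "fixed"  # "fixed": 1/L with L from power iteration
    normalize: bool = True
    monotone: bool = True
    power_iterations: int = 8

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ReconResult:
    image: np.ndarray  # complex volume
    cost_trace: list  # (iterations+1) rows of {total, fidelity, sparsity}
    config: ReconConfig
    scale: float = 1.0

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.image)

    @property
    def total_trace(self) -> np.ndarray:
        return np.array([c["total"] for c in self.cost_trace])


def soft_threshold(z: np.ndarray | complex, t: float) -> np.ndarray | complex:
    """Complex soft-thresholding: shrink |z| by t, preserve phase.

    Proximal operator of t * ||.||_1 for complex coefficients.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    z_arr = np.asarray(z)
    mag = np.abs(z_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(mag > t, (mag - t) / np.where(mag > 0, mag, 1.0), 0.0)
    out = z_arr * factor
    return out if isinstance(z, np.ndarray) else complex(out)


def objective(
    x: np.ndarray,
    acq: KSpaceAcquisition,
    maps: SenseMaps,
    lam: float,
    wavelet: WaveletTransform | None = None,
) -> dict:
    """Evaluate the reconstruction cost and its two terms at x."""
    if wavelet is None:
        wavelet = WaveletTransform(x.shape)
    op = SenseOperator(maps.maps, np.asarray(acq.mask.grid, dtype=bool))
    resid = op.forward(x) - acq.data
    fidelity = 0.5 * float(np.sum(np.abs(resid) ** 2))
    sparsity = wavelet.l1_norm(x)
    return {"total": fidelity + lam * sparsity, "fidelity": fidelity, "sparsity": sparsity}


def estimate_sensitivities(
    acq: KSpaceAcquisition, support_threshold: float = 0.1, smooth_sigma: float = 2.0
) -> SenseMaps:
    """Estimate coil sensitivity maps from the fully sampled k-space centre.

    The calibration ellipse is extracted per coil, apodised with a Hann
    window to suppress truncation ringing, and inverse-transformed to a
    low-resolution coil image.  The ratio to the root-sum-of-squares image
    is stabilised by a signal-weighted Gaussian smoothing (weight RSS^2, so
    low-signal voxels inherit their neighbourhood's sensitivity), then
    RSS-normalised.  The support is where the low-resolution RSS exceeds
    ``support_threshold`` of its maximum (default 10%, which excludes the
    air fringe where the low-resolution ratio is extrapolation); maps are zero off support.
    """
    from scipy.ndimage import gaussian_filter

    mask = acq.mask
    calib = mask.calib_mask()
    if not calib.any():
        raise ValueError("empty calibration region")
    from .sampling import _calib_radius

    ny, nz = mask.grid.shape
    rho_c = _calib_radius(ny, nz, mask.calib_semi_axes)
    window = np.where(rho_c <= 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(rho_c, 0, 1))), 0.0)

    lowres = np.empty_like(acq.data)
    for n in range(acq.n_coils):
        lowres[n] = ifft_c(acq.data[n] * window[None, :, :])
    rss = np.sqrt(np.sum(np.abs(lowres) ** 2, axis=0))
    support = rss > support_threshold * rss.max()

    if smooth_sigma > 0:
        den = gaussian_filter(rss**2, smooth_sigma)
        den = np.where(den > 0, den, 1.0)
        maps = np.empty_like(lowres)
        for n in range(acq.n_coils):
            num_r = gaussian_filter((lowres[n] * rss).real, smooth_sigma)
            num_i = gaussian_filter((lowres[n] * rss).imag, smooth_sigma)
            maps[n] = (num_r + 1j * num_i) / den
        rss_m = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps /= np.where(rss_m > 0, rss_m, 1.0)
    else:
        maps = lowres / np.where(rss > 0, rss, 1.0)
    # off support the smoothed ratio is kept (RSS-normalised extrapolation)
    # rather than zeroed, so low-signal periphery still reconstructs
    return SenseMaps(maps=maps, support=support)


def zero_filled(acq: KSpaceAcquisition, maps: SenseMaps) -> np.ndarray:
    """Zero-filled coil-combined adjoint image (the solver's start point)."""
    op = SenseOperator(maps.maps, np.asarray(acq.mask.grid, dtype=bool))
    return op.adjoint(acq.data)


def reconstruct_cs(
    acq: KSpaceAcquisition, maps: SenseMaps, config: ReconConfig | None = None
) -> ReconResult:
    """FISTA minimisation of the CS + parallel-imaging cost function.

    Returns the complex image together with the per-iteration cost trace
    (length iterations + 1, including the zero-filled initialisation).  The
    trace is non-increasing when the monotone safeguard is on; with the
    safeguard off, a sustained cost increase raises with the trace attached.
    """
    if config is None:
        config = ReconConfig()
    if not np.all(np.isfinite(acq.data)):
        raise ValueError("k-space data contains non-finite values")

    mask2d = np.asarray(acq.mask.grid, dtype=bool)
    op = SenseOperator(maps.maps, mask2d)
    x0 = op.adjoint(acq.data)
    scale = float(np.abs(x0).max()) if config.normalize else 1.0
    if scale == 0.0:
        scale = 1.0
    data = acq.data / scale
    acq_n = KSpaceAcquisition(data=data, mask=acq.mask)
    wavelet = WaveletTransform(x0.shape, config.wavelet, config.wavelet_levels)

    L = op.lipschitz(config.power_iterations) if config.step_rule == "fixed" else 1.0
    L = max(L, 1e-12)
    step = 1.0 / L

    def cost(x):
        resid = op.forward(x) - data
        fid = 0.5 * float(np.sum(np.abs(resid) ** 2))
        sp = wavelet.l1_norm(x)
        return {"total": fid + config.lam * sp, "fidelity": fid, "sparsity": sp}

    x = x0 / scale
    trace = [cost(x)]
    z = x.copy()
    t_mom = 1.0
    bad_streak = 0
    for _ in range(config.iterations):
        grad = op.normal(z) - op.adjoint(data)
        x_cand = z - step * grad
        if config.lam > 0:
            w = wavelet.forward(x_cand)
            w = soft_threshold(w, config.lam * step)
            x_cand = wavelet.inverse(w)
        c_cand = cost(x_cand)
        if config.monotone and c_cand["total"] > trace[-1]["total"]:
            # monotone safeguard: keep the previous iterate, restart momentum
            x_new = x
            c_new = dict(trace[-1])
            t_next = 1.0
        else:
            x_new = x_cand
            c_new = c_cand
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        if not config.monotone:
            if c_new["total"] > trace[-1]["total"] * (1.0 + 1e-9):
                bad_streak += 1
                if bad_streak >= 3:
                    raise RuntimeError(
                        "reconstruction diverged: cost increased for 3 consecutive "
                        f"iterations; trace={[c['total'] for c in trace]}"
                    )
            else:
                bad_streak = 0
        z = x_new + ((t_mom - 1.0) / t_next) * (x_new - x)
        x, t_mom = x_new, t_next
        trace.append(c_new)

    return ReconResult(image=x * scale, cost_trace=trace, config=config, scale=scale)


def reconstruct_reference(acq_full: KSpaceAcquisition, maps: SenseMaps) -> np.ndarray:
    """Coil-combined reconstruction of a fully sampled acquisition.

    sum_n conj(CSM_n) IFT(y_n) / sum_n |CSM_n|^2 on the support, with a
    root-sum-of-squares fallback off support.  Returns magnitude.
    """
    if not acq_full.mask.is_full:
        raise ValueError("reference reconstruction requires a fully sampled mask")
    imgs = np.empty_like(acq_full.data)
    for n in range(acq_full.n_coils):
        imgs[n] = ifft_c(acq_full.data[n])
    rss2 = np.sum(np.abs(maps.maps) ** 2, axis=0)
    num = np.sum(np.conj(maps.maps) * imgs, axis=0)
    combined = np.where(rss2 > 1e-12, np.abs(num) / np.where(rss2 > 1e-12, rss2, 1.0), 0.0)
    rss_img = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    return np.where(maps.support, combined, rss_img)


def nrmse(test: np.ndarray, reference: np.ndarray) -> float:
    """RMS error normalised by the reference intensity range."""
    test = np.abs(np.asarray(test))
    reference = np.abs(np.asarray(reference))
    rng = reference.max() - reference.min()
    if rng == 0:
        raise ValueError("reference has zero intensity range")
    return float(np.sqrt(np.mean((test - reference) ** 2)) / rng)


def sweep_recon_params(
    acq: KSpaceAcquisition,
    maps: SenseMaps,
    truth: np.ndarray,
    lambdas=(0.0005, 0.001, 0.002, 0.004),
    iteration_counts=(10, 20, 40),
    base_config: ReconConfig | None = None,
):
    """NRMSE against ground truth over a (lambda, iterations) grid.

    Runs the reconstruction once per lambda at the largest iteration count
    and reads intermediate iterates off the same run is *not* done — each
    cell is an independent run so the monotone-safeguard state matches what
    a user would get at that setting.  Returns a pandas DataFrame with one
    row per (lambda, iterations) cell.
    """
    import pandas as pd

    rows = []
    for lam in lambdas:
        for it in iteration_counts:
            cfg = ReconConfig(
                lam=lam,
                iterations=it,
                **{
                    k: getattr(base_config, k)
                    for k in ("wavelet", "wavelet_levels", "step_rule", "normalize", "monotone")
                }
                if base_config
                else {},
            )
            res = reconstruct_cs(acq, maps, cfg)
            rows.append(
                {
                    "lambda": lam,
                    "iterations": it,
                    "nrmse": nrmse(res.magnitude, truth),
                    "final_cost": res.cost_trace[-1]["total"],
                }
            )
    return pd.DataFrame(rows)
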