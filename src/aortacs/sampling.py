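"""Variable-density Poisson-disc undersampling of the phase-encode plane.

The mask lives on the ny x nz phase-encode grid with elliptical k-space
coverage (semi-axes ny/2, nz/2 in index units) and a fully sampled central
calibration ellipse used downstream for coil-sensitivity estimation.  The
Poisson-disc minimum distance grows linearly with the normalised elliptical
radius rho:

    r(rho) = r0 * (1 + density_decay * rho),   rho in [0, 1]

so sampling density falls towards the k-space periphery.  r0 is calibrated
by bisection until the achieved in-ellipse sampling fraction matches
1/target_accel within a declared tolerance (an acceleration factor of 5
corresponds to acquiring 20% of the elliptical k-space).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "poisson_disc_mask",
    "full_mask",
    "uniform_random_mask",
    "sampling_fraction",
    "mask_diagnostics",
]


@dataclass
class SamplingMask:
    grid: np.ndarray  # (ny, nz) bool
    ellipse_semi_axes: tuple[float, float]
    calib_semi_axes: tuple[float, float]
    target_accel: float
    achieved_fraction: float
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def is_full(self) -> bool:
        """True when every in-ellipse location is sampled."""
        return bool(np.all(self.grid[_ellipse_support(*self.grid.shape)]))

    def calib_mask(self) -> np.ndarray:
        ny, nz = self.grid.shape
        rho = _calib_radius(ny, nz, self.calib_semi_axes)
        return rho <= 1.0

    def save(self, path, sidecar: bool = True) -> None:
        """Plain-text 0/1 matrix plus a JSON parameter sidecar."""
        np.savetxt(path, self.grid.astype(np.int8), fmt="%d")
        if sidecar:
            meta = {
                "ellipse_semi_axes": list(self.ellipse_semi_axes),
                "calib_semi_axes": list(self.calib_semi_axes),
                "target_accel": self.target_accel,
                "achieved_fraction": self.achieved_fraction,
                "seed": self.seed,
                "params": self.params,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @staticmethod
    def load(path) -> "SamplingMask":
        grid = np.loadtxt(path, dtype=np.int8).astype(bool)
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            ny, nz = grid.shape
            meta = {
                "ellipse_semi_axes": [ny / 2, nz / 2],
                "calib_semi_axes": [0.0, 0.0],
                "target_accel": float("nan"),
                "achieved_fraction": float("nan"),
                "seed": None,
                "params": {},
            }
        return SamplingMask(
            grid=grid,
            ellipse_semi_axes=tuple(meta["ellipse_semi_axes"]),
            calib_semi_axes=tuple(meta["calib_semi_axes"]),
            target_accel=meta["target_accel"],
            achieved_fraction=meta["achieved_fraction"],
            seed=meta["seed"],
            params=meta.get("params", {}),
        )


def _grid_coords(ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    cy, cz = ny / 2.0, nz / 2.0  # DC sits at index ny//2 after fftshift
    yy, zz = np.meshgrid(np.arange(ny) - cy + 0.5, np.arange(nz) - cz + 0.5, indexing="ij")
    return yy, zz


def _normalized_radius(ny: int, nz: int) -> np.ndarray:
    yy, zz = _grid_coords(ny, nz)
    return np.sqrt((yy / (ny / 2.0)) ** 2 + (zz / (nz / 2.0)) ** 2)


def _ellipse_support(ny: int, nz: int) -> np.ndarray:
    return _normalized_radius(ny, nz) <= 1.0


def _calib_radius(ny: int, nz: int, calib_semi: tuple[float, float]) -> np.ndarray:
    yy, zz = _grid_coords(ny, nz)
    ay = max(calib_semi[0], 1e-9)
    az = max(calib_semi[1], 1e-9)
    return np.sqrt((yy / ay) ** 2 + (zz / az) ** 2)


def _dart_throw(
    ny: int,
    nz: int,
    r0: float,
    density_decay: float,
    calib: np.ndarray,
    support: np.ndarray,
    order: np.ndarray,
    rho_flat: np.ndarray,
) -> np.ndarray:
    """Greedy dart throwing over a randomly permuted candidate list.

    A candidate is accepted when no previously accepted (non-calibration)
    point lies within its local radius r(rho).  Points are grid locations,
    so an occupancy array doubles as the background acceleration grid.
    """
    occupied = np.zeros((ny, nz), dtype=bool)
    grid = calib.copy()  # calibration region always sampled
    r_max = r0 * (1.0 + max(density_decay, 0.0))
    w_max = int(np.ceil(r_max))
    # squared-distance stencil around a candidate, computed once
    off = np.arange(-w_max, w_max + 1)
    d2 = off[:, None] ** 2 + off[None, :] ** 2
    for idx in order:
        y, z = divmod(int(idx), nz)
        r_loc = r0 * (1.0 + density_decay * rho_flat[idx])
        w = int(np.ceil(r_loc))
        y0, y1 = max(0, y - w), min(ny, y + w + 1)
        z0, z1 = max(0, z - w), min(nz, z + w + 1)
        win = occupied[y0:y1, z0:z1]
        if win.any():
            sten = d2[w_max - (y - y0) : w_max + (y1 - y), w_max - (z - z0) : w_max + (z1 - z)]
            if np.any(win & (sten <= r_loc * r_loc)):
                continue
        occupied[y, z] = True
        grid[y, z] = True
    return grid


def poisson_disc_mask(
    ny: int,
    nz: int,
    target_accel: float,
    calib_fraction: float = 0.04,
    density_decay: float = 2.0,
    seed: int = 0,
    tol: float = 0.005,
    max_calibration_steps: int = 30,
) -> SamplingMask:
    """Generate a variable-density Poisson-disc mask at a target acceleration.

    Parameters
    ----------
    ny, nz
        Phase-encode grid size (phase- and slice-encode directions).
    target_accel
        Acceleration factor R; the mask samples ~1/R of the in-ellipse
        points (R = 5 acquires 20% of elliptical k-space).
    calib_fraction
        Area fraction of the ellipse covered by the fully sampled central
        calibration ellipse.
    density_decay
        Slope of the minimum-distance growth towards the periphery; 0 gives
        a uniform-density Poisson-disc pattern.
    tol
        Tolerance on |achieved_fraction - 1/target_accel|; bisection on the
        base radius r0 stops when met.
    """
    if target_accel < 1:
        raise ValueError("target_accel must be >= 1")
    support = _ellipse_support(ny, nz)
    n_support = int(support.sum())
    target_fraction = 1.0 / target_accel

    scale = np.sqrt(calib_fraction)
    calib_semi = (scale * ny / 2.0, scale * nz / 2.0)
    calib = (_calib_radius(ny, nz, calib_semi) <= 1.0) & support
    if calib.sum() / n_support > target_fraction:
        raise ValueError(
            f"calibration region ({calib.sum() / n_support:.1%} of ellipse) exceeds the "
            f"sampling budget 1/R = {target_fraction:.1%}"
        )

    if target_accel == 1:
        grid = support.copy()
        return SamplingMask(
            grid=grid,
            ellipse_semi_axes=(ny / 2.0, nz / 2.0),
            calib_semi_axes=calib_semi,
            target_accel=target_accel,
            achieved_fraction=1.0,
            seed=seed,
            params={"calib_fraction": calib_fraction, "density_decay": density_decay, "r0": 0.0},
        )

    rng = np.random.default_rng(seed)
    rho = _normalized_radius(ny, nz)
    candidates = np.flatnonzero(support & ~calib)
    order = rng.permutation(candidates)
    rho_flat = rho.ravel()

    def fraction_at(r0: float) -> tuple[float, np.ndarray]:
        grid = _dart_throw(ny, nz, r0, density_decay, calib, support, order, rho_flat)
        return grid[support].sum() / n_support, grid

    # bracket: small r0 -> everything accepted (fraction 1); grow until below target
    lo, hi = 0.25, 2.0
    f_hi, grid_hi = fraction_at(hi)
    steps = 0
    while f_hi > target_fraction and steps < 12:
        lo, hi = hi, hi * 1.8
        f_hi, grid_hi = fraction_at(hi)
        steps += 1
    best = (abs(f_hi - target_fraction), f_hi, grid_hi, hi)
    for _ in range(max_calibration_steps):
        mid = 0.5 * (lo + hi)
        f, grid = fraction_at(mid)
        if abs(f - target_fraction) < best[0]:
            best = (abs(f - target_fraction), f, grid, mid)
        if abs(f - target_fraction) <= tol:
            break
        if f > target_fraction:
            lo = mid
        else:
            hi = mid
    err, f, grid, r0 = best
    if err > tol:
        raise RuntimeError(
            f"acceleration calibration did not reach tol={tol}: best achieved "
            f"fraction {f:.4f} vs target {target_fraction:.4f}"
        )
    return SamplingMask(
        grid=grid,
        ellipse_semi_axes=(ny / 2.0, nz / 2.0),
        calib_semi_axes=calib_semi,
        target_accel=target_accel,
        achieved_fraction=float(f),
        seed=seed,
        params={"calib_fraction": calib_fraction, "density_decay": density_decay, "r0": r0},
    )


def full_mask(ny: int, nz: int, calib_fraction: float = 0.04) -> SamplingMask:
    """Fully sampled elliptical mask (the reference-arm acquisition)."""
    return poisson_disc_mask(ny, nz, target_accel=1, calib_fraction=calib_fraction)


def uniform_random_mask(
    ny: int, nz: int, fraction: float, calib_fraction: float = 0.04, seed: int = 0
) -> SamplingMask:
    """Uniform (non-Poisson) random mask at a given in-ellipse fraction.

    Diagnostic baseline: same sampling budget and calibration region as the
    Poisson-disc mask but with unconstrained point placement.
    """
    support = _ellipse_support(ny, nz)
    scale = np.sqrt(calib_fraction)
    calib_semi = (scale * ny / 2.0, scale * nz / 2.0)
    calib = (_calib_radius(ny, nz, calib_semi) <= 1.0) & support
    n_support = int(support.sum())
    n_target = int(round(fraction * n_support))
    n_extra = max(0, n_target - int(calib.sum()))
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(support & ~calib)
    chosen = rng.choice(candidates, size=min(n_extra, candidates.size), replace=False)
    grid = calib.copy()
    grid.ravel()[chosen] = True
    return SamplingMask(
        grid=grid,
        ellipse_semi_axes=(ny / 2.0, nz / 2.0),
        calib_semi_axes=calib_semi,
        target_accel=1.0 / fraction,
        achieved_fraction=grid[support].sum() / n_support,
        seed=seed,
        params={"calib_fraction": calib_fraction, "kind": "uniform"},
    )


def matched_density_random_mask(like: SamplingMask, seed: int = 0) -> SamplingMask:
    """Random mask with the same density profile but no minimum distance.

    Draws the same number of non-calibration points as ``like`` with
    selection probability proportional to the local Poisson-disc density
    1/r(rho)^2.  Isolates the effect of the minimum-distance property in
    point-spread-function comparisons.
    """
    ny, nz = like.grid.shape
    support = _ellipse_support(ny, nz)
    calib = like.calib_mask() & support
    rho = _normalized_radius(ny, nz)
    r0 = like.params.get("r0", 1.0)
    alpha = like.params.get("density_decay", 0.0)
    dens = 1.0 / np.maximum(r0 * (1.0 + alpha * rho), 1e-9) ** 2
    cand = support & ~calib
    n_target = int(like.grid[support].sum() - calib.sum())
    p = dens[cand]
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(cand.ravel())
    chosen = rng.choice(idx, size=min(n_target, idx.size), replace=False, p=p)
    grid = calib.copy()
    grid.ravel()[chosen] = True
    return SamplingMask(
        grid=grid,
        ellipse_semi_axes=like.ellipse_semi_axes,
        calib_semi_axes=like.calib_semi_axes,
        target_accel=like.target_accel,
        achieved_fraction=grid[support].sum() / support.sum(),
        seed=seed,
        params={**like.params, "kind": "matched_density_random"},
    )


def sampling_fraction(mask: SamplingMask) -> float:
    """(# sampled in-ellipse points) / (# in-ellipse points)."""
    support = _ellipse_support(*mask.grid.shape)
    return float(mask.grid[support].sum() / support.sum())


def point_spread_function(mask: SamplingMask) -> np.ndarray:
    """Magnitude PSF of the mask (inverse DFT of the sampling pattern)."""
    psf = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(mask.grid.astype(float))))
    return np.abs(psf)


def mask_diagnostics(mask: SamplingMask, n_annuli: int = 4) -> dict:
    """Poisson-disc and incoherence diagnostics.

    Returns per-annulus minimum pairwise distances between sampled points
    outside the calibration region (with the corresponding theoretical
    lower bounds r(rho) at each annulus inner edge) and the PSF
    peak-to-max-sidelobe ratio.
    """
    ny, nz = mask.grid.shape
    rho = _normalized_radius(ny, nz)
    calib = mask.calib_mask()
    pts_mask = mask.grid & ~calib
    ys, zs = np.nonzero(pts_mask)
    rhos = rho[ys, zs]

    edges = np.linspace(0.0, 1.0, n_annuli + 1)
    min_d = []
    bounds = []
    r0 = mask.params.get("r0", 0.0)
    alpha = mask.params.get("density_decay", 0.0)
    for i in range(n_annuli):
        sel = (rhos >= edges[i]) & (rhos < edges[i + 1])
        p = np.stack([ys[sel], zs[sel]], axis=1).astype(float)
        if len(p) < 2:
            min_d.append(np.nan)
        else:
            from scipy.spatial import cKDTree

            tree = cKDTree(p)
            d, _ = tree.query(p, k=2)
            min_d.append(float(d[:, 1].min()))
        bounds.append(r0 * (1.0 + alpha * edges[i]))

    psf = point_spread_function(mask)
    peak_idx = np.unravel_index(np.argmax(psf), psf.shape)
    peak = psf[peak_idx]
    side = psf.copy()
    side[peak_idx] = 0.0
    max_side = float(side.max())
    return {
        "annulus_edges": edges.tolist(),
        "min_pairwise_distance_by_annulus": min_d,
        "min_distance_bounds": bounds,
        "psf_peak": float(peak),
        "psf_max_sidelobe": max_side,
        "psf_peak_to_max_sidelobe": float(peak / max_side) if max_side > 0 else np.inf,
    }
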