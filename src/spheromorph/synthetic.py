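"""Synthetic biosphere data with known ground truth.

Generates every input the analysis pipeline consumes — single-spheroid
masks, whole-field images, per-biosphere cell-count time series and 3D
tumour volume cohorts — from explicit seeds, together with exact
ground-truth shape and growth parameters computed on the continuous
geometry before rasterisation.

The emulated biology: patient-derived glioblastoma cells embedded in a
hydrogel biosphere proliferate exponentially, n(t) = n0 * exp((t-t0)/tau),
and the multicellular spheroids they form grow spherically, so diameter and
area follow d(t) = d0 * exp((t-t0)/(3*tau)) and A(t) = A0 * exp(2(t-t0)/(3*tau)).
Mesenchymal-like cultures grow fast and stay compact and round at all
sizes; proneural-like cultures grow slowly, track the spherical prediction
poorly, and become more irregular as they enlarge.  Tumour cohorts show the
3D analogue: sphericity decreasing with volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import sph_harm_y

from .growth import CountSeries
from .morphometry import Mask2D, Volume3D, polygon_area_perimeter

_N_VERTICES = 4096  # angular samples for the continuous boundary truth


@dataclass(frozen=True)
class SubtypeProfile:
    """Growth/shape phenotype of one culture subtype.

    tau : proliferation e-folding time in days (doubling time = tau*ln 2).
    irregularity_base : boundary perturbation amplitude at the initial size.
    irregularity_slope : increase of that amplitude per doubling of area;
        0 means shape statistics are independent of spheroid size.
    growth_coupling : ratio of the spheroid volumetric growth rate to the
        cell-count growth rate.  1 reproduces the compact, spherically
        growing phenotype; values < 1 model cultures whose structures lag
        the proliferation-derived prediction (loose, diffusive clustering).
    """

    name: str
    tau: float
    irregularity_base: float
    irregularity_slope: float
    growth_coupling: float = 1.0
    n_modes: int = 8
    slope_heterogeneity: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.irregularity_base < 0:
            raise ValueError("irregularity_base must be >= 0")
        if not 0 < self.growth_coupling <= 2:
            raise ValueError("growth_coupling must be in (0, 2]")


MESENCHYMAL_LIKE = SubtypeProfile(
    name="mesenchymal-like", tau=2.5,
    irregularity_base=0.10, irregularity_slope=0.0,
)
PRONEURAL_LIKE = SubtypeProfile(
    name="proneural-like", tau=5.0,
    irregularity_base=0.15, irregularity_slope=0.15,
    growth_coupling=0.5,
)


@dataclass
class SyntheticTruth:
    """Ground truth attached to one generated object.

    Shape fields are computed on the continuous boundary/surface before
    rasterisation; growth fields are the exact generator parameters.
    Fields not applicable to an object kind are None.
    """

    object_id: str = ""
    area_um2: float | None = None
    perimeter_um: float | None = None
    circularity: float | None = None
    diameter_um: float | None = None
    irregularity: float | None = None
    time_d: float | None = None
    n0: float | None = None
    tau: float | None = None
    volume_cm3: float | None = None
    surface_cm2: float | None = None
    sphericity: float | None = None


# ---------------------------------------------------------------------------
# 2D spheroids


def _fourier_boundary(
    irregularity: float, n_modes: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean radial profile r(theta)/r0 on _N_VERTICES angles.

    Random-phase Fourier perturbation over modes 2..n_modes with amplitudes
    proportional to 1/k, L1-normalised so the total perturbation magnitude
    never exceeds ``irregularity`` and the boundary cannot self-intersect.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)
    k = np.arange(2, n_modes + 1)
    amp = rng.uniform(0.3, 1.0, size=k.size) / k
    amp /= amp.sum()
    phase = rng.uniform(0.0, 2.0 * math.pi, size=k.size)
    r = 1.0 + irregularity * np.sum(
        amp[:, None] * np.cos(k[:, None] * theta[None, :] + phase[:, None]),
        axis=0,
    )
    return np.maximum(r, 0.05)  # radial clipping; unreachable for irr < 1


def generate_spheroid_mask(
    equivalent_diameter: float,
    irregularity: float,
    pixel_size: float = 0.5,
    n_modes: int = 8,
    seed: int = 0,
    object_id: str = "",
    time: float | None = None,
) -> tuple[Mask2D, SyntheticTruth]:
    """Rasterise one spheroid with a randomly perturbed circular boundary.

    The continuous boundary is scaled so its exact polygon area equals that
    of a disk of the requested ``equivalent_diameter`` (um); the truth record
    carries the exact polygon area, perimeter and circularity.  With
    ``irregularity=0`` the boundary is a circle and truth circularity is 1.
    """
    if equivalent_diameter < 4 * pixel_size:
        raise ValueError(
            f"equivalent_diameter {equivalent_diameter:g} um below the "
            f"resolvable minimum of {4 * pixel_size:g} um at "
            f"{pixel_size:g} um/pixel"
        )
    if not 0 <= irregularity < 1:
        raise ValueError("irregularity must lie in [0, 1)")
    if n_modes < 2:
        raise ValueError("n_modes must be >= 2")

    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)
    target_area = math.pi * equivalent_diameter ** 2 / 4.0

    if irregularity == 0:
        radius = equivalent_diameter / 2.0
        verts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        truth = SyntheticTruth(
            object_id=object_id,
            area_um2=target_area,
            perimeter_um=math.pi * equivalent_diameter,
            circularity=1.0,
            diameter_um=equivalent_diameter,
            irregularity=0.0,
            time_d=time,
        )
    else:
        profile = _fourier_boundary(irregularity, n_modes, rng)
        verts = (equivalent_diameter / 2.0) * profile[:, None] * \
            np.column_stack([np.cos(theta), np.sin(theta)])
        area, _ = polygon_area_perimeter(verts)
        verts *= math.sqrt(target_area / area)  # exact equivalent diameter
        area, perim = polygon_area_perimeter(verts)
        truth = SyntheticTruth(
            object_id=object_id,
            area_um2=area,
            perimeter_um=perim,
            circularity=4.0 * math.pi * area / perim ** 2,
            diameter_um=2.0 * math.sqrt(area / math.pi),
            irregularity=irregularity,
            time_d=time,
        )

    # rasterise by radial test at pixel centres: the boundary is
    # star-shaped, so a pixel is foreground iff its centre radius is
    # below r(theta) at the pixel's angle (linear interpolation on the
    # dense angular grid)
    radii = np.hypot(verts[:, 0], verts[:, 1])
    rmax = float(radii.max())
    half = int(math.ceil(rmax / pixel_size)) + 2
    coords = (np.arange(2 * half) - half + 0.5) * pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    pix_theta = np.mod(np.arctan2(yy, xx), 2.0 * math.pi)
    r_bound = np.interp(
        pix_theta, theta, radii, period=2.0 * math.pi
    )
    grid = np.hypot(xx, yy) <= r_bound
    return Mask2D(grid, pixel_size, object_id=object_id, time=time), truth


@dataclass
class Timecourse:
    """Masks and truth for one simulated biosphere culture over time."""

    masks: dict[float, list[Mask2D]]
    truths: dict[float, list[SyntheticTruth]]
    profile: SubtypeProfile

    def truth_table(self):
        import pandas as pd

        rows = []
        for t, truths in self.truths.items():
            for tr in truths:
                rows.append(
                    {
                        "object_id": tr.object_id,
                        "time_d": t,
                        "area_um2": tr.area_um2,
                        "perimeter_um": tr.perimeter_um,
                        "circularity": tr.circularity,
                        "diameter_um": tr.diameter_um,
                        "irregularity": tr.irregularity,
                    }
                )
        return pd.DataFrame(rows)


def generate_biosphere_timecourse(
    profile: SubtypeProfile,
    n_spheroids: int,
    times: Sequence[float],
    d0_mean: float = 40.0,
    d0_sd: float = 8.0,
    pixel_size: float = 0.5,
    seed: int = 0,
) -> Timecourse:
    """Simulate a population of spheroids imaged at several time points.

    Each spheroid draws an initial equivalent diameter from
    N(d0_mean, d0_sd) (um, clipped to the resolvable minimum) and grows as
    d(t) = d0 * exp(g*(t-t0)/(3*tau)) with the profile's tau and growth
    coupling g.  Its boundary irregularity at time t is
    irregularity_base + irregularity_slope * log2(A(t)/A(t0)), clipped to
    [0, 0.9); the Fourier phases are drawn once per spheroid so a given
    object keeps its shape identity while its amplitude evolves.
    """
    if n_spheroids < 1:
        raise ValueError("n_spheroids must be >= 1")
    times = [float(t) for t in times]
    if not times:
        raise ValueError("times must be non-empty")
    if sorted(times) != times:
        raise ValueError("times must be sorted ascending")

    rng = np.random.default_rng(seed)
    d_min = 4.0 * pixel_size
    d0 = np.maximum(
        rng.normal(d0_mean, d0_sd, size=n_spheroids), d_min * 1.25
    )
    shape_seeds = rng.integers(0, 2 ** 31, size=n_spheroids)
    # Per-spheroid slope: large structures "can adopt very different
    # shapes", i.e. the size coupling raises shape *heterogeneity*, not a
    # uniform drift -- some spheroids stay round while sibling structures
    # degrade.  Uniform(0, 2*slope) keeps the nominal slope as the mean.
    if profile.slope_heterogeneity:
        slopes = rng.uniform(
            0.0, 2.0 * profile.irregularity_slope, size=n_spheroids
        )
    else:
        slopes = np.full(n_spheroids, profile.irregularity_slope)
    t0 = times[0]
    g = profile.growth_coupling

    masks: dict[float, list[Mask2D]] = {t: [] for t in times}
    truths: dict[float, list[SyntheticTruth]] = {t: [] for t in times}
    for i in range(n_spheroids):
        for t in times:
            d_t = d0[i] * math.exp(g * (t - t0) / (3.0 * profile.tau))
            log2_area_ratio = 2.0 * math.log2(d_t / d0[i])
            irr = profile.irregularity_base + slopes[i] * log2_area_ratio
            irr = float(np.clip(irr, 0.0, 0.9 - 1e-9))
            mask, truth = generate_spheroid_mask(
                d_t, irr, pixel_size=pixel_size, n_modes=profile.n_modes,
                seed=int(shape_seeds[i]), object_id=f"sph{i:04d}", time=t,
            )
            masks[t].append(mask)
            truths[t].append(truth)
    return Timecourse(masks=masks, truths=truths, profile=profile)


def compose_field(
    masks: Sequence[Mask2D],
    pad: int = 8,
    foreground: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Paste single-object masks into one grayscale field image.

    Objects are laid out on a non-overlapping grid with ``pad`` background
    pixels around each, for segmentation tests.  Optional Gaussian intensity
    noise; no photorealism intended.  Returns the image and the (row, col)
    offset at which each mask was pasted.
    """
    if not masks:
        raise ValueError("need at least one mask")
    n = len(masks)
    ncol = int(math.ceil(math.sqrt(n)))
    nrow = int(math.ceil(n / ncol))
    cell_h = max(m.pixels.shape[0] for m in masks) + 2 * pad
    cell_w = max(m.pixels.shape[1] for m in masks) + 2 * pad
    img = np.full((nrow * cell_h, ncol * cell_w), background, dtype=float)
    offsets = []
    for idx, m in enumerate(masks):
        r0 = (idx // ncol) * cell_h + pad
        c0 = (idx % ncol) * cell_w + pad
        h, w = m.pixels.shape
        img[r0:r0 + h, c0:c0 + w][m.pixels] = foreground
        offsets.append((r0, c0))
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return img, offsets


# ---------------------------------------------------------------------------
# cell counts


def generate_count_series(
    n0: float,
    tau: float,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    culture_id: str = "",
    replicate_id: str = "",
) -> CountSeries:
    """Exponential cell counts with multiplicative lognormal noise.

    n(t) = n0 * exp((t-t0)/tau), multiplied by a unit-mean lognormal factor
    with coefficient of variation ``noise_cv``, rounded to integers with a
    floor of 1 cell.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    expected = n0 * np.exp((t - t[0]) / tau)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        rng = np.random.default_rng(seed)
        expected = expected * rng.lognormal(-sigma ** 2 / 2.0, sigma, t.size)
    counts = np.maximum(np.rint(expected), 1.0)
    return CountSeries(
        times=t, counts=counts, culture_id=culture_id,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# 3D volumes


def _spherical_field(
    l_max: int,
    rng: np.random.Generator,
    spectral_power: float = 1.0,
    n_theta: int = 257,
):
    """Band-limited random field on the sphere, max-normalised to [-1, 1].

    Real spherical-harmonic expansion over degrees 2..l_max with random
    Gaussian coefficients scaled by l**(-spectral_power): larger powers
    give smoother, lobed surfaces; smaller powers push energy into fine
    surface texture.  The field is evaluated separably
    (Y_lm(theta, phi) = Y_lm(theta, 0) * e^{i m phi}) on a regular grid and
    wrapped in a linear interpolator so arbitrary directions are cheap.
    """
    n_phi = 2 * (n_theta - 1) + 1
    theta = np.linspace(0.0, math.pi, n_theta)
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi)
    # accumulate per-order cos/sin profiles, then two matrix products
    cos_prof = np.zeros((n_theta, l_max + 1))
    sin_prof = np.zeros((n_theta, l_max + 1))
    for ell in range(2, l_max + 1):
        coeff = rng.normal(0.0, ell ** (-spectral_power), size=2 * ell + 1)
        for m in range(ell + 1):
            y_theta = sph_harm_y(ell, m, theta, 0.0).real
            if m == 0:
                cos_prof[:, 0] += coeff[0] * y_theta
            else:
                cos_prof[:, m] += math.sqrt(2.0) * coeff[2 * m - 1] * y_theta
                sin_prof[:, m] -= math.sqrt(2.0) * coeff[2 * m] * y_theta
    orders = np.arange(l_max + 1)
    f = cos_prof @ np.cos(np.outer(orders, phi)) \
        + sin_prof @ np.sin(np.outer(orders, phi))
    f /= np.max(np.abs(f))
    interp = RegularGridInterpolator(
        (theta, phi), f, bounds_error=False, fill_value=None
    )
    return theta, phi, f, interp


def _surface_truth(
    theta: np.ndarray, phi: np.ndarray, r: np.ndarray
) -> tuple[float, float]:
    """Volume and surface area of a star-shaped surface r(theta, phi).

    Quadrature on the regular grid with finite-difference derivatives:
    dS = r * sqrt((r^2 + r_theta^2) * sin^2(theta) + r_phi^2) dtheta dphi,
    dV = r^3/3 * sin(theta) dtheta dphi.
    """
    sin_t = np.sin(theta)[:, None]
    r_t = np.gradient(r, theta, axis=0)
    r_p = np.gradient(r, phi, axis=1)
    integrand_s = r * np.sqrt((r ** 2 + r_t ** 2) * sin_t ** 2 + r_p ** 2)
    integrand_v = (r ** 3 / 3.0) * sin_t
    surf = np.trapezoid(np.trapezoid(integrand_s, phi, axis=1), theta)
    vol = np.trapezoid(np.trapezoid(integrand_v, phi, axis=1), theta)
    return float(vol), float(surf)


def generate_volume_mask(
    target_volume: float,
    irregularity: float,
    voxel_size: float = 0.5,
    seed: int = 0,
    l_max: int = 6,
    spectral_power: float = 1.0,
    tumor_id: str = "",
) -> tuple[Volume3D, SyntheticTruth]:
    """Rasterise one tumour as a radially perturbed ball.

    The continuous surface is r(u) = r0 * (1 + irregularity * f(u)) with f a
    band-limited random field on the sphere (degrees 2..l_max, amplitudes
    proportional to 1/l, max-normalised); r0 is rescaled so the continuous
    volume equals ``target_volume`` (cm^3).  Truth volume, surface area and
    sphericity are computed on the continuous surface by quadrature.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    if not 0 <= irregularity < 0.95:
        raise ValueError("irregularity must lie in [0, 0.95)")

    rng = np.random.default_rng(seed)
    r0_mm = 10.0 * (3.0 * target_volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    if irregularity == 0:
        # exact ball: closed-form truth, spherical raster below
        half = int(math.ceil(r0_mm / voxel_size)) + 2
        if 2.0 * r0_mm / voxel_size < 16:
            raise ValueError(
                f"grid too coarse: tumour spans "
                f"{2 * r0_mm / voxel_size:.1f} voxels; voxel_size <= "
                f"{2 * r0_mm / 16:.3f} mm required"
            )
        axis = (np.arange(2 * half) - half + 0.5) * voxel_size
        x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
        voxels = x ** 2 + y ** 2 + z ** 2 <= r0_mm ** 2
        truth = SyntheticTruth(
            object_id=tumor_id,
            volume_cm3=target_volume,
            surface_cm2=4.0 * math.pi * r0_mm ** 2 / 100.0,
            sphericity=1.0,
            irregularity=0.0,
        )
        return Volume3D(voxels, voxel_size, tumor_id=tumor_id), truth

    theta, phi, f, interp = _spherical_field(
        l_max, rng, spectral_power=spectral_power
    )
    radial = np.maximum(1.0 + irregularity * f, 0.05)
    vol_unit, _ = _surface_truth(theta, phi, radial)  # at r0 = 1
    r0_mm = (target_volume * 1000.0 / vol_unit) ** (1.0 / 3.0)

    r_grid = r0_mm * radial
    vol_mm3, surf_mm2 = _surface_truth(theta, phi, r_grid)
    truth = SyntheticTruth(
        object_id=tumor_id,
        volume_cm3=vol_mm3 / 1000.0,
        surface_cm2=surf_mm2 / 100.0,
        sphericity=(
            math.pi ** (1.0 / 3.0) * (6.0 * vol_mm3) ** (2.0 / 3.0)
            / surf_mm2
        ),
        irregularity=irregularity,
    )

    r_max = r0_mm * (1.0 + irregularity)
    half = int(math.ceil(r_max / voxel_size)) + 2
    n_across = 2 * half
    if 2.0 * r0_mm / voxel_size < 16:
        raise ValueError(
            f"grid too coarse: tumour spans {2 * r0_mm / voxel_size:.1f} "
            f"voxels; voxel_size <= {2 * r0_mm / 16:.3f} mm required"
        )
    axis = (np.arange(n_across) - half + 0.5) * voxel_size
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
    rad = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    zr = np.divide(z, rad, out=np.zeros_like(z), where=rad > 0)
    th = np.arccos(np.clip(zr, -1, 1))
    ph = np.mod(np.arctan2(y, x), 2.0 * math.pi)
    r_dir = r0_mm * np.maximum(
        1.0 + irregularity * np.clip(
            interp(np.stack([th.ravel(), ph.ravel()], axis=1)), -1, 1
        ).reshape(rad.shape),
        0.05,
    )
    voxels = rad <= r_dir
    return Volume3D(voxels, voxel_size, tumor_id=tumor_id), truth


def generate_cohort(
    n_tumors: int,
    volume_median: float = 29.09,
    volume_log_sd: float = 0.9,
    sphericity_volume_coupling: float = 0.12,
    irregularity_base: float = 0.55,
    seed: int = 0,
    voxel_size: float | str = "auto",
    voxel_target_across: int = 40,
    l_max: int = 16,
    spectral_power: float = 0.5,
):
    """Simulate a tumour cohort in which larger tumours are less spherical.

    Volumes (cm^3) are lognormal around ``volume_median``; each tumour's
    surface irregularity is irregularity_base +
    sphericity_volume_coupling * log2(V / volume_median), clipped to
    [0.05, 0.9), so a positive coupling makes sphericity decrease with
    volume.  ``voxel_size="auto"`` picks, per tumour, the coarsest of
    0.5-2.0 mm that keeps the tumour about 40 voxels across.

    Returns (volumes, truth table): a list of ``Volume3D`` and a DataFrame
    with columns tumor_id, volume_cm3, irregularity, true_sphericity,
    voxel_size_mm.
    """
    import pandas as pd

    if n_tumors < 2:
        raise ValueError("n_tumors must be >= 2")
    rng = np.random.default_rng(seed)
    volumes_cm3 = volume_median * np.exp(
        rng.normal(0.0, volume_log_sd, size=n_tumors)
    )
    seeds = rng.integers(0, 2 ** 31, size=n_tumors)

    vols: list[Volume3D] = []
    rows = []
    for i, v in enumerate(volumes_cm3):
        irr = irregularity_base + sphericity_volume_coupling * \
            math.log2(v / volume_median)
        irr = float(np.clip(irr, 0.05, 0.9 - 1e-9))
        if voxel_size == "auto":
            r_mm = 10.0 * (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
            vx = float(np.clip(2.0 * r_mm / voxel_target_across, 0.5, 2.0))
        else:
            vx = float(voxel_size)
        tid = f"tumor{i:04d}"
        vol, truth = generate_volume_mask(
            v, irr, voxel_size=vx, seed=int(seeds[i]), l_max=l_max,
            spectral_power=spectral_power, tumor_id=tid,
        )
        vols.append(vol)
        rows.append(
            {
                "tumor_id": tid,
                "volume_cm3": truth.volume_cm3,
                "irregularity": irr,
                "true_sphericity": truth.sphericity,
                "voxel_size_mm": vx,
            }
        )
    return vols, pd.DataFrame(rows)
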