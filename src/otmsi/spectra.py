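"""Spectrum and MSI dataset containers plus profile-mode preprocessing.

Covers trapezoid TIC, TIC normalization, m/z-range restriction, Gaussian
resolution degradation, centroiding and average spectra.  No peak alignment
or m/z binning across pixels is performed anywhere in the package: the
downstream optimal-transport deconvolution is robust to small m/z shifts, so
those lossy steps are unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "Spectrum",
    "MSIDataset",
    "tic_trapezoid",
    "normalize_tic",
    "restrict_mz",
    "gaussian_blur",
    "centroid",
    "average_spectrum",
    "centroid_dataset",
]


@dataclass(frozen=True)
class Spectrum:
    """Paired ascending m/z and nonnegative intensity arrays.

    ``mode`` is ``"profile"`` (continuous sampling of the signal) or
    ``"centroid"`` (one stick per peak, intensity = integrated area).
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z must be strictly increasing")
        if np.any(~np.isfinite(intensity)) or np.any(intensity < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.mz.size

    @property
    def total_intensity(self) -> float:
        """Sum of stick intensities (meaningful for centroid mode)."""
        return float(self.intensity.sum())

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * factor)


@dataclass
class MSIDataset:
    """A pixel grid of spectra with integer 0-based (x, y) coordinates."""

    pixels: list[tuple[int, int, Spectrum]]
    width: int
    height: int
    mode: str = "profile"

    def __post_init__(self) -> None:
        seen = set()
        for x, y, s in self.pixels:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"pixel ({x}, {y}) outside {self.width}x{self.height} grid")
            if (x, y) in seen:
                raise ValueError(f"duplicate pixel coordinate ({x}, {y})")
            if s.mode != self.mode:
                raise ValueError("all pixel spectra must share the dataset mode")
            seen.add((x, y))

    def __len__(self) -> int:
        return len(self.pixels)

    def map_spectra(self, func) -> "MSIDataset":
        """Apply ``func`` to every pixel spectrum, keeping coordinates."""
        new = [(x, y, func(s)) for x, y, s in self.pixels]
        mode = new[0][2].mode if new else self.mode
        return MSIDataset(new, self.width, self.height, mode)


def tic_trapezoid(s: Spectrum) -> float:
    """Total ion current of a profile spectrum by trapezoid integration."""
    if s.mode != "profile":
        raise ValueError("TIC integration requires a profile-mode spectrum")
    if len(s) < 2:
        raise ValueError("need at least 2 points to integrate")
    return float(np.trapezoid(s.intensity, s.mz))


def normalize_tic(s: Spectrum, target: float = 1.0) -> Spectrum:
    """Scale intensities so the trapezoid TIC equals ``target``."""
    tic = tic_trapezoid(s)
    if tic <= 0:
        raise ValueError("cannot normalize a spectrum with nonpositive TIC")
    return s.scaled(target / tic)


def restrict_mz(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep points with lo <= m/z <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    mask = (s.mz >= lo) & (s.mz <= hi)
    return Spectrum(s.mz[mask], s.intensity[mask], s.mode)


def _grid_step(mz: np.ndarray, rtol: float = 1e-3) -> float:
    steps = np.diff(mz)
    step = steps.mean()
    if np.any(np.abs(steps - step) > rtol * step):
        raise ValueError("profile grid is not uniform within tolerance")
    return float(step)


def gaussian_blur(s: Spectrum, sigma: float) -> Spectrum:
    """Convolve a uniform-grid profile spectrum with a Gaussian of width sigma (Da).

    Used to emulate a lower-resolution acquisition; the trapezoid TIC is
    preserved up to zero-padded tail losses at the spectrum edges.
    """
    if s.mode != "profile":
        raise ValueError("gaussian_blur requires profile mode")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    step = _grid_step(s.mz)
    blurred = ndimage.gaussian_filter1d(s.intensity, sigma / step, mode="constant")
    return Spectrum(s.mz, blurred, "profile")


def _local_maxima(intensity: np.ndarray, floor: float) -> np.ndarray:
    """Apex indices: strictly greater than neighbors; plateaus take the
    leftmost point; apexes at or below the noise floor are discarded."""
    peaks, props = signal.find_peaks(intensity, height=floor, plateau_size=1)
    return props.get("left_edges", peaks)


def centroid(
    s: Spectrum,
    height_fraction: float = 0.5,
    max_width: float = 0.2,
    noise_floor: float = 1e-6,
) -> Spectrum:
    """Convert a profile spectrum to centroid sticks.

    For each local maximum above ``noise_floor`` x the spectrum maximum, the
    integration window is the contiguous region around the apex with
    intensity >= ``height_fraction`` x apex intensity, truncated symmetrically
    to ``max_width`` Da and split at the minimum between adjacent apexes.
    The stick m/z is the intensity-weighted mean over the window and the
    stick intensity is the trapezoid area of the window.
    """
    if s.mode != "profile":
        raise ValueError("centroiding requires profile mode")
    if not 0 < height_fraction < 1:
        raise ValueError("height_fraction must be in (0, 1)")
    n = len(s)
    if n < 3 or s.intensity.max() <= 0:
        return Spectrum(np.empty(0), np.empty(0), "centroid")
    intensity, mz = s.intensity, s.mz
    floor = noise_floor * intensity.max()
    apexes = _local_maxima(intensity, floor)
    if apexes.size == 0:
        return Spectrum(np.empty(0), np.empty(0), "centroid")

    # split points between adjacent apexes: leftmost minimum between them
    left_bounds = np.empty(apexes.size, dtype=int)
    right_bounds = np.empty(apexes.size, dtype=int)
    left_bounds[0] = 0
    right_bounds[-1] = n - 1
    for i in range(apexes.size - 1):
        lo, hi = apexes[i], apexes[i + 1]
        split = lo + int(np.argmin(intensity[lo : hi + 1]))
        right_bounds[i] = split
        left_bounds[i + 1] = split

    out_mz, out_area = [], []
    for apex, lo_bound, hi_bound in zip(apexes, left_bounds, right_bounds):
        cut = height_fraction * intensity[apex]
        left = apex
        while left > lo_bound and intensity[left - 1] >= cut:
            left -= 1
        right = apex
        while right < hi_bound and intensity[right + 1] >= cut:
            right += 1
        # symmetric truncation to the maximum window width
        half = max_width / 2.0
        while mz[apex] - mz[left] > half:
            left += 1
        while mz[right] - mz[apex] > half:
            right -= 1
        if right <= left:
            continue
        window_i = intensity[left : right + 1]
        window_mz = mz[left : right + 1]
        total = window_i.sum()
        if total <= 0:
            continue
        out_mz.append(float((window_i * window_mz).sum() / total))
        out_area.append(float(np.trapezoid(window_i, window_mz)))

    if not out_mz:
        return Spectrum(np.empty(0), np.empty(0), "centroid")
    order = np.argsort(out_mz)
    out_mz = np.asarray(out_mz)[order]
    out_area = np.asarray(out_area)[order]
    # windows are disjoint, so apex m/z order is preserved and sticks distinct
    keep = np.concatenate(([True], np.diff(out_mz) > 0))
    return Spectrum(out_mz[keep], out_area[keep], "centroid")


def average_spectrum(ds: MSIDataset, pixel_subset=None) -> Spectrum:
    """Mean spectrum over a pixel set.

    Profile mode requires a common m/z grid and averages pointwise.  Centroid
    mode pools all sticks (summing sticks at identical m/z) and divides by
    the number of pixels, i.e. the mean of the pixel point-mass measures.
    """
    spectra = [s for x, y, s in ds.pixels]
    if pixel_subset is not None:
        wanted = set(map(tuple, pixel_subset))
        spectra = [s for x, y, s in ds.pixels if (x, y) in wanted]
    if not spectra:
        raise ValueError("empty pixel set")
    if ds.mode == "profile":
        grid = spectra[0].mz
        for s in spectra[1:]:
            if len(s) != len(spectra[0]) or not np.allclose(s.mz, grid):
                raise ValueError("profile averaging requires a common m/z grid")
        mean = np.mean([s.intensity for s in spectra], axis=0)
        return Spectrum(grid, mean, "profile")
    all_mz = np.concatenate([s.mz for s in spectra])
    all_i = np.concatenate([s.intensity for s in spectra])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_i = all_mz[order], all_i[order]
    uniq, inverse = np.unique(all_mz, return_inverse=True)
    pooled = np.zeros_like(uniq)
    np.add.at(pooled, inverse, all_i)
    pooled /= len(spectra)
    keep = pooled > 0
    return Spectrum(uniq[keep], pooled[keep], "centroid")


def centroid_dataset(
    ds: MSIDataset,
    height_fraction: float = 0.5,
    max_width: float = 0.2,
    noise_floor: float = 1e-6,
) -> MSIDataset:
    """Centroid every pixel spectrum of a profile-mode dataset."""
    return ds.map_spectra(
        lambda s: centroid(s, height_fraction, max_width, noise_floor)
    )
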