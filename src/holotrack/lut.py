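"""Radial-profile look-up-table (LUT) localization baseline.

The classical magnetic-tweezer approach to axial localization: a z-stack of a
bead's diffraction pattern at known defocus values is reduced to a table of
1D radial intensity profiles; an unknown image is then reduced the same way
and matched against the table, with sub-row precision from quadratic
interpolation of the match score.  In-plane localization exploits the radial
symmetry of the ring pattern: the center is found where the pattern best
matches its own mirror image along x and y.

This method is the comparison baseline for the holographic pipeline: it is
fast and precise on isolated, symmetric ring patterns but degrades when
diffraction patterns of neighboring objects overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .holography import DataError

__all__ = [
    "RadialLUT",
    "radial_profile",
    "build_lut",
    "lut_z_lookup",
    "lut_xy_localize",
]


@dataclass(frozen=True)
class RadialLUT:
    """Stack of radial diffraction profiles indexed by defocus.

    ``profiles[i]`` is the radial profile at ``defocus_values[i]`` (nm);
    profile bin ``j`` covers radius ``(j + 0.5) * bin_width`` pixels.
    """

    profiles: np.ndarray  # (n_defocus, n_bins)
    defocus_values: np.ndarray  # nm, strictly increasing
    bin_width: float  # pixels
    center_used: tuple[float, float]  # (x, y) pixels

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        d = np.asarray(self.defocus_values, dtype=float)
        if p.ndim != 2 or p.shape[0] != d.size:
            raise DataError("profiles must be (n_defocus, n_bins)")
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise DataError("defocus values must be strictly increasing")
        object.__setattr__(self, "profiles", p)
        object.__setattr__(self, "defocus_values", d)

    def save(self, path: str | Path) -> None:
        """Serialize as CSV with a JSON header line (defocus, bin width, center)."""
        path = Path(path)
        header = json.dumps(
            {
                "defocus_values_nm": self.defocus_values.tolist(),
                "bin_width_px": self.bin_width,
                "center_used_px": list(self.center_used),
            }
        )
        with path.open("w") as fh:
            fh.write(f"# {header}\n")
            np.savetxt(fh, self.profiles, delimiter=",")

    @classmethod
    def load(cls, path: str | Path) -> "RadialLUT":
        path = Path(path)
        with path.open() as fh:
            header = json.loads(fh.readline().lstrip("# ").strip())
            profiles = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(
            profiles=profiles,
            defocus_values=np.asarray(header["defocus_values_nm"], dtype=float),
            bin_width=float(header["bin_width_px"]),
            center_used=tuple(header["center_used_px"]),
        )


def radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    n_bins: int,
    bin_width: float = 1.0,
) -> np.ndarray:
    """Mean intensity on circles of radius ``(i + 0.5) * bin_width`` pixels.

    The sub-pixel ``center`` (x, y) is honored by bilinear sampling along each
    circle.  A circle that leaves the image is averaged over its in-image arc
    only; a circle entirely outside yields an interpolated value from its
    neighbors (flagged by a NaN-free output — the interpolation is silent in
    the returned array but logged).
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise DataError(f"center {center} outside image {image.shape}")
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        r = (i + 0.5) * bin_width
        n_samples = max(16, int(np.ceil(4.0 * np.pi * r / bin_width)))
        theta = 2.0 * np.pi * np.arange(n_samples) / n_samples
        xs = cx + r * np.cos(theta)
        ys = cy + r * np.sin(theta)
        inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
        if not np.any(inside):
            continue  # interpolate from neighbors afterwards
        vals = map_coordinates(
            image, np.vstack([ys[inside], xs[inside]]), order=1, mode="nearest"
        )
        out[i] = vals.mean()
    if np.any(np.isnan(out)):
        idx = np.arange(n_bins)
        good = ~np.isnan(out)
        if not np.any(good):
            raise DataError("no radial bin intersects the image")
        out[~good] = np.interp(idx[~good], idx[good], out[good])
    return out


def build_lut(
    zstack: list[np.ndarray] | np.ndarray,
    defocus_values: np.ndarray,
    center: tuple[float, float],
    n_bins: int | None = None,
    bin_width: float = 1.0,
) -> RadialLUT:
    """Convert a defocus-ordered image stack into a radial-profile LUT."""
    frames = [np.asarray(f, dtype=float) for f in zstack]
    defocus_values = np.asarray(defocus_values, dtype=float)
    if len(frames) < 2:
        raise DataError("at least 2 frames required to build a LUT")
    if defocus_values.size != len(frames):
        raise DataError("one defocus value per frame required")
    if not np.all(np.diff(defocus_values) > 0):
        raise DataError("defocus values must be strictly increasing")
    if n_bins is None:
        ny, nx = frames[0].shape
        n_bins = int(min(nx, ny) // 2 / bin_width)
    profiles = np.stack(
        [radial_profile(f, center, n_bins, bin_width) for f in frames]
    )
    return RadialLUT(
        profiles=profiles,
        defocus_values=defocus_values,
        bin_width=bin_width,
        center_used=tuple(center),
    )


def lut_z_lookup(
    profile: np.ndarray,
    lut: RadialLUT,
    skip_inner_bins: int = 2,
    max_bin: int | None = None,
) -> tuple[float, bool]:
    """Defocus estimate (nm) for a radial profile by least-squares LUT match.

    The match score against each LUT row is the sum of squared differences
    over a configurable radial range (the innermost ``skip_inner_bins`` bins
    are excluded as they average few pixels).  The minimizing row is refined
    to sub-row precision by quadratic interpolation of the score over the
    three bracketing rows.  Returns ``(z_estimate, boundary_flag)``;
    ``boundary_flag`` is True when the minimum sits on the first or last row,
    where no bracket exists.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size != lut.profiles.shape[1]:
        raise DataError(
            f"profile length {profile.size} != LUT bin count {lut.profiles.shape[1]}"
        )
    sl = slice(skip_inner_bins, max_bin)
    scores = np.sum((lut.profiles[:, sl] - profile[sl]) ** 2, axis=1)
    j = int(np.argmin(scores))
    d = lut.defocus_values
    if j == 0 or j == scores.size - 1:
        return float(d[j]), True
    s_m, s_0, s_p = scores[j - 1], scores[j], scores[j + 1]
    if s_0 == 0.0:  # exact row match: no sub-row refinement to do
        return float(d[j]), False
    denom = s_m - 2.0 * s_0 + s_p
    delta = 0.0 if denom == 0 else 0.5 * (s_m - s_p) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    # locally uniform row spacing assumed for the sub-row step
    spacing = 0.5 * (d[j + 1] - d[j - 1])
    return float(d[j] + delta * spacing), False


def _symmetry_center_1d(p: np.ndarray) -> float:
    """Axis of mirror symmetry of a 1D profile.

    A coarse estimate comes from the peak of the correlation of the profile
    with its own reverse; it is then refined by minimizing the mirror error
    sum_u [p(c+u) - p(c-u)]^2 (linear interpolation) on successively finer
    grids of candidate centers, to millipixel resolution.
    """
    p = np.asarray(p, dtype=float) - p.mean()
    corr = np.convolve(p, p)  # full convolution = correlation with reverse
    c = float(np.argmax(corr)) / 2.0
    idx = np.arange(p.size, dtype=float)
    u = np.arange(0.5, p.size / 2.0 - 2.0, 0.5)

    def mirror_err(cc: float) -> float:
        a = np.interp(cc + u, idx, p, left=np.nan, right=np.nan)
        b = np.interp(cc - u, idx, p, left=np.nan, right=np.nan)
        m = ~(np.isnan(a) | np.isnan(b))
        if not m.any():
            return np.inf
        return float(np.sum((a[m] - b[m]) ** 2) / m.sum())

    for step in (0.2, 0.02, 0.002):
        cand = c + np.arange(-10, 11) * step
        c = float(cand[int(np.argmin([mirror_err(cc) for cc in cand]))])
    return c


def lut_xy_localize(
    image: np.ndarray,
    approx_center: tuple[float, float],
    window: int | None = None,
    tol: float = 1e-3,
    max_iter: int = 20,
) -> tuple[tuple[float, float], bool]:
    """Refine the center of a ring pattern by mirror-symmetry correlation.

    Row and column sums of a window around the current center estimate are
    cross-correlated with their own mirror image; the correlation peak locates
    the symmetry axis to sub-pixel precision.  The window is re-centered and
    the procedure iterated to convergence.  Returns ``((x, y), converged)``.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    cx, cy = approx_center
    if window is None:
        window = 2 * (min(nx, ny) // 4) + 1
    hw = window // 2
    converged = False
    for _ in range(max_iter):
        ix, iy = int(round(cx)), int(round(cy))
        x_lo, x_hi = max(ix - hw, 0), min(ix + hw + 1, nx)
        y_lo, y_hi = max(iy - hw, 0), min(iy + hw + 1, ny)
        sub = image[y_lo:y_hi, x_lo:x_hi]
        new_cx = x_lo + _symmetry_center_1d(sub.sum(axis=0))
        new_cy = y_lo + _symmetry_center_1d(sub.sum(axis=1))
        shift = np.hypot(new_cx - cx, new_cy - cy)
        cx, cy = new_cx, new_cy
        if shift < tol:
            converged = True
            break
    return (float(cx), float(cy)), converged
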