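"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: direct spatial-domain summation instead of spectral
multiplication, triple loops instead of vectorized convolution, dense grid
search instead of fixed-point iteration.
"""

import numpy as np


def direct_rs_convolution(src: np.ndarray, z: float, optics) -> np.ndarray:
    """O(N^4) spatial-domain Rayleigh-Sommerfeld convolution:
    field(target) = sum_source src * h(target - source) * dA with the
    first RS kernel h = z/(2 pi) (1/rho - i k) e^{i k rho} / rho^2."""
    n = src.shape[0]
    k = optics.wavenumber
    dx = optics.pixel_spacing
    off = np.arange(-(n - 1), n) * dx
    ox, oy = np.meshgrid(off, off)
    rho = np.sqrt(ox**2 + oy**2 + z**2)
    h = z / (2 * np.pi) * np.exp(1j * k * rho) / rho**2 * (1 / rho - 1j * k)
    rows = np.arange(n)
    out = np.zeros((n, n), dtype=complex)
    for ty in range(n):
        for tx in range(n):
            out[ty, tx] = (
                np.sum(src * h[ty - rows[:, None] + n - 1, tx - rows[None, :] + n - 1])
                * dx
                * dx
            )
    return out


def triple_loop_gradient(col: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-region 3D convolution written as six nested loops."""
    nz, ny, nx = col.shape
    out = np.zeros((nz - 2, ny - 2, nx - 2))
    for z in range(nz - 2):
        for y in range(ny - 2):
            for x in range(nx - 2):
                acc = 0.0
                for dz in range(3):
                    for dy in range(3):
                        for dx in range(3):
                            acc += (
                                kernel[dz, dy, dx]
                                * col[z + 2 - dz, y + 2 - dy, x + 2 - dx]
                            )
                out[z, y, x] = acc
    return out


def dense_grid_fixed_point(cuboid: np.ndarray,
                           levels=(0.1, 0.01, 0.001, 0.0002),
                           span: float = 1.5) -> np.ndarray:
    """Parabolic-masking fixed point by dense grid search: minimize
    |centroid(c) - c| over candidate centers c on successively finer grids."""
    shape = cuboid.shape
    half = np.array([(s - 1) / 2 for s in shape])
    semi = np.maximum(half, 1.0)
    grids = np.meshgrid(*(np.arange(s) - h for s, h in zip(shape, half)),
                        indexing="ij")
    flat_i = cuboid.ravel()
    flat = [g.ravel() for g in grids]

    def residual(c):
        w = 1.0 - sum(((f - ci) / a) ** 2 for f, ci, a in zip(flat, c, semi))
        w = np.maximum(w, 0.0) * flat_i
        m = w.sum()
        cen = np.array([(w * f).sum() / m for f in flat])
        return np.linalg.norm(cen - c)

    best = np.zeros(3)
    for step in levels:
        offs = np.arange(-span, span + step / 2, step)
        best_r = np.inf
        best_c = best
        for dz in offs:
            for dy in offs:
                for dx in offs:
                    c = best + np.array([dz, dy, dx])
                    r = residual(c)
                    if r < best_r:
                        best_r, best_c = r, c
        best = best_c
        span = step * 1.5
    return best
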