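"""Magnetic-tweezer track analysis: linking, drift and axial corrections,
dissociation detection, survival and slip-bond kinetics, force calibration.

The observables follow standard single-molecule force-spectroscopy practice:

* Tether extension is the drift- and z-corrected bead height above its
  pre-force baseline, bounded by the DNA contour length (0.34 nm per base
  pair of B-form DNA).
* A dissociation event is the bead disappearing from the field of view after
  the magnetic force is engaged; its time is measured from force engagement.
* Per-force survival is fitted with a single exponential,
  S(t) = (1 - c) exp(-k_off t) + c, with the offset c fixed to zero unless
  requested (a nonzero c accounts for a long-lived, e.g. multivalent,
  subpopulation).  The bond half-life is t_F = ln 2 / k_off.
* Half-lives across forces follow the Bell slip-bond model
  t_F = t_0 exp(-F x_b / k_B T), fitted by least squares in log space.
* The applied force is calibrated from tethered Brownian motion,
  F = k_B T <z> / <dx^2>, with <z> the mean extension and <dx^2> the lateral
  positional variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .holography import DataError
from .localize import Position3D

__all__ = [
    "KB_PN_NM_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "BP_RISE_NM",
    "contour_length_nm",
    "Track",
    "ZCorrection",
    "DissociationRecord",
    "SurvivalFit",
    "BellFit",
    "ForceEstimate",
    "StepTrace",
    "link_tracks",
    "drift_correct",
    "apply_z_correction",
    "detect_dissociation",
    "fit_survival",
    "fit_bell",
    "force_from_fluctuations",
    "step_snr",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant in pN nm / K.
KB_PN_NM_PER_K = 0.0138065
DEFAULT_TEMPERATURE_K = 298.15
#: Axial rise per base pair of B-form DNA, nm.
BP_RISE_NM = 0.34


def contour_length_nm(n_bp: float, rise_per_bp: float = BP_RISE_NM) -> float:
    """Contour length of a double-stranded DNA tether of ``n_bp`` base pairs."""
    return n_bp * rise_per_bp


@dataclass
class Track:
    """Time-linked 3D positions of one bead.

    Gaps are explicit: ``present[i]`` is False on frames where the bead was
    not detected (coordinates there are NaN).  ``role`` distinguishes tethered
    beads from surface-fixed reference beads used for drift correction.
    """

    bead_id: int
    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # nm
    y: np.ndarray
    z: np.ndarray
    present: np.ndarray  # bool
    role: str = "tethered"  # "tethered" | "reference"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise DataError("track timestamps must be strictly increasing")
        for name in ("x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.present = np.asarray(self.present, dtype=bool)
        if self.role not in ("tethered", "reference"):
            raise DataError(f"unknown track role {self.role!r}")

    def copy(self) -> "Track":
        return Track(
            bead_id=self.bead_id,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            z=self.z.copy(),
            present=self.present.copy(),
            role=self.role,
        )


@dataclass(frozen=True)
class ZCorrection:
    """Correction of reconstructed z for refractive-index mismatch and the
    systematic axial bias of scalar back-propagation.

    Modes: ``linear`` (z' = slope*z + intercept, coefficients from a bead-scan
    calibration), ``smallangle`` (z' = n_medium/n_oil * z, the small-angle
    index-ratio correction) or ``spline`` (monotonic interpolation through a
    user-supplied knot table for nonlinear regimes).  Values outside
    ``valid_range`` are corrected by extrapolation with a warning.
    """

    mode: str = "linear"
    slope: float = 1.0
    intercept: float = 0.0
    n_medium: float = 1.33
    n_oil: float = 1.515
    knots: tuple[tuple[float, float], ...] | None = None  # (z_raw, z_true) nm
    valid_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "smallangle", "spline"):
            raise DataError(f"unknown z-correction mode {self.mode!r}")
        if self.mode == "spline":
            if not self.knots or len(self.knots) < 2:
                raise DataError("spline correction requires >= 2 knots")
            kz = np.array([k[0] for k in self.knots])
            kv = np.array([k[1] for k in self.knots])
            if not (np.all(np.diff(kz) > 0) and np.all(np.diff(kv) > 0)):
                raise DataError("spline correction must be monotonic")

    def apply(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lo, hi = self.valid_range
        out_of_range = (z < lo) | (z > hi)
        if np.any(out_of_range & np.isfinite(z)):
            logger.warning(
                "%d z values outside the correction's valid range; extrapolating",
                int(np.count_nonzero(out_of_range & np.isfinite(z))),
            )
        if self.mode == "linear":
            return self.slope * z + self.intercept
        if self.mode == "smallangle":
            return (self.n_medium / self.n_oil) * z
        kz = np.array([k[0] for k in self.knots])
        kv = np.array([k[1] for k in self.knots])
        slope_lo = (kv[1] - kv[0]) / (kz[1] - kz[0])
        slope_hi = (kv[-1] - kv[-2]) / (kz[-1] - kz[-2])
        out = np.interp(z, kz, kv)
        out = np.where(z < kz[0], kv[0] + slope_lo * (z - kz[0]), out)
        out = np.where(z > kz[-1], kv[-1] + slope_hi * (z - kz[-1]), out)
        return out


@dataclass(frozen=True)
class DissociationRecord:
    """Outcome of one bead under one applied force."""

    bead_id: int
    force: float  # pN
    t_dissoc: float | None  # s from force engagement; None if censored
    censored_at: float | None  # s; mutually exclusive with t_dissoc
    max_extension: float  # nm above pre-force baseline
    gate_passed: bool

    def __post_init__(self) -> None:
        if (self.t_dissoc is None) == (self.censored_at is None):
            raise DataError("exactly one of t_dissoc and censored_at must be set")


@dataclass(frozen=True)
class SurvivalFit:
    """Single-exponential survival fit at one force."""

    k_off: float  # 1/s
    half_life: float  # s, ln2 / k_off
    offset: float | None
    r_squared: float
    n_beads: int


@dataclass(frozen=True)
class BellFit:
    """Slip-bond (Bell model) force dependence of the bond half-life."""

    t0: float  # s, zero-force half-life
    x_b: float  # nm, reaction coordinate
    temperature: float  # K
    r_squared: float

    @property
    def kbt(self) -> float:
        return KB_PN_NM_PER_K * self.temperature

    def half_life(self, force: np.ndarray) -> np.ndarray:
        return self.t0 * np.exp(-np.asarray(force, dtype=float) * self.x_b / self.kbt)


@dataclass(frozen=True)
class ForceEstimate:
    """Force from tethered Brownian fluctuations, F = kB T <z> / <dx^2>."""

    force: float  # pN
    mean_extension: float  # nm
    lateral_variance: float  # nm^2
    temperature: float  # K


@dataclass(frozen=True)
class StepTrace:
    """A staircase position trace with known dwell boundaries."""

    positions: np.ndarray  # nm
    step_size: float  # nm
    dwell_frames: int  # frames per dwell

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.step_size <= 0:
            raise DataError("step_size must be > 0")


def link_tracks(
    frame_times: np.ndarray,
    frame_positions: list[list[Position3D]],
    gate_radius: float,
) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame detections into tracks.

    Pairings are assigned in order of increasing 3D distance, within
    ``gate_radius`` (nm); an exact distance tie resolves to the lower bead id
    (logged).  Unmatched detections start new tracks; frames without a match
    are recorded as gaps (``present=False``).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n_frames = len(frame_positions)
    if frame_times.size != n_frames:
        raise DataError("one timestamp per frame required")
    tracks: list[dict] = []  # each: {"last": (x,y,z), "rows": {frame: (x,y,z)}}

    for fi, detections in enumerate(frame_positions):
        coords = np.array([(p.x, p.y, p.z) for p in detections], dtype=float).reshape(
            -1, 3
        )
        active = [tr for tr in tracks if tr["last"] is not None]
        if active and coords.size:
            last = np.array([tr["last"] for tr in active])
            dists = np.linalg.norm(last[:, None, :] - coords[None, :, :], axis=2)
            pairs = sorted(
                (
                    (dists[a, d], active[a]["bead_id"], a, d)
                    for a in range(len(active))
                    for d in range(len(detections))
                ),
            )
            used_tracks: set[int] = set()
            used_dets: set[int] = set()
            for dist, _bead_id, a, d in pairs:
                if dist > gate_radius:
                    break
                if a in used_tracks or d in used_dets:
                    continue
                used_tracks.add(a)
                used_dets.add(d)
                active[a]["rows"][fi] = tuple(coords[d])
                active[a]["last"] = tuple(coords[d])
        else:
            used_dets = set()
        for d in range(len(detections)):
            if d not in used_dets:
                tr = {
                    "bead_id": len(tracks),
                    "last": tuple(coords[d]),
                    "rows": {fi: tuple(coords[d])},
                }
                tracks.append(tr)

    out: list[Track] = []
    for tr in tracks:
        first = min(tr["rows"])
        xs = np.full(n_frames, np.nan)
        ys = np.full(n_frames, np.nan)
        zs = np.full(n_frames, np.nan)
        present = np.zeros(n_frames, dtype=bool)
        for fi, (x, y, z) in tr["rows"].items():
            xs[fi], ys[fi], zs[fi] = x, y, z
            present[fi] = True
        # leading frames before first appearance are not gaps, trim them
        out.append(
            Track(
                bead_id=tr["bead_id"],
                t=frame_times[first:],
                x=xs[first:],
                y=ys[first:],
                z=zs[first:],
                present=present[first:],
                role="tethered",
            )
        )
    return out


def drift_correct(
    tracks: list[Track], reference_ids: list[int]
) -> list[Track]:
    """Subtract the per-frame mean displacement of reference beads.

    Each reference bead's displacement is measured relative to its own first
    frame, so the corrected tracks stay in absolute coordinates.  Frames where
    no reference is present get an interpolated correction and are flagged in
    the log.  Correction is idempotent: re-running it subtracts an (all-zero)
    reference displacement.
    """
    refs = [tr for tr in tracks if tr.bead_id in reference_ids]
    if not refs:
        raise DataError("at least one reference track required")
    all_t = np.unique(np.concatenate([tr.t for tr in tracks]))
    n = all_t.size
    disp = np.zeros((n, 3))
    counts = np.zeros(n)
    for tr in refs:
        idx = np.searchsorted(all_t, tr.t)
        first_present = int(np.argmax(tr.present))
        ref0 = np.array([tr.x[first_present], tr.y[first_present], tr.z[first_present]])
        for axis, arr in enumerate((tr.x, tr.y, tr.z)):
            disp[idx[tr.present], axis] += arr[tr.present] - ref0[axis]
        counts[idx[tr.present]] += 1
    missing = counts == 0
    if np.any(missing):
        logger.warning(
            "no reference bead in %d frames; interpolating drift", int(missing.sum())
        )
    have = ~missing
    if not np.any(have):
        raise DataError("reference beads present in no frame")
    mean_disp = np.empty_like(disp)
    for axis in range(3):
        mean_disp[have, axis] = disp[have, axis] / counts[have]
        mean_disp[missing, axis] = np.interp(
            all_t[missing], all_t[have], mean_disp[have, axis]
        )
    corrected = []
    for tr in tracks:
        new = tr.copy()
        idx = np.searchsorted(all_t, tr.t)
        new.x -= mean_disp[idx, 0]
        new.y -= mean_disp[idx, 1]
        new.z -= mean_disp[idx, 2]
        corrected.append(new)
    return corrected


def apply_z_correction(track: Track, corr: ZCorrection) -> Track:
    """Return a copy of ``track`` with the axial correction applied."""
    new = track.copy()
    new.z = corr.apply(track.z)
    return new


def detect_dissociation(
    track: Track,
    magnet_on: float,
    force: float,
    absence_frames: int = 3,
    gate_nm: float = 1000.0,
    response_window_s: float = 10.0,
    magnet_off: float | None = None,
) -> DissociationRecord:
    """Classify one track into a dissociation record.

    The dissociation time is the first time after ``magnet_on`` (s) at which
    the bead is absent for at least ``absence_frames`` consecutive frames,
    measured from ``magnet_on``; a bead present to the end is censored at the
    last frame.  ``max_extension`` is the maximum z during the force interval
    minus the pre-force baseline z (mean over present frames before
    ``magnet_on``).  The record passes the extension gate if it reached
    ``gate_nm`` within ``response_window_s`` of force engagement — the
    single-tether criterion (a multivalent attachment extends shorter and/or
    responds in steps).
    """
    t = track.t
    if t[-1] < magnet_on:
        raise DataError("track ends before the magnet engages")
    t_end = magnet_off if magnet_off is not None else t[-1]
    pre = (t < magnet_on) & track.present
    baseline = float(np.mean(track.z[pre])) if np.any(pre) else 0.0

    on = (t >= magnet_on) & (t <= t_end)
    on_present = on & track.present
    if np.any(on_present):
        ext = track.z[on_present] - baseline
        max_extension = float(np.max(ext))
        t_on_present = t[on_present]
        responded = np.any(
            (ext >= gate_nm) & (t_on_present <= magnet_on + response_window_s)
        )
    else:
        max_extension = 0.0
        responded = False
    gate_passed = bool(max_extension >= gate_nm and responded)

    # first run of >= absence_frames consecutive absent frames after magnet_on
    idx_on = np.flatnonzero(on)
    absent = ~track.present[idx_on]
    run = 0
    t_dissoc = None
    for j, a in enumerate(absent):
        if a:
            run += 1
            if run == absence_frames:
                start = idx_on[j - absence_frames + 1]
                t_dissoc = float(t[start] - magnet_on)
                break
        else:
            run = 0
    if t_dissoc is not None:
        return DissociationRecord(
            bead_id=track.bead_id,
            force=force,
            t_dissoc=t_dissoc,
            censored_at=None,
            max_extension=max_extension,
            gate_passed=gate_passed,
        )
    return DissociationRecord(
        bead_id=track.bead_id,
        force=force,
        t_dissoc=None,
        censored_at=float(t[-1] - magnet_on),
        max_extension=max_extension,
        gate_passed=gate_passed,
    )


def fit_survival(
    records: list[DissociationRecord],
    with_offset: bool = False,
) -> SurvivalFit:
    """Fit S(t) = (1 - c) exp(-k_off t) + c to the fraction-remaining curve.

    The empirical curve steps down by 1/n at each dissociation time; censored
    records contribute to n (they remain attached), which is what motivates
    the offset term for mixtures with a long-lived subpopulation.  Least
    squares on the step curve, as is conventional for these decay plots;
    ``half_life`` is ln 2 / k_off.
    """
    n = len(records)
    times = sorted(r.t_dissoc for r in records if r.t_dissoc is not None)
    if len(times) < 3:
        raise DataError("at least 3 uncensored records required")
    if np.ptp(times) == 0:
        raise DataError("degenerate data: all dissociation times identical")
    t_pts = np.concatenate([[0.0], times])
    s_pts = np.concatenate([[1.0], 1.0 - (np.arange(len(times)) + 1) / n])

    k0 = 1.0 / np.mean(times)
    if with_offset:
        c0 = max(0.0, float(s_pts[-1]))

        def model(t, k, c):
            return (1.0 - c) * np.exp(-k * t) + c

        popt, _ = curve_fit(
            model, t_pts, s_pts, p0=[k0, c0], bounds=([1e-12, 0.0], [np.inf, 1.0]),
            maxfev=10000,
        )
        k_off, offset = float(popt[0]), float(popt[1])
        fitted = model(t_pts, *popt)
    else:

        def model(t, k):
            return np.exp(-k * t)

        popt, _ = curve_fit(model, t_pts, s_pts, p0=[k0], bounds=(1e-12, np.inf),
                            maxfev=10000)
        k_off, offset = float(popt[0]), None
        fitted = model(t_pts, *popt)
    ss_res = float(np.sum((s_pts - fitted) ** 2))
    ss_tot = float(np.sum((s_pts - s_pts.mean()) ** 2))
    r_sq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SurvivalFit(
        k_off=k_off,
        half_life=float(np.log(2.0) / k_off),
        offset=offset,
        r_squared=r_sq,
        n_beads=n,
    )


def fit_bell(
    half_lives: list[tuple[float, float]],
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> BellFit:
    """Fit the Bell slip-bond model t_F = t0 exp(-F x_b / kB T).

    Least squares in log space: ln t_F is linear in F with slope
    -x_b / (kB T) and intercept ln t0.
    """
    forces = np.array([f for f, _ in half_lives], dtype=float)
    tf = np.array([t for _, t in half_lives], dtype=float)
    if forces.size < 2 or np.unique(forces).size < 2:
        raise DataError("at least 2 distinct forces required")
    if np.any(tf <= 0):
        raise DataError("half-lives must be positive")
    kbt = KB_PN_NM_PER_K * temperature
    slope, intercept = np.polyfit(forces, np.log(tf), 1)
    fitted = intercept + slope * forces
    resid = np.log(tf) - fitted
    ss_tot = float(np.sum((np.log(tf) - np.log(tf).mean()) ** 2))
    r_sq = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return BellFit(
        t0=float(np.exp(intercept)),
        x_b=float(-slope * kbt),
        temperature=temperature,
        r_squared=r_sq,
    )


def force_from_fluctuations(
    z: np.ndarray,
    x: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE_K,
    min_frames: int = 100,
) -> ForceEstimate:
    """Force on a tethered bead from its Brownian motion.

    F = kB T <z> / <dx^2>, with <z> the mean (corrected) extension and <dx^2>
    the variance of the lateral position about its mean, over a segment
    recorded at constant magnet position.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.size < min_frames or x.size < min_frames:
        raise DataError(f"at least {min_frames} frames required")
    mean_ext = float(np.mean(z))
    var_x = float(np.var(x))
    if var_x < 1e-12:
        raise DataError("lateral variance ~ 0: tracking failure, not infinite force")
    force = KB_PN_NM_PER_K * temperature * mean_ext / var_x
    return ForceEstimate(
        force=force,
        mean_extension=mean_ext,
        lateral_variance=var_x,
        temperature=temperature,
    )


def step_snr(trace: StepTrace) -> float:
    """Signal-to-noise ratio of a staircase trace.

    SNR = step size / mean over dwells of the within-dwell standard
    deviation.  A noise-free staircase has zero within-dwell scatter; the SNR
    is then reported as the sentinel ``inf`` (logged).  Invariant to adding a
    constant offset to the trace.
    """
    p = trace.positions
    d = trace.dwell_frames
    if d < 2:
        raise DataError("single-frame dwells have no within-dwell scatter")
    n_dwells = p.size // d
    if n_dwells < 1:
        raise DataError("trace shorter than one dwell")
    stds = [float(np.std(p[i * d : (i + 1) * d], ddof=1)) for i in range(n_dwells)]
    mean_std = float(np.mean(stds))
    if mean_std == 0.0:
        logger.info("noise-free trace: SNR reported as inf")
        return float("inf")
    return trace.step_size / mean_std
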