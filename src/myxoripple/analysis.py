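"""Quantification of emergent ripples and single-cell motility statistics.

Operates on two inputs that both the simulator and (in principle) tracked
microscopy data can provide:

* a :class:`Kymograph` — the space–time matrix of y-averaged 1-D cell
  density, from which wavelength, wave-crest width, ripple order parameter
  and crest-collision regions are estimated (continuous 1-D wavelet
  transform with a Ricker mother wavelet);
* :class:`Trajectory` tables (t, x, y per agent) — from which reversals are
  detected (principal-axis projection with multi-frame confirmation), the
  mean-square displacement is computed, and reversal/crest co-localization
  is measured.

The wavelength–motility relation λ = 2·v·τ + 2·Δ ties the two levels
together: cells in colliding crests travel λ − 2Δ between reversals at
relative speed 2v, so the crest-width-free form λ = 2·v·τ is recovered at
Δ = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, optimize

__all__ = [
    "Kymograph", "Trajectory", "RippleMetrics",
    "WavelengthEstimate", "CrestWidthEstimate", "ReversalDetection",
    "predicted_wavelength", "estimate_wavelength", "estimate_crest_width",
    "order_parameter", "detect_crests", "detect_crests_per_frame",
    "detect_reversals", "principal_axis", "split_directions",
    "collision_mask", "fraction_reversals_in_crest_collisions",
    "compute_msd", "fit_slope_no_intercept", "trajectories_from_table",
]

# Ricker ("mexh") centre frequency in cycles per unit scale; fixed once from
# the analytic wavelet and verified on synthetic sinusoids.
_RICKER_CENTER_FREQ = pywt.central_frequency("mexh")  # = 0.25


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Space–time matrix of 1-D cell density (rows = frames, cols = x-bins)."""

    data: np.ndarray
    bin_width: float       # µm
    frame_interval: float  # min
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (frames × bins)")
        if np.any(self.data < 0):
            raise ValueError("kymograph densities must be non-negative")
        if self.bin_width <= 0 or self.frame_interval <= 0:
            raise ValueError("kymograph grid spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.frame_interval

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def extent_x(self) -> float:
        return self.n_bins * self.bin_width

    def window(self, t_start: float, t_stop: float) -> "Kymograph":
        """Sub-kymograph restricted to t_start ≤ t ≤ t_stop."""
        keep = (self.times >= t_start - 1e-9) & (self.times <= t_stop + 1e-9)
        if not np.any(keep):
            raise ValueError("empty kymograph window")
        first = int(np.argmax(keep))
        return Kymograph(self.data[keep], self.bin_width, self.frame_interval,
                         t0=float(self.times[first]))

    def to_csv(self, path: str | Path) -> None:
        header = (f"# kymograph bin_width_um={self.bin_width:g} "
                  f"frame_interval_min={self.frame_interval:g} t0_min={self.t0:g}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, delimiter=",", fmt="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Kymograph":
        with open(path) as fh:
            header = fh.readline()
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        fields = dict(tok.split("=") for tok in header.strip("#\n ").split()[1:])
        return cls(data, bin_width=float(fields["bin_width_um"]),
                   frame_interval=float(fields["frame_interval_min"]),
                   t0=float(fields.get("t0_min", 0.0)))


@dataclass
class Trajectory:
    """Uniformly sampled single-agent track."""

    id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("trajectory arrays must share a length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("trajectory times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-6 * max(1.0, dt[0])):
                raise ValueError("trajectory must be uniformly sampled without gaps")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else math.nan

    def window(self, t_start: float, t_stop: float) -> "Trajectory":
        keep = (self.t >= t_start - 1e-9) & (self.t <= t_stop + 1e-9)
        return Trajectory(self.id, self.t[keep], self.x[keep], self.y[keep])


def trajectories_from_table(table: pd.DataFrame,
                            ids: Optional[Sequence[int]] = None) -> List[Trajectory]:
    """Split a tidy (t_min, id, x_um, y_um) table into per-agent trajectories.

    Accepts simulator trajectory tables and generic external tracking tables
    with columns named (t|t_min, id, x|x_um, y|y_um).
    """
    cols = {c: c for c in table.columns}
    rename = {}
    for want, alts in (("t_min", ("t", "time", "time_min")),
                       ("x_um", ("x",)), ("y_um", ("y",))):
        if want not in cols:
            for alt in alts:
                if alt in cols:
                    rename[alt] = want
                    break
    if rename:
        table = table.rename(columns=rename)
    out = []
    for aid, grp in table.groupby("id", sort=True):
        if ids is not None and aid not in set(int(i) for i in ids):
            continue
        grp = grp.sort_values("t_min")
        out.append(Trajectory(int(aid), grp.t_min.to_numpy(),
                              grp.x_um.to_numpy(), grp.y_um.to_numpy()))
    return out


@dataclass
class RippleMetrics:
    """Summary of one rippling field."""

    lambda_hat: float       # wavelength, µm
    delta_hat: float        # crest full width at half maximum, µm
    order_param: float
    crest_positions: List[np.ndarray] = field(default_factory=list)
    ripples_present: bool = True


# ---------------------------------------------------------------------------
# wavelength relation (closed form)
# ---------------------------------------------------------------------------

def predicted_wavelength(v: float, tau: float, delta: float = 0.0) -> float:
    """Predicted ripple wavelength λ = 2·v·τ + 2·Δ (µm).

    ``v`` agent speed (µm/min), ``tau`` reversal period (min), ``delta`` wave
    crest width (µm).  With Δ = 0 this is the classic colliding-crest
    relation λ = 2·v·τ; the crest-width term accounts for reversals firing
    as soon as the leading edges of two crests meet, so cells travel only
    λ − 2Δ between reversals.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if v < 0 or delta < 0:
        raise ValueError("v and delta must be >= 0")
    return 2.0 * v * tau + 2.0 * delta


# ---------------------------------------------------------------------------
# wavelet wavelength / order parameter
# ---------------------------------------------------------------------------

def _scale_grid(kym: Kymograph, n_scales: int = 48) -> np.ndarray:
    """Log-spaced CWT scales spanning wavelengths from 4 bins to half the domain."""
    lam_min = 4.0 * kym.bin_width
    lam_max = kym.extent_x / 2.0
    if lam_max <= lam_min:
        lam_max = 2.0 * lam_min
    scales = np.geomspace(lam_min, lam_max, n_scales) * _RICKER_CENTER_FREQ / kym.bin_width
    return scales


def _frame_scale_power(row: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Mean squared CWT coefficient per scale for one mean-subtracted profile."""
    coef, _ = pywt.cwt(row - row.mean(), scales, "mexh")
    return np.mean(coef ** 2, axis=1)


@dataclass
class WavelengthEstimate:
    wavelength: float       # µm (nan when flagged)
    spread: float           # SD across frames, µm
    per_frame: np.ndarray
    ok: bool
    flag: str = ""


def estimate_wavelength(kym: Kymograph, n_scales: int = 48,
                        min_frames: int = 10) -> WavelengthEstimate:
    """Dominant ripple wavelength of a kymograph via the Ricker CWT.

    Per frame, the wavelength is the scale-to-wavelength conversion of the
    power-maximizing CWT scale of the mean-subtracted density profile;
    frames without structure (flat profiles, or a power maximum pinned to
    the scale-grid edge) are skipped.  The estimate is the mean over frames
    and the dispersion across frames is returned as confidence.
    """
    if kym.n_frames < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {kym.n_frames}")
    scales = _scale_grid(kym, n_scales)
    wavelengths = []
    for row in kym.data:
        if row.std() < 1e-12:
            continue
        power = _frame_scale_power(row, scales)
        k = int(np.argmax(power))
        if k == 0 or k == len(scales) - 1:
            continue  # no interior dominant scale
        wavelengths.append(scales[k] * kym.bin_width / _RICKER_CENTER_FREQ)
    wavelengths = np.asarray(wavelengths)
    if len(wavelengths) < max(3, kym.n_frames // 4):
        return WavelengthEstimate(math.nan, math.nan, wavelengths, False,
                                  "no dominant scale")
    return WavelengthEstimate(float(wavelengths.mean()), float(wavelengths.std()),
                              wavelengths, True)


# Complex Morlet for the order parameter: its narrow scale response makes a
# periodic field stand out as a sharp peak over the smooth power background.
_OP_WAVELET = "cmor2.0-1.0"


def order_parameter(kym: Kymograph, n_scales: int = 40,
                    background_window: int = 9,
                    max_frames: int = 60) -> float:
    """Normalized excess wavelet power at the dominant scale, in [0, 1].

    The squared CWT coefficients (complex Morlet) are averaged over bins and
    frames to one power-versus-scale curve; a running median over scales
    (window ≈ one octave) estimates the smooth background, and the order
    parameter is the largest positive excess above that background divided
    by the total power.  Unstructured fields (uniform + counting noise) and
    fields with only broad, scale-free density correlations score near
    zero; a traveling-wave field concentrates power at one scale and scores
    high.  This definition is fixed here and used consistently for all
    bifurcation-threshold statements.
    """
    fc = pywt.central_frequency(_OP_WAVELET)
    lam_min = 4.0 * kym.bin_width
    lam_max = max(kym.extent_x / 2.0, 2 * lam_min)
    scales = np.geomspace(lam_min, lam_max, n_scales) * fc / kym.bin_width
    rows = [row for row in kym.data if row.std() > 1e-12]
    if not rows:
        return 0.0
    if len(rows) > max_frames:
        # consecutive frames are strongly correlated; an evenly spaced
        # subset estimates the mean scale power just as well
        pick = np.linspace(0, len(rows) - 1, max_frames).round().astype(int)
        rows = [rows[i] for i in pick]
    power = np.zeros(n_scales)
    for row in rows:
        coef, _ = pywt.cwt(row - row.mean(), scales, _OP_WAVELET)
        power += np.mean(np.abs(coef) ** 2, axis=1)
    power /= len(rows)
    background = ndimage.median_filter(power, size=background_window,
                                       mode="nearest")
    excess = float(np.max(power - background))
    total = float(power.sum())
    if total <= 0:
        return 0.0
    return float(np.clip(max(excess, 0.0) / total, 0.0, 1.0))


def shuffled_baseline_op(kym: Kymograph, seed: int = 0,
                         n_shuffles: int = 5) -> float:
    """Order parameter of the structure-free counterpart of a kymograph.

    Each frame's bins are randomly permuted (fixed seed), which preserves
    the per-frame counting statistics but destroys all spatial structure —
    the uniform-field baseline against which ripple presence is judged.
    Averaged over ``n_shuffles`` independent permutations, since a single
    shuffle's order parameter is itself a noisy quantity.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    vals = []
    for _ in range(n_shuffles):
        shuffled = np.stack([rng.permutation(row) for row in kym.data])
        vals.append(order_parameter(Kymograph(shuffled, kym.bin_width,
                                              kym.frame_interval, t0=kym.t0)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# crest detection / width
# ---------------------------------------------------------------------------

def detect_crests(profile: np.ndarray, bin_width: float, smooth_bins: float = 2.0,
                  k_sd: float = 1.0, periodic: bool = True) -> np.ndarray:
    """Crest centre positions (µm) of one density profile.

    Local maxima of the Gaussian-smoothed profile exceeding mean + k_sd·SD,
    with sub-bin refinement by parabolic interpolation.
    """
    mode = "wrap" if periodic else "nearest"
    sm = ndimage.gaussian_filter1d(np.asarray(profile, dtype=float), smooth_bins,
                                   mode=mode)
    thr = sm.mean() + k_sd * sm.std()
    n = len(sm)
    if n < 3 or sm.std() < 1e-12:
        return np.array([])
    left = np.roll(sm, 1)
    right = np.roll(sm, -1)
    is_max = (sm >= left) & (sm > right) & (sm > thr)
    if not periodic:
        is_max[0] = is_max[-1] = False
    pos = []
    for k in np.nonzero(is_max)[0]:
        denom = sm[(k - 1) % n] - 2 * sm[k] + sm[(k + 1) % n]
        shift = 0.0 if denom == 0 else 0.5 * (sm[(k - 1) % n] - sm[(k + 1) % n]) / denom
        pos.append(((k + np.clip(shift, -0.5, 0.5)) + 0.5) * bin_width)
    return np.asarray(pos)


def detect_crests_per_frame(kym: Kymograph, **kw) -> List[np.ndarray]:
    return [detect_crests(row, kym.bin_width, **kw) for row in kym.data]


@dataclass
class CrestWidthEstimate:
    width: float          # FWHM, µm (nan when flagged)
    sigma: float          # Gaussian σ of the fit, µm
    n_crests: int
    ok: bool
    flag: str = ""


def estimate_crest_width(kym: Kymograph,
                         crest_positions: Optional[List[np.ndarray]] = None,
                         ) -> CrestWidthEstimate:
    """Wave-crest width from a Gaussian fit to the average aligned crest.

    Windows around each detected crest centre are aligned and averaged over
    all crests and frames; a Gaussian (+ constant baseline) is fitted to the
    mean profile and the width is reported as its full width at half
    maximum.  Fewer than 3 detected crests yields an insufficient-data flag.
    """
    if crest_positions is None:
        crest_positions = detect_crests_per_frame(kym)
    spacings = []
    for pos in crest_positions:
        if len(pos) > 1:
            spacings.extend(np.diff(np.sort(pos)))
    n_crests = int(sum(len(p) for p in crest_positions))
    if n_crests < 3:
        return CrestWidthEstimate(math.nan, math.nan, n_crests, False, "insufficient crests")
    spacing = float(np.median(spacings)) if spacings else kym.extent_x / 2.0
    half_w = max(3, int(round(0.45 * spacing / kym.bin_width)))
    offsets = np.arange(-half_w, half_w + 1)
    acc = np.zeros(len(offsets))
    count = 0
    n = kym.n_bins
    for row, pos in zip(kym.data, crest_positions):
        base = row - row.mean()
        for xc in pos:
            k = int(round(xc / kym.bin_width - 0.5))
            acc += base[(k + offsets) % n]
            count += 1
    mean_crest = acc / max(count, 1)
    xg = offsets * kym.bin_width

    def gauss(x, amp, mu, sig, c):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c

    amp0 = float(mean_crest.max() - mean_crest.min())
    try:
        popt, _ = optimize.curve_fit(
            gauss, xg, mean_crest,
            p0=[amp0, 0.0, max(spacing / 6.0, kym.bin_width), float(mean_crest.min())],
            bounds=([0.0, -half_w * kym.bin_width, kym.bin_width / 4.0, -np.inf],
                    [np.inf, half_w * kym.bin_width, spacing, np.inf]),
            maxfev=5000)
    except RuntimeError:
        return CrestWidthEstimate(math.nan, math.nan, n_crests, False, "fit failed")
    sigma = float(popt[2])
    fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma
    # resolution floor: a single-bin spike cannot be narrower than the grid
    fwhm = max(fwhm, kym.bin_width)
    return CrestWidthEstimate(float(fwhm), sigma, n_crests, True)


def ripple_metrics(kym: Kymograph) -> RippleMetrics:
    """Convenience bundle: wavelength, crest width, order parameter, crests."""
    wl = estimate_wavelength(kym)
    crests = detect_crests_per_frame(kym)
    cw = estimate_crest_width(kym, crests)
    op = order_parameter(kym)
    present = wl.ok and cw.ok and (not math.isnan(wl.wavelength)) \
        and wl.wavelength > 2.0 * (cw.width if cw.ok else 0.0)
    return RippleMetrics(lambda_hat=wl.wavelength, delta_hat=cw.width,
                         order_param=op, crest_positions=crests,
                         ripples_present=bool(present))


# ---------------------------------------------------------------------------
# direction splitting and crest-collision regions
# ---------------------------------------------------------------------------

def split_directions(kym: Kymograph) -> Tuple[np.ndarray, np.ndarray]:
    """Decompose a kymograph into right- and left-moving wave components.

    2-D Fourier quadrant filtering: a plane wave cos(k·x − ω·t) with k, ω of
    the same sign moves toward +x.  Frame means (the k = 0 column) are
    removed; the ω = 0 and k = 0 lines are split evenly between the two
    components.  Returns (rightward, leftward) fields of the kymograph's
    shape.
    """
    data = kym.data - kym.data.mean(axis=1, keepdims=True)
    F = np.fft.fft2(data)
    ft = np.fft.fftfreq(data.shape[0])[:, None]  # time frequencies (rows)
    fx = np.fft.fftfreq(data.shape[1])[None, :]  # spatial frequencies (cols)
    s = np.sign(ft) * np.sign(fx)
    # x − c t propagation ⇒ phase k·x − ω·t: rightward has opposite signs in
    # the (ω, k) convention of fft2's forward transform exp(−2πi(f_t·t + f_x·x))
    right = np.where(s < 0, 1.0, np.where(s == 0, 0.5, 0.0))
    Fr = F * right
    Fl = F * (1.0 - right)
    return np.real(np.fft.ifft2(Fr)), np.real(np.fft.ifft2(Fl))


def collision_mask(kym: Kymograph, delta: float,
                   crest_k_sd: float = 0.5) -> np.ndarray:
    """Boolean (frame × bin) mask of wave-crest collision regions.

    A collision is a frame in which a rightward-moving and a leftward-moving
    crest (from :func:`split_directions`) lie within one crest width
    ``delta`` of each other; the marked interval spans both crests dilated
    by ``delta``/2 on each side and by one frame in time.
    """
    right_f, left_f = split_directions(kym)
    n = kym.n_bins
    L = kym.extent_x
    mask = np.zeros(kym.data.shape, dtype=bool)
    for fi in range(kym.n_frames):
        pr = detect_crests(right_f[fi], kym.bin_width, k_sd=crest_k_sd)
        pl = detect_crests(left_f[fi], kym.bin_width, k_sd=crest_k_sd)
        if len(pr) == 0 or len(pl) == 0:
            continue
        for xr in pr:
            d = np.abs((pl - xr + L / 2.0) % L - L / 2.0)  # periodic distance
            for xl in pl[d <= delta]:
                # periodic interval covering both crests, ± delta/2
                sep = (xl - xr + L / 2.0) % L - L / 2.0
                lo = xr - delta / 2.0 if sep >= 0 else xl - delta / 2.0
                hi = xr + sep + delta / 2.0 if sep >= 0 else xr + delta / 2.0
                b_lo = int(np.floor(lo / kym.bin_width))
                b_hi = int(np.ceil(hi / kym.bin_width))
                mask[fi, np.arange(b_lo, b_hi + 1) % n] = True
    # dilate by one frame in time
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 1), dtype=bool))
    return mask


def fraction_reversals_in_crest_collisions(
        trajs: Optional[List[Trajectory]],
        events: pd.DataFrame,
        kym: Kymograph,
        delta: Optional[float] = None,
        n_boot: int = 200,
        seed: int = 0) -> Tuple[float, float]:
    """Fraction of reversal events inside crest-collision space–time regions.

    ``events`` needs columns (t_min, agent_id, x_um); positions are wrapped
    into the kymograph extent.  The collision regions come from
    :func:`collision_mask` with crest width ``delta`` (estimated from the
    kymograph when omitted).  Returns (fraction, bootstrap s.e. over
    agents).  ``trajs`` is accepted for interface symmetry with external
    data (events can be produced from trajectories by
    :func:`detect_reversals`) and is unused when ``events`` is given.
    """
    del trajs
    if delta is None:
        cw = estimate_crest_width(kym)
        if not cw.ok:
            raise ValueError("no crests detected; cannot build collision regions")
        delta = cw.width
    mask = collision_mask(kym, delta)
    ev = events[(events.t_min >= kym.times[0] - kym.frame_interval / 2)
                & (events.t_min <= kym.times[-1] + kym.frame_interval / 2)]
    if len(ev) == 0:
        raise ValueError("no reversal events inside the kymograph time window")
    fi = np.clip(np.round((ev.t_min.to_numpy() - kym.t0) / kym.frame_interval
                          ).astype(int), 0, kym.n_frames - 1)
    bi = (np.floor(np.mod(ev.x_um.to_numpy(), kym.extent_x) / kym.bin_width)
          .astype(int)) % kym.n_bins
    inside = mask[fi, bi]
    frac = float(inside.mean())
    # bootstrap over agents
    agents = ev.agent_id.to_numpy()
    uniq = np.unique(agents)
    rng = np.random.Generator(np.random.PCG64(seed))
    by_agent = {a: inside[agents == a] for a in uniq}
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        vals = np.concatenate([by_agent[a] for a in pick])
        stats.append(vals.mean())
    return frac, float(np.std(stats))


# ---------------------------------------------------------------------------
# trajectory-level statistics
# ---------------------------------------------------------------------------

def principal_axis(trajs: List[Trajectory]) -> np.ndarray:
    """Dominant movement axis of a set of tracks (pooled, per-track centred PCA)."""
    pts = []
    for tr in trajs:
        pts.append(np.column_stack([tr.x - tr.x.mean(), tr.y - tr.y.mean()]))
    pooled = np.concatenate(pts, axis=0)
    cov = np.cov(pooled.T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, int(np.argmax(w))]
    return axis / np.linalg.norm(axis)


@dataclass
class ReversalDetection:
    times: np.ndarray
    positions: np.ndarray  # (n, 2) x/y at the reversal frame
    indices: np.ndarray    # frame indices
    ok: bool = True
    flag: str = ""


def detect_reversals(traj: Trajectory, k_frames: int = 3, v_min: float = 1.0,
                     axis: Optional[np.ndarray] = None) -> ReversalDetection:
    """Reversal times/positions of one track from principal-axis velocity.

    The displacement is projected onto the movement axis (the track's own
    principal axis unless a pooled one is supplied); a sign change of the
    projected per-frame velocity counts as a reversal only when the new
    direction persists for at least ``k_frames`` frames and the mean speed
    on both legs is at least ``v_min`` — single-frame flickers are ignored.
    """
    if len(traj) < 2 * k_frames:
        return ReversalDetection(np.array([]), np.empty((0, 2)), np.array([], int),
                                 ok=False, flag="trajectory too short")
    if axis is None:
        axis = principal_axis([traj])
    s = (traj.x - traj.x[0]) * axis[0] + (traj.y - traj.y[0]) * axis[1]
    dt = traj.frame_interval
    vel = np.diff(s) / dt
    sign = np.sign(vel)
    sign[sign == 0] = 1.0
    # run-length encode; merge runs shorter than k_frames into their
    # predecessor (flicker suppression), then boundaries are reversals
    runs: List[List[float]] = []  # [sign, length]
    for sg in sign:
        if runs and runs[-1][0] == sg:
            runs[-1][1] += 1
        else:
            runs.append([sg, 1])
    merged: List[List[float]] = []
    for sg, ln in runs:
        if merged and ln < k_frames and sg != merged[-1][0]:
            merged[-1][1] += ln  # flicker absorbed by the ongoing leg
        elif merged and sg == merged[-1][0]:
            merged[-1][1] += ln
        else:
            merged.append([sg, ln])
    # drop a too-short leading run
    if len(merged) > 1 and merged[0][1] < k_frames:
        merged[1][1] += merged[0][1]
        merged = merged[1:]
    times, idxs = [], []
    pos = 0
    for a, b in zip(merged[:-1], merged[1:]):
        pos += int(a[1])
        leg_a = vel[max(0, pos - int(a[1])):pos]
        leg_b = vel[pos:pos + int(b[1])]
        if (len(leg_a) and len(leg_b)
                and np.mean(np.abs(leg_a)) >= v_min
                and np.mean(np.abs(leg_b)) >= v_min):
            idxs.append(pos)
            times.append(traj.t[pos])
    idxs = np.asarray(idxs, dtype=int)
    positions = np.column_stack([traj.x[idxs], traj.y[idxs]]) if len(idxs) \
        else np.empty((0, 2))
    return ReversalDetection(np.asarray(times), positions, idxs)


def compute_msd(trajs: List[Trajectory], max_lag: float,
                overlapping: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """2-D mean-square displacement versus lag, averaged over agents.

    MSD(Δt) = ⟨|r(t+Δt) − r(t)|²⟩ with the average over all sliding time
    origins within each trajectory (or non-overlapping origins when
    ``overlapping`` is False) and then over agents.  MSD(0) = 0 exactly.
    """
    if len(trajs) < 1:
        raise ValueError("need at least one trajectory")
    dt = trajs[0].frame_interval
    n_lags = int(math.floor(max_lag / dt))
    lags = np.arange(n_lags + 1) * dt
    acc = np.zeros(n_lags + 1)
    cnt = np.zeros(n_lags + 1)
    for tr in trajs:
        m = len(tr)
        for k in range(1, min(n_lags, m - 1) + 1):
            if overlapping:
                dx = tr.x[k:] - tr.x[:-k]
                dy = tr.y[k:] - tr.y[:-k]
            else:
                dx = tr.x[k::k] - tr.x[:-k:k]
                dy = tr.y[k::k] - tr.y[:-k:k]
            if len(dx):
                acc[k] += np.mean(dx * dx + dy * dy)
                cnt[k] += 1
    cnt[0] = 1
    msd = np.divide(acc, np.maximum(cnt, 1))
    valid = cnt > 0
    return lags[valid], msd[valid]


def fit_slope_no_intercept(x: Sequence[float], y: Sequence[float]) -> float:
    """Least-squares slope of y on x through the origin: Σxy / Σx²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 matching points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x values are zero")
    return float(np.sum(x * y) / sxx)
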