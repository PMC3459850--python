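"""Synthetic ground-truth inputs for the analysis operations.

Every fixture stores its generating parameters next to the generated object
so tests can assert that the corresponding estimator recovers the truth:
traveling-wave kymographs with known wavelength and crest width, zigzag
trajectories with known reversal times, and Brownian trajectories with a
known diffusion coefficient.  Fixtures use the same containers and CSV
dialects as the simulator output, so the analysis code has exactly one
input path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .analysis import Kymograph, Trajectory
from .params import RandomSource

__all__ = ["FixtureSpec", "make_kymograph_fixture", "make_trajectory_fixture"]

KYMOGRAPH_KINDS = ("sin_kymograph", "gaussian_crest_kymograph", "uniform_kymograph")
TRAJECTORY_KINDS = ("zigzag_trajectory", "brownian_trajectory", "immobile_trajectory")


@dataclass(frozen=True)
class FixtureSpec:
    """Kind + ground-truth parameters + seed of one synthetic input."""

    kind: str
    seed: int = 0
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KYMOGRAPH_KINDS + TRAJECTORY_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _defaults(spec: FixtureSpec, **defaults) -> Dict[str, float]:
    out = dict(defaults)
    out.update(spec.params)
    return out


def make_kymograph_fixture(spec: FixtureSpec) -> Tuple[Kymograph, dict]:
    """Synthetic space–time density field with known structure.

    * ``sin_kymograph`` — two counter-propagating sinusoids of wavelength
      ``lambda_um`` moving at ``speed`` (µm/min) on a mean level
      ``baseline``; optional Gaussian noise (``noise_sd``) or Poisson
      sampling (``poisson=1``).
    * ``gaussian_crest_kymograph`` — counter-propagating trains of Gaussian
      crests with spacing ``lambda_um`` and FWHM ``delta_um``; ground truth
      includes the crest tracks and the closed-form collision times
      (right/left crest coincidences).
    * ``uniform_kymograph`` — structureless field (optionally noisy).
    """
    p = _defaults(spec, lambda_um=60.0, delta_um=12.0, speed=6.0, amplitude=1.0,
                  baseline=4.0, noise_sd=0.0, poisson=0.0, domain_x=480.0,
                  bin_width=2.0, duration=120.0, frame_interval=1.0)
    if p["lambda_um"] < 2.0 * p["bin_width"]:
        raise ValueError("lambda_um must be at least two bin widths")
    rng = RandomSource(spec.seed)
    nb = int(round(p["domain_x"] / p["bin_width"]))
    nf = int(round(p["duration"] / p["frame_interval"])) + 1
    x = (np.arange(nb) + 0.5) * p["bin_width"]
    t = np.arange(nf) * p["frame_interval"]
    X, T = np.meshgrid(x, t)
    truth: dict = {k: p[k] for k in ("lambda_um", "delta_um", "speed", "baseline")}

    if spec.kind == "sin_kymograph":
        k_wave = 2.0 * np.pi / p["lambda_um"]
        data = (p["baseline"]
                + p["amplitude"] * np.cos(k_wave * (X - p["speed"] * T))
                + p["amplitude"] * np.cos(k_wave * (X + p["speed"] * T)))
        if p["amplitude"] == 0.0:
            truth["flat"] = True
    elif spec.kind == "gaussian_crest_kymograph":
        sigma = p["delta_um"] / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        lam = p["lambda_um"]
        data = np.full_like(X, p["baseline"])
        phases_r = np.mod(X - p["speed"] * T, lam)
        phases_l = np.mod(X + p["speed"] * T, lam)
        for ph in (phases_r, phases_l):
            d = np.minimum(ph, lam - ph)  # distance to nearest crest centre
            data = data + p["amplitude"] * np.exp(-0.5 * (d / sigma) ** 2)
        # closed-form crest tracks and collision loci: right crests at
        # x = m·λ + v t, left crests at x = n·λ − v t; coincidences at
        # t = (m' λ)/(2 v), every λ/(2 v) minutes, λ/2 apart in x.
        truth["crest_tracks_right"] = [
            {"x0": m * lam, "speed": p["speed"]} for m in range(int(p["domain_x"] // lam))]
        truth["crest_tracks_left"] = [
            {"x0": n * lam, "speed": -p["speed"]} for n in range(int(p["domain_x"] // lam))]
        if p["speed"] > 0:
            truth["collision_period_min"] = lam / (2.0 * p["speed"])
            truth["collision_spacing_um"] = lam / 2.0
    else:  # uniform_kymograph
        data = np.full_like(X, p["baseline"])
        truth["flat"] = True

    if p["noise_sd"] > 0:
        data = data + rng.normal(size=data.shape, scale=p["noise_sd"])
    if p["poisson"]:
        data = rng.generator.poisson(np.maximum(data, 0.0)).astype(float)
    data = np.maximum(data, 0.0)
    kym = Kymograph(data=data, bin_width=p["bin_width"],
                    frame_interval=p["frame_interval"])
    return kym, truth


def make_trajectory_fixture(spec: FixtureSpec) -> Tuple[List[Trajectory], dict]:
    """Synthetic trajectories with known reversal times / diffusion.

    * ``zigzag_trajectory`` — back-and-forth runs of duration ``tau`` at
      speed ``v`` along x (optionally tilted by ``angle``), positional noise
      ``noise_sd`` per frame per axis; truth lists exact reversal times.
    * ``brownian_trajectory`` — 2-D random walks with diffusion coefficient
      ``D`` (per-axis step variance 2·D·Δt); MSD slope is 4·D.
    * ``immobile_trajectory`` — stationary points (+ optional noise).
    """
    p = _defaults(spec, n=10, v=6.0, tau=6.6, D=10.0, duration=120.0,
                  frame_interval=1.0, noise_sd=0.0, angle=0.0)
    rng = RandomSource(spec.seed)
    nf = int(round(p["duration"] / p["frame_interval"])) + 1
    t = np.arange(nf) * p["frame_interval"]
    trajs: List[Trajectory] = []
    truth: dict = {k: p[k] for k in ("v", "tau", "D")}

    if spec.kind == "zigzag_trajectory":
        # runs start half a period in so the first reversal is interior
        rev_times = np.arange(p["tau"] / 2.0, p["duration"], p["tau"])
        truth["reversal_times"] = {}
        ca, sa = math.cos(p["angle"]), math.sin(p["angle"])
        # piecewise-linear position with kinks exactly at the reversal times
        knots = np.concatenate([[0.0], rev_times, [p["duration"]]])
        seg_dir = np.where(np.arange(len(knots) - 1) % 2 == 0, 1.0, -1.0)
        s_knots = np.concatenate([[0.0],
                                  np.cumsum(seg_dir * p["v"] * np.diff(knots))])
        for i in range(int(p["n"])):
            sgn = 1.0 if i % 2 == 0 else -1.0
            s = sgn * np.interp(t, knots, s_knots)
            x0, y0 = rng.uniform(0, 100, size=2)
            x = x0 + s * ca
            y = y0 + s * sa
            if p["noise_sd"] > 0:
                x = x + rng.normal(size=nf, scale=p["noise_sd"])
                y = y + rng.normal(size=nf, scale=p["noise_sd"])
            trajs.append(Trajectory(i, t, x, y))
            truth["reversal_times"][i] = rev_times.copy()
    elif spec.kind == "brownian_trajectory":
        step_sd = math.sqrt(2.0 * p["D"] * p["frame_interval"])
        for i in range(int(p["n"])):
            dx = rng.normal(size=nf - 1, scale=step_sd)
            dy = rng.normal(size=nf - 1, scale=step_sd)
            trajs.append(Trajectory(i, t,
                                    np.concatenate([[0.0], np.cumsum(dx)]),
                                    np.concatenate([[0.0], np.cumsum(dy)])))
        truth["msd_slope"] = 4.0 * p["D"]
    else:  # immobile
        for i in range(int(p["n"])):
            x0, y0 = rng.uniform(0, 100, size=2)
            x = np.full(nf, x0)
            y = np.full(nf, y0)
            if p["noise_sd"] > 0:
                x = x + rng.normal(size=nf, scale=p["noise_sd"])
                y = y + rng.normal(size=nf, scale=p["noise_sd"])
            trajs.append(Trajectory(i, t, x, y))
        truth["msd_slope"] = 0.0
    return trajs, truth
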