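"""Synthetic inputs: tracer-bead movies, fibrous textures, observation tables.

These generators stand in for the microscopy data the analyses were designed
for.  Bead movies emulate fluorescent microsphere tracers advected by a
model displacement field (advection is applied analytically, so any PIV
error is attributable to PIV alone); fibre images emulate isotropic or
aligned actin textures; observation tables emulate noisy contraction-ratio
and boundary-trajectory measurements generated from the package's own
models at the reference parameter values (P = 0.11, K_inf = 0.15, K = 0.23,
tau_c = 12 min, gamma = 0.4).

All generators are deterministic under a fixed seed and emit a manifest of
their generating parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from skimage.draw import line_aa

from .dynamics import ContractionCurve, RectangleDynamics, PAPER_PRESET
from .stimulation import K_of_n

__all__ = [
    "SyntheticScene", "FibreTextureSpec",
    "render_bead_movie", "render_fibre_image", "synth_observation_tables",
    "radial_contraction_field", "penetrating_contraction_field",
]

#: average tracer count per 10 um x 10 um interrogation window
_BEADS_PER_WINDOW = 98.0


@dataclass
class SyntheticScene:
    """Rendering recipe for a tracer-bead movie.

    The default bead density puts ~98 beads in a 10 um x 10 um window at
    the default 1 um/px pixel size, matching the tracer loading the PIV
    stage expects.
    """

    size: tuple[int, int] = (256, 256)        # (height, width) px
    pixel_size: float = 1.0                   # um / px
    bead_density: float = _BEADS_PER_WINDOW / 100.0   # beads / um^2
    psf_sigma: float = 1.0                    # px
    bead_amplitude: float = 150.0
    noise_sigma: float = 2.0                  # additive Gaussian, counts
    poisson: bool = False
    seed: int = 0

    def n_beads(self) -> int:
        h, w = self.size
        area_um2 = h * w * self.pixel_size ** 2
        return int(round(self.bead_density * area_um2))


@dataclass
class FibreTextureSpec:
    """Recipe for a synthetic fibrous texture.

    ``kappa = 0`` gives orientations uniform on [0, 180) (isotropic);
    larger concentrations align fibres around ``mu_deg``.  Orientations are
    axial, so the von Mises law is applied on the doubled angle.
    """

    size: tuple[int, int] = (512, 512)
    n_fibres: int = 5000
    length: float = 40.0                      # px
    intensity: float = 100.0
    orientation_law: str = "uniform"          # "uniform" | "von_mises"
    mu_deg: float = 90.0
    kappa: float = 8.0
    noise_sigma: float = 0.0
    seed: int = 0


def radial_contraction_field(center: tuple[float, float], radius: float,
                             curve: ContractionCurve) -> Callable:
    """Displacement field of a shape-preserving contracting disk.

    Inside the disk the radius scales with the contraction curve,
    ``r(t) = r0 * C(t)/C_init``; outside, the displacement continues the
    boundary value with a 1/r decay (the far field of a 2D contraction).
    Returns ``field(x, y, t) -> (dx, dy)`` giving displacement from t = 0.
    """
    cx, cy = center

    def field(x, y, t):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        scale = curve.evaluate(t) / curve.L_init
        rx, ry = x - cx, y - cy
        r = np.hypot(rx, ry)
        inside = r <= radius
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(inside, scale - 1.0,
                           (scale - 1.0) * radius ** 2 / np.maximum(r, 1e-12) ** 2)
        amp = np.where(r == 0, 0.0, amp)
        return amp * rx, amp * ry

    return field


def penetrating_contraction_field(center: tuple[float, float], radius: float,
                                  curve: ContractionCurve,
                                  front_speed: Optional[float] = None) -> Callable:
    """Contracting disk whose interior joins the contraction with a delay.

    The ability to contract penetrates inward from the active/passive
    interface: a material point at initial radius ``r0`` starts moving only
    once the front (speed ``front_speed``, default ``radius / tau``) has
    covered its distance to the boundary, then follows the normalized
    contraction profile.  Early on the local strain rate is therefore high
    near the boundary and near zero at the centre, while the final state is
    the same uniform scaling by K as :func:`radial_contraction_field`.

    Returns ``field(x, y, t) -> (dx, dy)``; the field is zero outside the
    disk (the passive surround is not modelled here).
    """
    cx, cy = center
    speed = radius / curve.tau if front_speed is None else front_speed

    def profile(t):
        # normalized contraction progress: 0 at t<=0, -> 1 as t -> inf
        t = np.clip(t, 0.0, None)
        s = t / curve.tau
        return 1.0 - (1.0 + s) * np.exp(-s)

    def field(x, y, t):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rx, ry = x - cx, y - cy
        r = np.hypot(rx, ry)
        inside = r <= radius
        delay = (radius - r) / speed
        amp = -(1.0 - curve.K) * profile(t - delay) * inside
        return amp * rx, amp * ry

    return field


def _render_beads(shape: tuple[int, int], pos: np.ndarray, sigma: float,
                  amplitude: float) -> np.ndarray:
    """Render Gaussian spots at sub-pixel positions (x, y) in pixel units."""
    h, w = shape
    img = np.zeros(h * w)
    rad = max(1, int(math.ceil(4 * sigma)))
    span = np.arange(-rad, rad + 1)
    ix = np.round(pos[:, 0]).astype(int)
    iy = np.round(pos[:, 1]).astype(int)
    keep = (ix >= -rad) & (ix < w + rad) & (iy >= -rad) & (iy < h + rad)
    pos, ix, iy = pos[keep], ix[keep], iy[keep]
    gx = ix[:, None] + span[None, :]               # (n, k) sample columns
    gy = iy[:, None] + span[None, :]
    ex = np.exp(-0.5 * ((gx - pos[:, 0:1]) / sigma) ** 2)
    ey = np.exp(-0.5 * ((gy - pos[:, 1:2]) / sigma) ** 2)
    patch = amplitude * ey[:, :, None] * ex[:, None, :]    # (n, k, k)
    ok = (gx[:, None, :] >= 0) & (gx[:, None, :] < w) & \
         (gy[:, :, None] >= 0) & (gy[:, :, None] < h)
    flat = (gy[:, :, None] * w + gx[:, None, :])
    np.add.at(img, flat[ok], patch[ok])
    return img.reshape(h, w)


def render_bead_movie(scene: SyntheticScene, field: Callable,
                      frame_times: Sequence[float]):
    """Render a tracer-bead movie advected by a displacement field.

    Beads are placed uniformly at t = 0 and advected exactly by
    ``field(x, y, t)`` (positions in um, displacement in um); frames are the
    rendered Gaussian spots plus the scene's noise.  Returns
    ``(stack, truth)`` where ``stack`` is (n_frames, H, W) float and
    ``truth`` records the exact bead positions per frame (in px) plus the
    count of beads clipped outside the frame.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.size
    n = scene.n_beads()
    xy0 = rng.uniform([0, 0], [w * scene.pixel_size, h * scene.pixel_size],
                      size=(n, 2))
    frames = []
    truth = {"frame_times": list(frame_times), "positions_px": [],
             "clipped": [], "n_beads": n}
    for t in frame_times:
        dx, dy = field(xy0[:, 0], xy0[:, 1], t)
        pos_um = xy0 + np.column_stack([dx, dy])
        pos_px = pos_um / scene.pixel_size
        out = ((pos_px[:, 0] < 0) | (pos_px[:, 0] >= w)
               | (pos_px[:, 1] < 0) | (pos_px[:, 1] >= h))
        img = _render_beads((h, w), pos_px, scene.psf_sigma, scene.bead_amplitude)
        if scene.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
        frames.append(img)
        truth["positions_px"].append(pos_px)
        truth["clipped"].append(int(out.sum()))
    return np.stack(frames), truth


def _sample_orientations(spec: FibreTextureSpec, rng) -> np.ndarray:
    """Fibre orientations in degrees on [0, 180)."""
    if spec.orientation_law == "uniform" or spec.kappa == 0:
        return rng.uniform(0.0, 180.0, size=spec.n_fibres)
    if spec.orientation_law == "von_mises":
        # axial data: von Mises on the doubled angle, halved back
        doubled = rng.vonmises(math.radians(2 * spec.mu_deg), spec.kappa,
                               size=spec.n_fibres)
        return (np.degrees(doubled) / 2.0) % 180.0
    raise ValueError(f"unknown orientation law {spec.orientation_law!r}")


def render_fibre_image(spec: FibreTextureSpec) -> np.ndarray:
    """Render anti-aliased fibre segments on a dark background.

    Segment orientation follows the spec's law in the image's (x right,
    y down) pixel coordinates, with angles measured from the +x axis toward
    +y rows — the same convention :func:`orientation_distribution` reports.
    """
    if spec.n_fibres == 0:
        warnings.warn("zero fibres requested; returning blank image",
                      stacklevel=2)
        return np.zeros(spec.size)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.zeros((h, w))
    theta = np.radians(_sample_orientations(spec, rng))
    cx = rng.uniform(0, w, size=spec.n_fibres)
    cy = rng.uniform(0, h, size=spec.n_fibres)
    half = spec.length / 2.0
    x0 = cx - half * np.cos(theta)
    x1 = cx + half * np.cos(theta)
    y0 = cy - half * np.sin(theta)
    y1 = cy + half * np.sin(theta)
    for a, b, c, d in zip(y0, x0, y1, x1):
        rr, cc, val = line_aa(int(round(a)), int(round(b)),
                              int(round(c)), int(round(d)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] += spec.intensity * val[keep]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return img


def synth_observation_tables(
    out_dir=None, *,
    P: float = 0.11, K_inf: float = 0.15,
    K: float = PAPER_PRESET["K"], tau_c: float = PAPER_PRESET["tau_c"],
    gamma: float = PAPER_PRESET["gamma"],
    C_init: float = 388.0,                      # um, reference circle radius
    alpha_init: float = 2.0, area: float = 10_000.0,   # um^2, rectangle
    n_values: Sequence[int] = (0, 1, 2, 5, 10, 20, 40, 80, 160),
    time_grid: Optional[np.ndarray] = None,     # min
    ratio_noise: float = 0.02,                  # multiplicative, on K(n)
    length_noise_frac: float = 0.01,            # additive, x L_init
    seed: int = 0,
):
    """Generate noisy synthetic observation tables from the model curves.

    Produces three tables: contraction ratios versus stimulation cycles
    (multiplicative Gaussian noise), a circle-radius trajectory C(t), and a
    rectangle two-axis trajectory (X(t), Y(t)) (additive Gaussian noise),
    together with a manifest of the generating parameters.  Returns
    ``(tables, manifest)``; when ``out_dir`` is given the tables are also
    written as CSV plus ``manifest.json``.
    """
    rng = np.random.default_rng(seed)
    if time_grid is None:
        time_grid = np.arange(0.0, 90.1, 1.5)   # 90 min at the 90 s cadence
    t = np.asarray(time_grid, dtype=float)

    n_arr = np.asarray(list(n_values), dtype=int)
    ratio = K_of_n(n_arr, P, K_inf)
    if ratio_noise > 0:
        ratio = ratio * (1.0 + rng.normal(0.0, ratio_noise, size=ratio.shape))
    stim = pd.DataFrame({"n": n_arr, "ratio": np.clip(ratio, 1e-6, 1.0)})

    circle = ContractionCurve(L_init=C_init, K=K, tau=tau_c)
    L = circle.evaluate(t)
    if length_noise_frac > 0:
        L = L + rng.normal(0.0, length_noise_frac * C_init, size=L.shape)
    traj = pd.DataFrame({"t_min": t, "L_um": L})

    Y0 = math.sqrt(area / alpha_init)
    dyn = RectangleDynamics(X_init=alpha_init * Y0, Y_init=Y0, K=K,
                            tau_c=tau_c, gamma=gamma)
    X, Y, _ = dyn.curves(t)
    if length_noise_frac > 0:
        X = X + rng.normal(0.0, length_noise_frac * dyn.X_init, size=X.shape)
        Y = Y + rng.normal(0.0, length_noise_frac * dyn.Y_init, size=Y.shape)
    rect = pd.DataFrame({"t_min": t, "X_um": X, "Y_um": Y})

    manifest = {
        "P": P, "K_inf": K_inf, "K": K, "tau_c_min": tau_c, "gamma": gamma,
        "C_init_um": C_init, "alpha_init": alpha_init, "area_um2": area,
        "ratio_noise": ratio_noise, "length_noise_frac": length_noise_frac,
        "seed": seed, "n_values": [int(v) for v in n_arr],
    }
    tables = {"stimulation": stim, "circle_trajectory": traj,
              "rectangle_trajectory": rect}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stim.to_csv(out / "stimulation.csv", index=False)
        traj.to_csv(out / "circle_trajectory.csv", index=False)
        rect.to_csv(out / "rectangle_trajectory.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables, manifest
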