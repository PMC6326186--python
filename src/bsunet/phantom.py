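"""Seeded sagittal-spine phantoms with intervertebral-disc labels.

Each phantom is a vertical stack of elliptical "discs" interleaved with
brighter rectangular vertebral-body surrogates on a darker soft-tissue
background.  The generator reproduces the three properties that make real
disc segmentation hard:

1. *deformed, rotated shapes* — each ellipse is rotated and its radius is
   perturbed by a smooth low-order Fourier series (harmonics 2-4);
2. *low boundary contrast* — the disc/background intensity step is a
   controllable fraction, and can be made arbitrarily small;
3. *non-uniform intensity inside objects* — a smooth multiplicative bias
   field (the MR coil-shading surrogate) plus additive Gaussian noise.

Corruptions touch the image only; the label mask depends purely on
geometry.  Intensities are clipped to [0, 1] last.

Patients own 1-3 slices that share the same disc geometry (adjacent
mid-sagittal slices of one spine) but are corrupted independently, which is
what makes patient-exclusive cross-validation meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError, GeometryError
from .image import ImageSlice

__all__ = ["PhantomParams", "Patient", "PhantomCohort", "generate_phantom",
           "generate_cohort", "default_params", "small_params"]


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters; defaults emulate a 256x256 mid-sagittal
    acquisition at 1.5 mm pixels with five lumbar discs."""
    image_size: int = 256
    n_discs: int = 5
    disc_axes_px: tuple = ((26.0, 36.0), (7.0, 11.0))  # (semi-major, semi-minor) ranges
    rotation_deg: tuple = (-15.0, 15.0)
    deformation_amp: float = 0.12
    boundary_contrast: float = 0.35
    bias_field_amp: float = 0.25
    noise_sd: float = 0.04
    spacing_mm: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_discs < 1:
            raise ConfigError("n_discs must be >= 1")
        if not (0.0 <= self.boundary_contrast <= 1.0):
            raise ConfigError("boundary_contrast must lie in [0, 1]")
        if not (0.0 <= self.deformation_amp <= 0.5):
            raise ConfigError("deformation_amp must lie in [0, 0.5]")
        if self.noise_sd < 0 or self.bias_field_amp < 0:
            raise ConfigError("noise_sd and bias_field_amp must be >= 0")


def default_params(**overrides) -> PhantomParams:
    return PhantomParams(**overrides)


def small_params(**overrides) -> PhantomParams:
    """64x64 preset for CPU-scale training; geometry scaled by 1/4."""
    kw = dict(image_size=64,
              disc_axes_px=((7.0, 9.5), (2.4, 3.2)),
              n_discs=4)
    kw.update(overrides)
    return PhantomParams(**kw)


_BACKGROUND = 0.30
_BODY = 0.62
_CONTRAST_SCALE = 0.55  # disc-background step at boundary_contrast = 1


def _draw_geometry(params: PhantomParams, rng: np.random.Generator) -> dict:
    """Disc and vertebral-body geometry for one patient."""
    s = params.image_size
    n = params.n_discs
    pitch = s / (n + 1.0)
    (a_lo, a_hi), (b_lo, b_hi) = params.disc_axes_px
    discs = []
    for i in range(n):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        rot = np.deg2rad(rng.uniform(*params.rotation_deg))
        cy = pitch * (i + 1) + rng.uniform(-0.05, 0.05) * pitch
        cx = s / 2.0 + rng.uniform(-0.04, 0.04) * s
        n_harm = rng.integers(2, 5)  # harmonics 2..4, count 2-3
        harmonics = rng.choice([2, 3, 4], size=min(n_harm, 3), replace=False)
        weights = rng.dirichlet(np.ones(len(harmonics))) * params.deformation_amp
        phases = rng.uniform(0, 2 * np.pi, size=len(harmonics))
        discs.append(dict(cx=cx, cy=cy, a=a, b=b, rot=rot,
                          harmonics=harmonics, weights=weights, phases=phases))
    # reject geometries that leave the frame or collide
    margin = 2.0
    prev_bottom = -np.inf
    for d in discs:
        grow = 1.0 + params.deformation_amp
        hext = (abs(d["a"] * np.cos(d["rot"])) + abs(d["b"] * np.sin(d["rot"]))) * grow
        vext = (abs(d["a"] * np.sin(d["rot"])) + abs(d["b"] * np.cos(d["rot"]))) * grow
        if (d["cx"] - hext < margin or d["cx"] + hext > s - margin
                or d["cy"] - vext < margin or d["cy"] + vext > s - margin):
            raise GeometryError("disc does not fit inside the image frame")
        if d["cy"] - vext <= prev_bottom:
            raise GeometryError("adjacent discs overlap")
        prev_bottom = d["cy"] + vext
    bodies = []
    for i in range(n + 1):
        cy = pitch * (i + 0.5)
        half_h = 0.28 * pitch
        half_w = 0.85 * (a_lo + a_hi) / 2.0
        bodies.append(dict(cx=s / 2.0, cy=cy, half_w=half_w, half_h=half_h))
    return dict(discs=discs, bodies=bodies)


def _disc_mask(geom: dict, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    mask = np.zeros((size, size), bool)
    for d in geom["discs"]:
        u = np.cos(d["rot"]) * (xx - d["cx"]) + np.sin(d["rot"]) * (yy - d["cy"])
        v = -np.sin(d["rot"]) * (xx - d["cx"]) + np.cos(d["rot"]) * (yy - d["cy"])
        rho = np.hypot(u / d["a"], v / d["b"])
        phi = np.arctan2(v / d["b"], u / d["a"])
        r = np.ones_like(phi)
        for h, w, p in zip(d["harmonics"], d["weights"], d["phases"]):
            r += w * np.cos(h * phi + p)
        mask |= rho <= r
    return mask


def _body_mask(geom: dict, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    mask = np.zeros((size, size), bool)
    for b in geom["bodies"]:
        mask |= ((np.abs(xx - b["cx"]) <= b["half_w"])
                 & (np.abs(yy - b["cy"]) <= b["half_h"]))
    return mask


def _render(params: PhantomParams, geom: dict,
            rng: np.random.Generator) -> tuple[ImageSlice, np.ndarray]:
    s = params.image_size
    disc = _disc_mask(geom, s)
    body = _body_mask(geom, s) & ~disc
    img = np.full((s, s), _BACKGROUND, np.float64)
    img[body] = _BODY
    img[disc] = _BACKGROUND + _CONTRAST_SCALE * params.boundary_contrast
    if params.bias_field_amp > 0:
        fx = rng.uniform(0.5, 1.5)
        fy = rng.uniform(0.5, 1.5)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        yy, xx = np.mgrid[0:s, 0:s] / float(s)
        bias = np.cos(np.pi * fx * xx + px) * np.cos(np.pi * fy * yy + py)
        img *= 1.0 + params.bias_field_amp * bias
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return ImageSlice(img, params.spacing_mm), disc.astype(np.uint8)


def generate_phantom(params: PhantomParams,
                     corruption_rng: Optional[np.random.Generator] = None
                     ) -> tuple[ImageSlice, np.ndarray]:
    """One (image, mask) pair; bit-identical for identical params.

    ``corruption_rng`` lets cohort generation re-corrupt the same patient
    geometry independently per slice; by default geometry and corruption
    both derive from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    geom = _draw_geometry(params, rng)
    return _render(params, geom, corruption_rng or rng)


@dataclass
class Patient:
    patient_id: str
    params: PhantomParams
    slices: list  # of (ImageSlice, mask) pairs

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class PhantomCohort:
    patients: list

    @property
    def n_slices(self) -> int:
        return sum(p.n_slices for p in self.patients)

    def cases(self):
        """Flat iterator of (patient_id, case_id, image, mask)."""
        for p in self.patients:
            for j, (img, mask) in enumerate(p.slices):
                yield p.patient_id, f"{p.patient_id}_s{j}", img, mask


def generate_cohort(n_patients: int, params: PhantomParams, seed: int,
                    total_slices: Optional[int] = None) -> PhantomCohort:
    """Seeded cohort; each patient owns 1-3 slices of shared geometry.

    When ``total_slices`` is given (e.g. 25 slices over 20 patients), extra
    slices beyond one per patient are distributed to seeded-random distinct
    patients; otherwise counts are drawn iid from {1, 2, 3}.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    master = np.random.SeedSequence(seed)
    patient_seeds = master.spawn(n_patients)
    count_rng = np.random.default_rng(master.spawn(1)[0])
    if total_slices is None:
        counts = count_rng.integers(1, 4, size=n_patients)
    else:
        if not (n_patients <= total_slices <= 3 * n_patients):
            raise ConfigError("total_slices must lie in [n_patients, 3*n_patients]")
        counts = np.ones(n_patients, int)
        extras = total_slices - n_patients
        while extras > 0:
            take = min(extras, n_patients)
            chosen = count_rng.choice(np.flatnonzero(counts < 3),
                                      size=take, replace=False)
            counts[chosen] += 1
            extras -= take
    patients = []
    for i, ss in enumerate(patient_seeds):
        geom_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        p_params = replace(params, seed=geom_seed)
        rng = np.random.default_rng(geom_seed)
        geom = _draw_geometry(p_params, rng)
        slice_rngs = [np.random.default_rng(c) for c in ss.spawn(int(counts[i]))]
        slices = [_render(p_params, geom, r) for r in slice_rngs]
        patients.append(Patient(f"p{i:03d}", p_params, slices))
    return PhantomCohort(patients)
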