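"""Synthetic islet phantoms, perifusion traces, and qPCR fixtures.

No raw donor images or traces are publicly deposited for this kind of
study, so every analysis stage is exercised against synthetic data whose
ground truth is known by construction:

* **Image phantoms** — nuclear-stained islets emulated as elliptical
  intensity objects in a z-stack, brightest at mid-depth with a parabolic
  intensity falloff toward the top and bottom planes, plus small bright
  debris specks and additive Gaussian noise.  The generator refuses
  overlapping objects so each object's analytic ellipse area and axes are
  unambiguous ground truth.
* **Secretion traces** — a biphasic glucose-stimulated insulin secretion
  model sampled on the perifusion fraction grid.  Inside the stimulus
  window starting at t0::

      S(t) = basal * [1 + a1*(1 - exp(-(t-t0)/tau_rise))*exp(-(t-t0)/tau_decay)
                        + a2*sigma(t)]

  and S(t) = basal outside, where sigma ramps linearly 0 -> 1 across the
  stimulus window.  The transient term is the first phase, the ramp term
  the second phase; noise is multiplicative log-normal with unit mean.
  Ground-truth SI values are the noiseless model averaged over the same
  fraction windows the analysis uses.
* **qPCR fixtures** — Ct tables in which target Ct = reference Ct + a base
  offset - log2(fold), so injected group fold-changes are recoverable
  exactly at zero noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import morphology

from .morphometry import ImageStack
from .perifusion import (
    FIRST_PHASE_WINDOW,
    SECOND_PHASE_WINDOW,
    PerifusionTrace,
    RampSchedule,
    SamplingGrid,
)

__all__ = [
    "PhantomObject",
    "PhantomSpec",
    "PhantomGroundTruth",
    "SecretionSimSpec",
    "SecretionGroundTruth",
    "GLUCOSE_PRESETS",
    "generate_phantom_stack",
    "secretion_model",
    "simulate_perifusion_trace",
    "generate_qpcr_fixture",
]


# ---------------------------------------------------------------------------
# Image phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomObject:
    """One elliptical islet phantom: center (x, y) in pixels, axes in um."""

    center_xy: Tuple[float, float]
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float = 0.0
    peak_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise ValueError("need major_axis_um >= minor_axis_um > 0")
        if self.peak_intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise settings for one phantom stack."""

    image_shape: Tuple[int, int, int] = (9, 512, 512)  # (z, y, x)
    pixel_size_um: float = 1.0
    z_step_um: float = 10.0
    objects: Tuple[PhantomObject, ...] = ()
    n_debris: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.image_shape) or len(self.image_shape) != 3:
            raise ValueError("image_shape must be three positive voxel counts")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.noise_sd < 0 or self.n_debris < 0:
            raise ValueError("noise_sd and n_debris must be >= 0")
        object.__setattr__(self, "objects", tuple(self.objects))


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic geometry of each generated object (mm units)."""

    areas_mm2: Tuple[float, ...]
    major_axes_mm: Tuple[float, ...]
    minor_axes_mm: Tuple[float, ...]


def _ellipse_mask(shape_yx, obj: PhantomObject, pixel_size_um: float) -> np.ndarray:
    cy, cx = obj.center_xy[1], obj.center_xy[0]
    ra = obj.major_axis_um / 2.0 / pixel_size_um  # semi-axes in px
    rb = obj.minor_axis_um / 2.0 / pixel_size_um
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(obj.orientation_rad), np.sin(obj.orientation_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / ra) ** 2 + (v / rb) ** 2 <= 1.0


def generate_phantom_stack(spec: PhantomSpec) -> Tuple[ImageStack, PhantomGroundTruth]:
    """Render a phantom z-stack and its analytic ground truth.

    Each object keeps a constant elliptical footprint through z while its
    intensity follows a parabolic falloff, maximal at mid-depth — so the
    maximum-intensity projection equals the mid-plane and recovers the
    full footprint.  Debris specks (3-5 px) are placed clear of the
    objects; Gaussian noise is added last and intensities clipped at 0.

    Raises if objects overlap or extend past the image border: either
    would make the per-object ground truth ambiguous.
    """
    nz, ny, nx = spec.image_shape
    rng = np.random.default_rng(spec.seed)

    masks = []
    for obj in spec.objects:
        ra = obj.major_axis_um / 2.0 / spec.pixel_size_um
        cx, cy = obj.center_xy
        if cx - ra < 0 or cx + ra >= nx or cy - ra < 0 or cy + ra >= ny:
            raise ValueError("object extends past the image border")
        masks.append(_ellipse_mask((ny, nx), obj, spec.pixel_size_um))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError("phantom objects overlap; ground truth ambiguous")

    # parabolic z-profile, 1 at mid-depth, ~0.1 at the outermost planes
    if nz > 1:
        zc = (nz - 1) / 2.0
        z = np.arange(nz)
        zprofile = 1.0 - 0.9 * ((z - zc) / zc) ** 2
    else:
        zprofile = np.ones(1)

    stack = np.zeros((nz, ny, nx), dtype=float)
    for obj, mask in zip(spec.objects, masks):
        stack += zprofile[:, None, None] * (obj.peak_intensity * mask)[None, :, :]

    if spec.n_debris > 0:
        forbidden = np.zeros((ny, nx), dtype=bool)
        for mask in masks:
            forbidden |= morphology.dilation(mask, morphology.disk(5))
        peak = max((o.peak_intensity for o in spec.objects), default=1000.0)
        placed = 0
        while placed < spec.n_debris:
            y = int(rng.integers(2, ny - 2))
            x = int(rng.integers(2, nx - 2))
            if forbidden[y, x]:
                continue
            # 3-5 px speck: center pixel plus a random subset of its 4-neighbours
            n_extra = int(rng.integers(2, 5))
            offsets = rng.permutation([(0, 1), (0, -1), (1, 0), (-1, 0)])[:n_extra]
            zpos = int(rng.integers(0, nz))
            value = peak * float(rng.uniform(0.8, 1.2))
            stack[zpos, y, x] = value
            for dy, dx in offsets:
                stack[zpos, y + dy, x + dx] = value
            placed += 1

    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    gt = PhantomGroundTruth(
        areas_mm2=tuple(
            np.pi * (o.major_axis_um / 2000.0) * (o.minor_axis_um / 2000.0)
            for o in spec.objects
        ),
        major_axes_mm=tuple(o.major_axis_um / 1000.0 for o in spec.objects),
        minor_axes_mm=tuple(o.minor_axis_um / 1000.0 for o in spec.objects),
    )
    return ImageStack(stack, spec.pixel_size_um, spec.z_step_um), gt


# ---------------------------------------------------------------------------
# Perifusion traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecretionSimSpec:
    """Parameters of the biphasic secretion model.

    ``basal_rate`` sets the absolute scale (secretion units/min); ``a1``
    and ``a2`` are the first-phase peak drive and second-phase plateau as
    multiples of basal; ``tau_rise_min``/``tau_decay_min`` shape the
    first-phase transient; ``noise_cv`` is the coefficient of variation of
    the multiplicative log-normal fraction noise.
    """

    basal_rate: float = 2.0
    a1: float = 6.4
    tau_rise_min: float = 1.2
    tau_decay_min: float = 2.5
    a2: float = 1.0
    stimulus_start_min: float = 52.0
    stimulus_duration_min: float = 16.0
    run_length_min: float = 70.0
    noise_cv: float = 0.0
    seed: int = 0
    stimulus_label: str = "glucose 16.7 mM"

    def __post_init__(self) -> None:
        if self.basal_rate <= 0:
            raise ValueError("basal_rate must be positive")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("phase amplitudes must be >= 0")
        if self.tau_rise_min <= 0 or self.tau_decay_min <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.stimulus_start_min + self.stimulus_duration_min > self.run_length_min:
            raise ValueError("stimulus window must lie inside the run")


#: Presets emulating the three study arms' glucose responses.  First-phase
#: amplitudes were solved so the noiseless grid first/second-phase SI
#: ratios equal the arms' reported means (fresh 2.88, 1-week cultured
#: intact 0.97, pseudoislets 1.73) with physiological peak heights
#: (~6.8x, ~2.5x, ~3.6x basal).
GLUCOSE_PRESETS: Dict[str, SecretionSimSpec] = {
    "fresh": SecretionSimSpec(a1=14.867, tau_rise_min=1.0, tau_decay_min=2.0, a2=0.8),
    "cultured": SecretionSimSpec(a1=1.834, tau_rise_min=1.5, tau_decay_min=4.0, a2=1.5),
    "pseudoislet": SecretionSimSpec(a1=6.398, tau_rise_min=1.2, tau_decay_min=2.5, a2=1.0),
}


@dataclass(frozen=True)
class SecretionGroundTruth:
    """Noiseless-model metrics on the sampling grid (fold-over-basal AUC)."""

    si_first: float
    si_second: float
    first_second_ratio: float
    auc_ramp: float
    noiseless: np.ndarray = field(repr=False, default=None)


def secretion_model(times_min: np.ndarray, spec: SecretionSimSpec) -> np.ndarray:
    """Evaluate the noiseless biphasic secretion model at the given times."""
    t = np.asarray(times_min, dtype=float)
    t0 = spec.stimulus_start_min
    dur = spec.stimulus_duration_min
    x = t - t0
    inside = (t > t0) & (t <= t0 + dur)
    first = spec.a1 * (1.0 - np.exp(-x / spec.tau_rise_min)) * np.exp(-x / spec.tau_decay_min)
    second = spec.a2 * np.clip(x / dur, 0.0, 1.0)
    fold = np.where(inside, 1.0 + first + second, 1.0)
    return spec.basal_rate * fold


def simulate_perifusion_trace(
    spec: SecretionSimSpec, grid: SamplingGrid
) -> Tuple[PerifusionTrace, SecretionGroundTruth]:
    """Sample the secretion model on a fraction grid, with log-normal noise.

    The fraction value is the model evaluated at the fraction's collection
    time (matching how the analysis treats fractions, not an integral over
    the fraction).  Ground truth holds the noiseless model's window
    averages over the exact fractions the analysis windows select, so at
    ``noise_cv=0`` the analysis must reproduce it to rounding error.
    """
    times = grid.collection_times_min
    if times[-1] < spec.stimulus_start_min + spec.stimulus_duration_min:
        raise ValueError("grid is shorter than the stimulus window")

    noiseless = secretion_model(times, spec)
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        rng = np.random.default_rng(spec.seed)
        factors = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=times.shape))
        insulin = noiseless * factors
    else:
        insulin = noiseless.copy()

    basal = noiseless[times <= spec.stimulus_start_min].mean()
    w1 = (times >= FIRST_PHASE_WINDOW[0]) & (times <= FIRST_PHASE_WINDOW[1])
    w2 = (times >= SECOND_PHASE_WINDOW[0]) & (times <= SECOND_PHASE_WINDOW[1])
    si1 = noiseless[w1].mean() / basal
    si2 = noiseless[w2].mean() / basal
    lo, hi = spec.stimulus_start_min, spec.stimulus_start_min + spec.stimulus_duration_min
    ramp = (times >= lo) & (times <= hi)
    auc = float(np.trapezoid(noiseless[ramp] / basal, times[ramp]))

    schedule = RampSchedule(
        stimulus_label=spec.stimulus_label,
        stimulus_start_min=spec.stimulus_start_min,
        stimulus_duration_min=spec.stimulus_duration_min,
    )
    trace = PerifusionTrace(grid=grid, insulin=insulin, schedule=schedule)
    gt = SecretionGroundTruth(
        si_first=float(si1),
        si_second=float(si2),
        first_second_ratio=float(si1 / si2),
        auc_ramp=auc,
        noiseless=noiseless,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# qPCR fixtures
# ---------------------------------------------------------------------------

def generate_qpcr_fixture(
    n_samples: int,
    groups: Sequence[str],
    effect_map: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    genes: Sequence[str] = ("INS", "GCG", "SST"),
    reference_gene: str = "PPIB",
    reference_ct_mean: float = 20.0,
    base_delta_ct: float = 5.0,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with known group fold-changes.

    ``effect_map[group][gene]`` is the fold-change of that gene in that
    group relative to the first group in ``groups`` (missing entries mean
    fold 1).  Each target Ct is the sample's reference-gene Ct plus
    ``base_delta_ct`` minus log2(fold), plus Gaussian Ct noise — so with
    ``noise_sd=0`` the injected folds are recovered exactly by the ΔCt
    analysis.  Every sample carries a reference-gene Ct.

    Returns columns: sample_id, group, gene, ct, reference_ct.
    """
    if n_samples < 1 or not groups:
        raise ValueError("need at least one sample per at least one group")
    effect_map = effect_map or {}
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for group in groups:
        for i in range(n_samples):
            sample_id = f"{group}_{i + 1}"
            ref_ct = reference_ct_mean + rng.normal(0.0, noise_sd)
            for gene in genes:
                fold = float(effect_map.get(group, {}).get(gene, 1.0))
                if fold <= 0:
                    raise ValueError("fold-changes must be positive")
                ct = ref_ct + base_delta_ct - np.log2(fold) + rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": gene,
                        "ct": float(ct),
                        "reference_ct": float(ref_ct),
                        "reference_gene": reference_gene,
                    }
                )
    return pd.DataFrame(rows)
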