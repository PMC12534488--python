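"""Challenging-stimulus manipulations for the recognition benchmark.

This module implements the 16 image manipulations plus control used to probe
recurrent processing in visual recognition:

* ``clutter``     -- phase-scrambled natural-scene surrogates placed in the
                     object background, at a lightly or heavily cluttered
                     extreme of a contrast-energy / spatial-coherence ranking;
* ``blobs``       -- black circular occluders covering 40% (low) or 80% (high)
                     of the object's pixels, as many small or a few large disks;
* ``deletion``    -- the same disk geometry, but disk-covered object pixels are
                     replaced by the background grey;
* ``apertures``   -- a full black occluder with circular apertures, sized so
                     that 40% or 80% of the object is hidden;
* ``phase_scramble`` -- Fourier phase randomisation on one side of a spatial
                     frequency threshold (1.5 cycles/degree, image assumed to
                     subtend 10 degrees), amplitude spectrum untouched.

All disk-based manipulations hit their nominal coverage within a configurable
tolerance (default +-0.01) by greedy placement with a final-disk radius
shrink.  All phase operations preserve the 2-D amplitude spectrum exactly
(unit-modulus phase replacement on a Hermitian-symmetric grid) and return
real-valued images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import weibull_min
from skimage.transform import resize as _sk_resize

# ---------------------------------------------------------------------------
# Defaults shared across the pipeline
# ---------------------------------------------------------------------------

#: Uniform background luminance of all stimuli (the "grey background").
BACKGROUND_GREY = 0.5

#: Reference in-mask mean luminance used by :func:`equalize_image`.
REFERENCE_MEAN = 0.5

#: Reference in-mask RMS contrast (luminance standard deviation).
REFERENCE_RMS = 0.1

#: Disk radius bands (pixels) at the nominal 700-px frame.  "small" gives many
#: small occluders, "large" a few large ones; bands scale with frame size.
SMALL_RADII = (8.0, 16.0)
LARGE_RADII = (60.0, 110.0)

#: Spatial-frequency threshold separating the scrambled/retained phase bands.
THRESHOLD_CPD = 1.5
#: Assumed visual angle subtended by the image, in degrees.
VISUAL_ANGLE_DEG = 10.0

COVERAGE = {"low": 0.4, "high": 0.8}

KINDS = ("control", "clutter", "blobs", "deletion", "apertures", "phase_scramble")
DISK_KINDS = ("blobs", "deletion", "apertures")


class StimulusError(Exception):
    """Base class for stimulus-generation failures."""


class ParameterError(StimulusError, ValueError):
    pass


class ShapeError(StimulusError, ValueError):
    pass


class DegenerateContrastError(StimulusError):
    """Constant in-mask image cannot be matched to a nonzero RMS contrast."""


class DegenerateFitError(StimulusError):
    """Clutter indices are undefined for a gradient-free (constant) image."""


class ConvergenceError(StimulusError):
    """Disk placement could not reach the target coverage within max_iter."""


class ConfigurationError(StimulusError):
    """A manipulation was requested without the resources it needs."""


# ---------------------------------------------------------------------------
# Condition specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManipulationSpec:
    """One of the 17 experimental conditions.

    ``level`` (severity) applies to clutter and the disk manipulations,
    ``regime`` (disk-size band) only to disk manipulations, and ``band``
    only to phase scrambling.
    """

    kind: str
    level: str = "none"
    regime: str = "none"
    band: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown manipulation kind {self.kind!r}")
        if (self.regime != "none") != (self.kind in DISK_KINDS):
            raise ParameterError(
                f"regime={self.regime!r} invalid for kind={self.kind!r}"
            )
        if (self.band != "none") != (self.kind == "phase_scramble"):
            raise ParameterError(f"band={self.band!r} invalid for kind={self.kind!r}")
        if (self.level == "none") != (self.kind in ("control", "phase_scramble")):
            raise ParameterError(f"level={self.level!r} invalid for kind={self.kind!r}")
        if self.level not in ("low", "high", "none"):
            raise ParameterError(f"unknown level {self.level!r}")
        if self.regime not in ("small", "large", "none"):
            raise ParameterError(f"unknown regime {self.regime!r}")
        if self.band not in ("low_pass", "high_pass", "none"):
            raise ParameterError(f"unknown band {self.band!r}")

    @property
    def label(self) -> str:
        parts = [self.kind]
        for f in (self.level, self.regime, self.band):
            if f != "none":
                parts.append(f)
        return "_".join(parts)


def enumerate_conditions() -> list[ManipulationSpec]:
    """Return the 17 conditions in canonical order.

    Control first, then clutter, blobs, deletion, apertures, phase
    scrambling; within a type, severity low before high, disk regime small
    before large, scrambled band low before high.
    """
    specs = [ManipulationSpec("control")]
    for level in ("low", "high"):
        specs.append(ManipulationSpec("clutter", level=level))
    for kind in ("blobs", "deletion", "apertures"):
        for level in ("low", "high"):
            for regime in ("small", "large"):
                specs.append(ManipulationSpec(kind, level=level, regime=regime))
    for band in ("low_pass", "high_pass"):
        specs.append(ManipulationSpec("phase_scramble", band=band))
    return specs


def condition_labels() -> list[str]:
    return [s.label for s in enumerate_conditions()]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClutterIndex:
    """Contrast energy (Weibull scale) and spatial coherence (Weibull shape)
    of the local gradient-magnitude distribution of an image."""

    ce: float
    sc: float


@dataclass
class DiskSet:
    """Disks placed by :func:`place_disks` plus the coverage they achieved."""

    disks: list[tuple[int, int, float]]
    achieved_coverage: float


@dataclass
class StimulusImage:
    pixels: np.ndarray
    spec: ManipulationSpec
    category: str = ""
    exemplar_id: int = -1
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Luminance / contrast equalisation
# ---------------------------------------------------------------------------


def equalize_image(image, target_mean: float = REFERENCE_MEAN,
                   target_rms: float = REFERENCE_RMS):
    """Match the in-mask mean luminance and RMS contrast of a silhouette.

    RMS contrast is the standard deviation of in-mask luminance.  Pixels are
    clipped to [0, 1] only after moment matching; if clipping moved either
    moment by more than 1e-3 the affine match is re-applied once.
    """
    mask = np.asarray(image.object_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("object mask is empty")
    pixels = np.asarray(image.pixels, dtype=float).copy()

    def _match(px):
        vals = px[mask]
        mu = vals.mean()
        sd = vals.std()
        if target_rms > 0:
            if sd < 1e-12:
                raise DegenerateContrastError(
                    "constant in-mask image cannot reach a nonzero RMS contrast"
                )
            new = (vals - mu) / sd * target_rms + target_mean
        else:
            new = vals - mu + target_mean
        out = px.copy()
        out[mask] = new
        return out

    out = np.clip(_match(pixels), 0.0, 1.0)
    vals = out[mask]
    if (abs(vals.mean() - target_mean) > 1e-3
            or abs(vals.std() - target_rms) > 1e-3):
        out = np.clip(_match(out), 0.0, 1.0)
    return replace(image, pixels=out)


def in_mask_moments(image) -> tuple[float, float]:
    """(mean luminance, RMS contrast) inside the object mask."""
    mask = np.asarray(image.object_mask, dtype=bool)
    vals = np.asarray(image.pixels, dtype=float)[mask]
    return float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# Phase scrambling
# ---------------------------------------------------------------------------


def _random_phases(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Hermitian-consistent uniform random phases.

    Taking the phase spectrum of a real white-noise image yields phases that
    are uniform on (-pi, pi], antisymmetric under frequency negation, and
    real-valued (0 or pi) at the self-conjugate (DC/Nyquist) bins, so the
    reconstructed image is exactly real.
    """
    noise = rng.standard_normal(shape)
    return np.angle(np.fft.fft2(noise))


def phase_scramble_full(image: np.ndarray, seed: int) -> np.ndarray:
    """Replace the whole phase spectrum by random noise, keeping the origin.

    The amplitude spectrum is preserved exactly; the output is real.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ShapeError(f"expected a square 2-D image, got shape {image.shape}")
    F = np.fft.fft2(image)
    phases = _random_phases(image.shape, np.random.default_rng(seed))
    phases[0, 0] = np.angle(F[0, 0])
    return np.real(np.fft.ifft2(np.abs(F) * np.exp(1j * phases)))


def _radial_cpd(n: int, visual_angle: float) -> np.ndarray:
    """Radial frequency of every 2-D Fourier bin in cycles per degree."""
    cyc = np.fft.fftfreq(n) * n  # integer cycles per image
    fr = np.hypot(cyc[:, None], cyc[None, :])
    return fr / visual_angle


def scrambled_band_mask(n: int, band: str, threshold: float = THRESHOLD_CPD,
                        visual_angle: float = VISUAL_ANGLE_DEG) -> np.ndarray:
    """Boolean grid of the Fourier bins whose phases get scrambled.

    ``low_pass`` keeps phases at or below the threshold and scrambles above it
    (the image retains its coarse structure); ``high_pass`` is the converse.
    The DC bin is never scrambled, and at any threshold the two bands
    partition all non-DC bins.
    """
    if band not in ("low_pass", "high_pass"):
        raise ParameterError(f"unknown band {band!r}")
    cpd = _radial_cpd(n, visual_angle)
    if band == "low_pass":
        m = cpd > threshold
    else:
        m = cpd <= threshold
    m[0, 0] = False
    return m


def phase_scramble_band(image: np.ndarray, band: str,
                        threshold: float = THRESHOLD_CPD,
                        visual_angle: float = VISUAL_ANGLE_DEG,
                        seed: int = 0) -> np.ndarray:
    """Scramble phases on one side of a spatial-frequency threshold.

    Frequencies are measured radially in cycles/degree (cycles per image
    divided by the assumed visual angle).  Amplitudes and retained-band
    phases are untouched.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ShapeError(f"expected a square 2-D image, got shape {image.shape}")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    F = np.fft.fft2(image)
    scramble = scrambled_band_mask(image.shape[0], band, threshold, visual_angle)
    phases = np.angle(F)
    noise = _random_phases(image.shape, np.random.default_rng(seed))
    phases = np.where(scramble, noise, phases)
    return np.real(np.fft.ifft2(np.abs(F) * np.exp(1j * phases)))


# ---------------------------------------------------------------------------
# Clutter indices and backgrounds
# ---------------------------------------------------------------------------


def compute_clutter_indices(image: np.ndarray, sigma: float = 1.5,
                            max_samples: int = 20000) -> ClutterIndex:
    """Two-parameter Weibull fit to the local gradient-magnitude distribution.

    Gradients are Gaussian-derivative filtered at scale ``sigma`` (pixels).
    The Weibull scale parameter is the contrast energy (CE) and the shape
    parameter the spatial coherence (SC).  The fit subsamples at most
    ``max_samples`` gradient magnitudes deterministically (even striding), so
    identical images always map to identical indices.
    """
    image = np.asarray(image, dtype=float)
    gx = ndimage.gaussian_filter(image, sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(image, sigma, order=(1, 0), mode="reflect")
    grad = np.hypot(gx, gy).ravel()
    grad = grad[grad > 1e-12]
    if grad.size < 16 or grad.std() < 1e-12:
        raise DegenerateFitError("gradient distribution is degenerate")
    if grad.size > max_samples:
        grad = grad[:: grad.size // max_samples + 1]
    shape, _, scale = weibull_min.fit(grad, floc=0.0)
    return ClutterIndex(ce=float(scale), sc=float(shape))


def clutter_rank_scores(indices: Sequence[ClutterIndex]) -> np.ndarray:
    """Composite clutter score: rank of CE plus rank of decreasing SC.

    Higher contrast energy and a heavier-tailed (lower-shape) gradient
    distribution both read as more cluttered; the composite is the sum of the
    two ranks, so only the ordering of each index matters.
    """
    ce = np.array([c.ce for c in indices])
    sc = np.array([c.sc for c in indices])
    rank_ce = np.argsort(np.argsort(ce, kind="stable"), kind="stable")
    rank_sc = np.argsort(np.argsort(-sc, kind="stable"), kind="stable")
    return (rank_ce + rank_sc).astype(float)


def make_clutter_background(scenes: Sequence[np.ndarray], level: str,
                            seed: int = 0) -> np.ndarray:
    """Pick the fully phase-scrambled scene at the requested clutter extreme.

    Every scene is phase scrambled, scored with
    :func:`compute_clutter_indices`, and ranked by the composite clutter
    score; ``level='low'`` returns the least cluttered scrambled scene,
    ``'high'`` the most cluttered.  Ties resolve to the lowest input index.
    """
    if level not in ("low", "high"):
        raise ParameterError(f"unknown clutter level {level!r}")
    scenes = list(scenes)
    if len(scenes) < 4:
        raise ParameterError("need at least 4 candidate scenes")
    scrambled = [phase_scramble_full(s, seed + i) for i, s in enumerate(scenes)]
    scores = clutter_rank_scores([compute_clutter_indices(s) for s in scrambled])
    idx = int(np.argmin(scores)) if level == "low" else int(np.argmax(scores))
    return scrambled[idx]


# ---------------------------------------------------------------------------
# Disk placement and disk-based manipulations
# ---------------------------------------------------------------------------


def _radius_band(regime: str, frame: int) -> tuple[float, float]:
    if regime == "small":
        lo, hi = SMALL_RADII
    elif regime == "large":
        lo, hi = LARGE_RADII
    else:
        raise ParameterError(f"unknown disk regime {regime!r}")
    scale = frame / 700.0
    return max(1.0, lo * scale), max(1.5, hi * scale)


def _stamp(covered: np.ndarray, mask_covered_count: int, mask: np.ndarray,
           r: int, c: int, radius: float, commit: bool) -> int:
    """Count (and optionally commit) newly covered object pixels of one disk."""
    n_rows, n_cols = covered.shape
    rad = int(np.ceil(radius))
    r0, r1 = max(0, r - rad), min(n_rows, r + rad + 1)
    c0, c1 = max(0, c - rad), min(n_cols, c + rad + 1)
    yy, xx = np.ogrid[r0:r1, c0:c1]
    disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius * radius
    new = disk & ~covered[r0:r1, c0:c1]
    gained = int((new & mask[r0:r1, c0:c1]).sum())
    if commit:
        covered[r0:r1, c0:c1] |= disk
    return mask_covered_count + gained


def place_disks(mask: np.ndarray, target_coverage: float, regime: str,
                seed: int = 0, tolerance: float = 0.01,
                max_iter: int = 20000) -> tuple[DiskSet, np.ndarray]:
    """Greedily place disks until they cover ``target_coverage`` of the mask.

    Disk centres are drawn uniformly within the mask's bounding box and radii
    uniformly within the regime's band.  A disk that would overshoot the
    target band has its radius shrunk by bisection so the achieved coverage
    lands within ``tolerance`` of the target; disks that cannot help are
    skipped.  Returns the disk set and the boolean union of the disks.
    """
    mask = np.asarray(mask, dtype=bool)
    if not (0.0 < target_coverage < 1.0):
        raise ParameterError("target_coverage must lie in (0, 1)")
    if not mask.any():
        raise ParameterError("object mask is empty")
    rng = np.random.default_rng(seed)
    lo, hi = _radius_band(regime, mask.shape[0])
    rows, cols = np.nonzero(mask)
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    total = int(mask.sum())
    lo_count = int(np.ceil((target_coverage - tolerance) * total))
    hi_count = int(np.floor((target_coverage + tolerance) * total))

    covered = np.zeros_like(mask)
    count = 0
    disks: list[tuple[int, int, float]] = []
    for _ in range(max_iter):
        if count >= lo_count:
            break
        r = int(rng.integers(rmin, rmax + 1))
        c = int(rng.integers(cmin, cmax + 1))
        radius = float(rng.uniform(lo, hi))
        trial = _stamp(covered, count, mask, r, c, radius, commit=False)
        if trial > hi_count:
            # shrink this disk by bisection to land inside the tolerance band
            lo_r, hi_r = 0.0, radius
            chosen = None
            for _ in range(48):
                mid = 0.5 * (lo_r + hi_r)
                t = _stamp(covered, count, mask, r, c, mid, commit=False)
                if t > hi_count:
                    hi_r = mid
                elif t < lo_count:
                    lo_r = mid
                else:
                    chosen = mid
                    break
            if chosen is None:
                continue  # this centre cannot land in the band; resample
            radius = chosen
        count = _stamp(covered, count, mask, r, c, radius, commit=True)
        disks.append((r, c, radius))
    else:
        raise ConvergenceError(
            f"coverage {count / total:.3f} after {max_iter} disks "
            f"(target {target_coverage})"
        )
    return DiskSet(disks=disks, achieved_coverage=count / total), covered


def apply_disk_manipulation(image, kind: str, level: str, regime: str,
                            seed: int = 0,
                            tolerance: float = 0.01) -> StimulusImage:
    """Apply the blob, deletion, or aperture manipulation to a silhouette.

    The severity level fixes the fraction of object pixels affected (low:
    40%, high: 80%).  Blobs paint the disks black on top of the image;
    deletion replaces disk-covered object pixels with the background grey;
    apertures black out the whole frame and cut disk-shaped holes revealing
    the image, sized so the *hidden* object fraction hits the target.
    """
    if kind not in DISK_KINDS:
        raise ParameterError(f"not a disk manipulation: {kind!r}")
    target = COVERAGE[level]
    mask = np.asarray(image.object_mask, dtype=bool)
    place_target = (1.0 - target) if kind == "apertures" else target
    disks, union = place_disks(mask, place_target, regime, seed=seed,
                               tolerance=tolerance)
    pixels = np.asarray(image.pixels, dtype=float).copy()
    if kind == "blobs":
        pixels[union] = 0.0
        affected = disks.achieved_coverage
    elif kind == "deletion":
        pixels[union & mask] = BACKGROUND_GREY
        affected = disks.achieved_coverage
    else:  # apertures: full occluder, disks reveal the underlying image
        out = np.zeros_like(pixels)
        out[union] = pixels[union]
        pixels = out
        affected = 1.0 - disks.achieved_coverage  # hidden object fraction
    spec = ManipulationSpec(kind, level=level, regime=regime)
    return StimulusImage(
        pixels=pixels, spec=spec,
        category=getattr(image, "category", ""),
        exemplar_id=getattr(image, "exemplar_id", -1),
        provenance={"seed": seed, "achieved_coverage": disks.achieved_coverage,
                    "affected_fraction": affected, "n_disks": len(disks.disks)},
    )


# ---------------------------------------------------------------------------
# Composition, masks, dispatch
# ---------------------------------------------------------------------------


def compose_clutter_stimulus(image, background: np.ndarray) -> StimulusImage:
    """Object pixels from the silhouette, everything else from the background."""
    background = np.asarray(background, dtype=float)
    pixels = np.asarray(image.pixels, dtype=float)
    if background.shape != pixels.shape:
        raise ShapeError(
            f"background shape {background.shape} != image shape {pixels.shape}"
        )
    mask = np.asarray(image.object_mask, dtype=bool)
    out = np.where(mask, pixels, background)
    return StimulusImage(pixels=out, spec=ManipulationSpec("clutter", level="low"),
                         category=getattr(image, "category", ""),
                         exemplar_id=getattr(image, "exemplar_id", -1))


def make_mask_pattern(scene: np.ndarray, size: int = 700, seed: int = 0) -> np.ndarray:
    """Backward-masking pattern: a resized, fully phase-scrambled scene."""
    scene = np.asarray(scene, dtype=float)
    if scene.shape != (size, size):
        scene = _sk_resize(scene, (size, size), anti_aliasing=True,
                           preserve_range=True)
    return phase_scramble_full(scene, seed)


def generate_stimulus(image, spec: ManipulationSpec, resources: dict | None = None,
                      seed: int = 0) -> StimulusImage:
    """Dispatch a silhouette through the manipulation named by ``spec``.

    ``resources`` must supply ``scenes`` (a list of greyscale images) for the
    clutter conditions.  The control condition returns the equalised object on
    its uniform grey background unchanged.
    """
    resources = resources or {}
    if spec.kind == "control":
        out = StimulusImage(pixels=np.asarray(image.pixels, dtype=float).copy(),
                            spec=spec,
                            category=getattr(image, "category", ""),
                            exemplar_id=getattr(image, "exemplar_id", -1))
    elif spec.kind == "clutter":
        scenes = resources.get("scenes")
        if not scenes:
            raise ConfigurationError("clutter conditions need resources['scenes']")
        background = make_clutter_background(scenes, spec.level, seed=seed)
        out = compose_clutter_stimulus(image, background)
        out.spec = spec
    elif spec.kind in DISK_KINDS:
        out = apply_disk_manipulation(image, spec.kind, spec.level, spec.regime,
                                      seed=seed)
    elif spec.kind == "phase_scramble":
        pixels = phase_scramble_band(np.asarray(image.pixels, dtype=float),
                                     spec.band, seed=seed)
        out = StimulusImage(pixels=np.clip(pixels, 0.0, 1.0), spec=spec,
                            category=getattr(image, "category", ""),
                            exemplar_id=getattr(image, "exemplar_id", -1))
    else:  # pragma: no cover - kinds are validated by ManipulationSpec
        raise ParameterError(f"unhandled kind {spec.kind!r}")
    out.provenance.setdefault("seed", seed)
    out.provenance["condition"] = spec.label
    return out
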