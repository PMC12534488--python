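"""Synthetic inputs for the benchmark: silhouettes, scenes, and observers.

The real study photographs segmented objects (8 categories x 10 exemplars,
700x700, grey background) and collects a pooled human trial table.  Everything
downstream only relies on the *structure* of those inputs, which this module
reproduces procedurally so the whole pipeline runs with no download:

* ``generate_category_shapes`` -- seedable smoothed star-polygon silhouettes,
  one parametric shape family per category (lobe count, aspect ratio,
  boundary roughness, size), textured inside the mask and equalised to the
  reference luminance/contrast;
* ``generate_scene_surrogates`` -- 1/f-spectrum noise images with sparse
  edge-like structure, spanning a range of clutter indices so the clutter
  manipulation can pick genuine extremes;
* ``simulate_trials`` -- a parametric observer (:class:`ResponseModel`) with
  per-condition difficulty, masking susceptibility concentrated in hard
  conditions, similarity-structured confusions, and shifted-lognormal RTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .stimuli import (
    BACKGROUND_GREY,
    REFERENCE_MEAN,
    REFERENCE_RMS,
    ParameterError,
    condition_labels,
    equalize_image,
)

#: The eight object categories of the recognition task.  The synthetic shape
#: families stand in for the photographic exemplars; only the labels and the
#: 8-way design carry over.
CATEGORIES = ("person", "cat", "bird", "tree", "hydrant",
              "building", "bus", "banana")

TRIAL_COLUMNS = ("subject", "condition", "masked", "true", "response",
                 "rt", "correct")


class ResponseModelError(ParameterError):
    """The simulated observer's parameters are inconsistent."""


# ---------------------------------------------------------------------------
# Shape families and silhouettes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCategory:
    """Parametric shape family standing in for one object category."""

    name: str
    lobes: int            # angular lobe count of the star polygon
    aspect: float         # width / height ratio
    roughness: float      # amplitude of high-order boundary harmonics
    size_frac: float      # silhouette radius as a fraction of the frame
    exemplar_seeds: tuple = ()


#: Default families; pairwise distinct in at least one parameter.
DEFAULT_FAMILIES = (
    SyntheticCategory("person", lobes=2, aspect=0.45, roughness=0.06, size_frac=0.38),
    SyntheticCategory("cat", lobes=4, aspect=1.10, roughness=0.10, size_frac=0.33),
    SyntheticCategory("bird", lobes=3, aspect=1.40, roughness=0.08, size_frac=0.28),
    SyntheticCategory("tree", lobes=7, aspect=0.80, roughness=0.22, size_frac=0.40),
    SyntheticCategory("hydrant", lobes=2, aspect=0.60, roughness=0.03, size_frac=0.30),
    SyntheticCategory("building", lobes=4, aspect=0.75, roughness=0.015, size_frac=0.42),
    SyntheticCategory("bus", lobes=4, aspect=1.60, roughness=0.02, size_frac=0.36),
    SyntheticCategory("banana", lobes=2, aspect=1.80, roughness=0.05, size_frac=0.26),
)


@dataclass
class SilhouetteImage:
    """A 700x700-style greyscale object on uniform grey plus its binary mask."""

    pixels: np.ndarray
    object_mask: np.ndarray
    category: str
    exemplar_id: int


def default_categories(n_categories: int = 8) -> list[SyntheticCategory]:
    """First ``n_categories`` shape families; extended by lobe-count variation
    beyond the default eight."""
    fams = list(DEFAULT_FAMILIES)
    i = 0
    while len(fams) < n_categories:
        base = DEFAULT_FAMILIES[i % len(DEFAULT_FAMILIES)]
        fams.append(SyntheticCategory(
            name=f"{base.name}{len(fams)}", lobes=base.lobes + 3 + i,
            aspect=base.aspect, roughness=base.roughness,
            size_frac=base.size_frac))
        i += 1
    return fams[:n_categories]


def _boundary_radius(theta: np.ndarray, fam: SyntheticCategory,
                     rng: np.random.Generator) -> np.ndarray:
    """Radial Fourier descriptor of one exemplar's boundary."""
    r = np.ones_like(theta)
    phase = rng.uniform(0, 2 * np.pi)
    r += 0.25 * np.cos(fam.lobes * theta + phase)
    for k in range(5, 13):
        amp = fam.roughness * rng.uniform(0.3, 1.0) / np.sqrt(k)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return np.clip(r, 0.25, None)


def _rasterise(fam: SyntheticCategory, size: int,
               rng: np.random.Generator) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = _boundary_radius(theta, fam, rng)
    base = fam.size_frac * size / 2.0
    jitter = rng.uniform(0.9, 1.1)
    ar = fam.aspect
    rows = size / 2.0 + base * jitter * r * np.sin(theta) / np.sqrt(ar)
    cols = size / 2.0 + base * jitter * r * np.cos(theta) * np.sqrt(ar)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = _sk_polygon(np.clip(rows, 0, size - 1), np.clip(cols, 0, size - 1),
                         shape=mask.shape)
    mask[rr, cc] = True
    # keep the mask fraction inside the documented [1%, 60%] band
    frac = mask.mean()
    if frac > 0.60 or frac < 0.01:
        target = 0.5 if frac > 0.60 else 0.02
        scale = np.sqrt(target / max(frac, 1e-6))
        rows = size / 2.0 + (rows - size / 2.0) * scale
        cols = size / 2.0 + (cols - size / 2.0) * scale
        mask[:] = False
        rr, cc = _sk_polygon(np.clip(rows, 0, size - 1),
                             np.clip(cols, 0, size - 1), shape=mask.shape)
        mask[rr, cc] = True
    return mask


def _texture(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth, bounded in-mask texture; tanh squashing keeps the subsequent
    affine equalisation free of clipping."""
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 3.0)
    z = (noise - noise.mean()) / max(noise.std(), 1e-12)
    return 3.0 * np.tanh(z / 3.0)


def generate_category_shapes(n_categories: int = 8, n_exemplars: int = 10,
                             size: int = 700, seed: int = 42,
                             ) -> list[SilhouetteImage]:
    """Generate ``n_categories x n_exemplars`` equalised silhouettes.

    Each exemplar is reproducible from ``(seed, category, exemplar)`` alone;
    the default design (8 x 10 at 700 px) yields the 80-image stimulus set.
    """
    if n_categories < 2 or n_exemplars < 1 or size < 64:
        raise ParameterError(
            "need n_categories >= 2, n_exemplars >= 1, size >= 64")
    images: list[SilhouetteImage] = []
    for ci, fam in enumerate(default_categories(n_categories)):
        for ei in range(n_exemplars):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, ei]))
            mask = _rasterise(fam, size, rng)
            pixels = np.full((size, size), BACKGROUND_GREY)
            pixels[mask] = 0.5 + 0.1 * _texture(mask, rng)[mask]
            img = SilhouetteImage(pixels=pixels, object_mask=mask,
                                  category=fam.name, exemplar_id=ei)
            images.append(equalize_image(img, REFERENCE_MEAN, REFERENCE_RMS))
    return images


# ---------------------------------------------------------------------------
# Natural-scene surrogates
# ---------------------------------------------------------------------------


def generate_scene_surrogates(n: int, size: int = 700,
                              seed: int = 0) -> list[np.ndarray]:
    """Greyscale 1/f-spectrum images with sparse edge-like structure.

    The spectral slope and the number of superimposed rectangle edges vary
    across scenes, so the computed clutter indices span a genuine range.
    """
    if n < 1 or size < 8:
        raise ParameterError("need n >= 1 and size >= 8")
    scenes = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        slope = rng.uniform(0.6, 1.6)
        f = np.hypot(*np.meshgrid(np.fft.fftfreq(size), np.fft.fftfreq(size),
                                  indexing="ij"))
        amp = 1.0 / np.maximum(f, 1.0 / size) ** slope
        spec = np.fft.fft2(rng.standard_normal((size, size))) * amp
        img = np.real(np.fft.ifft2(spec))
        # sparse edge-like structure: a few axis-aligned luminance steps
        for _ in range(int(rng.integers(0, 12))):
            r0, c0 = rng.integers(0, size, 2)
            h = int(rng.integers(size // 16, size // 3))
            w = int(rng.integers(size // 16, size // 3))
            img[r0:r0 + h, c0:c0 + w] += rng.uniform(-1.5, 1.5) * img.std()
        img = (img - img.mean()) / max(img.std(), 1e-12)
        scenes.append(np.clip(0.5 + 0.15 * img, 0.0, 1.0))
    return scenes


# ---------------------------------------------------------------------------
# Simulated observers
# ---------------------------------------------------------------------------


@dataclass
class ResponseModel:
    """Parametric observer generating condition-dependent responses.

    ``condition_difficulty`` (delta) is the probability correct per condition
    without masking; ``masking_susceptibility`` (mu) is the accuracy drop a
    backward mask causes in that condition; errors are allocated across wrong
    categories in proportion to the off-diagonal of ``similarity_kernel``;
    RTs follow a lognormal whose median grows linearly with difficulty.
    """

    condition_difficulty: np.ndarray
    masking_susceptibility: np.ndarray
    similarity_kernel: np.ndarray
    rt_base: float = 0.5
    rt_slope: float = 0.8
    rt_noise_sd: float = 0.15
    categories: tuple = CATEGORIES
    conditions: tuple = field(default_factory=lambda: tuple(condition_labels()))

    def __post_init__(self) -> None:
        self.condition_difficulty = np.asarray(self.condition_difficulty, float)
        self.masking_susceptibility = np.asarray(self.masking_susceptibility, float)
        self.similarity_kernel = np.asarray(self.similarity_kernel, float)
        n_cond = len(self.conditions)
        n_cat = len(self.categories)
        if self.condition_difficulty.shape != (n_cond,):
            raise ResponseModelError("condition_difficulty has wrong length")
        if self.masking_susceptibility.shape != (n_cond,):
            raise ResponseModelError("masking_susceptibility has wrong length")
        if self.similarity_kernel.shape != (n_cat, n_cat):
            raise ResponseModelError("similarity_kernel has wrong shape")
        if (self.similarity_kernel < 0).any():
            raise ResponseModelError("similarity_kernel must be nonnegative")
        if (self.masking_susceptibility < 0).any():
            raise ResponseModelError("masking_susceptibility must be >= 0")
        if (self.condition_difficulty - self.masking_susceptibility < 0).any():
            raise ResponseModelError(
                "masked accuracy delta - mu would be negative")

    def error_allocation(self) -> np.ndarray:
        """Off-diagonal of the similarity kernel, rows renormalised to 1."""
        W = self.similarity_kernel.copy()
        np.fill_diagonal(W, 0.0)
        sums = W.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ResponseModelError("a kernel row has no off-diagonal mass")
        return W / sums


def default_similarity_kernel() -> np.ndarray:
    """Similarity structure over the 8 categories.

    Animate things (person/cat/bird) cluster, as do large rigid objects
    (building/bus) and vertical outdoor items (tree/hydrant); banana sits
    apart.  The kernel is symmetric and only its off-diagonal matters.
    """
    coords = np.array([
        [0.0, 0.0],   # person
        [0.4, 0.2],   # cat
        [0.5, -0.3],  # bird
        [1.6, 0.8],   # tree
        [1.4, -0.6],  # hydrant
        [2.2, 0.3],   # building
        [2.1, -0.4],  # bus
        [0.9, 1.6],   # banana
    ])
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    return np.exp(-d)


def default_response_model() -> ResponseModel:
    """Observer whose difficulty profile mirrors the benchmark's findings:
    nine easy conditions above 0.9, eight hard ones below, masking effects
    concentrated in (and proportional to) condition difficulty."""
    delta_by_label = {
        "control": 0.97,
        "clutter_low": 0.95,
        "clutter_high": 0.92,
        "blobs_low_small": 0.93,
        "blobs_low_large": 0.94,
        "blobs_high_small": 0.70,
        "blobs_high_large": 0.82,
        "deletion_low_small": 0.93,
        "deletion_low_large": 0.94,
        "deletion_high_small": 0.80,
        "deletion_high_large": 0.85,
        "apertures_low_small": 0.92,
        "apertures_low_large": 0.93,
        "apertures_high_small": 0.55,
        "apertures_high_large": 0.65,
        "phase_scramble_low_pass": 0.60,
        "phase_scramble_high_pass": 0.88,
    }
    labels = condition_labels()
    delta = np.array([delta_by_label[c] for c in labels])
    # susceptibility grows with difficulty: negligible in easy conditions
    mu = np.where(delta > 0.9, 0.015, 0.5 * (0.95 - delta))
    return ResponseModel(condition_difficulty=delta,
                         masking_susceptibility=mu,
                         similarity_kernel=default_similarity_kernel())


def simulate_trials(model: ResponseModel, n_subjects: int,
                    trials_per_cell: int, seed: int = 0) -> pd.DataFrame:
    """Simulate the pooled trial table of the categorisation experiment.

    Every subject contributes ``trials_per_cell`` trials to each of the
    ``condition x masked`` cells, with true categories cycling through the
    category set.  Expected accuracy in cell (c, m) is delta_c - m * mu_c;
    error responses follow the off-diagonal-renormalised similarity kernel
    row of the true category; RTs are lognormal with median
    ``rt_base + rt_slope * (1 - delta_c)``.
    """
    if n_subjects < 1 or trials_per_cell < 1:
        raise ParameterError("need n_subjects >= 1 and trials_per_cell >= 1")
    rng = np.random.default_rng(seed)
    cats = np.array(model.categories)
    n_cat = len(cats)
    W = model.error_allocation()
    frames = []
    for s in range(n_subjects):
        for ci, cond in enumerate(model.conditions):
            for masked in (False, True):
                p = model.condition_difficulty[ci] - (
                    model.masking_susceptibility[ci] if masked else 0.0)
                true_idx = np.arange(trials_per_cell) % n_cat
                correct = rng.random(trials_per_cell) < p
                resp_idx = true_idx.copy()
                wrong = ~correct
                if wrong.any():
                    cum = np.cumsum(W[true_idx[wrong]], axis=1)
                    u = rng.random(wrong.sum())[:, None]
                    resp_idx[wrong] = np.minimum((u > cum).sum(axis=1), n_cat - 1)
                correct = resp_idx == true_idx  # exact flag/response coupling
                median = model.rt_base + model.rt_slope * (
                    1.0 - model.condition_difficulty[ci])
                rt = np.exp(np.log(median)
                            + model.rt_noise_sd * rng.standard_normal(trials_per_cell))
                frames.append(pd.DataFrame({
                    "subject": f"sub{s:03d}",
                    "condition": cond,
                    "masked": masked,
                    "true": cats[true_idx],
                    "response": cats[resp_idx],
                    "rt": rt,
                    "correct": correct,
                }))
    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]
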