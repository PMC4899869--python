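"""Synthetic tissue fields with known ground truth.

Emulates the geometry the association analysis assumes: two interleaved
cell classes in interstitial stroma, with the epithelial layer, hair
follicles and background excluded by a mask. Three point patterns are
available for the query class:

- ``csr`` — complete spatial randomness (uniform over the valid region),
  the null the Monte-Carlo score is calibrated against;
- ``attracted`` — a parent–offspring cluster process (Thomas-like): each
  offspring picks a uniformly random parent and lands at an isotropic
  Gaussian displacement of scale ``sigma_c``; one interpretable
  effect-size knob, with CSR recovered as ``sigma_c -> inf``;
- ``inhibited`` — uniform placement rejected until at least ``r_min`` from
  every parent (hard-core repulsion).

Mask containment uses rejection, not truncation, so within-mask placement
stays exactly uniform / exactly Gaussian-conditioned. ``render_image``
turns a point set into a fluorescence-like raster (Gaussian PSF spots on a
constant background, optional Poisson shot noise and Gaussian read noise)
for end-to-end detection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import EmptyValidRegionError, GenerationFailureError
from .io import ChannelImage, PointSet, RegionMask, nearest_pixel

__all__ = ["SyntheticSpec", "generate_mask", "generate_points",
           "render_image", "generate_sample"]

_REJECTION_CAP = 10_000  # attempts per point before declaring infeasibility


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic sample.

    The mask is an elliptical tissue section (semi-axes ``tissue_axes`` as
    fractions of the raster half-dimensions) minus an epithelial band of
    ``epithelium_rows`` rows along the top of the tissue and ``n_holes``
    circular follicle holes with radii in ``hole_radius`` (pixels).
    Rendering uses peak ``amplitude`` over ``background`` with
    ``noise_model`` in {"none", "gaussian", "poisson"}; Poisson shot noise
    applies to signal + background, the standard fluorescence forward
    model, with optional additive ``read_noise_sd``.
    """

    shape: tuple = (256, 256)
    tissue_axes: tuple = (0.9, 0.9)
    epithelium_rows: int = 20
    n_holes: int = 3
    hole_radius: tuple = (8.0, 16.0)
    n_parents: int = 30
    n_offspring: int = 150
    pattern: str = "csr"
    sigma_c: float = 5.0
    r_min: float = 30.0
    spot_sigma: float = 2.0
    amplitude: float = 100.0
    background: float = 10.0
    noise_model: str = "poisson"
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("csr", "attracted", "inhibited"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "attracted" and not self.sigma_c > 0:
            raise ValueError("attracted pattern requires sigma_c > 0")
        if self.pattern == "inhibited" and not self.r_min > 0:
            raise ValueError("inhibited pattern requires r_min > 0")
        if self.n_parents < 0 or self.n_offspring < 0:
            raise ValueError("counts must be non-negative")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError("shape must be positive 2D")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def asdict(self):
        return asdict(self)


def _rng_for(spec, stream):
    # independent, reproducible sub-streams for mask / points / each render
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), hash_stream(stream)])
    )


def hash_stream(name):
    return int.from_bytes(name.encode(), "big") % (2**31)


def generate_mask(spec: SyntheticSpec) -> RegionMask:
    """Irregular valid region: tissue ellipse minus epithelium and follicles.

    The named excluded regions partition the non-valid pixels: background
    (outside the tissue), epithelium (top band of the tissue), follicle_i
    (circular holes, drawn inside the remaining stroma). Deterministic in
    ``spec.seed``.
    """
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay = spec.tissue_axes[0] * h / 2.0
    ax = spec.tissue_axes[1] * w / 2.0
    tissue = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if not tissue.any():
        raise EmptyValidRegionError("tissue ellipse contains no pixel")

    top = int(np.nonzero(tissue.any(axis=1))[0][0])
    epithelium = tissue & (yy < top + spec.epithelium_rows)
    stroma = tissue & ~epithelium

    rng = _rng_for(spec, "mask")
    excluded = {"background": ~tissue}
    if spec.epithelium_rows > 0:
        excluded["epithelium"] = epithelium
    valid = stroma.copy()
    stroma_rows, stroma_cols = np.nonzero(stroma)
    for i in range(spec.n_holes):
        k = rng.integers(0, len(stroma_rows))
        r = rng.uniform(*spec.hole_radius)
        hole = (
            (yy - stroma_rows[k]) ** 2 + (xx - stroma_cols[k]) ** 2
        ) <= r * r
        hole &= stroma  # keep excluded regions pairwise disjoint
        for prev in excluded.values():
            hole &= ~prev
        excluded[f"follicle_{i}"] = hole
        valid &= ~hole
    if not valid.any():
        raise EmptyValidRegionError("exclusions leave no valid pixel")
    return RegionMask(valid=valid, excluded_regions=excluded)


def _uniform_in_mask(rng, valid_xy, n):
    idx = rng.integers(0, len(valid_xy), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return valid_xy[idx] + jitter


def _inside(mask, pts):
    xi = nearest_pixel(pts[:, 0])
    yi = nearest_pixel(pts[:, 1])
    h, w = mask.shape
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = mask.valid[yi[ok], xi[ok]]
    return out


def generate_points(spec: SyntheticSpec, mask: RegionMask):
    """Draw (parents, offspring) point sets per ``spec.pattern``.

    Parents are always uniform over the valid region. Offspring placement
    follows the pattern; rejection resampling is capped at 10,000 attempts
    per point, after which a :class:`GenerationFailureError` signals an
    infeasible spec (e.g. an ``r_min`` excluding the whole stroma).
    """
    valid_xy = mask.valid_pixel_coords()
    rng = _rng_for(spec, "points")

    parents = _uniform_in_mask(rng, valid_xy, spec.n_parents)

    n = spec.n_offspring
    if spec.pattern == "csr" or n == 0:
        offspring = _uniform_in_mask(rng, valid_xy, n)
    elif spec.pattern == "attracted":
        if spec.n_parents == 0:
            raise GenerationFailureError("attracted pattern needs parents")
        offspring = np.empty((n, 2))
        pending = np.arange(n)
        for _ in range(_REJECTION_CAP):
            m = len(pending)
            pick = rng.integers(0, spec.n_parents, size=m)
            cand = parents[pick] + rng.normal(0.0, spec.sigma_c, size=(m, 2))
            ok = _inside(mask, cand)
            offspring[pending[ok]] = cand[ok]
            pending = pending[~ok]
            if len(pending) == 0:
                break
        else:
            raise GenerationFailureError(
                f"could not place {len(pending)} attracted offspring within "
                f"{_REJECTION_CAP} attempts"
            )
    else:  # inhibited
        offspring = np.empty((n, 2))
        pending = np.arange(n)
        for _ in range(_REJECTION_CAP):
            m = len(pending)
            cand = _uniform_in_mask(rng, valid_xy, m)
            if spec.n_parents:
                dx = cand[:, None, 0] - parents[None, :, 0]
                dy = cand[:, None, 1] - parents[None, :, 1]
                ok = (dx * dx + dy * dy).min(axis=1) >= spec.r_min**2
            else:
                ok = np.ones(m, dtype=bool)
            offspring[pending[ok]] = cand[ok]
            pending = pending[~ok]
            if len(pending) == 0:
                break
        else:
            raise GenerationFailureError(
                f"could not place {len(pending)} inhibited offspring within "
                f"{_REJECTION_CAP} attempts"
            )

    parent_set = PointSet(parents, cell_class="reference",
                          sample_id=f"sim-{spec.seed}",
                          provenance="simulated")
    offspring_set = PointSet(offspring, cell_class="query",
                             sample_id=f"sim-{spec.seed}",
                             provenance="simulated")
    return parent_set, offspring_set


def render_image(points: PointSet, spec: SyntheticSpec,
                 channel_name: str = "query") -> ChannelImage:
    """Render points as Gaussian PSF spots on a constant background.

    Each point contributes ``amplitude * exp(-r^2 / (2 spot_sigma^2))``;
    spots are truncated at 5 sigma. Noise (per ``spec.noise_model``) is
    seeded from ``spec.seed`` and the channel name, so the two channels of
    one sample get independent noise.
    """
    h, w = spec.shape
    img = np.full((h, w), float(spec.background))
    s = float(spec.spot_sigma)
    half = max(1, int(np.ceil(5 * s)))
    for x, y in points.coords:
        x0 = max(0, int(np.floor(x)) - half)
        x1 = min(w, int(np.ceil(x)) + half + 1)
        y0 = max(0, int(np.floor(y)) - half)
        y1 = min(h, int(np.ceil(y)) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        ys = np.arange(y0, y1, dtype=float)[:, None]
        xs = np.arange(x0, x1, dtype=float)[None, :]
        img[y0:y1, x0:x1] += spec.amplitude * np.exp(
            -((xs - x) ** 2 + (ys - y) ** 2) / (2 * s * s)
        )
    rng = _rng_for(spec, f"render:{channel_name}")
    if spec.noise_model == "poisson":
        img = rng.poisson(img).astype(np.float64)
    elif spec.noise_model == "gaussian":
        img = img + rng.normal(0.0, max(spec.read_noise_sd, 1.0), img.shape)
    if spec.read_noise_sd > 0 and spec.noise_model != "gaussian":
        img = img + rng.normal(0.0, spec.read_noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    return ChannelImage(pixels=img, channel_name=channel_name,
                        sample_id=points.sample_id)


def generate_sample(spec: SyntheticSpec):
    """Mask, point sets and rendered two-channel images for one sample.

    Returns a dict with keys ``mask``, ``parents``, ``offspring``,
    ``parent_image``, ``offspring_image`` and ``spec``.
    """
    mask = generate_mask(spec)
    parents, offspring = generate_points(spec, mask)
    return {
        "mask": mask,
        "parents": parents,
        "offspring": offspring,
        "parent_image": render_image(parents, spec, channel_name="reference"),
        "offspring_image": render_image(offspring, spec,
                                        channel_name="query"),
        "spec": spec,
    }
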