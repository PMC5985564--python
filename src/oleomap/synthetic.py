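"""Synthetic root-slice images with ground truth.

Emulates what the pipeline sees in real composed fluorescence images of
valerian root cross-sections: a roughly circular-to-oval tissue disk with
an irregular closed edge (low-order Fourier perturbation of a circle),
faint tissue autofluorescence against a black frame, bright round oil
droplets whose radial placement follows per-class expectations (a
droplet-poor central cylinder, a droplet-rich outer cell layer), plus
Gaussian sensor noise and sparse salt pixels. Every droplet carries its
true position, relative distance and class, so each pipeline stage can be
scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import SyntheticSpecError
from .geometry import N_CLASSES

__all__ = [
    "SyntheticSliceSpec",
    "GroundTruthDroplet",
    "SyntheticSlice",
    "generate_contour",
    "place_droplets",
    "render_slice",
    "generate_slice",
    "simulate_batch",
    "DEFAULT_LAMBDAS",
]

#: Per-class expected droplet counts. Sum 280 matches the order of
#: magnitude of droplets per real slice; classes 1–2 nearly empty
#: (central cylinder), class 9 holds ~43% of the total (outer cell layers).
DEFAULT_LAMBDAS = (1.0, 3.0, 12.0, 17.0, 22.0, 28.0, 35.0, 42.0, 120.0)


@dataclass(frozen=True)
class SyntheticSliceSpec:
    """All knobs of one synthetic slice; ``seed`` fixes every random draw."""

    size: int = 768  # square image side, px
    mean_radius: float = 300.0  # mean edge radius R, px
    #: Fourier amplitudes a_j (fractions of R) for harmonics j = 2..6;
    #: sum of |a_j| must stay < 0.35 to keep the contour star-shaped.
    amplitudes: tuple[float, ...] = (0.08, 0.05, 0.03, 0.0, 0.0)
    center_offset: tuple[float, float] = (0.0, 0.0)  # center shift from image middle, px
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS  # per-class expected counts
    droplet_radius: tuple[float, float] = (3.0, 6.0)  # px, uniform range
    droplet_peak: float = 255.0
    background: float = 20.0  # tissue autofluorescence level
    noise_sd: float = 8.0  # additive Gaussian noise
    salt_density: float = 2e-5  # fraction of pixels set to bright salt
    n_contour_points: int = 1440
    scale: float = 2.0  # µm per px, metadata passthrough
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise SyntheticSpecError("image size must be >= 64 px")
        if sum(abs(a) for a in self.amplitudes) >= 0.35:
            raise SyntheticSpecError("sum of |a_j| must be < 0.35 (star-shape bound)")
        if len(self.lambdas) != N_CLASSES or any(l < 0 for l in self.lambdas):
            raise SyntheticSpecError("lambdas must be 9 non-negative values")
        if not 0 < self.droplet_radius[0] <= self.droplet_radius[1]:
            raise SyntheticSpecError("invalid droplet radius range")
        if not (0 <= self.background <= 255 and 0 < self.droplet_peak <= 255):
            raise SyntheticSpecError("intensities must lie in [0, 255]")
        if self.n_contour_points < 720:
            raise SyntheticSpecError("contour needs >= 720 sample points")

    @property
    def center(self) -> tuple[float, float]:
        mid = (self.size - 1) / 2.0
        return mid + self.center_offset[0], mid + self.center_offset[1]


@dataclass(frozen=True)
class GroundTruthDroplet:
    x: float
    y: float
    radius: float
    pp: float
    class_index: int


@dataclass
class SyntheticSlice:
    """One rendered slice bundle: image, true masks and ground truth."""

    spec: SyntheticSliceSpec
    image: np.ndarray  # uint8 (H, W)
    contour: np.ndarray  # (N, 2) x-y polygon
    inside_mask: np.ndarray  # bool (H, W), true tissue support
    droplets: list[GroundTruthDroplet]

    @property
    def center(self) -> tuple[float, float]:
        return self.spec.center


def _radius_profile(spec: SyntheticSliceSpec, thetas: np.ndarray, phases: np.ndarray) -> np.ndarray:
    r = np.ones_like(thetas)
    for j, (a, ph) in enumerate(zip(spec.amplitudes, phases), start=2):
        r += a * np.cos(j * thetas + ph)
    return spec.mean_radius * r


def generate_contour(
    spec: SyntheticSliceSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Closed star-shaped polygon r(θ) = R·(1 + Σ a_j cos(jθ + φ_j)).

    Phases φ_j come from the seeded generator; the polygon is sampled at
    ``spec.n_contour_points`` angles and is star-shaped about the true
    center by the amplitude bound.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=len(spec.amplitudes))
    thetas = np.linspace(0.0, 2.0 * math.pi, spec.n_contour_points, endpoint=False)
    r = _radius_profile(spec, thetas, phases)
    cx, cy = spec.center
    return np.stack([cx + r * np.cos(thetas), cy + r * np.sin(thetas)], axis=1)


def _contour_radius_at(contour: np.ndarray, center: tuple[float, float], phi: np.ndarray) -> np.ndarray:
    """Nearest-vertex radius lookup (contour is star-shaped and dense)."""
    rel = contour - np.asarray(center)
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * math.pi)
    order = np.argsort(ang)
    ang_s = ang[order]
    rad_s = np.hypot(rel[:, 0], rel[:, 1])[order]
    idx = np.searchsorted(ang_s, np.mod(phi, 2.0 * math.pi))
    idx_lo = (idx - 1) % ang_s.size
    idx_hi = idx % ang_s.size
    d_lo = np.abs(np.mod(phi, 2 * math.pi) - ang_s[idx_lo])
    d_hi = np.abs(ang_s[idx_hi] - np.mod(phi, 2 * math.pi))
    return np.where(d_lo <= d_hi, rad_s[idx_lo], rad_s[idx_hi])


def place_droplets(
    spec: SyntheticSliceSpec,
    contour: np.ndarray,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> list[GroundTruthDroplet]:
    """Draw droplets class by class with controlled relative positions.

    Per class k the count is Poisson(λ_k); each droplet draws a uniform
    angle, a pp uniform within the class sub-interval, and sits at
    center + direction(φ)·(pp/100)·r_CE(φ). A minimum center separation
    of 2·max droplet radius is enforced by rejection.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cx, cy = spec.center
    min_sep = 2.0 * spec.droplet_radius[1]
    placed_xy: list[tuple[float, float]] = []
    droplets: list[GroundTruthDroplet] = []
    width = 100.0 / N_CLASSES
    for k in range(1, N_CLASSES + 1):
        n_k = int(rng.poisson(spec.lambdas[k - 1]))
        for _ in range(n_k):
            for _attempt in range(max_retries):
                phi = rng.uniform(0.0, 2.0 * math.pi)
                pp = rng.uniform((k - 1) * width, k * width)
                r_ce = float(_contour_radius_at(contour, spec.center, np.array([phi]))[0])
                x = cx + math.cos(phi) * pp / 100.0 * r_ce
                y = cy + math.sin(phi) * pp / 100.0 * r_ce
                if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in placed_xy):
                    break
            else:
                raise SyntheticSpecError(
                    f"cannot place droplet in class {k} after {max_retries} retries; "
                    "lower the lambdas or shrink the droplets"
                )
            placed_xy.append((x, y))
            radius = rng.uniform(*spec.droplet_radius)
            droplets.append(GroundTruthDroplet(x=x, y=y, radius=radius, pp=pp, class_index=k))
    return droplets


def render_slice(
    spec: SyntheticSliceSpec,
    contour: np.ndarray,
    droplets: list[GroundTruthDroplet],
    rng: np.random.Generator | None = None,
) -> SyntheticSlice:
    """Rasterize the slice: tissue background, Gaussian-profile droplets, noise.

    Droplet intensity is a Gaussian bump of σ = radius/2 at the droplet
    peak, clipped to the tissue support (the cut surface ends at the
    edge). Gaussian noise and salt pixels are added over the whole frame.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]

    # tissue support: pixel centers inside the analytic contour
    cx, cy = spec.center
    dx, dy = xx - cx, yy - cy
    r_pix = np.hypot(dx, dy)
    phi_pix = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
    r_edge = _contour_radius_at(contour, spec.center, phi_pix.ravel()).reshape(n, n)
    inside = r_pix <= r_edge

    img = np.where(inside, spec.background, 0.0)
    for d in droplets:
        rad = int(math.ceil(3.0 * d.radius)) + 1
        x0, x1 = max(0, int(d.x) - rad), min(n, int(d.x) + rad + 1)
        y0, y1 = max(0, int(d.y) - rad), min(n, int(d.y) + rad + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
        sigma = d.radius / 2.0
        bump = spec.droplet_peak * np.exp(
            -((sub_x - d.x) ** 2 + (sub_y - d.y) ** 2) / (2.0 * sigma**2)
        )
        patch = img[y0:y1, x0:x1]
        np.maximum(patch, np.where(inside[y0:y1, x0:x1], bump, patch), out=patch)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.salt_density > 0:
        salt = rng.random(img.shape) < spec.salt_density
        img[salt] = 255.0
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSlice(
        spec=spec, image=image, contour=contour, inside_mask=inside, droplets=droplets
    )


def generate_slice(spec: SyntheticSliceSpec) -> SyntheticSlice:
    """Contour, droplets and rendering from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    contour = generate_contour(spec, rng)
    droplets = place_droplets(spec, contour, rng)
    return render_slice(spec, contour, droplets, rng)


def simulate_batch(
    base_spec: SyntheticSliceSpec,
    out_dir: str | Path,
    n_slices: int = 5,
    metas: list[dict] | None = None,
    image_format: str = "png",
) -> pd.DataFrame:
    """Write a directory of slices: images, edge masks, sidecars, ground truth.

    Per-slice seeds derive from the base seed by fixed offsets
    (``base.seed + index``) so any slice can be regenerated alone. Factor
    labels cycle through clones × fractions × horizons unless ``metas``
    supplies explicit assignments. Returns (and writes) the metadata
    table the pipeline consumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .profiles import FORMED_FRACTIONS, FRACTIONS, HORIZONS  # local import avoids cycle

    # clone varies fastest so even tiny batches span both root classifications
    combos = [
        (ce, rf, hz)
        for hz in HORIZONS
        for rf in FRACTIONS
        for ce in FORMED_FRACTIONS
        if rf in FORMED_FRACTIONS[ce]
    ]
    centers, meta_rows, truth_rows = [], [], []
    for i in range(n_slices):
        sid = f"slice{i:03d}"
        spec = replace(base_spec, seed=int(base_spec.seed) + i)
        sl = generate_slice(spec)
        img_path = out / f"{sid}.{image_format}"
        iio.imwrite(img_path, sl.image)
        iio.imwrite(out / f"{sid}_edge.png", (sl.inside_mask * np.uint8(255)))
        cx, cy = sl.center
        centers.append({"slice_id": sid, "x": cx, "y": cy})
        if metas is not None:
            ce, rf, hz = metas[i]["clone"], metas[i]["fraction"], metas[i]["horizon"]
        else:
            ce, rf, hz = combos[i % len(combos)]
        meta_rows.append(
            {
                "slice_id": sid,
                "image_path": img_path.name,
                "center_path": "centers.csv",
                "clone": ce,
                "fraction": rf,
                "horizon": hz,
                "scale_um_per_px": spec.scale,
            }
        )
        for j, d in enumerate(sl.droplets):
            truth_rows.append(
                {
                    "slice_id": sid,
                    "droplet_id": j,
                    "x": d.x,
                    "y": d.y,
                    "radius_px": d.radius,
                    "pp_true": d.pp,
                    "class_true": d.class_index,
                }
            )
    pd.DataFrame(centers).to_csv(out / "centers.csv", index=False)
    truth = pd.DataFrame(
        truth_rows,
        columns=["slice_id", "droplet_id", "x", "y", "radius_px", "pp_true", "class_true"],
    )
    truth.to_csv(out / "ground_truth.csv", index=False)
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "metadata.csv", index=False)
    return meta
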