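"""Synthetic multicolor STED/confocal scene generator with ground truth.

Emulates the statistical structure of two-color STED imaging of peroxisomes:
punctate organelles 130–650 nm in diameter, a confocal matrix-marker channel
(GFP-SCP2) filling organelle interiors, one or two STED membrane-protein
channels whose staining is either dot-like (protein fills a sub-resolution
organelle) or ring-/ellipse-like (2-px rim annulus carrying Gaussian angular
domains), an optional filamentous off-target channel mimicking mitochondrial
TOM20, Gaussian PSF blur (confocal ~250 nm FWHM, STED <60 nm FWHM) and
Poisson photon noise over a uniform background.

Every scene is bit-reproducible from its :class:`SceneSpec` and carries a
:class:`GroundTruth` record so downstream detection, colocalization and
compartmentalization stages can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ._geometry import fwhm_to_sigma

MATRIX = "matrix"
PROTEIN_A = "protein_a"
PROTEIN_B = "protein_b"
FILAMENT = "filament"

_MORPHOLOGIES = ("dot", "ring", "ellipse")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults describe the imaging conditions this generator emulates:
    20 nm pixels, organelle diameters uniform on 130–650 nm, confocal matrix
    channel at 250 nm FWHM, STED protein channels at 60 nm FWHM.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 20.0
    n_organelles: int = 50
    diameter_range_nm: tuple[float, float] = (130.0, 650.0)
    morphology_mix: dict[str, float] = field(
        default_factory=lambda: {"dot": 0.4, "ring": 0.4, "ellipse": 0.2}
    )
    domain_offset_deg: float = 0.0
    n_domains_per_organelle: int = 1
    psf_fwhm_nm: dict[str, float] = field(
        default_factory=lambda: {MATRIX: 250.0, PROTEIN_A: 60.0, PROTEIN_B: 60.0, FILAMENT: 60.0}
    )
    photon_budget: dict[str, float] = field(
        default_factory=lambda: {MATRIX: 2.0e4, PROTEIN_A: 1.0e4, PROTEIN_B: 1.0e4, FILAMENT: 1.0e4}
    )
    background_rate: float = 0.1
    filament_channel: bool = False
    seed: int = 0
    # generator conveniences (not observables): center spacing so organelles
    # are mutually resolvable, and angular width of membrane domains
    min_separation_nm: float = 900.0
    domain_arc_sigma_nm: float = 80.0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_nm
        if not lo < hi:
            raise ValueError("diameter_range_nm must satisfy min < max")
        if lo < 2.0 * self.pixel_size_nm:
            raise ValueError("organelle diameter below 2 pixels")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        if self.n_domains_per_organelle < 1:
            raise ValueError("n_domains_per_organelle must be >= 1")
        if not 0.0 <= self.domain_offset_deg <= 180.0:
            raise ValueError("domain_offset_deg must lie in [0, 180]")
        if unknown := set(self.morphology_mix) - set(_MORPHOLOGIES):
            raise ValueError(f"unknown morphologies: {sorted(unknown)}")
        tot = sum(self.morphology_mix.values())
        if not math.isclose(tot, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError("morphology_mix proportions must sum to 1")
        for name, v in self.photon_budget.items():
            if not v > 0:
                raise ValueError(f"photon_budget[{name!r}] must be positive")
        for name, v in self.psf_fwhm_nm.items():
            if not v > 0:
                raise ValueError(f"psf_fwhm_nm[{name!r}] must be positive")

    @property
    def channel_names(self) -> list[str]:
        names = [MATRIX, PROTEIN_A, PROTEIN_B]
        if self.filament_channel:
            names.append(FILAMENT)
        return names


@dataclass
class GroundTruth:
    """Per-organelle truth plus any shifts applied to the rendered stack."""

    centers_px: np.ndarray  # (n, 2) float, (row, col)
    diameters_nm: np.ndarray  # (n,)
    morphology: list[str]
    domain_angles_a_deg: np.ndarray  # (n, k)
    domain_angles_b_deg: np.ndarray  # (n, k)
    drift_shift_px: tuple[int, int] = (0, 0)
    chromatic_shift_px: tuple[float, float] = (0.0, 0.0)
    mean_channels: dict[str, np.ndarray] | None = None  # noiseless means, pre-background

    @property
    def n_organelles(self) -> int:
        return len(self.morphology)

    def to_json_dict(self) -> dict:
        return {
            "centers_px": self.centers_px.tolist(),
            "diameters_nm": self.diameters_nm.tolist(),
            "morphology": list(self.morphology),
            "domain_angles_a_deg": self.domain_angles_a_deg.tolist(),
            "domain_angles_b_deg": self.domain_angles_b_deg.tolist(),
            "drift_shift_px": list(self.drift_shift_px),
            "chromatic_shift_px": list(self.chromatic_shift_px),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            centers_px=np.asarray(d["centers_px"], dtype=float).reshape(-1, 2),
            diameters_nm=np.asarray(d["diameters_nm"], dtype=float),
            morphology=list(d["morphology"]),
            domain_angles_a_deg=np.asarray(d["domain_angles_a_deg"], dtype=float),
            domain_angles_b_deg=np.asarray(d["domain_angles_b_deg"], dtype=float),
            drift_shift_px=tuple(d["drift_shift_px"]),
            chromatic_shift_px=tuple(d["chromatic_shift_px"]),
        )


@dataclass
class ImageStack:
    """Registered multichannel 2-D image with pixel size and channel metadata."""

    channels: list[np.ndarray]
    pixel_size_nm: float
    meta: list[dict]  # per channel: {"label": ..., "modality": "confocal"|"sted"}
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for c in self.channels:
            if c.ndim != 2:
                raise ValueError("channels must be 2-D")
            if np.any(c < 0):
                raise ValueError("intensities must be nonnegative")
        if len(self.meta) != len(self.channels):
            raise ValueError("one metadata record per channel required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def channel_index(self, label: str) -> int:
        for i, m in enumerate(self.meta):
            if m["label"] == label:
                return i
        raise KeyError(label)

    def copy(self) -> "ImageStack":
        return ImageStack(
            channels=[c.copy() for c in self.channels],
            pixel_size_nm=self.pixel_size_nm,
            meta=[dict(m) for m in self.meta],
            extra=dict(self.extra),
        )


def _sample_centers(rng: np.random.Generator, spec: SceneSpec, margin: float) -> np.ndarray:
    """Rejection-sample organelle centers with a minimum mutual spacing."""
    h, w = spec.image_size_px
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        raise ValueError("image too small for requested organelles")
    min_sep = spec.min_separation_nm / spec.pixel_size_nm
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < spec.n_organelles:
        tries += 1
        if tries > 20000:
            raise RuntimeError(
                "could not place organelles with the requested spacing; "
                "reduce n_organelles or min_separation_nm"
            )
        cand = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    return np.array(centers).reshape(-1, 2)


def _render_organelle(
    shape: tuple[int, int],
    center: np.ndarray,
    radius_px: float,
    morphology: str,
    angles_deg: np.ndarray,
    arc_sigma_px: float,
    ellipse_ratio: float,
    ellipse_phi_deg: float,
    matrix: bool,
) -> np.ndarray:
    """Unblurred unit-flux pattern of one organelle in one channel.

    Matrix channel and dot morphology: filled disc. Ring/ellipse morphology:
    2-px-wide rim weighted by Gaussian angular domains centered at angles_deg
    (counterclockwise from the +col axis) over a small uniform floor.
    """
    r0, c0 = center
    pad = int(np.ceil(radius_px)) + 3
    rlo, rhi = int(np.floor(r0)) - pad, int(np.floor(r0)) + pad + 1
    clo, chi = int(np.floor(c0)) - pad, int(np.floor(c0)) + pad + 1
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, shape[0]), min(chi, shape[1])
    ys, xs = np.mgrid[rlo:rhi, clo:chi]
    dy = ys - r0
    dx = xs - c0

    out = np.zeros(shape, dtype=float)
    if matrix or morphology == "dot":
        body = (dy**2 + dx**2) <= radius_px**2
        out[rlo:rhi, clo:chi] = body.astype(float)
        return out

    if morphology == "ellipse":
        phi = np.deg2rad(ellipse_phi_deg)
        xr = dx * np.cos(phi) + dy * np.sin(phi)
        yr = -dx * np.sin(phi) + dy * np.cos(phi)
        rho = np.hypot(xr, yr / ellipse_ratio)
    else:  # ring
        rho = np.hypot(dx, dy)
    rim = np.abs(rho - radius_px) <= 1.0  # 2-px-thick rim

    # angle counterclockwise from +col axis; image rows grow downward
    theta = np.arctan2(-dy, dx)
    weight = np.full(theta.shape, 0.05)
    sigma_theta = arc_sigma_px / max(radius_px, 1e-6)  # arc length -> angle
    for a in np.deg2rad(angles_deg):
        dtheta = np.angle(np.exp(1j * (theta - a)))
        weight += np.exp(-0.5 * (dtheta / sigma_theta) ** 2)
    out[rlo:rhi, clo:chi] = rim * weight
    return out


def _render_filament(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Persistent random-walk polyline, 1 px wide, mimicking a mitochondrion."""
    h, w = shape
    img = np.zeros(shape, dtype=float)
    pos = np.array([rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)])
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = 4 * (h + w)
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.15)
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < h and 0 <= c < w):
            heading += np.pi / 2  # bounce off the border
            pos = np.clip(pos, [0, 0], [h - 1, w - 1])
            continue
        img[r, c] += 1.0
    return img


def generate_scene(spec: SceneSpec, include_means: bool = True) -> tuple[ImageStack, GroundTruth]:
    """Render a scene and its ground truth.

    Deterministic for a fixed spec (the seed lives in the spec). Each channel's
    noiseless mean is normalized so its total equals
    ``photon_budget[channel] × n_organelles`` before background is added, then
    Poisson-sampled. A non-finite photon budget renders that channel noiseless
    (the mean itself is returned, scaled to 1000 expected photons/organelle).
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_nm
    h, w = spec.image_size_px

    radii_px_max = spec.diameter_range_nm[1] / 2.0 / px
    sigma_max = fwhm_to_sigma(max(spec.psf_fwhm_nm.values())) / px
    margin = radii_px_max + 3.0 * sigma_max + 10.0

    centers = _sample_centers(rng, spec, margin)
    n = spec.n_organelles
    diameters = rng.uniform(*spec.diameter_range_nm, size=n)
    morphs = list(
        rng.choice(
            _MORPHOLOGIES,
            size=n,
            p=[spec.morphology_mix.get(m, 0.0) for m in _MORPHOLOGIES],
        )
    ) if n else []
    k = spec.n_domains_per_organelle
    base = rng.uniform(0.0, 360.0, size=(n, 1))
    angles_a = (base + 360.0 / k * np.arange(k)[None, :]) % 360.0
    angles_b = (angles_a + spec.domain_offset_deg) % 360.0
    ellipse_ratio = rng.uniform(0.55, 0.85, size=n)
    ellipse_phi = rng.uniform(0.0, 180.0, size=n)

    arc_sigma_px = spec.domain_arc_sigma_nm / px
    means: dict[str, np.ndarray] = {}
    for name in spec.channel_names:
        if name == FILAMENT:
            pattern = _render_filament(rng, (h, w))
            patterns = [pattern] if pattern.sum() > 0 else []
        else:
            patterns = []
            for i in range(n):
                pat = _render_organelle(
                    (h, w),
                    centers[i],
                    diameters[i] / 2.0 / px,
                    morphs[i],
                    angles_a[i] if name != PROTEIN_B else angles_b[i],
                    arc_sigma_px,
                    ellipse_ratio[i],
                    ellipse_phi[i],
                    matrix=(name == MATRIX),
                )
                patterns.append(pat)
        mean = np.zeros((h, w), dtype=float)
        for pat in patterns:
            s = pat.sum()
            if s > 0:
                mean += pat / s
        sigma_px = fwhm_to_sigma(spec.psf_fwhm_nm[name]) / px
        if sigma_px > 0:
            mean = gaussian_filter(mean, sigma_px, mode="constant")
        budget = spec.photon_budget[name]
        target = (budget if np.isfinite(budget) else 1000.0) * max(len(patterns), 1)
        s = mean.sum()
        if s > 0:
            mean *= target / s  # exact flux: budget × n_organelles
        means[name] = mean

    channels: list[np.ndarray] = []
    meta: list[dict] = []
    for name in spec.channel_names:
        mean = means[name] + spec.background_rate
        if np.isfinite(spec.photon_budget[name]):
            img = rng.poisson(mean).astype(np.int64)
        else:
            img = mean.copy()
        channels.append(img)
        meta.append({"label": name, "modality": "confocal" if name == MATRIX else "sted"})

    stack = ImageStack(channels=channels, pixel_size_nm=px, meta=meta)
    gt = GroundTruth(
        centers_px=centers,
        diameters_nm=diameters,
        morphology=morphs,
        domain_angles_a_deg=angles_a,
        domain_angles_b_deg=angles_b,
        mean_channels=means if include_means else None,
    )
    return stack, gt


def true_rim_distance_nm(diameter_nm: float, offset_deg: float) -> float:
    """Arc length along the rim between channel-A and channel-B domain centers."""
    return (diameter_nm / 2.0) * np.deg2rad(offset_deg)


def translate_with_zero_fill(image: np.ndarray, shift_px: tuple[int, int]) -> np.ndarray:
    """Translate content by +shift (rows, cols), filling vacated pixels with 0."""
    s0, s1 = int(shift_px[0]), int(shift_px[1])
    out = np.zeros_like(image)
    h, w = image.shape
    src_r = slice(max(0, -s0), h - max(0, s0))
    src_c = slice(max(0, -s1), w - max(0, s1))
    dst_r = slice(max(0, s0), h + min(0, s0))
    dst_c = slice(max(0, s1), w + min(0, s1))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def apply_known_shift(
    stack: ImageStack, shift_px: tuple[int, int], channel: int, window: int = 18
) -> ImageStack:
    """Translate one channel by a known integer shift (drift-correction fixture).

    Shifts beyond the registration search window are refused: a shift the
    estimator is not allowed to find cannot be used to test it.
    """
    s0, s1 = int(shift_px[0]), int(shift_px[1])
    if abs(s0) > window or abs(s1) > window:
        raise ValueError(f"shift {shift_px} outside ±{window} px search window")
    out = stack.copy()
    out.channels[channel] = translate_with_zero_fill(stack.channels[channel], (s0, s1))
    out.extra.setdefault("applied_shifts", []).append(
        {"channel": channel, "shift_px": [s0, s1]}
    )
    return out


def write_scene(stack: ImageStack, gt: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write a multipage TIFF (one page per channel) and a JSON ground-truth sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff = outdir / "scene.tif"
    data = np.stack([np.asarray(c, dtype=np.float32) for c in stack.channels])
    tifffile.imwrite(tiff, data, photometric="minisblack", metadata=None)
    sidecar = outdir / "scene_ground_truth.json"
    payload = {
        "pixel_size_nm": stack.pixel_size_nm,
        "channels": stack.meta,
        "ground_truth": gt.to_json_dict(),
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return {"tiff": tiff, "sidecar": sidecar}


def read_scene(outdir: str | Path) -> tuple[ImageStack, GroundTruth]:
    import tifffile

    outdir = Path(outdir)
    data = tifffile.imread(outdir / "scene.tif")
    payload = json.loads((outdir / "scene_ground_truth.json").read_text())
    stack = ImageStack(
        channels=[np.asarray(page, dtype=float) for page in data],
        pixel_size_nm=float(payload["pixel_size_nm"]),
        meta=list(payload["channels"]),
    )
    return stack, GroundTruth.from_json_dict(payload["ground_truth"])


def spec_to_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["image_size_px"] = list(spec.image_size_px)
    d["diameter_range_nm"] = list(spec.diameter_range_nm)
    return d


def spec_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    if "image_size_px" in d:
        d["image_size_px"] = tuple(d["image_size_px"])
    if "diameter_range_nm" in d:
        d["diameter_range_nm"] = tuple(d["diameter_range_nm"])
    return SceneSpec(**d)
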