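"""End-to-end orchestration: simulate/load → register → detect → quantify.

One input image (or synthetic scene) is one cell; per-cell statistics
aggregate within it. Stage order is fixed — corrections first, detection on
the corrected matrix channel, then the intensity, morphology, colocalization
and compartmentalization stages all consume the corrected stack. Every output
CSV carries the config hash, and a rerun with identical config and seed
reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import coloc_histograms
from .compartments import compartmentalization_table
from .corrections import CorrectionTransform, apply_correction
from .detection import build_exclusion_mask, find_maxima, make_random_regions, make_regions
from .intensity import cell_correlation, integrate_regions, normalized_histogram
from .morphology import circle_reference, region_cluster_shapes
from .scene import (
    ImageStack,
    SceneSpec,
    generate_scene,
    read_scene,
    spec_from_dict,
    spec_to_dict,
)
from ._geometry import disc_mask
from .coloc import extract_patch

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters with their standard defaults.

    Defaults: detection smoothing σ=2.0, noise tolerance 10, region diameter
    19 px (380 nm), random-region radius 180 px, drift search window 18 px,
    patch smoothing σ=1.0, maxima retention 50%, 25 intensity bins.
    """

    scene: SceneSpec | None = None
    input_dir: str | None = None
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"matrix": 0, "protein_a": 1, "protein_b": 2}
    )
    sigma: float = 2.0
    noise_tolerance: float = 10.0
    diameter_px: int = 19
    random_radius_px: float = 180.0
    drift_window_px: int = 18
    patch_sigma: float = 1.0
    retain_frac: float = 0.5
    outdir: str = "peroxiquant_out"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if "matrix" not in self.channel_roles:
            raise ValueError("channel_roles must include 'matrix'")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel roles must map to distinct channels")
        if self.scene is None and self.input_dir is None:
            raise ValueError("either a SceneSpec or an input directory is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = spec_to_dict(self.scene)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scene") is not None:
            d["scene"] = spec_from_dict(d["scene"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("make_figures", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict[str, int]
    flagged: dict[str, int]
    manifest: list[str]
    version: str
    config: dict
    config_hash: str
    timings_s: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=float))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: list[str] = []
    counts: dict[str, int] = {}
    flagged: dict[str, int] = {}
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    def fail(stage: str, err: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # --- load or simulate ------------------------------------------------
    try:
        if config.scene is not None:
            stack, gt = generate_scene(config.scene)
        else:
            stack, gt = read_scene(config.input_dir)
    except Exception as e:
        raise fail("input", e)
    counts["channels"] = len(stack.channels)
    counts["ground_truth_organelles"] = gt.n_organelles
    tick("input")

    # --- corrections ------------------------------------------------------
    # A single synthetic acquisition is self-registered; the identity
    # transform is applied so downstream stages consume the corrected stack.
    try:
        transform = CorrectionTransform(search_window_px=config.drift_window_px)
        stack = apply_correction(stack, transform)
    except Exception as e:
        raise fail("corrections", e)
    tick("corrections")

    roles = config.channel_roles
    matrix_ch = roles["matrix"]
    prot_a = roles.get("protein_a")
    prot_b = roles.get("protein_b")

    # --- detection --------------------------------------------------------
    try:
        maxima = find_maxima(
            stack.channels[matrix_ch], sigma=config.sigma, noise_tolerance=config.noise_tolerance
        )
        regions = make_regions(maxima, stack.shape, diameter_px=config.diameter_px)
        exclusion = build_exclusion_mask(
            stack.channels[matrix_ch], sigma=config.sigma, noise_tolerance=config.noise_tolerance
        )
        rng = np.random.default_rng(config.seed)
        random_regions = make_random_regions(
            regions, exclusion, radius_px=config.random_radius_px, seed=rng
        )
    except Exception as e:
        raise fail("detection", e)
    counts["maxima"] = len(maxima)
    counts["regions"] = len(regions)
    counts["random_regions"] = len(random_regions)
    reg_df = pd.DataFrame(
        [
            {
                "center_row": r.center[0],
                "center_col": r.center[1],
                "diameter_px": r.diameter_px,
                "kind": r.kind,
                "source_value": r.source_maximum.value if r.source_maximum else np.nan,
            }
            for r in regions + random_regions
        ]
    )
    p = outdir / "regions.csv"
    _write_csv(reg_df, p, chash)
    manifest.append(p.name)
    tick("detection")

    # --- intensity --------------------------------------------------------
    if prot_a is not None:
        try:
            rows = []
            for label, ch in (("protein_a", prot_a), ("protein_b", prot_b)):
                if ch is None:
                    continue
                pairs = integrate_regions(stack, regions, matrix_ch, ch)
                rnd_pairs = integrate_regions(stack, random_regions, matrix_ch, ch)
                corr = cell_correlation(pairs) if len(pairs) >= 2 else None
                ref_max = max((pr.g for pr in pairs), default=0.0)
                for pr in pairs + rnd_pairs:
                    rows.append(
                        {"protein": label, "region_id": pr.region_id, "kind": pr.kind,
                         "g": pr.g, "r": pr.r}
                    )
                if corr is not None:
                    counts[f"intensity_pairs_{label}"] = corr.n_regions
                if ref_max > 0:
                    hist_p = normalized_histogram([pr.g for pr in pairs], ref_max, "peroxisomal")
                    hist_r = normalized_histogram(
                        [pr.g for pr in rnd_pairs], ref_max, "random"
                    ) if rnd_pairs else None
                    hdf = pd.DataFrame(
                        {
                            "bin_left": hist_p.edges[:-1],
                            "bin_right": hist_p.edges[1:],
                            "count_peroxisomal": hist_p.counts,
                            "count_random": hist_r.counts if hist_r is not None else 0,
                        }
                    )
                    p = outdir / f"intensity_hist_{label}.csv"
                    _write_csv(hdf, p, chash)
                    manifest.append(p.name)
            df = pd.DataFrame(rows)
            p = outdir / "intensity_pairs.csv"
            _write_csv(df, p, chash)
            manifest.append(p.name)
        except Exception as e:
            raise fail("intensity", e)
    tick("intensity")

    # --- morphology -------------------------------------------------------
    if prot_a is not None:
        try:
            dmask = disc_mask(config.diameter_px)
            shapes = []
            for i, reg in enumerate(regions):
                patch = extract_patch(stack.channels[prot_a], reg)
                shapes.extend(
                    region_cluster_shapes(
                        patch, pixel_size_nm=stack.pixel_size_nm, region_id=i, disc=dmask
                    )
                )
            mdf = pd.DataFrame([dataclasses.asdict(s) for s in shapes])
            p = outdir / "morphology_clusters.csv"
            _write_csv(mdf, p, chash)
            manifest.append(p.name)
            counts["morphology_clusters"] = len(shapes)
            if config.make_figures and len(shapes):
                _morphology_figure(mdf, outdir / "morphology_scatter.png")
                manifest.append("morphology_scatter.png")
        except Exception as e:
            raise fail("morphology", e)
    tick("morphology")

    # --- colocalization ---------------------------------------------------
    coloc = None
    if prot_a is not None and prot_b is not None:
        try:
            coloc = coloc_histograms(stack, regions, prot_a, prot_b, random_regions)
            cdf = pd.DataFrame(
                [
                    {"region_id": r.region_id, "variant": r.variant, "pearson": r.pearson}
                    for r in coloc.records
                ]
            )
            p = outdir / "coloc_regions.csv"
            _write_csv(cdf, p, chash)
            manifest.append(p.name)
            hdf = pd.DataFrame(
                {"bin_left": coloc.edges[:-1], "bin_right": coloc.edges[1:]}
                | {f"count_{v}": coloc.histograms[v] for v in coloc.histograms}
            )
            p = outdir / "coloc_hist.csv"
            _write_csv(hdf, p, chash)
            manifest.append(p.name)
            counts["coloc_real_rows"] = sum(1 for r in coloc.records if r.variant == "real")
            flagged.update({f"coloc_{k}": v for k, v in coloc.n_flagged.items()})
            if config.make_figures:
                _coloc_figure(coloc, outdir / "coloc_hist.png")
                manifest.append("coloc_hist.png")
        except Exception as e:
            raise fail("colocalization", e)
    tick("colocalization")

    # --- compartmentalization --------------------------------------------
    if prot_a is not None and prot_b is not None:
        try:
            records, freq, (dedges, redges) = compartmentalization_table(
                stack, regions, prot_a, prot_b,
                sigma=config.patch_sigma, retain_frac=config.retain_frac,
            )
            rdf = pd.DataFrame([dataclasses.asdict(r) for r in records])
            p = outdir / "compartments.csv"
            _write_csv(rdf, p, chash)
            manifest.append(p.name)
            fdf = pd.DataFrame(
                freq,
                index=[f"{a:.2f}" for a in dedges[:-1]],
                columns=[f"{a:.2f}" for a in redges[:-1]],
            )
            p = outdir / "compartments_map.csv"
            with open(p, "w") as fh:
                fh.write(f"# config_sha256={chash}\n")
                fdf.to_csv(fh)
            manifest.append(p.name)
            counts["compartment_records"] = len(records)
            flagged["compartments_invalid"] = len(regions) - len(records)
            if config.make_figures and len(records):
                _compartment_figure(records, outdir / "compartments_map.png")
                manifest.append("compartments_map.png")
        except Exception as e:
            raise fail("compartmentalization", e)
    tick("compartmentalization")

    report = RunReport(
        counts=counts,
        flagged=flagged,
        manifest=manifest,
        version=__version__,
        config=config.to_dict(),
        config_hash=chash,
        timings_s=timings,
    )
    report.to_json(outdir / "report.json")
    logger.info("pipeline complete: %s", counts)
    return report


def _agg() -> None:
    import matplotlib

    matplotlib.use("Agg")


def _morphology_figure(mdf: pd.DataFrame, path: Path) -> None:
    _agg()
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mdf["area_px"], mdf["perimeter_px"], s=8, alpha=0.5, label="clusters")
    d = np.linspace(1, max(np.sqrt(mdf["area_px"].max() * 4 / np.pi), 10), 200)
    perim, area = zip(*(circle_reference(x) for x in d))
    ax.plot(area, perim, "k-", label="circle πd")
    ax.set_xlabel("area (px)")
    ax.set_ylabel("perimeter (px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _coloc_figure(coloc, path: Path) -> None:
    _agg()
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    centers = 0.5 * (coloc.edges[:-1] + coloc.edges[1:])
    styles = {"real": "-", "flip": ":", "random": "--"}
    for variant, counts in coloc.histograms.items():
        ax.plot(centers, counts, styles.get(variant, "-"), label=variant)
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("regions")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _compartment_figure(records, path: Path) -> None:
    _agg()
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [r.avg_interchannel_distance_px for r in records],
        [r.pearson for r in records],
        s=8,
        alpha=0.5,
    )
    ax.set_xlabel("avg interchannel nearest-maxima distance (px)")
    ax.set_ylabel("Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
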