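#!/usr/bin/env python
"""Detect peroxisomes, build matched random regions, and compare intensities.

On a congruent two-color scene: finds the matrix-marker maxima, integrates
both channels over the 19-px regions, reports the per-cell intensity
correlation, and writes the normalized peroxisomal vs random histograms.
Outputs: results/intensity_pairs.csv, results/intensity_hist.csv.
"""

from pathlib import Path

import pandas as pd

from peroxiquant.detection import (
    build_exclusion_mask,
    find_maxima,
    make_random_regions,
    make_regions,
)
from peroxiquant.intensity import cell_correlation, integrate_regions, normalized_histogram
from peroxiquant.scene import SceneSpec, generate_scene

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec = SceneSpec(
        image_size_px=(640, 640),
        n_organelles=40,
        diameter_range_nm=(150.0, 650.0),
        morphology_mix={"dot": 0.4, "ring": 0.4, "ellipse": 0.2},
        min_separation_nm=1100.0,
        seed=23,
    )
    stack, gt = generate_scene(spec)
    maxima = find_maxima(stack.channels[0], sigma=2.0, noise_tolerance=10)
    regions = make_regions(maxima, stack.shape)
    rnd = make_random_regions(
        regions, build_exclusion_mask(stack.channels[0]), radius_px=180, seed=1
    )
    print(f"detected {len(maxima)} maxima ({gt.n_organelles} true organelles); "
          f"{len(regions)} regions, {len(rnd)} random controls")

    pairs = integrate_regions(stack, regions, 0, 1)
    rnd_pairs = integrate_regions(stack, rnd, 0, 1)
    corr = cell_correlation(pairs)
    print(f"per-cell intensity correlation r = {corr.pearson_r:.3f} "
          f"over {corr.n_regions} regions")

    ref = max(p.g for p in pairs)
    h_perox = normalized_histogram([p.g for p in pairs], ref, "peroxisomal")
    h_rand = normalized_histogram([p.g for p in rnd_pairs], ref, "random")
    print(f"histogram: random regions put {h_rand.counts[:2].sum()}/{h_rand.counts.sum()} "
          f"values in the two lowest bins (peroxisomal: {h_perox.counts[:2].sum()})")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"region_id": p.region_id, "kind": p.kind, "g": p.g, "r": p.r}
         for p in pairs + rnd_pairs]
    ).to_csv(OUT / "intensity_pairs.csv", index=False)
    pd.DataFrame(
        {"bin_left": h_perox.edges[:-1], "bin_right": h_perox.edges[1:],
         "count_peroxisomal": h_perox.counts, "count_random": h_rand.counts}
    ).to_csv(OUT / "intensity_hist.csv", index=False)


if __name__ == "__main__":
    main()
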