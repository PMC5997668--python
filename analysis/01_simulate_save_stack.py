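#!/usr/bin/env python
"""Simulate single-aggregate ThT movies for three aggregation stages.

Emulates the qualitative progression of an aggregation reaction: early
oligomers (few, dim puncta), late oligomers (more, brighter puncta) and a
fibril-containing endpoint (puncta plus micron-scale fibrils).  Writes one
100-frame 16-bit TIFF per condition plus the ground-truth emitter tables.
"""

import json
from pathlib import Path

from colocq import CameraModel, generate_scene, render_stack
from colocq import io as cio

SEED = 1
OUT = Path("results/save")

CONDITIONS = {
    # name: (n_points, n_fibrils, photon_range)
    "early_oligomers": (12, 0, (40.0, 80.0)),
    "late_oligomers": (25, 0, (60.0, 140.0)),
    "fibrils": (10, 3, (80.0, 160.0)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    camera = CameraModel(read_noise_adu=5.0)
    for k, (name, (n_points, n_fibrils, photons)) in enumerate(CONDITIONS.items()):
        scene = generate_scene(
            n_points, n_fibrils, fwhm_nm=320.0, photon_range=photons,
            field_size=(40_960.0, 40_960.0), seed=SEED + k,
        )
        stack = render_stack(scene, camera, n_frames=100, seed=SEED + 100 + k)
        cio.write_stack(stack, OUT / f"{name}.tif")
        (OUT / f"{name}.truth.json").write_text(
            json.dumps(
                {
                    "seed": SEED + k,
                    "n_points": n_points,
                    "n_fibrils": n_fibrils,
                    "emitters": scene.emitters.to_dict(orient="list"),
                },
                indent=2,
                sort_keys=True,
            )
        )
        print(
            f"{name}: {scene.n_emitters} emitters "
            f"({n_fibrils} fibrils) -> {OUT / (name + '.tif')} "
            f"({stack.n_frames} frames, {stack.frame_shape[0]}x{stack.frame_shape[1]} px)"
        )


if __name__ == "__main__":
    main()
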