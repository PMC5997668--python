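"""Run configuration and the end-to-end pipeline.

``run_pipeline`` composes the stages in their canonical order — SAVE stack
analysis for image input; precision filter -> DBSCAN -> FRC -> coincidence
for two-channel localization input — writing every intermediate plus a
provenance log (parameters, seed, versions, record counts per stage).
Reruns with identical config and seed produce byte-identical result JSON.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .coincidence import coincidence_analysis
from .paint_locs import dbscan_filter, filter_by_precision, frc_resolution
from .save_imaging import SaveConfig, analyze_stack

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    Method-defining constants (160 nm pixel, 5 SD detection, 50 nm precision
    cutoff, 135 nm DBSCAN radius, >20 cluster size, FRC threshold 1/7) are
    defaults here, never hard-coded downstream.
    """

    seed: int = 0
    out_dir: str = "results"
    # SAVE stage
    stack_path: str | None = None
    pixel_nm: float = 160.0
    k_sd: float = 5.0
    kernel_px: int = 21
    window_px: int = 15
    # localization stages
    locs_a_path: str | None = None
    locs_b_path: str | None = None
    roi: tuple[float, float, float, float] | None = None
    precision_cutoff_nm: float = 50.0
    eps_nm: float = 135.0
    min_cluster_size: int = 20
    render_pixel_nm: float = 10.0
    frc_threshold: float = 1.0 / 7.0
    n_reps: int = 100

    def __post_init__(self) -> None:
        for name in (
            "pixel_nm",
            "k_sd",
            "precision_cutoff_nm",
            "eps_nm",
            "render_pixel_nm",
            "frc_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_px % 2 == 0 or self.kernel_px < 3:
            raise ValueError("kernel_px must be odd and >= 3")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.roi is not None:
            self.roi = tuple(float(v) for v in self.roi)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["roi"] is not None:
            d["roi"] = list(d["roi"])
        return d


def _filter_channel(table, cfg: RunConfig, stages: list[dict], name: str):
    n0 = len(table)
    table = filter_by_precision(table, cfg.precision_cutoff_nm)
    stages.append({"stage": f"precision_filter_{name}", "rows_in": n0, "rows_out": len(table)})
    n1 = len(table)
    table, _ = dbscan_filter(table, cfg.eps_nm, cfg.min_cluster_size)
    stages.append({"stage": f"dbscan_filter_{name}", "rows_in": n1, "rows_out": len(table)})
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config provides inputs for.

    Returns the result bundle (also written to ``out_dir``): SAVE detections
    and histograms when a stack is given; filtered tables, per-channel FRC
    and the coincidence result when both localization channels are given.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    results: dict = {"config": config.to_dict(), "colocq_version": __version__}

    if config.stack_path is not None:
        stack = cio.read_stack(config.stack_path, pixel_nm=config.pixel_nm)
        save_cfg = SaveConfig(
            kernel_px=config.kernel_px, k_sd=config.k_sd, window_px=config.window_px
        )
        save_res = analyze_stack(stack, save_cfg)
        save_res.detections.to_csv(out / "detections.csv", index=False)
        cio.write_json(
            {"fwhm": save_res.fwhm_hist, "integrated_intensity": save_res.intensity_hist},
            out / "histograms.json",
        )
        stages.append(
            {
                "stage": "save_detect",
                "rows_in": save_res.n_candidates,
                "rows_out": int(len(save_res.detections)),
            }
        )
        results["save"] = {
            "n_candidates": save_res.n_candidates,
            "n_detections": int(len(save_res.detections)),
            "n_failed_fits": save_res.n_failed_fits,
        }

    if config.locs_a_path is not None and config.locs_b_path is not None:
        table_a = cio.read_localizations(config.locs_a_path, "A", roi=config.roi)
        table_b = cio.read_localizations(config.locs_b_path, "B", roi=config.roi)
        table_a = _filter_channel(table_a, config, stages, "a")
        table_b = _filter_channel(table_b, config, stages, "b")
        cio.write_localizations(table_a, out / "filtered_a.csv")
        cio.write_localizations(table_b, out / "filtered_b.csv")

        frc_block = {}
        for name, table in (("a", table_a), ("b", table_b)):
            res = frc_resolution(
                table,
                render_pixel_nm=config.render_pixel_nm,
                threshold=config.frc_threshold,
                seed=config.seed,
            )
            frc_block[name] = {
                "resolution_nm": res.resolution_nm,
                "defined": res.defined,
            }
        results["frc"] = frc_block

        roi = config.roi if config.roi is not None else table_b.bounds()
        coinc = coincidence_analysis(
            table_a, table_b, roi=roi, n_reps=config.n_reps, seed=config.seed
        )
        stages.append({"stage": "coincidence", "rows_in": coinc.A, "rows_out": coinc.C})
        results["coincidence"] = {
            "A": coinc.A,
            "C": coinc.C,
            "E": coinc.E,
            "E_sd": coinc.E_sd,
            "Q": None if np.isnan(coinc.Q) else coinc.Q,
            "percent_coloc": coinc.percent_coloc,
            "n_reps": coinc.n_reps,
        }

    results["provenance"] = {
        "seed": config.seed,
        "versions": {
            "colocq": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": stages,
    }
    cio.write_json(results, out / "result.json")
    return results
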