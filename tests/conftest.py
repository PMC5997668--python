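"""Shared synthetic-data builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from colocq import LocalizationTable


def make_table(
    x: np.ndarray,
    y: np.ndarray,
    precision,
    roi=None,
    channel: str = "A",
) -> LocalizationTable:
    """Build a LocalizationTable from bare coordinate arrays."""
    x = np.asarray(x, dtype=float)
    precision = np.broadcast_to(np.asarray(precision, dtype=float), x.shape)
    df = pd.DataFrame(
        {
            "frame": np.zeros(len(x), dtype=int),
            "x_nm": x,
            "y_nm": np.asarray(y, dtype=float),
            "precision_nm": precision,
            "photons": np.full(len(x), 1000),
        }
    )
    return LocalizationTable(df=df, channel_id=channel, roi=roi)


def spot_field(
    seed: int,
    n_spots: int = 15,
    size_px: int = 512,
    amplitude: float = 20.0,
    noise_sd: float = 1.0,
    sigma_px: float = 1.3,
    baseline: float = 100.0,
):
    """A noisy field of well-separated Gaussian spots plus truth positions.

    Spot amplitude is expressed in units of the noise SD (default 20x), the
    regime where detection should be essentially certain.
    """
    rng = np.random.default_rng(seed)
    img = rng.normal(0.0, noise_sd, (size_px, size_px))
    gx, gy = np.meshgrid(
        np.arange(30, size_px - 30, 120), np.arange(30, size_px - 30, 120)
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:n_spots]
    pts += rng.uniform(-10, 10, pts.shape)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    for px, py in pts:
        img += amplitude * noise_sd * np.exp(
            -(((xx + 0.5) - px) ** 2 + ((yy + 0.5) - py) ** 2) / (2 * sigma_px**2)
        )
    return np.clip(img + baseline, 0, None), pts


def structured_table(
    sigma_nm: float,
    seed: int,
    n_locs: int = 10_000,
    n_sites: int = 60,
    extent_nm: float = 5000.0,
) -> LocalizationTable:
    """Localizations scattered around fixed emitter sites.

    The per-localization scatter ``sigma_nm`` plays the role of localization
    error, so the achievable image resolution degrades as it grows.
    """
    rng = np.random.default_rng(seed)
    sites = rng.uniform(500, extent_nm - 500, (n_sites, 2))
    idx = rng.integers(0, n_sites, n_locs)
    pos = np.clip(sites[idx] + rng.normal(0, sigma_nm, (n_locs, 2)), 0, extent_nm)
    return make_table(
        pos[:, 0], pos[:, 1], sigma_nm, roi=(0.0, 0.0, extent_nm, extent_nm)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
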