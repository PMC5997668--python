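"""Post-processing of DNA-PAINT localization tables.

A localization table is the product of fitting single-molecule emission
events frame by frame: each record carries a position (nm), the fitting
precision (nm, the standard deviation of the fitted position), the frame
index and the photon count.  The chain implemented here retains well-fit
localizations (precision cutoff), discards spurious isolated localizations
with DBSCAN (a cluster-size rule on top of the density clustering), renders
super-resolved count images, and estimates image resolution by Fourier ring
correlation (FRC) with the 1/7 threshold criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .save_imaging import Image

__all__ = [
    "LocalizationTable",
    "ClusterLabeling",
    "FRCResult",
    "REQUIRED_COLUMNS",
    "filter_by_precision",
    "filter_by_noise_threshold",
    "dbscan_filter",
    "render_localization_image",
    "frc_curve",
    "frc_resolution",
]

#: Columns every localization table must provide.
REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "precision_nm")


@dataclass
class LocalizationTable:
    """Per-channel set of single-molecule localizations.

    ``df`` holds one row per localization with at least the columns
    ``frame, x_nm, y_nm, precision_nm`` (``photons`` and extra columns are
    carried through untouched). ``roi`` is the analysis rectangle
    ``(xmin_nm, ymin_nm, xmax_nm, ymax_nm)``; when omitted it defaults to
    the bounding box of the data where needed.
    """

    df: pd.DataFrame
    channel_id: str = ""
    roi: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        prec = np.asarray(self.df["precision_nm"], dtype=float)
        if len(prec) and np.any(~(prec > 0)):
            bad = int(np.flatnonzero(~(prec > 0))[0])
            raise ValueError(
                f"non-positive precision at row {bad}: {prec[bad]!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def precisions(self) -> np.ndarray:
        return self.df["precision_nm"].to_numpy(dtype=float)

    def bounds(self) -> tuple[float, float, float, float]:
        """The roi if set, else the data bounding box."""
        if self.roi is not None:
            return self.roi
        if len(self.df) == 0:
            return (0.0, 0.0, 0.0, 0.0)
        x = self.df["x_nm"]
        y = self.df["y_nm"]
        return (float(x.min()), float(y.min()), float(x.max()), float(y.max()))

    def subset(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset preserving order, metadata and record contents."""
        return replace(self, df=self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class ClusterLabeling:
    """DBSCAN labels (−1 = noise) and the per-record retention mask."""

    labels: np.ndarray
    retained: np.ndarray


@dataclass
class FRCResult:
    """Fourier ring correlation curve and the resolution it implies.

    ``resolution_nm`` is ``1 / f`` at the first spatial frequency where the
    smoothed curve drops below ``threshold``; ``None`` when the curve never
    crosses (resolution undefined at the rendered pixel size).
    """

    freq_per_nm: np.ndarray
    correlation: np.ndarray
    smoothed: np.ndarray
    threshold: float
    resolution_nm: float | None

    @property
    def defined(self) -> bool:
        return self.resolution_nm is not None


def filter_by_precision(
    table: LocalizationTable, max_precision_nm: float = 50.0
) -> LocalizationTable:
    """Retain localizations with precision <= cutoff (boundary inclusive)."""
    if max_precision_nm <= 0:
        raise ValueError("max_precision_nm must be positive")
    return table.subset(table.precisions <= max_precision_nm)


def filter_by_noise_threshold(
    table: LocalizationTable, threshold: float = 20.0, noise_photons: float = 1.0
) -> LocalizationTable:
    """Minimum-amplitude filter: keep records with photons >= threshold x noise.

    This is an approximate stand-in for the "noise threshold" parameter of
    peak-fitting software, which rejects candidate peaks below a multiple of
    the per-frame noise estimate before fitting. Tables without a photons
    column pass through unchanged.
    """
    if "photons" not in table.df.columns:
        return table
    photons = table.df["photons"].to_numpy(dtype=float)
    return table.subset(photons >= threshold * noise_photons)


def dbscan_filter(
    table: LocalizationTable,
    eps_nm: float = 135.0,
    min_cluster_size: int = 20,
    min_samples: int = 5,
) -> tuple[LocalizationTable, ClusterLabeling]:
    """DBSCAN on (x, y) followed by a strict cluster-size retention rule.

    ``eps_nm`` is the Euclidean neighbourhood radius (one camera pixel,
    135 nm, by convention). Clusters with strictly more than
    ``min_cluster_size`` members are retained; DBSCAN noise and smaller
    clusters are discarded. ``min_samples`` is the DBSCAN core-point
    parameter, distinct from the retention rule.
    """
    if eps_nm <= 0:
        raise ValueError("eps_nm must be positive")
    n = len(table)
    if n == 0:
        empty = ClusterLabeling(labels=np.empty(0, dtype=int), retained=np.empty(0, dtype=bool))
        return table.subset(np.empty(0, dtype=bool)), empty
    labels = DBSCAN(eps=eps_nm, min_samples=min_samples).fit_predict(table.positions)
    retained = np.zeros(n, dtype=bool)
    for lab in np.unique(labels):
        if lab == -1:
            continue
        members = labels == lab
        if int(members.sum()) > min_cluster_size:
            retained[members] = True
    return table.subset(retained), ClusterLabeling(labels=labels, retained=retained)


def render_localization_image(
    table: LocalizationTable, render_pixel_nm: float
) -> Image:
    """2D count histogram of localizations over the table's roi.

    Bins are half-open; the image sums to the number of records that fall
    inside the roi (all of them, when positions respect the roi invariant).
    """
    if render_pixel_nm <= 0:
        raise ValueError("render_pixel_nm must be positive")
    xmin, ymin, xmax, ymax = table.bounds()
    nx = max(int(np.ceil((xmax - xmin) / render_pixel_nm)), 1)
    ny = max(int(np.ceil((ymax - ymin) / render_pixel_nm)), 1)
    pos = table.positions
    counts, _, _ = np.histogram2d(
        pos[:, 1] if len(pos) else np.empty(0),
        pos[:, 0] if len(pos) else np.empty(0),
        bins=(ny, nx),
        range=((ymin, ymin + ny * render_pixel_nm), (xmin, xmin + nx * render_pixel_nm)),
    )
    return Image(counts, render_pixel_nm)


def _render_square(pos: np.ndarray, bounds: tuple, pixel_nm: float, n: int) -> np.ndarray:
    xmin, ymin = bounds[0], bounds[1]
    counts, _, _ = np.histogram2d(
        pos[:, 1],
        pos[:, 0],
        bins=(n, n),
        range=((ymin, ymin + n * pixel_nm), (xmin, xmin + n * pixel_nm)),
    )
    return counts


def frc_curve(
    img1: np.ndarray, img2: np.ndarray, pixel_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fourier ring correlation between two equally shaped square images.

    Returns (spatial frequency per nm, correlation per ring). Ring ``k``
    collects Fourier components whose radial index rounds to ``k``; its
    frequency is ``k / (N * pixel_nm)``.
    """
    if img1.shape != img2.shape or img1.shape[0] != img1.shape[1]:
        raise ValueError("FRC requires two square images of identical shape")
    n = img1.shape[0]
    f1 = np.fft.fft2(img1)
    f2 = np.fft.fft2(img2)
    ix = np.fft.fftfreq(n) * n  # integer-valued radial coordinates
    rad = np.sqrt(ix[None, :] ** 2 + ix[:, None] ** 2)
    ring = np.rint(rad).astype(int).ravel()
    n_rings = n // 2 + 1
    keep = ring < n_rings
    ring = ring[keep]
    num = np.bincount(ring, weights=(f1 * np.conj(f2)).real.ravel()[keep], minlength=n_rings)
    d1 = np.bincount(ring, weights=(np.abs(f1) ** 2).ravel()[keep], minlength=n_rings)
    d2 = np.bincount(ring, weights=(np.abs(f2) ** 2).ravel()[keep], minlength=n_rings)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    freq = np.arange(n_rings) / (n * pixel_nm)
    return freq, corr


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average; shrinks the window near the edges."""
    if width <= 1:
        return x.copy()
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def frc_resolution(
    table: LocalizationTable,
    render_pixel_nm: float = 10.0,
    threshold: float = 1.0 / 7.0,
    seed: int = 0,
    smooth_bins: int = 7,
    min_records: int = 100,
) -> FRCResult:
    """FRC resolution of a localization table by seeded random half-splitting.

    The records are split uniformly at random into two halves, each half is
    rendered on the same square grid, and the ring correlation of the two
    Fourier transforms is computed.  The curve is smoothed with a centred
    moving average over ``smooth_bins`` frequency bins and the resolution is
    the reciprocal of the first frequency at which the smoothed curve falls
    below ``threshold``.  Identical seed implies identical result; a table
    with fewer than ``min_records`` records, or a curve that never crosses,
    yields ``resolution_nm=None``.
    """
    n = len(table)
    if n < min_records:
        empty = np.empty(0)
        return FRCResult(empty, empty, empty, threshold, None)
    xmin, ymin, xmax, ymax = table.bounds()
    n_px = max(int(np.ceil(max(xmax - xmin, ymax - ymin) / render_pixel_nm)), 2)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    pos = table.positions
    half1 = pos[perm[: n // 2]]
    half2 = pos[perm[n // 2:]]
    bounds = (xmin, ymin)
    img1 = _render_square(half1, bounds, render_pixel_nm, n_px)
    img2 = _render_square(half2, bounds, render_pixel_nm, n_px)
    freq, corr = frc_curve(img1, img2, render_pixel_nm)
    smoothed = _moving_average(corr, smooth_bins)
    below = np.flatnonzero(smoothed[1:] < threshold) + 1  # skip the DC ring
    resolution = float(1.0 / freq[below[0]]) if below.size else None
    return FRCResult(freq, corr, smoothed, threshold, resolution)
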