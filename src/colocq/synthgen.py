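"""Synthetic ground truth for both pipelines.

Two kinds of synthetic data are produced:

* **Image stacks** emulating single-aggregate ThT TIRF movies: diffraction-
  limited puncta (oligomer-like) and micron-scale fibrils rendered as chains
  of emitters, imaged through a Gaussian PSF onto an EMCCD-like camera with
  Poisson photon noise, linear ADU conversion, Gaussian read noise and a
  constant baseline.

* **Two-channel localization tables** with a known association structure: a
  chosen fraction of channel-A localizations carries a channel-B partner,
  the rest of channel B is a uniform background of controlled density, and
  every record carries a fitting precision drawn from a per-channel
  distribution.  The generating association fraction is the ground truth
  that the association quotient Q should recover.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .paint_locs import LocalizationTable
from .save_imaging import FWHM_PER_SIGMA, ImageStack

__all__ = [
    "CameraModel",
    "FibrilSpec",
    "GroundTruthScene",
    "PrecisionModel",
    "ColocConfig",
    "generate_scene",
    "render_stack",
    "generate_coloc_tables",
]


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-like camera calibration.

    Defaults follow a typical single-aggregate TIRF setup: 160 nm pixels,
    250 ADU per detected photon, EM gain 11.5 electrons per ADU.  Read noise
    and baseline are free parameters of the simulation.
    """

    pixel_nm: float = 160.0
    counts_per_photon: float = 250.0
    em_gain_e_per_adu: float = 11.5
    read_noise_adu: float = 10.0
    baseline_adu: float = 100.0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if self.counts_per_photon <= 0:
            raise ValueError("counts_per_photon must be positive")
        if self.read_noise_adu < 0:
            raise ValueError("read_noise_adu must be nonnegative")


@dataclass(frozen=True)
class FibrilSpec:
    """One fibril: a line segment of emitters."""

    x_nm: float  # centre
    y_nm: float
    length_nm: float
    orientation_rad: float
    emitters_per_um: float


@dataclass
class GroundTruthScene:
    """Emitters (points and rasterized fibrils) in a rectangular field.

    ``emitters`` has columns ``x_nm, y_nm, kind, fwhm_nm,
    photons_per_frame, fibril_id`` (fibril_id is −1 for point emitters).
    """

    emitters: pd.DataFrame
    fibrils: list[FibrilSpec] = field(default_factory=list)
    field_size: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        w, h = self.field_size
        e = self.emitters
        if len(e):
            if (e["x_nm"] < 0).any() or (e["x_nm"] > w).any() \
                    or (e["y_nm"] < 0).any() or (e["y_nm"] > h).any():
                raise ValueError("emitter outside field_size")
            if (e["fwhm_nm"] <= 0).any() or (e["photons_per_frame"] <= 0).any():
                raise ValueError("fwhm_nm and photons_per_frame must be positive")

    @property
    def n_emitters(self) -> int:
        return len(self.emitters)


_EMITTER_COLUMNS = ["x_nm", "y_nm", "kind", "fwhm_nm", "photons_per_frame", "fibril_id"]


def generate_scene(
    n_points: int,
    n_fibrils: int,
    fwhm_nm: float,
    photon_range: tuple[float, float],
    field_size: tuple[float, float],
    seed: int,
    fibril_length_range_nm: tuple[float, float] = (1000.0, 5000.0),
    fibril_orientation_rad: float | None = None,
    margin_nm: float | None = None,
) -> GroundTruthScene:
    """Place point emitters and fibrils uniformly at random in the field.

    Fibrils are rasterized into emitter chains with spacing ``fwhm_nm / 4``
    (end points included, so the chain spans the full length) and placed so
    the whole segment fits inside the field.  Lengths are drawn uniformly
    from ``fibril_length_range_nm`` — fibrils up to ~5 um occur in mature
    aggregation reactions — and orientations uniformly in [0, pi) unless
    ``fibril_orientation_rad`` pins them.
    """
    if n_points < 0 or n_fibrils < 0:
        raise ValueError("emitter counts must be nonnegative")
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    lo_p, hi_p = photon_range
    if lo_p <= 0 or hi_p < lo_p:
        raise ValueError("photon_range must be positive and ordered")
    w, h = field_size
    if margin_nm is None:
        margin_nm = 2.0 * fwhm_nm
    if n_fibrils > 0 and min(w, h) <= fibril_length_range_nm[1]:
        raise ValueError("field too small for the requested fibril length")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for _ in range(n_points):
        rows.append(
            {
                "x_nm": rng.uniform(margin_nm, w - margin_nm),
                "y_nm": rng.uniform(margin_nm, h - margin_nm),
                "kind": "point",
                "fwhm_nm": fwhm_nm,
                "photons_per_frame": rng.uniform(lo_p, hi_p),
                "fibril_id": -1,
            }
        )
    fibrils: list[FibrilSpec] = []
    spacing = fwhm_nm / 4.0
    for fid in range(n_fibrils):
        length = rng.uniform(*fibril_length_range_nm)
        theta = (
            fibril_orientation_rad
            if fibril_orientation_rad is not None
            else rng.uniform(0, np.pi)
        )
        half_dx = abs(length / 2 * np.cos(theta))
        half_dy = abs(length / 2 * np.sin(theta))
        cx = rng.uniform(half_dx + margin_nm, w - half_dx - margin_nm)
        cy = rng.uniform(half_dy + margin_nm, h - half_dy - margin_nm)
        emitters_per_um = 1000.0 / spacing
        fibrils.append(FibrilSpec(cx, cy, length, theta, emitters_per_um))
        n_seg = int(np.ceil(length / spacing))
        t = np.linspace(-length / 2, length / 2, n_seg + 1)
        photons = rng.uniform(lo_p, hi_p)
        for ti in t:
            rows.append(
                {
                    "x_nm": cx + ti * np.cos(theta),
                    "y_nm": cy + ti * np.sin(theta),
                    "kind": "fibril",
                    "fwhm_nm": fwhm_nm,
                    "photons_per_frame": photons,
                    "fibril_id": fid,
                }
            )
    emitters = pd.DataFrame(rows, columns=_EMITTER_COLUMNS)
    if len(emitters):
        emitters["fibril_id"] = emitters["fibril_id"].astype(int)
    return GroundTruthScene(emitters=emitters, fibrils=fibrils, field_size=field_size)


def _expected_photon_image(
    scene: GroundTruthScene, pixel_nm: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixel-integrated Gaussian PSF rendering (expected photons per frame).

    Each emitter contributes ``photons * [Phi(hi)-Phi(lo)]_x [Phi(hi)-Phi(lo)]_y``
    over a window of +-5 sigma; truncation outside the window loses < 0.01%
    of the photon budget. Emitters whose PSF extends past the field edge are
    silently clipped.
    """
    ny, nx = shape
    img = np.zeros(shape)
    root2 = np.sqrt(2.0)
    for rec in scene.emitters.itertuples(index=False):
        sigma_px = (rec.fwhm_nm / FWHM_PER_SIGMA) / pixel_nm
        x_px = rec.x_nm / pixel_nm
        y_px = rec.y_nm / pixel_nm
        halfw = 5.0 * sigma_px
        c0 = max(int(np.floor(x_px - halfw)), 0)
        c1 = min(int(np.ceil(x_px + halfw)) + 1, nx)
        r0 = max(int(np.floor(y_px - halfw)), 0)
        r1 = min(int(np.ceil(y_px + halfw)) + 1, ny)
        if c0 >= c1 or r0 >= r1:
            continue  # fully outside the field: clipped
        ex = np.arange(c0, c1 + 1)
        ey = np.arange(r0, r1 + 1)
        fx = 0.5 * (1 + special.erf((ex - x_px) / (root2 * sigma_px)))
        fy = 0.5 * (1 + special.erf((ey - y_px) / (root2 * sigma_px)))
        img[r0:r1, c0:c1] += rec.photons_per_frame * np.outer(np.diff(fy), np.diff(fx))
    return img


def render_stack(
    scene: GroundTruthScene,
    camera: CameraModel,
    n_frames: int,
    seed: int,
) -> ImageStack:
    """Render a movie of the scene through the camera model.

    Per frame: expected photons per pixel -> Poisson sample -> ADU via
    ``counts_per_photon`` -> plus baseline and Gaussian read noise, clipped
    at zero.  The excess-noise factor of electron multiplication is not
    modelled (the shot-noise/readout structure, not camera physics, is what
    downstream fitting is exercised against).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    w, h = scene.field_size
    nx = max(int(np.ceil(w / camera.pixel_nm)), 1)
    ny = max(int(np.ceil(h / camera.pixel_nm)), 1)
    expected = _expected_photon_image(scene, camera.pixel_nm, (ny, nx))
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, ny, nx))
    for k in range(n_frames):
        photons = rng.poisson(expected)
        adu = camera.baseline_adu + photons * camera.counts_per_photon
        if camera.read_noise_adu > 0:
            adu = adu + rng.normal(0.0, camera.read_noise_adu, size=adu.shape)
        frames[k] = np.clip(adu, 0.0, None)
    return ImageStack(frames, camera.pixel_nm, camera=camera)


@dataclass(frozen=True)
class PrecisionModel:
    """Truncated-normal distribution of localization precisions (nm)."""

    mean_nm: float = 15.0
    sd_nm: float = 3.0
    min_nm: float = 2.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.normal(self.mean_nm, self.sd_nm, size=n)
        # resample below-floor draws rather than clipping, keeping the shape
        bad = draws < self.min_nm
        while bad.any():
            draws[bad] = rng.normal(self.mean_nm, self.sd_nm, size=int(bad.sum()))
            bad = draws < self.min_nm
        return draws


@dataclass
class ColocConfig:
    """Two-channel localization simulation with known association fraction.

    ``coloc_fraction`` of the ``n_a`` channel-A records carry a true channel-B
    partner whose *observed* displacement from the A record is an isotropic
    Gaussian of SD ``partner_offset_nm`` (the paired record's localization
    error is folded into this net offset, so recorded precisions remain the
    coincidence radii).  The rest of channel B is a uniform background of
    ``density_b`` per um^2.  Channel densities are a scaled-down stand-in for
    real acquisitions with >5x10^5 localizations per channel.
    """

    roi: tuple[float, float, float, float] = (0.0, 0.0, 10_000.0, 10_000.0)
    n_a: int = 2000
    density_b: float = 50.0  # per um^2
    coloc_fraction: float = 0.5
    precision_a: PrecisionModel = field(default_factory=PrecisionModel)
    precision_b: PrecisionModel = field(default_factory=PrecisionModel)
    partner_offset_nm: float = 10.0
    n_frames: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_a < 0 or self.density_b < 0:
            raise ValueError("counts and densities must be nonnegative")
        xmin, ymin, xmax, ymax = self.roi
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("roi must have positive area")

    @property
    def area_um2(self) -> float:
        xmin, ymin, xmax, ymax = self.roi
        return (xmax - xmin) * (ymax - ymin) / 1e6


def _table(df: pd.DataFrame, channel: str, roi) -> LocalizationTable:
    return LocalizationTable(df=df.reset_index(drop=True), channel_id=channel, roi=roi)


def generate_coloc_tables(
    cfg: ColocConfig, seed: int
) -> tuple[LocalizationTable, LocalizationTable, np.ndarray]:
    """Generate channel A, channel B and the per-A ground-truth partner flags.

    ``round(coloc_fraction * n_a)`` A records (chosen at random) receive a B
    partner; background B counts are Poisson with mean ``density_b * area``.
    A positions are jittered by their own precision; partner positions are
    displaced from the observed A position by ``partner_offset_nm`` (see
    :class:`ColocConfig`).  All positions are clipped into the roi.
    """
    xmin, ymin, xmax, ymax = cfg.roi
    rng = np.random.default_rng(seed)

    n_a = cfg.n_a
    true_a = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_a, 2))
    prec_a = cfg.precision_a.sample(rng, n_a)
    obs_a = true_a + rng.normal(0.0, 1.0, size=(n_a, 2)) * prec_a[:, None]
    obs_a[:, 0] = np.clip(obs_a[:, 0], xmin, xmax)
    obs_a[:, 1] = np.clip(obs_a[:, 1], ymin, ymax)

    n_true = int(round(cfg.coloc_fraction * n_a))
    flags = np.zeros(n_a, dtype=bool)
    flags[rng.choice(n_a, size=n_true, replace=False)] = True

    partners = obs_a[flags] + rng.normal(0.0, cfg.partner_offset_nm, size=(n_true, 2))
    n_bg = rng.poisson(cfg.density_b * cfg.area_um2)
    background = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_bg, 2))
    prec_bg = cfg.precision_b.sample(rng, n_bg)
    background = background + rng.normal(0.0, 1.0, size=(n_bg, 2)) * prec_bg[:, None]
    pos_b = np.vstack([partners, background]) if n_true + n_bg else np.empty((0, 2))
    prec_b = np.concatenate([cfg.precision_b.sample(rng, n_true), prec_bg])
    if len(pos_b):
        pos_b[:, 0] = np.clip(pos_b[:, 0], xmin, xmax)
        pos_b[:, 1] = np.clip(pos_b[:, 1], ymin, ymax)

    def _frame_photons(n: int) -> tuple[np.ndarray, np.ndarray]:
        frames = rng.integers(0, cfg.n_frames, size=n)
        photons = rng.integers(500, 5000, size=n)
        return frames, photons

    fa, pa = _frame_photons(n_a)
    df_a = pd.DataFrame(
        {
            "frame": fa,
            "x_nm": obs_a[:, 0],
            "y_nm": obs_a[:, 1],
            "precision_nm": prec_a,
            "photons": pa,
            "channel": "A",
        }
    )
    fb, pb = _frame_photons(len(pos_b))
    df_b = pd.DataFrame(
        {
            "frame": fb,
            "x_nm": pos_b[:, 0] if len(pos_b) else np.empty(0),
            "y_nm": pos_b[:, 1] if len(pos_b) else np.empty(0),
            "precision_nm": prec_b,
            "photons": pb,
            "channel": "B",
        }
    )
    return _table(df_a, "A", cfg.roi), _table(df_b, "B", cfg.roi), flags
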