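"""Coordinate-based two-colour co-localization and the association quotient.

A channel-A localization (the aggregate / filament channel) is *coincident*
with channel B (the mitochondrial-marker channel) when the Euclidean
distance between the two positions does not exceed the sum of their fitting
precisions — each point, inflated to a disc of radius equal to its
localization uncertainty, must touch a disc of the other channel.

Because two dense, entirely unrelated point sets produce coincidences by
chance, the raw coincident count C is corrected by an estimate E of the
chance count, obtained by re-running the same coincidence analysis against
simulated marker channels with the same number of localizations (hence the
same density) and the same precision distribution, placed uniformly in the
analysis region.  The association quotient

    Q = (C - E) / (A - E)

is then a chance-corrected fraction of the A (filament) localizations
associated with the marker: Q = 1 when every A localization is coincident,
Q = 0 when coincidences are fully explained by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .paint_locs import LocalizationTable

__all__ = [
    "CoincidenceResult",
    "count_coincident",
    "estimate_chance",
    "association_quotient",
    "coincidence_analysis",
]


@dataclass
class CoincidenceResult:
    """Full output of one co-localization analysis (Q and its ingredients)."""

    A: int
    C: int
    E: float
    E_sd: float
    Q: float
    percent_coloc: float
    per_record_flags: np.ndarray
    n_reps: int
    seed: int

    @property
    def q_defined(self) -> bool:
        return not np.isnan(self.Q)


def _coincident_flags(
    pos_a: np.ndarray,
    prec_a: np.ndarray,
    pos_b: np.ndarray,
    prec_b: np.ndarray,
    tree_a: cKDTree | None = None,
) -> np.ndarray:
    """Boolean flag per A record: has some B within prec_a + prec_b.

    Queries the A-side spatial index from each B point with radius
    ``prec_b + max(prec_a)`` and then applies the exact per-pair radius, so
    the result equals all-pairs evaluation (boundary inclusive).
    """
    flags = np.zeros(len(pos_a), dtype=bool)
    if len(pos_a) == 0 or len(pos_b) == 0:
        return flags
    if tree_a is None:
        tree_a = cKDTree(pos_a)
    rmax_a = float(prec_a.max())
    neighbours = tree_a.query_ball_point(pos_b, r=prec_b + rmax_a)
    for j, idx in enumerate(neighbours):
        if not idx:
            continue
        idx = np.asarray(idx)
        cand = idx[~flags[idx]]
        if cand.size == 0:
            continue
        d = np.hypot(
            pos_a[cand, 0] - pos_b[j, 0], pos_a[cand, 1] - pos_b[j, 1]
        )
        flags[cand[d <= prec_a[cand] + prec_b[j]]] = True
    return flags


def count_coincident(
    table_a: LocalizationTable, table_b: LocalizationTable
) -> tuple[int, np.ndarray]:
    """Count A localizations coincident with at least one B localization.

    Each A record is counted at most once however many B partners it has;
    the contract equals brute-force all-pairs evaluation of
    ``dist(a, b) <= precision(a) + precision(b)``.
    """
    flags = _coincident_flags(
        table_a.positions, table_a.precisions, table_b.positions, table_b.precisions
    )
    return int(flags.sum()), flags


def estimate_chance(
    table_a: LocalizationTable,
    roi: tuple[float, float, float, float],
    b_template: LocalizationTable,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance-coincidence count from density-matched uniform simulations.

    Each replicate places ``len(b_template)`` synthetic marker localizations
    uniformly in ``roi`` with precisions resampled (with replacement) from
    the template channel, and counts coincidences against the real A table.
    Returns the mean count E over replicates and its replicate SD.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    xmin, ymin, xmax, ymax = roi
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("roi must have positive area")
    n_b = len(b_template)
    if n_b == 0:
        return 0.0, 0.0
    pos_a = table_a.positions
    prec_a = table_a.precisions
    tree_a = cKDTree(pos_a) if len(pos_a) else None
    template_prec = b_template.precisions
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps)
    for rep in range(n_reps):
        pos_b = np.column_stack(
            [rng.uniform(xmin, xmax, n_b), rng.uniform(ymin, ymax, n_b)]
        )
        prec_b = rng.choice(template_prec, size=n_b, replace=True)
        flags = _coincident_flags(pos_a, prec_a, pos_b, prec_b, tree_a=tree_a)
        counts[rep] = flags.sum()
    e_sd = float(counts.std(ddof=1)) if n_reps > 1 else 0.0
    return float(counts.mean()), e_sd


def association_quotient(C: float, E: float, A: float, tol: float = 1e-9) -> float:
    """Q = (C - E) / (A - E); NaN when the null saturates (A == E)."""
    if A <= 0:
        raise ValueError("A must be positive")
    if abs(A - E) < tol:
        return float("nan")
    return (C - E) / (A - E)


def coincidence_analysis(
    table_a: LocalizationTable,
    table_b: LocalizationTable,
    roi: tuple[float, float, float, float] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> CoincidenceResult:
    """Full co-localization analysis of two (already filtered) channels.

    Both tables are expected to have passed the precision and DBSCAN
    filters.  ``roi`` defaults to channel B's analysis rectangle (its roi,
    else its bounding box); it is where the simulated marker channel is
    placed uniformly.
    """
    A = len(table_a)
    if A == 0:
        raise ValueError("channel A has no localizations (Q undefined)")
    if roi is None:
        roi = table_b.bounds()
    C, flags = count_coincident(table_a, table_b)
    E, E_sd = estimate_chance(table_a, roi, table_b, n_reps=n_reps, seed=seed)
    Q = association_quotient(C, E, A)
    return CoincidenceResult(
        A=A,
        C=C,
        E=E,
        E_sd=E_sd,
        Q=Q,
        percent_coloc=100.0 * C / A,
        per_record_flags=flags,
        n_reps=n_reps,
        seed=seed,
    )
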