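"""Association profiles (COM distance + spherical angles) and stage
segmentation of piecewise-constant series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import PepmpcError
from ..units import A_PER_NM
from ..structure_model.beads import Trajectory


@dataclass
class AssociationProfile:
    """Per-frame peptide-cluster geometry.

    ``d_com`` in Angstrom; ``theta`` in [0, pi], ``phi`` in (-pi, pi]
    (radians); frames with coincident COMs carry NaN angles.
    """

    times: np.ndarray
    d_com: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    stage_labels: np.ndarray | None = None


def minimum_image(vec: np.ndarray, box_length: float | None) -> np.ndarray:
    """Wrap displacement vectors into the primary periodic image."""
    if box_length is None:
        return vec
    return vec - box_length * np.round(vec / box_length)


def association_profile(traj: Trajectory, peptide_id: str = "peptide",
                        cluster_id: str = "cluster") -> AssociationProfile:
    """COM separation and spherical angles of the peptide around the
    cluster, per frame, with the minimum-image convention applied."""
    pep = traj.molecule(peptide_id)
    clu = traj.molecule(cluster_id)
    vec = pep.mean(axis=1) - clu.mean(axis=1)
    vec = minimum_image(vec, traj.box_length)
    d = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(vec[:, 2] / d, -1.0, 1.0))
        phi = np.arctan2(vec[:, 1], vec[:, 0])
    coincident = d < 1e-12
    theta[coincident] = np.nan
    phi[coincident] = np.nan
    return AssociationProfile(times=traj.times.copy(),
                              d_com=d * A_PER_NM, theta=theta, phi=phi)


def _segment_cost_table(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) per-interval squared-error cost."""
    s1 = np.concatenate([[0.0], np.cumsum(series)])
    s2 = np.concatenate([[0.0], np.cumsum(series**2)])
    return s1, s2


def _interval_cost(s1, s2, i, j) -> float:
    """Squared error of fitting mean over series[i:j] (half-open)."""
    n = j - i
    total = s1[j] - s1[i]
    return float((s2[j] - s2[i]) - total * total / n)


def _best_segmentation(series: np.ndarray, k: int,
                       min_len: int) -> tuple[list[int], float]:
    """Exact dynamic-programming least-squares segmentation into k pieces.

    Returns (breakpoints, cost); breakpoints are start indices of
    segments 2..k.
    """
    n = len(series)
    s1, s2 = _segment_cost_table(series)
    INF = float("inf")
    # cost[m][j]: best cost of fitting series[:j] with m segments
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m * min_len, n + 1):
            best, arg = INF, -1
            lo = (m - 1) * min_len
            hi = j - min_len
            for i in range(lo, hi + 1):
                if cost[m - 1, i] == INF:
                    continue
                c = cost[m - 1, i] + _interval_cost(s1, s2, i, j)
                if c < best:
                    best, arg = c, i
            cost[m, j] = best
            back[m, j] = arg
    if not np.isfinite(cost[k, n]):
        raise PepmpcError("series too short for requested segmentation")
    breaks = []
    j = n
    for m in range(k, 1, -1):
        j = int(back[m, j])
        breaks.append(j)
    return sorted(breaks), float(cost[k, n])


def segment_stages(series, max_segments: int = 3,
                   min_len: int = 5) -> list[int]:
    """Change-point detection for a piecewise-constant noisy series.

    Fits 1..``max_segments`` constant segments by exact least squares and
    selects the segment count by BIC (Gaussian likelihood); returns the
    breakpoints as frame indices (start of each new segment).
    """
    series = np.asarray(series, float)
    n = len(series)
    if max_segments < 1 or min_len < 1:
        raise PepmpcError("max_segments and min_len must be >= 1")
    if n < max_segments * min_len:
        raise PepmpcError("series too short for requested segmentation")
    best_bic, best_breaks = None, []
    for k in range(1, max_segments + 1):
        breaks, cost = _best_segmentation(series, k, min_len)
        sigma2 = max(cost / n, 1e-300)
        # k means + (k-1) breakpoints + variance
        n_params = 2 * k
        bic = n * np.log(sigma2) + n_params * np.log(n)
        if best_bic is None or bic < best_bic - 1e-12:
            best_bic, best_breaks = bic, breaks
    return best_breaks


def label_stages(n_frames: int, breakpoints: list[int]) -> np.ndarray:
    """Integer stage label per frame from an ordered breakpoint list."""
    labels = np.zeros(n_frames, dtype=int)
    for b in breakpoints:
        labels[b:] += 1
    return labels
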