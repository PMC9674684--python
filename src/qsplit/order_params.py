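"""C-D bond order parameters from trajectories and their NMR observables.

The order parameter of a C-D bond is the time average

    S_CD = < (3 cos^2 theta - 1) / 2 >

with theta the angle between the bond and the director (here the bilayer
normal, laboratory z).  In an oriented phase the quadrupolar splitting is
proportional to |S_CD|:

    dnu = (3/2) * chi * |S_CD| * f

where chi is the quadrupolar coupling constant (167 kHz for aliphatic C-D)
and f a geometric factor set by the director orientation relative to the
magnetic field: 1 for parallel, 1/2 for perpendicular (SDS-based mimetics
orient with the director perpendicular to B0, so 1/2 is the default).

A CD3 group spinning fast about its C-C axis scales the deuteron order
parameter by P2(cos 109.47 deg) = -1/3, so the methyl-axis order parameter
offers a second, equivalent route to the same observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvalidParameterError, SelectionError
from .spectra import SplittingSet
from .trajectory import Trajectory

#: default aliphatic C-D quadrupolar coupling constant, Hz
DEFAULT_CHI_HZ = 167_000.0
#: default director-vs-field geometric factor (director perpendicular to B0)
DEFAULT_GEOMETRY_FACTOR = 0.5
#: P2(cos 109.47 deg): fast-rotor scaling of a tetrahedral methyl deuteron
TETRAHEDRAL_FACTOR = -1.0 / 3.0
#: angle where P2 vanishes, degrees
MAGIC_ANGLE_DEG = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))


def p2(cos_theta):
    """Second Legendre polynomial."""
    c = np.asarray(cos_theta, dtype=float)
    return 1.5 * c * c - 0.5


@dataclass(frozen=True)
class BondSelection:
    """Atom-index pairs defining the C-D vectors of one labelled fragment.

    ``pairs`` lists (carbon, deuteron) index pairs; for a CD3 label,
    ``methyl_axis`` optionally names the (Cgamma, Cdelta) pair whose axis
    carries the fast-rotor average.
    """

    fragment: str
    pairs: tuple[tuple[int, int], ...]
    methyl_axis: tuple[int, int] | None = None

    def __post_init__(self):
        pairs = tuple((int(c), int(d)) for c, d in self.pairs)
        if not pairs:
            raise SelectionError(f"fragment {self.fragment!r}: no bond pairs given")
        for c, d in pairs:
            if c == d:
                raise SelectionError(f"fragment {self.fragment!r}: pair ({c}, {d}) is degenerate")
        object.__setattr__(self, "pairs", pairs)
        if self.methyl_axis is not None:
            ax = (int(self.methyl_axis[0]), int(self.methyl_axis[1]))
            if ax[0] == ax[1]:
                raise SelectionError(f"fragment {self.fragment!r}: methyl axis pair is degenerate")
            object.__setattr__(self, "methyl_axis", ax)


@dataclass(frozen=True)
class OrderParameterEstimate:
    fragment: str
    s_cd: float
    stderr: float
    n_frames: int

    def __post_init__(self):
        if not -0.5 - 1e-9 <= self.s_cd <= 1.0 + 1e-9:
            raise InvalidParameterError(f"S_CD = {self.s_cd} outside [-0.5, 1]")
        if self.stderr < 0:
            raise InvalidParameterError("standard error must be >= 0")


def _unit_director(director) -> np.ndarray:
    d = np.asarray(director, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise InvalidParameterError("director must be a non-zero vector")
    return d / norm


def p2_series(
    traj: Trajectory,
    pairs: Sequence[tuple[int, int]],
    director=(0.0, 0.0, 1.0),
) -> np.ndarray:
    """Per-frame P2(cos theta), averaged over the given bond pairs.

    Raises :class:`DegenerateGeometryError` naming the first frame and pair
    whose bond vector has zero length.
    """
    d_hat = _unit_director(director)
    coords = traj.coordinates
    n_atoms = traj.n_atoms
    for c, d in pairs:
        if not (0 <= c < n_atoms and 0 <= d < n_atoms):
            raise SelectionError(f"bond pair ({c}, {d}) out of range for {n_atoms} atoms")
    ci = np.array([p[0] for p in pairs])
    di = np.array([p[1] for p in pairs])
    vec = coords[:, di, :] - coords[:, ci, :]  # (frames, pairs, 3)
    norms = np.linalg.norm(vec, axis=2)
    bad = norms < 1e-12
    if np.any(bad):
        f, k = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"zero-length bond vector in frame {f} for pair {tuple(pairs[k])}"
        )
    cos_theta = np.einsum("fpk,k->fp", vec, d_hat) / norms
    return p2(cos_theta).mean(axis=1)


def _block_stderr(series: np.ndarray, block_count: int) -> float:
    if block_count < 2 or series.size < 2 * block_count:
        return float("nan")
    means = np.array([b.mean() for b in np.array_split(series, block_count)])
    return float(means.std(ddof=1) / np.sqrt(block_count))


def compute_scd(
    traj: Trajectory,
    sel: BondSelection,
    director=(0.0, 0.0, 1.0),
    block_count: int = 5,
) -> OrderParameterEstimate:
    """Time-and-bond averaged C-D order parameter with a block-average error.

    The standard error comes from the scatter of ``block_count`` contiguous
    block means, which absorbs slow orientational correlations better than a
    naive per-frame variance would.
    """
    if traj.n_frames < 2:
        raise InvalidParameterError("compute_scd needs at least 2 frames")
    series = p2_series(traj, sel.pairs, director)
    s = float(series.mean())
    return OrderParameterEstimate(
        fragment=sel.fragment,
        s_cd=min(max(s, -0.5), 1.0),
        stderr=_block_stderr(series, block_count),
        n_frames=traj.n_frames,
    )


def methyl_axis_scd(
    traj: Trajectory,
    sel: BondSelection,
    director=(0.0, 0.0, 1.0),
    block_count: int = 5,
) -> OrderParameterEstimate:
    """Deuteron order parameter via the methyl-axis route.

    For a fast CD3 rotor, S_CD = S_axis * P2(cos 109.47 deg) = -S_axis / 3,
    with S_axis the order parameter of the Cgamma-Cdelta axis.  Equivalent to
    direct three-deuteron averaging when the spin is fast; a useful
    cross-check and a cheaper estimator when only heavy atoms are stored.
    """
    if sel.methyl_axis is None:
        raise SelectionError(
            f"fragment {sel.fragment!r} has no methyl-axis pair; methyl_axis_scd "
            "needs one"
        )
    if traj.n_frames < 2:
        raise InvalidParameterError("methyl_axis_scd needs at least 2 frames")
    series = p2_series(traj, [sel.methyl_axis], director) * TETRAHEDRAL_FACTOR
    return OrderParameterEstimate(
        fragment=sel.fragment,
        s_cd=float(np.clip(series.mean(), -0.5, 1.0)),
        stderr=_block_stderr(series, block_count),
        n_frames=traj.n_frames,
    )


def scd_to_splitting(
    s_cd: float,
    chi: float = DEFAULT_CHI_HZ,
    geometry_factor: float = DEFAULT_GEOMETRY_FACTOR,
) -> float:
    """Quadrupolar splitting dnu = (3/2) chi |S_CD| f, in Hz.

    Experimental splittings are magnitudes, so the sign of S_CD is dropped.
    """
    if not chi > 0:
        raise InvalidParameterError(f"chi must be positive, got {chi}")
    if geometry_factor not in (0.5, 1, 1.0):
        raise InvalidParameterError(
            f"geometry_factor must be 1 (director || B0) or 0.5 (perpendicular), "
            f"got {geometry_factor}"
        )
    return 1.5 * chi * abs(float(s_cd)) * float(geometry_factor)


def _two_means_split(x: np.ndarray):
    """Exact 1-D two-means: the split of sorted values minimising total
    within-class sum of squares.  Returns (weights, means, stds)."""
    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs * xs)
    k = np.arange(1, n)  # left class sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_n = n - k
    right_sum = csum[-1] - csum[:-1]
    right_ss = (csq[-1] - csq[:-1]) - right_sum**2 / right_n
    best = int(np.argmin(left_ss + right_ss))
    lo, hi = xs[: best + 1], xs[best + 1 :]
    weights = (lo.size / n, hi.size / n)
    means = (float(lo.mean()), float(hi.mean()))
    stds = (float(lo.std()), float(hi.std()))
    return weights, means, stds


def detect_bimodality(
    series: np.ndarray,
    min_weight: float = 0.2,
    separation: float = 2.0,
):
    """Two-component test on a P2 time series.

    Declares two metastable orientations when the exact 1-D two-means split
    leaves both clusters with weight >= ``min_weight`` and cluster means
    separated by more than ``separation`` times the summed within-cluster
    standard deviations.  Returns (is_bimodal, cluster_means, weights).
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4 or np.ptp(series) == 0:
        return False, (float(series.mean()),), (1.0,)
    weights, means, stds = _two_means_split(series)
    if min(weights) >= min_weight and abs(means[1] - means[0]) > separation * (stds[0] + stds[1]):
        return True, means, weights
    return False, (float(series.mean()),), (1.0,)


def predict_splitting_set(
    traj: Trajectory,
    selections: Sequence[BondSelection],
    chi: float = DEFAULT_CHI_HZ,
    geometry_factor: float = DEFAULT_GEOMETRY_FACTOR,
    director=(0.0, 0.0, 1.0),
    bimodal_min_weight: float = 0.2,
    bimodal_separation: float = 2.0,
) -> SplittingSet:
    """Predicted splittings per fragment, with bimodal fragments given two.

    A fragment whose orientational P2 series splits into two well-populated,
    well-separated clusters is reported with one splitting per cluster
    (mirroring labels that live in two long-lived average orientations);
    otherwise the overall time average yields a single splitting.  Two-valued
    fragments are listed largest first.
    """
    if not selections:
        raise SelectionError("predict_splitting_set needs at least one fragment selection")
    result: dict[str, tuple[float, ...]] = {}
    for sel in selections:
        series = p2_series(traj, sel.pairs, director)
        bimodal, means, _w = detect_bimodality(series, bimodal_min_weight, bimodal_separation)
        if bimodal:
            values = sorted(
                (scd_to_splitting(m, chi, geometry_factor) for m in means), reverse=True
            )
            result[sel.fragment] = tuple(values)
        else:
            result[sel.fragment] = (scd_to_splitting(series.mean(), chi, geometry_factor),)
    return SplittingSet(result, provenance="predicted")
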