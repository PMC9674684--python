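"""Umbrella-sampling window management and WHAM free-energy reconstruction.

The potential of mean force along the bilayer normal is rebuilt from biased
window histograms by the standard WHAM self-consistency,

    P(xi) = sum_i n_i(xi) / sum_i N_i exp[(F_i - w_i(xi)) / kT]
    F_i   = -kT ln sum_xi P(xi) exp(-w_i(xi) / kT)

with harmonic biases w_i(xi) = (1/2) k_i (xi - xi_i)^2, iterated until the
window free energies stop moving.  The profile is reported in kJ/mol, gauge
fixed so its minimum is zero, at 310.15 K (37 C) unless the windows say
otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DisconnectedHistogramError,
    InvalidParameterError,
    TooShortPullError,
)

log = logging.getLogger(__name__)

#: molar gas constant, kJ/(mol K)
R_KJ_PER_MOL_K = 0.008314462618
#: simulation/experiment temperature, K (37 C)
DEFAULT_TEMPERATURE_K = 310.15
#: window spacing along the pull coordinate, nm (2.0 A)
DEFAULT_WINDOW_SPACING_NM = 0.2
DEFAULT_N_BINS = 200
DEFAULT_TOL_KT = 1e-6
DEFAULT_MAX_ITER = 100_000


@dataclass
class UmbrellaWindow:
    """One biased simulation window: harmonic restraint plus its samples."""

    center: float  # nm
    spring_k: float  # kJ/mol/nm^2
    samples: np.ndarray  # reaction-coordinate series, nm
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self):
        if not self.spring_k > 0:
            raise InvalidParameterError(f"spring constant must be positive, got {self.spring_k}")
        if not self.temperature > 0:
            raise InvalidParameterError(f"temperature must be positive, got {self.temperature}")
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile on uniform bins."""

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol, min 0; +inf on empty bins
    counts: np.ndarray  # total samples per bin
    temperature: float = DEFAULT_TEMPERATURE_K
    uncertainty: np.ndarray | None = None  # kJ/mol, bootstrap, optional

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.counts = np.asarray(self.counts)
        occupied = self.counts > 0
        if occupied.any() and not np.all(np.isfinite(self.free_energy[occupied])):
            raise InvalidParameterError("free energy must be finite on occupied bins")

    @property
    def kt(self) -> float:
        return R_KJ_PER_MOL_K * self.temperature


def windows_from_pull(
    times: np.ndarray,
    xi: np.ndarray,
    spacing: float = DEFAULT_WINDOW_SPACING_NM,
    spring_k: float = 1000.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[UmbrellaWindow]:
    """Window centers from a pull trajectory, one per multiple of ``spacing``.

    Each center sits at a multiple of ``spacing`` (default 0.2 nm) inside the
    coordinate range covered by the pull; the configuration at the first
    crossing of that value seeds the window (here only the centers matter —
    the returned windows carry empty sample arrays, to be filled by the
    production runs).
    """
    if not spacing > 0:
        raise InvalidParameterError(f"spacing must be positive, got {spacing}")
    xi = np.asarray(xi, dtype=float)
    times = np.asarray(times, dtype=float)
    if xi.size != times.size or xi.size < 2:
        raise InvalidParameterError("pull series needs matching time/xi arrays of length >= 2")
    lo, hi = float(xi.min()), float(xi.max())
    if hi - lo < spacing:
        raise TooShortPullError(
            f"pull spans {hi - lo:.3f} nm, less than one window spacing ({spacing} nm)"
        )
    eps = 1e-9 * spacing
    first = int(np.ceil((lo - eps) / spacing))
    last = int(np.floor((hi + eps) / spacing))
    windows = []
    for m in range(first, last + 1):
        center = m * spacing
        crossed = np.flatnonzero(
            np.sign(xi[:-1] - center) * np.sign(xi[1:] - center) <= 0
        )
        if crossed.size == 0 and not np.any(np.isclose(xi, center)):
            continue  # pull skipped this multiple (non-monotone edge case)
        windows.append(
            UmbrellaWindow(
                center=center,
                spring_k=spring_k,
                samples=np.empty(0),
                temperature=temperature,
            )
        )
    return windows


def _common_histograms(windows: Sequence[UmbrellaWindow], n_bins: int):
    all_samples = np.concatenate([w.samples for w in windows])
    lo, hi = all_samples.min(), all_samples.max()
    if hi <= lo:
        raise InvalidParameterError("all samples identical; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers, counts


def _window_components(counts: np.ndarray) -> list[set[int]]:
    """Connected components of windows, linked when their histograms share at
    least one occupied bin.  WHAM can only place windows on a common free-
    energy scale within a component."""
    n = counts.shape[0]
    occupied = counts > 0
    adjacency = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(occupied[i] & occupied[j]):
                adjacency[i].add(j)
                adjacency[j].add(i)
    seen: set[int] = set()
    components = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.append(comp)
    return components


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = DEFAULT_N_BINS,
    tol: float = DEFAULT_TOL_KT,
    max_iter: int = DEFAULT_MAX_ITER,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> PMFProfile:
    """Self-consistent WHAM solution over uniform half-open bins.

    Iterates the window free energies until the largest change falls below
    ``tol`` (in kT) or ``max_iter`` is reached; non-convergence emits a
    warning with the final residual and still returns the profile.  Windows
    whose occupied bins leave an interior gap raise
    :class:`DisconnectedHistogramError` listing the gap intervals.  Optional
    bootstrap (resampling each window's series) attaches per-bin
    uncertainties.
    """
    if not windows:
        raise InvalidParameterError("wham_solve needs at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise InvalidParameterError(f"windows carry mixed temperatures: {sorted(temps)}")
    for w in windows:
        if w.n_samples < 100:
            raise InvalidParameterError(
                f"window at {w.center} nm has {w.n_samples} samples; "
                ">= 100 are required for solving"
            )
    temperature = windows[0].temperature
    kt = R_KJ_PER_MOL_K * temperature
    edges, centers, counts = _common_histograms(windows, n_bins)
    total = counts.sum(axis=0)
    components = _window_components(counts)
    if len(components) > 1:
        spans = sorted(
            (min(windows[i].center for i in comp), max(windows[i].center for i in comp))
            for comp in components
        )
        gaps = [(spans[i][1], spans[i + 1][0]) for i in range(len(spans) - 1)]
        raise DisconnectedHistogramError(
            f"umbrella histograms split into {len(components)} disconnected "
            "group(s); unsampled gap(s): "
            + ", ".join(f"[{a:.3f}, {b:.3f}] nm" for a, b in gaps),
            gaps=gaps,
        )

    k_arr = np.array([w.spring_k for w in windows])
    c_arr = np.array([w.center for w in windows])
    n_i = counts.sum(axis=1).astype(float)
    bias_kt = 0.5 * k_arr[:, None] * (centers[None, :] - c_arr[:, None]) ** 2 / kt

    def solve(counts_mat: np.ndarray):
        tot = counts_mat.sum(axis=0).astype(float)
        n_per = counts_mat.sum(axis=1).astype(float)
        f = np.zeros(len(windows))
        residual = np.inf
        exp_neg_bias = np.exp(-bias_kt)
        for _ in range(max_iter):
            denom = (n_per[:, None] * np.exp(f)[:, None] * exp_neg_bias).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(denom > 0, tot / denom, 0.0)
            p_sum = p.sum()
            if p_sum == 0:
                raise InvalidParameterError("WHAM produced an empty distribution")
            p /= p_sum
            with np.errstate(divide="ignore"):
                f_new = -np.log((p[None, :] * exp_neg_bias).sum(axis=1))
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < tol:
                break
        else:
            warnings.warn(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.2e} kT > tol {tol:.2e} kT)",
                RuntimeWarning,
                stacklevel=3,
            )
        with np.errstate(divide="ignore"):
            fe = np.where(tot > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.inf)
        fe = fe - fe[np.isfinite(fe)].min()
        return fe

    log.info(
        "WHAM: %d windows, %d bins, tol %.1e kT, max_iter %d, T = %.2f K",
        len(windows),
        n_bins,
        tol,
        max_iter,
        temperature,
    )
    free_energy = solve(counts)

    uncertainty = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            boot_counts = np.stack(
                [
                    np.histogram(
                        rng.choice(w.samples, size=w.n_samples, replace=True), bins=edges
                    )[0]
                    for w in windows
                ]
            )
            try:
                reps.append(solve(boot_counts))
            except (InvalidParameterError, DisconnectedHistogramError):
                continue
        if reps:
            stack = np.stack(reps)
            with np.errstate(invalid="ignore"):
                uncertainty = np.nanstd(np.where(np.isfinite(stack), stack, np.nan), axis=0)

    return PMFProfile(
        bin_centers=centers,
        free_energy=free_energy,
        counts=total,
        temperature=temperature,
        uncertainty=uncertainty,
    )


def detect_poor_sampling(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = DEFAULT_N_BINS,
    min_overlap: float = 0.05,
) -> list[tuple[float, float]]:
    """Coordinate intervals where neighbouring windows barely overlap.

    Consecutive windows (by center) are compared through the shared-bin mass
    of their normalised histograms; pairs sharing less than ``min_overlap``
    (default 5 %) — or no samples at all — flag the interval between their
    centers as poorly sampled, the cue to add windows there.
    """
    if len(windows) < 2:
        warnings.warn("detect_poor_sampling needs >= 2 windows; nothing to compare",
                      RuntimeWarning, stacklevel=2)
        return []
    ordered = sorted(windows, key=lambda w: w.center)
    edges, _, counts = _common_histograms(ordered, n_bins)
    gaps = []
    for i in range(len(ordered) - 1):
        a, b = counts[i].astype(float), counts[i + 1].astype(float)
        if a.sum() == 0 or b.sum() == 0:
            overlap = 0.0
        else:
            overlap = float(np.minimum(a / a.sum(), b / b.sum()).sum())
        if overlap < min_overlap:
            gaps.append((ordered[i].center, ordered[i + 1].center))
    return gaps


def endpoint_symmetry(profile: PMFProfile, margin: float) -> float:
    """Mean free energy over the first ``margin`` nm minus over the last.

    A translocation with no driving force ends where it started: the profile
    should show the same potential at entry and exit, making this difference
    vanish within sampling error.  Bin means are count-weighted so sparsely
    visited tail bins do not dominate.  Sign follows (start - end).
    """
    centers = profile.bin_centers
    span = centers[-1] - centers[0]
    if not 0 < margin <= span / 2:
        raise InvalidParameterError(
            f"margin must lie in (0, {span / 2:.3f}] nm for this profile, got {margin}"
        )
    finite = np.isfinite(profile.free_energy) & (profile.counts > 0)
    head = finite & (centers <= centers[0] + margin)
    tail = finite & (centers >= centers[-1] - margin)
    if not head.any() or not tail.any():
        raise InvalidParameterError("no occupied bins inside one of the margins")

    def wmean(mask):
        w = profile.counts[mask].astype(float)
        return float(np.average(profile.free_energy[mask], weights=w))

    return wmean(head) - wmean(tail)
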