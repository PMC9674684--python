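"""Trajectory descriptors used to stage the translocation mechanism.

Three observables describe where the peptide is and what it looks like while
crossing the bilayer: radial distribution functions between peptide moieties
and bilayer components, the number of alpha-helical residues as a function of
depth, and the center-of-mass depth itself.  The helix assignment
re-implements the Kabsch-Sander hydrogen-bond energy criterion (alpha class
only) so no external secondary-structure binary is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SelectionError, StructuralInputError
from .selections import select_indices
from .trajectory import Trajectory

#: Kabsch-Sander electrostatic model: E = Q * (1/rON + 1/rCH - 1/rOH - 1/rCN)
#: with distances in Angstrom and E in kcal/mol
_KS_Q_KCAL_A = 0.084 * 332.0
#: hydrogen bond accepted below this energy, kcal/mol
_KS_CUTOFF_KCAL = -0.5
#: reconstructed amide N-H bond length, Angstrom
_NH_BOND_A = 1.01


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray  # dimensionless
    selection_labels: tuple[str, str]
    n_frames: int

    def __post_init__(self):
        if np.any(self.g < 0):
            raise InvalidParameterError("g(r) must be non-negative")


@dataclass
class HelixProfile:
    depth_centers: np.ndarray  # nm
    mean_count: np.ndarray  # helical residues; NaN where occupancy is 0
    std_count: np.ndarray
    occupancy: np.ndarray  # frames per bin


def _resolve(traj: Trajectory, sel) -> np.ndarray:
    if isinstance(sel, str):
        return traj.select(sel)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty atom selection")
    return idx


def compute_rdf(
    traj: Trajectory,
    sel_a,
    sel_b,
    r_max: float,
    n_bins: int = 120,
    chunk: int = 256,
) -> RDFResult:
    """3-D radial distribution function with periodic minimum image.

    Pair distances between the two selections (self-pairs excluded when the
    selections share atoms) are histogrammed and normalised by the ideal-gas
    expectation using exact spherical-shell volumes, so a uniform fluid gives
    g(r) = 1.  ``r_max`` may not exceed half the smallest box length.
    """
    ia = _resolve(traj, sel_a)
    ib = _resolve(traj, sel_b)
    if not r_max > 0:
        raise InvalidParameterError("r_max must be positive")
    if r_max > traj.box.min() / 2 + 1e-12:
        raise InvalidParameterError(
            f"r_max = {r_max} nm exceeds half the smallest box length "
            f"({traj.box.min() / 2:.3f} nm)"
        )
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    shared = np.intersect1d(ia, ib).size > 0
    n_excess_per_frame = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f]
        a = traj.coordinates[f, ia]
        b = traj.coordinates[f, ib]
        for start in range(0, ia.size, chunk):
            sl = slice(start, start + chunk)
            d = a[sl, None, :] - b[None, :, :]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=2)
            if shared:
                same = ia[sl][:, None] == ib[None, :]
                r = r[~same]
            hist += np.histogram(r, bins=edges)[0]
    n_pairs = ia.size * ib.size - (ia.size if shared else 0)
    if n_pairs <= 0:
        raise SelectionError("selections define no distinct atom pairs")
    volume = float(np.prod(traj.box.mean(axis=0)))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 + 0.0 - edges[:-1] ** 3)
    ideal = n_pairs / volume * shell * traj.n_frames
    g = np.where(ideal > 0, hist / ideal, 0.0)
    label_a = sel_a if isinstance(sel_a, str) else f"{ia.size} atoms"
    label_b = sel_b if isinstance(sel_b, str) else f"{ib.size} atoms"
    return RDFResult(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        selection_labels=(label_a, label_b),
        n_frames=traj.n_frames,
    )


def _backbone_arrays(coords_nm: np.ndarray, atoms: pd.DataFrame):
    """Per-residue N, CA, C, O (and H when present) positions in Angstrom."""
    resids = atoms["resid"].to_numpy()
    order = sorted(pd.unique(resids))
    names = atoms["name"].to_numpy()
    pos = {}
    for want in ("N", "CA", "C", "O"):
        rows = []
        for rid in order:
            idx = np.flatnonzero((resids == rid) & (names == want))
            if idx.size == 0:
                raise StructuralInputError(
                    f"residue {rid} is missing backbone atom {want}"
                )
            rows.append(idx[0])
        pos[want] = coords_nm[rows] * 10.0  # nm -> Angstrom
    h_rows = []
    for rid in order:
        idx = np.flatnonzero((resids == rid) & np.isin(names, ("H", "HN")))
        h_rows.append(idx[0] if idx.size else -1)
    h = np.full((len(order), 3), np.nan)
    present = np.array(h_rows) >= 0
    if present.any():
        h[present] = coords_nm[np.array(h_rows)[present]] * 10.0
    return order, pos, h


def _reconstruct_amide_h(pos, h):
    """Fill missing amide hydrogens from local backbone geometry.

    H sits on nitrogen, 1.01 A along the direction opposing the bisector of
    the C(prev)->N and CA->N bonds — the standard planar-amide placement.
    The first residue has no preceding carbonyl and keeps no H (it cannot
    donate an i -> i+4 bond that the alpha assignment would use anyway).
    """
    n_res = pos["N"].shape[0]
    out = h.copy()
    for i in range(1, n_res):
        if np.all(np.isfinite(out[i])):
            continue
        n = pos["N"][i]
        d1 = n - pos["C"][i - 1]
        d2 = n - pos["CA"][i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = d1 + d2
        bis /= np.linalg.norm(bis)
        out[i] = n + _NH_BOND_A * bis
    return out


def helix_residue_count(coords_nm: np.ndarray, atoms: pd.DataFrame) -> int:
    """Number of residues assigned alpha-helical by the Kabsch-Sander rule.

    An i -> i+4 backbone hydrogen bond (acceptor C=O of residue i, donor N-H
    of residue i+4) is accepted when the electrostatic energy

        E = 0.084 * (1/rON + 1/rCH - 1/rOH - 1/rCN) * 332 kcal/mol

    falls below -0.5 kcal/mol.  Two consecutive accepted bonds (i and i+1)
    mark the four bracketed residues i+1 .. i+4 helical; the count is the
    size of the union over all such runs.
    """
    coords_nm = np.asarray(coords_nm, dtype=float)
    if coords_nm.ndim != 2 or coords_nm.shape[1] != 3:
        raise InvalidParameterError("helix_residue_count expects a single (atoms, 3) frame")
    order, pos, h = _backbone_arrays(coords_nm, atoms)
    n_res = len(order)
    if n_res < 5:
        return 0
    h = _reconstruct_amide_h(pos, h)

    def hbond(i_acc: int, j_don: int) -> bool:
        if not np.all(np.isfinite(h[j_don])):
            return False
        c, o = pos["C"][i_acc], pos["O"][i_acc]
        n, hh = pos["N"][j_don], h[j_don]
        r_on = np.linalg.norm(o - n)
        r_ch = np.linalg.norm(c - hh)
        r_oh = np.linalg.norm(o - hh)
        r_cn = np.linalg.norm(c - n)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, not a bond
            return False
        e = _KS_Q_KCAL_A * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        return e < _KS_CUTOFF_KCAL

    bonds = [hbond(i, i + 4) for i in range(n_res - 4)]
    helical = np.zeros(n_res, dtype=bool)
    for i in range(len(bonds) - 1):
        if bonds[i] and bonds[i + 1]:
            helical[i + 1 : i + 5] = True
    return int(helical.sum())


def com_depth(
    traj: Trajectory,
    selection,
    masses: np.ndarray | None = None,
    bilayer_selection=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame |z_COM - z_bilayer| series, nm.

    The bilayer center is the mean z of the designated bilayer atoms per
    frame, or 0 when no bilayer selection is given (a pre-centered system).
    Unit masses are the default; pass per-selected-atom masses to weight.
    Depth is unsigned: distance from the bilayer center, either leaflet.
    """
    idx = _resolve(traj, selection)
    if masses is None:
        w = np.ones(idx.size)
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (idx.size,):
            raise InvalidParameterError(
                f"masses must match the selection ({idx.size} atoms), got {w.shape}"
            )
    z = traj.coordinates[:, idx, 2]
    z_com = (z * w).sum(axis=1) / w.sum()
    if bilayer_selection is not None:
        bidx = _resolve(traj, bilayer_selection)
        z_ref = traj.coordinates[:, bidx, 2].mean(axis=1)
    else:
        z_ref = np.zeros(traj.n_frames)
    return traj.times.copy(), np.abs(z_com - z_ref)


def helix_vs_depth(
    traj: Trajectory,
    bin_width: float = 0.2,
    peptide_selection=None,
    bilayer_selection=None,
) -> HelixProfile:
    """Mean and spread of the helical residue count, binned by COM depth.

    Each frame contributes its Kabsch-Sander helical count at its
    center-of-mass distance from the bilayer center.  Bins nobody visits are
    reported with zero occupancy and NaN statistics — never fabricated
    values.
    """
    if traj.n_frames < 1:
        raise InvalidParameterError("helix_vs_depth needs at least one frame")
    if not bin_width > 0:
        raise InvalidParameterError("bin_width must be positive")
    idx = _resolve(traj, peptide_selection) if peptide_selection is not None else np.arange(traj.n_atoms)
    sub_atoms = traj.atoms.iloc[idx].reset_index(drop=True)
    counts = np.array(
        [helix_residue_count(traj.coordinates[f, idx], sub_atoms) for f in range(traj.n_frames)]
    )
    _, depths = com_depth(traj, idx, bilayer_selection=bilayer_selection)
    n_bins = max(1, int(np.ceil((depths.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(np.digitize(depths, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    std = np.full(n_bins, np.nan)
    occ = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        occ[b] = int(sel.sum())
        if occ[b]:
            mean[b] = counts[sel].mean()
            std[b] = counts[sel].std()
    return HelixProfile(
        depth_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_count=mean,
        std_count=std,
        occupancy=occ,
    )
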