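"""Synthetic inputs with known ground truth.

Every generator here emulates one of the three input kinds the analysis
consumes — orientationally diffusing C-D vectors, doublet spectra, biased
umbrella samples — plus helices and point clouds for the membrane metrics.
Each returns its analytic ground truth alongside the data so tests assert
against metadata instead of re-deriving it, and every draw flows from an
explicit seed: identical parameters give identical output, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InvalidParameterError
from .order_params import (
    DEFAULT_CHI_HZ,
    DEFAULT_GEOMETRY_FACTOR,
    TETRAHEDRAL_FACTOR,
    BondSelection,
    p2,
    scd_to_splitting,
)
from .pmf_wham import DEFAULT_TEMPERATURE_K, R_KJ_PER_MOL_K, UmbrellaWindow
from .spectra import QuadrupolarDoublet, Spectrum, SpectrumAxis, build_axis, synthesize_spectrum
from .trajectory import Trajectory, make_atom_table

#: C-D and C-C bond lengths, nm
_CD_BOND_NM = 0.109
_CC_BOND_NM = 0.153
#: cosine of the angle between a methyl C-D bond and the +Cgamma->Cdelta axis
_METHYL_COS = 1.0 / 3.0


@dataclass
class TrajectoryFixture:
    """A synthetic trajectory bundled with its selections and ground truth."""

    trajectory: Trajectory
    selections: list[BondSelection]
    truth: dict = field(default_factory=dict)


def cone_axis_order_parameter(theta0_deg: float) -> float:
    """Closed-form order parameter of a vector uniform on a spherical cap:
    S = (1/2) cos(theta0) (1 + cos(theta0))."""
    c0 = math.cos(math.radians(theta0_deg))
    return 0.5 * c0 * (1.0 + c0)


def _cap_uniform(rng: np.random.Generator, n: int, theta0_deg: float, axis: np.ndarray):
    """Unit vectors uniform on the spherical cap of half-angle theta0 about
    ``axis`` — inverse-CDF in cos(theta), exact rather than rejection-based."""
    c0 = math.cos(math.radians(theta0_deg))
    u = rng.uniform(c0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - u * u)
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    return local @ _frame_about(axis).T


def _frame_about(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is ``axis`` (unit)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return np.column_stack([e1, e2, a])


def _tilted_axis(tilt_deg: float, azimuth_deg: float = 0.0) -> np.ndarray:
    t, p = math.radians(tilt_deg), math.radians(azimuth_deg)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def _bond_trajectory(directions: np.ndarray, fragment: str, box_nm: float = 5.0,
                     resname: str = "LEU") -> TrajectoryFixture:
    """Wrap per-frame unit C-D directions as a two-atom trajectory."""
    n = directions.shape[0]
    coords = np.zeros((n, 2, 3))
    coords[:, 1, :] = directions * _CD_BOND_NM
    atoms = make_atom_table(["CD1", "HD11"], [resname] * 2, [1, 1])
    traj = Trajectory(coords, atoms, np.full(3, box_nm), times=np.arange(n, dtype=float))
    sel = BondSelection(fragment=fragment, pairs=((0, 1),))
    return TrajectoryFixture(trajectory=traj, selections=[sel], truth={})


def make_cone_trajectory(
    theta0_deg: float,
    n_frames: int,
    seed: int,
    fragment: str = "Leu",
) -> TrajectoryFixture:
    """Wobble-in-a-cone fixture: one C-D vector uniform on a cap about z.

    Ground truth (``truth['s_axis']``) is the closed form
    S = (1/2) cos(theta0) (1 + cos(theta0)).
    """
    if not 0.0 < theta0_deg <= 90.0:
        raise InvalidParameterError(f"theta0 must lie in (0, 90] degrees, got {theta0_deg}")
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    dirs = _cap_uniform(rng, n_frames, theta0_deg, np.array([0.0, 0.0, 1.0]))
    fx = _bond_trajectory(dirs, fragment)
    fx.truth = {
        "kind": "cone",
        "theta0_deg": theta0_deg,
        "s_axis": cone_axis_order_parameter(theta0_deg),
        "seed": seed,
    }
    return fx


def make_methyl_rotor_trajectory(
    tilt_deg: float,
    n_frames: int,
    seed: int,
    fragment: str = "Leu",
) -> TrajectoryFixture:
    """Fast CD3 rotor on a static tilted axis.

    Three deuterons spin about the Cgamma->Cdelta axis (uniform random phase
    per frame — the fast-rotation limit).  Direct three-deuteron averaging and
    the methyl-axis route must agree: both equal P2(cos tilt) * (-1/3).
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    axis = _tilted_axis(tilt_deg)
    frame = _frame_about(axis)
    e1, e2 = frame[:, 0], frame[:, 1]
    sin_a = math.sqrt(1.0 - _METHYL_COS**2)
    phase = rng.uniform(0.0, 2.0 * np.pi, n_frames)
    coords = np.zeros((n_frames, 5, 3))
    cg = np.zeros(3)
    cd = axis * _CC_BOND_NM
    coords[:, 0, :] = cg
    coords[:, 1, :] = cd
    for k in range(3):
        ang = phase + k * 2.0 * np.pi / 3.0
        bond_dir = (
            _METHYL_COS * axis[None, :]
            + sin_a * (np.cos(ang)[:, None] * e1[None, :] + np.sin(ang)[:, None] * e2[None, :])
        )
        coords[:, 2 + k, :] = cd + bond_dir * _CD_BOND_NM
    atoms = make_atom_table(
        ["CG", "CD1", "HD11", "HD12", "HD13"], ["LEU"] * 5, [1] * 5
    )
    traj = Trajectory(coords, atoms, np.full(3, 5.0), times=np.arange(n_frames, dtype=float))
    sel = BondSelection(
        fragment=fragment,
        pairs=((1, 2), (1, 3), (1, 4)),
        methyl_axis=(0, 1),
    )
    s_axis = float(p2(math.cos(math.radians(tilt_deg))))
    return TrajectoryFixture(
        trajectory=traj,
        selections=[sel],
        truth={
            "kind": "methyl_rotor",
            "tilt_deg": tilt_deg,
            "s_axis": s_axis,
            "s_cd": s_axis * TETRAHEDRAL_FACTOR,
            "seed": seed,
        },
    )


def make_two_state_trajectory(
    tilt_a_deg: float = 0.0,
    tilt_b_deg: float = 90.0,
    occupancy_a: float = 0.5,
    dwell_frames: int = 200,
    wobble_deg: float = 10.0,
    n_frames: int = 4000,
    seed: int = 0,
    fragment: str = "Leu",
) -> TrajectoryFixture:
    """Bond alternating between two long-lived average orientations.

    State dwell times are geometric with mean ``dwell_frames``; within each
    state the bond wobbles in a narrow cone about a tilted axis.  The
    azimuthally averaged order parameter per state is exactly
    P2(cos tilt) * S_cone(wobble), recorded in the ground truth together with
    the two splittings a bimodality-aware predictor should report.
    """
    if not 0.0 < occupancy_a < 1.0:
        raise InvalidParameterError("occupancy_a must lie strictly between 0 and 1")
    if dwell_frames < 1 or n_frames < 2:
        raise InvalidParameterError("dwell_frames >= 1 and n_frames >= 2 required")
    rng = np.random.default_rng(seed)
    # alternating geometric dwells, scaled so state A holds occupancy_a on average
    dwell_a = max(1, int(round(2 * dwell_frames * occupancy_a)))
    dwell_b = max(1, int(round(2 * dwell_frames * (1 - occupancy_a))))
    state = np.empty(n_frames, dtype=int)
    pos, cur = 0, 0
    while pos < n_frames:
        mean_dwell = dwell_a if cur == 0 else dwell_b
        run = 1 + rng.geometric(1.0 / mean_dwell)
        state[pos : pos + run] = cur
        pos += run
        cur = 1 - cur
    axes = [_tilted_axis(tilt_a_deg), _tilted_axis(tilt_b_deg)]
    dirs = np.empty((n_frames, 3))
    for s_idx in (0, 1):
        mask = state == s_idx
        dirs[mask] = _cap_uniform(rng, int(mask.sum()), wobble_deg, axes[s_idx])
    fx = _bond_trajectory(dirs, fragment)
    s_cone = cone_axis_order_parameter(wobble_deg)
    s_states = [
        float(p2(math.cos(math.radians(t)))) * s_cone for t in (tilt_a_deg, tilt_b_deg)
    ]
    fx.truth = {
        "kind": "two_state",
        "s_states": s_states,
        "splittings": sorted((scd_to_splitting(s) for s in s_states), reverse=True),
        "occupancy_a": float(np.mean(state == 0)),
        "seed": seed,
    }
    return fx


def make_placement_trajectory(
    tilt_deg: float,
    fragment_offsets_deg: dict[str, float],
    wobble_deg: float = 15.0,
    n_frames: int = 2000,
    seed: int = 0,
    azimuth_deg: float = 0.0,
    depth_nm: float = 0.0,
) -> TrajectoryFixture:
    """Rigid-placement forward model for the configuration search.

    Each labelled fragment owns a C-D axis at a fixed angle to the peptide
    axis; tilting the peptide by ``tilt_deg`` moves every fragment axis to
    polar angle offset + tilt, about which the bond wobbles in a cone.  The
    azimuth (rotation about the bilayer normal) and depth do not change any
    order parameter — exactly as in the real observable, which is blind to
    both — but are kept so candidates map one-to-one onto trajectories.
    Ground truth records the expected splitting per fragment.
    """
    if not fragment_offsets_deg:
        raise InvalidParameterError("need at least one fragment offset")
    rng = np.random.default_rng(seed)
    fragments = list(fragment_offsets_deg)
    n_frag = len(fragments)
    coords = np.zeros((n_frames, 2 * n_frag, 3))
    selections = []
    s_cone = cone_axis_order_parameter(wobble_deg)
    truth_split = {}
    names, resnames, resids = [], [], []
    for k, frag in enumerate(fragments):
        polar = fragment_offsets_deg[frag] + tilt_deg
        axis = _tilted_axis(polar, azimuth_deg)
        dirs = _cap_uniform(rng, n_frames, wobble_deg, axis)
        base = np.array([0.0, 0.0, depth_nm]) + np.array([0.4 * k, 0.0, 0.0])
        coords[:, 2 * k, :] = base
        coords[:, 2 * k + 1, :] = base + dirs * _CD_BOND_NM
        selections.append(BondSelection(fragment=frag, pairs=((2 * k, 2 * k + 1),)))
        s_frag = float(p2(math.cos(math.radians(polar)))) * s_cone
        truth_split[frag] = scd_to_splitting(s_frag)
        names += ["CD1", "HD11"]
        resnames += ["LEU", "LEU"]
        resids += [k + 1, k + 1]
    atoms = make_atom_table(names, resnames, resids)
    traj = Trajectory(coords, atoms, np.full(3, 6.0), times=np.arange(n_frames, dtype=float))
    return TrajectoryFixture(
        trajectory=traj,
        selections=selections,
        truth={
            "kind": "placement",
            "tilt_deg": tilt_deg,
            "splittings": truth_split,
            "seed": seed,
        },
    )


def placement_provider(
    fragment_offsets_deg: dict[str, float],
    wobble_deg: float = 15.0,
    n_frames: int = 2000,
):
    """Trajectory provider for the configuration search, closed over the
    fragment geometry; each candidate is realised with its own seed."""

    def provider(cand) -> Trajectory:
        return make_placement_trajectory(
            tilt_deg=cand.tilt,
            fragment_offsets_deg=fragment_offsets_deg,
            wobble_deg=wobble_deg,
            n_frames=n_frames,
            seed=cand.seed,
            azimuth_deg=cand.azimuth,
            depth_nm=cand.depth,
        ).trajectory

    return provider


# --- helices ---------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}
_EXTENDED = (-120.0, 120.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float,
           torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: position atom d from a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix_coords(
    n_res: int,
    phi_deg: float = -57.0,
    psi_deg: float = -47.0,
    unwound_termini: int = 0,
    resname: str = "ALA",
) -> TrajectoryFixture:
    """Ideal polypeptide backbone at fixed (phi, psi), optionally frayed.

    Standard bond geometry, trans peptide bonds.  ``unwound_termini`` residues
    (split between the two ends) are set to extended dihedrals
    (phi, psi) = (-120, 120), emulating frayed helix ends.  Ground truth lists
    which residues carry helical dihedrals.
    """
    if n_res < 5:
        raise InvalidParameterError(f"need n_res >= 5, got {n_res}")
    if unwound_termini < 0 or unwound_termini >= n_res:
        raise InvalidParameterError("unwound_termini must lie in [0, n_res)")
    n_head = unwound_termini // 2
    n_tail = unwound_termini - n_head
    dihedrals = []
    for i in range(n_res):
        if i < n_head or i >= n_res - n_tail:
            dihedrals.append(_EXTENDED)
        else:
            dihedrals.append((phi_deg, psi_deg))

    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    ang = math.radians(_ANGLE["N-CA-C"])
    c_pos = [
        ca_pos[0]
        + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    ]
    for i in range(1, n_res):
        psi_prev = dihedrals[i - 1][1]
        n_next = _place(n_pos[-1], ca_pos[-1], c_pos[-1], _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        ca_next = _place(ca_pos[-1], c_pos[-1], n_next, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        phi_i = dihedrals[i][0]
        c_next = _place(c_pos[-1], n_next, ca_next, _BOND["CA-C"], _ANGLE["N-CA-C"], phi_i)
        n_pos.append(n_next)
        ca_pos.append(ca_next)
        c_pos.append(c_next)
    o_pos = [
        _place(n_pos[i], ca_pos[i], c_pos[i], _BOND["C-O"], _ANGLE["CA-C-O"],
               dihedrals[i][1] + 180.0)
        for i in range(n_res)
    ]

    coords, names, resnames, resids = [], [], [], []
    for i in range(n_res):
        for nm, arr in (("N", n_pos), ("CA", ca_pos), ("C", c_pos), ("O", o_pos)):
            coords.append(arr[i])
            names.append(nm)
            resnames.append(resname)
            resids.append(i + 1)
    coords_nm = np.asarray(coords) / 10.0  # Angstrom -> nm
    span = coords_nm.max(axis=0) - coords_nm.min(axis=0)
    box = np.maximum(span * 2.0 + 2.0, 3.0)
    atoms = make_atom_table(names, resnames, resids)
    traj = Trajectory(coords_nm[None, :, :], atoms, box, times=np.zeros(1))
    helical = [i + 1 for i in range(n_res) if dihedrals[i] == (phi_deg, psi_deg)]
    return TrajectoryFixture(
        trajectory=traj,
        selections=[],
        truth={
            "kind": "helix",
            "helical_dihedral_residues": helical,
            "phi_deg": phi_deg,
            "psi_deg": psi_deg,
            "unwound_termini": unwound_termini,
        },
    )


# --- umbrella sampling -----------------------------------------------------


def stair_potential(
    well_kj: float = -10.0,
    step1_kj: float = 8.0,
    step2_kj: float = 16.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth 'potential stair' along the bilayer normal.

    Flat in bulk on both sides (equal endpoint energies), an adsorption well
    in the outer leaflet, then two ascending steps before the descent on the
    exit side — the shape of a translocation that must carry first one, then
    the other charged residue across the midplane.  Monotone-preserving
    interpolation (PCHIP) through hand-picked knots; no overshoot.
    """
    knots_x = np.array([-3.0, -2.6, -1.8, -1.1, -0.55, -0.1, 0.35, 0.85, 1.4, 1.9, 2.6, 3.0])
    knots_y = np.array(
        [0.0, 0.0, well_kj, 0.3 * step1_kj, step1_kj, step1_kj + 0.5,
         0.6 * (step1_kj + step2_kj), step2_kj, step2_kj + 0.5, 0.5 * step2_kj, 0.0, 0.0]
    )
    interp = PchipInterpolator(knots_x, knots_y, extrapolate=False)

    def u(x):
        x = np.asarray(x, dtype=float)
        out = interp(np.clip(x, knots_x[0], knots_x[-1]))
        return out

    return u


def make_umbrella_samples(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    spring_k: float,
    n_per_window: int = 10_000,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
    grid_points: int = 10_001,
    pad_sigmas: float = 6.0,
) -> tuple[list[UmbrellaWindow], dict]:
    """Exact Boltzmann samples from U(xi) + harmonic bias, via grid inverse-CDF.

    Sampling is by inverse transform on a fine grid (default 10^4 points), so
    each window's samples follow the target biased density up to grid
    resolution with zero autocorrelation — WHAM tests then probe WHAM, not a
    sampler.  Returns the windows and a truth dict holding the potential on
    the grid.
    """
    if n_per_window < 100:
        raise InvalidParameterError("n_per_window must be >= 100")
    centers = np.asarray(centers, dtype=float)
    kt = R_KJ_PER_MOL_K * temperature
    sigma = math.sqrt(kt / spring_k)
    lo = centers.min() - pad_sigmas * sigma
    hi = centers.max() + pad_sigmas * sigma
    grid = np.linspace(lo, hi, grid_points)
    u_grid = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(u_grid)):
        raise InvalidParameterError("potential must be finite over the sampled range")
    windows = []
    for i, c in enumerate(centers):
        rng = np.random.default_rng([seed, i])
        energy = u_grid + 0.5 * spring_k * (grid - c) ** 2
        w = np.exp(-(energy - energy.min()) / kt)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        samples = np.interp(rng.uniform(0.0, 1.0, n_per_window), cdf, grid)
        windows.append(
            UmbrellaWindow(center=float(c), spring_k=spring_k, samples=samples,
                           temperature=temperature)
        )
    truth = {
        "kind": "umbrella",
        "grid": grid,
        "pmf": u_grid - u_grid.min(),
        "temperature": temperature,
        "spring_k": spring_k,
        "seed": seed,
    }
    return windows, truth


# --- point clouds and spectra ----------------------------------------------


def make_pointcloud(
    n_points: int,
    box_nm: float = 5.0,
    seed: int = 0,
    n_frames: int = 1,
    name: str = "PT",
) -> Trajectory:
    """Ideal gas: uniform points in a periodic cubic box, independent frames."""
    if n_points < 2:
        raise InvalidParameterError("need at least 2 points")
    if n_frames < 1:
        raise InvalidParameterError("need at least 1 frame")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_nm, (n_frames, n_points, 3))
    atoms = make_atom_table([name] * n_points, ["PNT"] * n_points, np.arange(1, n_points + 1))
    return Trajectory(coords, atoms, np.full(3, float(box_nm)),
                      times=np.arange(n_frames, dtype=float))


def make_doublet_spectrum(
    splittings_hz: Sequence[float],
    axis: SpectrumAxis | None = None,
    amplitude: float = 1.0,
    linewidth_hz: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, dict]:
    """Doublet spectrum with programmed splittings on the instrument axis.

    The default axis is the acquisition geometry of the oriented-sample
    experiments: 32768 points over 43.1 kHz centered at zero.
    """
    if axis is None:
        axis = build_axis(32768, 43_100.0)
    doublets = [
        QuadrupolarDoublet(splitting=float(s), amplitude=amplitude, linewidth=linewidth_hz)
        for s in splittings_hz
    ]
    spec = synthesize_spectrum(doublets, axis, noise_sd=noise_sd, seed=seed)
    truth = {
        "kind": "spectrum",
        "splittings_hz": [float(s) for s in splittings_hz],
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return spec, truth
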