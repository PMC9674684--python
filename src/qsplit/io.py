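"""File formats and run configuration.

All outputs are plain text (two-column spectra with a JSON metadata sidecar,
TSV manifests and profiles, JSON rankings) so runs diff cleanly.  Trajectories
travel either as multi-model PDB — read and written through MDAnalysis — or
as a simple documented text dialect used for fixtures:

    # qsplit-traj atoms=<A> frames=<F>
    # atom <name> <resname> <resid> <chain>      (A lines)
    # frame t=<ps> box=<bx> <by> <bz>            (then A coordinate rows, nm)
    <x> <y> <z>
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .order_params import DEFAULT_CHI_HZ, DEFAULT_GEOMETRY_FACTOR, BondSelection
from .pmf_wham import (
    DEFAULT_MAX_ITER,
    DEFAULT_N_BINS,
    DEFAULT_TEMPERATURE_K,
    DEFAULT_TOL_KT,
    PMFProfile,
    UmbrellaWindow,
)
from .spectra import Spectrum, SpectrumAxis, SplittingSet
from .structure_fit import DEFAULT_RMSRD_THRESHOLD_PCT, CandidateConfiguration
from .trajectory import Trajectory, make_atom_table

# --- spectra ---------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_spectrum(spec: Spectrum, path) -> Path:
    """Two-column text (Hz, intensity) plus a JSON metadata sidecar."""
    path = Path(path)
    freqs = spec.axis.frequencies()
    np.savetxt(path, np.column_stack([freqs, spec.intensity]), fmt="%.6f %.8e")
    meta = {
        "n_points": spec.axis.n_points,
        "spectral_width_hz": spec.axis.spectral_width,
        "spectrometer_freq_mhz": spec.axis.spectrometer_freq,
        "center_hz": spec.axis.center,
        "label": spec.label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_spectrum(path, meta_path=None) -> Spectrum:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(path)
    if not meta_path.exists():
        raise InvalidParameterError(f"metadata sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    axis = SpectrumAxis(
        n_points=int(meta["n_points"]),
        spectral_width=float(meta["spectral_width_hz"]),
        spectrometer_freq=float(meta.get("spectrometer_freq_mhz", 61.422)),
        center=float(meta.get("center_hz", 0.0)),
    )
    data = np.loadtxt(path)
    return Spectrum(axis, data[:, 1], meta.get("label", path.stem))


# --- splitting sets and rankings ------------------------------------------


def write_splitting_set(sset: SplittingSet, path) -> Path:
    path = Path(path)
    payload = {"provenance": sset.provenance,
               "splittings_hz": {k: list(v) for k, v in sset.items()}}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_splitting_set(path) -> SplittingSet:
    payload = json.loads(Path(path).read_text())
    return SplittingSet(payload["splittings_hz"], provenance=payload.get("provenance", "experimental"))


def write_ranking(candidates: list[CandidateConfiguration], path) -> Path:
    path = Path(path)
    rows = []
    for c in candidates:
        rows.append(
            {
                "seed": c.seed,
                "tilt_deg": c.tilt,
                "azimuth_deg": c.azimuth,
                "depth_nm": c.depth,
                "rmsrd_pct": c.rmsrd,
                "predicted_hz": {k: list(v) for k, v in c.predicted.items()} if c.predicted else None,
            }
        )
    path.write_text(json.dumps(rows, indent=2) + "\n")
    return path


def read_bond_selections(path) -> list[BondSelection]:
    """Selection config: JSON list of {fragment, pairs, methyl_axis?}."""
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        out.append(
            BondSelection(
                fragment=entry["fragment"],
                pairs=tuple(tuple(p) for p in entry["pairs"]),
                methyl_axis=tuple(entry["methyl_axis"]) if entry.get("methyl_axis") else None,
            )
        )
    return out


# --- trajectories ----------------------------------------------------------


def write_trajectory_text(traj: Trajectory, path) -> Path:
    path = Path(path)
    lines = [f"# qsplit-traj atoms={traj.n_atoms} frames={traj.n_frames}"]
    for _, row in traj.atoms.iterrows():
        lines.append(f"# atom {row['name']} {row['resname']} {row['resid']} {row['chain']}")
    for f in range(traj.n_frames):
        bx, by, bz = traj.box[f]
        lines.append(f"# frame t={traj.times[f]:.6f} box={bx:.6f} {by:.6f} {bz:.6f}")
        for a in range(traj.n_atoms):
            x, y, z = traj.coordinates[f, a]
            lines.append(f"{x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trajectory_text(path) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# qsplit-traj"):
        raise InvalidParameterError(f"{path} is not a qsplit-traj text file")
    header = dict(tok.split("=") for tok in lines[0].split()[2:])
    n_atoms, n_frames = int(header["atoms"]), int(header["frames"])
    names, resnames, resids, chains = [], [], [], []
    i = 1
    while len(names) < n_atoms:
        parts = lines[i].split()
        if parts[:2] != ["#", "atom"]:
            raise InvalidParameterError(f"{path}: expected atom record at line {i + 1}")
        names.append(parts[2])
        resnames.append(parts[3])
        resids.append(int(parts[4]))
        chains.append(parts[5])
        i += 1
    coords = np.empty((n_frames, n_atoms, 3))
    box = np.empty((n_frames, 3))
    times = np.empty(n_frames)
    for f in range(n_frames):
        parts = lines[i].split()
        times[f] = float(parts[2].split("=")[1])
        box[f] = [float(parts[3].split("=")[1]), float(parts[4]), float(parts[5])]
        i += 1
        for a in range(n_atoms):
            coords[f, a] = [float(v) for v in lines[i].split()]
            i += 1
    atoms = make_atom_table(names, resnames, resids, chains)
    return Trajectory(coords, atoms, box, times)


def write_trajectory_pdb(traj: Trajectory, path) -> Path:
    """Multi-model PDB through MDAnalysis (coordinates nm -> Angstrom)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    resids = traj.atoms["resid"].to_numpy()
    unique_resids, resindex = np.unique(resids, return_inverse=True)
    n_res = unique_resids.size
    u = mda.Universe.empty(
        traj.n_atoms, n_residues=n_res, atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=False,
    )
    u.add_TopologyAttr("names", traj.atoms["name"].tolist())
    first = pd.Series(range(len(resids))).groupby(resids).first()
    u.add_TopologyAttr("resnames", traj.atoms["resname"].to_numpy()[first.to_numpy()].tolist())
    u.add_TopologyAttr("resids", unique_resids.tolist())
    u.add_TopologyAttr("segids", ["A"])
    dims = np.column_stack([traj.box * 10.0, np.full((traj.n_frames, 3), 90.0)])
    u.load_new(traj.coordinates * 10.0, format=MemoryReader, dimensions=dims)
    with mda.Writer(str(path), multiframe=True) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)
    return path


def _cryst1_box_nm(path: Path) -> np.ndarray | None:
    """First CRYST1 record of a PDB, in nm; None if absent."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                return np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33])]) / 10.0
    return None


def read_trajectory_pdb(path) -> Trajectory:
    """Multi-model PDB through MDAnalysis (Angstrom -> nm)."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    # some multi-model PDBs lose their single leading CRYST1 in per-frame
    # timesteps; fall back to parsing it directly, then to the coordinate span
    fallback = _cryst1_box_nm(path)
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3))
    box = np.empty((n_frames, 3))
    times = np.empty(n_frames)
    for f, ts in enumerate(u.trajectory):
        coords[f] = u.atoms.positions / 10.0
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box[f] = ts.dimensions[:3] / 10.0
        elif fallback is not None:
            box[f] = fallback
        else:
            box[f] = coords[f].max(axis=0) - coords[f].min(axis=0) + 2.0
        times[f] = getattr(ts, "time", float(f))
    chains = (
        u.atoms.chainIDs if hasattr(u.atoms, "chainIDs") else
        (u.atoms.segids if hasattr(u.atoms, "segids") else ["A"] * len(u.atoms))
    )
    atoms = make_atom_table(
        list(u.atoms.names), list(u.atoms.resnames), list(u.atoms.resids), list(chains)
    )
    return Trajectory(coords, atoms, box, times)


def read_trajectory(path) -> Trajectory:
    """Dispatch on extension: .pdb via MDAnalysis, anything else as text."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_trajectory_pdb(path)
    return read_trajectory_text(path)


# --- umbrella windows and PMF ----------------------------------------------


def write_windows(windows: list[UmbrellaWindow], directory, manifest_name="windows.tsv") -> Path:
    """One two-column (time, xi) series file per window plus a TSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.txt"
        series = np.column_stack([np.arange(w.n_samples, dtype=float), w.samples])
        np.savetxt(directory / fname, series, fmt="%.6f")
        rows.append((fname, w.center, w.spring_k, w.temperature))
    manifest = directory / manifest_name
    df = pd.DataFrame(rows, columns=["file", "center_nm", "k_kj_mol_nm2", "temperature_k"])
    df.to_csv(manifest, sep="\t", index=False)
    return manifest


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    windows = []
    for _, row in df.iterrows():
        series = np.loadtxt(manifest_path.parent / row["file"])
        samples = series[:, 1] if series.ndim == 2 else series
        windows.append(
            UmbrellaWindow(
                center=float(row["center_nm"]),
                spring_k=float(row["k_kj_mol_nm2"]),
                samples=samples,
                temperature=float(row["temperature_k"]),
            )
        )
    return windows


def write_pmf(profile: PMFProfile, path) -> Path:
    path = Path(path)
    unc = profile.uncertainty if profile.uncertainty is not None else np.full_like(
        profile.free_energy, np.nan
    )
    df = pd.DataFrame(
        {
            "center_nm": profile.bin_centers,
            "free_energy_kj_mol": profile.free_energy,
            "count": profile.counts,
            "uncertainty_kj_mol": unc,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# --- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Defaults shared by the CLI; a TOML file can override any field and the
    command line overrides the file (precedence CLI > file > defaults)."""

    chi_hz: float = DEFAULT_CHI_HZ
    geometry_factor: float = DEFAULT_GEOMETRY_FACTOR
    temperature_k: float = DEFAULT_TEMPERATURE_K
    rmsrd_threshold_pct: float = DEFAULT_RMSRD_THRESHOLD_PCT
    wham_bins: int = DEFAULT_N_BINS
    wham_tol_kt: float = DEFAULT_TOL_KT
    wham_max_iter: int = DEFAULT_MAX_ITER
    pairing_tolerance_hz: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.chi_hz <= 0 or self.temperature_k <= 0:
            raise ConfigError("chi_hz and temperature_k must be positive")
        if self.geometry_factor not in (0.5, 1, 1.0):
            raise ConfigError("geometry_factor must be 0.5 or 1")
        if self.rmsrd_threshold_pct <= 0 or self.wham_bins < 2:
            raise ConfigError("rmsrd_threshold_pct must be > 0 and wham_bins >= 2")

    def as_dict(self):
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Merge defaults, a TOML file, and explicit overrides (highest wins).

    Unknown keys in the file are rejected by name rather than ignored, so a
    typo cannot silently fall back to a default.
    """
    known = {f.name for f in fields(RunConfig)}
    values = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    return RunConfig(**values)
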