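"""In-memory trajectory container.

Coordinates are in nm, times in ps, and the box is orthorhombic with the
bilayer normal along z; after centering, the bilayer midplane sits at z = 0.
Atom metadata lives in a pandas table with columns ``name``, ``resname``,
``resid`` and ``chain`` so selections and per-residue grouping stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .selections import select_indices

ATOM_COLUMNS = ("name", "resname", "resid", "chain")


def make_atom_table(names, resnames, resids, chains=None) -> pd.DataFrame:
    names = list(names)
    n = len(names)
    if chains is None:
        chains = ["A"] * n
    table = pd.DataFrame(
        {
            "name": names,
            "resname": list(resnames),
            "resid": np.asarray(resids, dtype=int),
            "chain": list(chains),
        }
    )
    return table


@dataclass
class Trajectory:
    """frames x atoms x 3 coordinates (nm) plus atom metadata and box."""

    coordinates: np.ndarray
    atoms: pd.DataFrame
    box: np.ndarray
    times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InvalidParameterError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        n_frames, n_atoms, _ = self.coordinates.shape
        if len(self.atoms) != n_atoms:
            raise InvalidParameterError(
                f"atom table has {len(self.atoms)} rows for {n_atoms} atoms"
            )
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InvalidParameterError(f"atom table missing columns {missing}")
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (n_frames, 3)).copy()
        if box.shape != (n_frames, 3):
            raise InvalidParameterError(
                f"box must be (3,) or (frames, 3), got {np.asarray(self.box).shape}"
            )
        if not np.all(box > 0):
            raise InvalidParameterError("box lengths must be positive")
        self.box = box
        if self.times is None:
            self.times = np.arange(n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (n_frames,):
                raise InvalidParameterError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, expression: str) -> np.ndarray:
        """Atom indices matching the selection mini-language."""
        return select_indices(self.atoms, expression)
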