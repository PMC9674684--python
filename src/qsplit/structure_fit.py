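"""Configuration search: rank rigid peptide placements against experiment.

The equilibrium membrane-bound configuration is found by scoring candidate
placements (tilt, azimuth, insertion depth) through the root-mean-square
relative deviation (RMSRD) between the splittings each placement predicts and
the experimental ones.  A placement is accepted when its RMSRD drops below a
threshold (50 % by default); all evaluated candidates come back ranked.

The trajectory for each placement is injected through a provider callable:
in production that is externally run MD, in tests the synthetic fixture
generator.  This module never launches an MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    CandidateEvaluationError,
    FragmentMismatchError,
    InvalidParameterError,
    UndefinedRelativeDeviationError,
)
from .order_params import (
    DEFAULT_CHI_HZ,
    DEFAULT_GEOMETRY_FACTOR,
    BondSelection,
    predict_splitting_set,
)
from .spectra import SplittingSet
from .trajectory import Trajectory

#: accept threshold on RMSRD, percent
DEFAULT_RMSRD_THRESHOLD_PCT = 50.0


@dataclass(frozen=True)
class CandidateConfiguration:
    """A rigid placement of the peptide in the bilayer frame.

    tilt (deg, [0, 180]) and azimuth (deg, [0, 360)) orient the peptide axis
    relative to the bilayer normal; depth (nm, signed) is the center-of-mass
    z offset from the bilayer midplane.  ``seed`` identifies the candidate and
    seeds whatever stochastic machinery realises it.
    """

    tilt: float
    azimuth: float
    depth: float
    seed: int
    predicted: SplittingSet | None = None
    rmsrd: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.tilt <= 180.0:
            raise InvalidParameterError(f"tilt must lie in [0, 180] deg, got {self.tilt}")
        if not 0.0 <= self.azimuth < 360.0:
            raise InvalidParameterError(f"azimuth must lie in [0, 360) deg, got {self.azimuth}")
        if self.rmsrd is not None and self.rmsrd < 0:
            raise InvalidParameterError("rmsrd must be >= 0")


def rmsrd(predicted: SplittingSet, experimental: SplittingSet) -> float:
    """Root-mean-square relative deviation between splitting sets, percent.

    Within each fragment, predicted and experimental splittings are matched by
    the minimum-cost one-to-one assignment on |(p - e) / e| (fragments carry at
    most two splittings, so the assignment is tiny).  Experimental splittings
    with no predicted partner contribute a relative deviation of 1.0, so a
    missing doublet can never improve the score.  The mean square runs over
    all experimental entries.
    """
    exp_labels = set(experimental.fragments)
    missing = exp_labels - set(predicted.fragments)
    if missing:
        raise FragmentMismatchError(
            f"predicted set lacks experimental fragments: {sorted(missing)}"
        )
    sq_devs: list[float] = []
    for fragment in experimental.fragments:
        e = np.asarray(experimental[fragment], dtype=float)
        if np.any(e == 0):
            raise UndefinedRelativeDeviationError(
                f"fragment {fragment!r} has an experimental splitting of 0 Hz; "
                "relative deviation is undefined"
            )
        p = np.asarray(predicted[fragment], dtype=float)
        cost = np.abs((p[None, :] - e[:, None]) / e[:, None])  # (n_exp, n_pred)
        rows, cols = linear_sum_assignment(cost)
        sq_devs.extend(cost[rows, cols] ** 2)
        sq_devs.extend([1.0] * (e.size - rows.size))  # unmatched experimental
    return 100.0 * math.sqrt(float(np.mean(sq_devs)))


def generate_candidates(
    n: int,
    depth_range: tuple[float, float] = (-3.0, 3.0),
    seed: int = 0,
) -> list[CandidateConfiguration]:
    """Draw ``n`` random placements, reproducibly from ``seed``.

    Tilt is uniform on the sphere (uniform in cos tilt), azimuth uniform on
    [0, 360), depth uniform over ``depth_range``.  Each candidate receives its
    own derived seed for downstream stochastic realisation.
    """
    if n < 1:
        raise InvalidParameterError(f"need n >= 1 candidates, got {n}")
    lo, hi = depth_range
    if not lo < hi:
        raise InvalidParameterError(f"empty depth range {depth_range}")
    rng = np.random.default_rng(seed)
    cos_tilt = rng.uniform(-1.0, 1.0, n)
    tilt = np.degrees(np.arccos(cos_tilt))
    azimuth = rng.uniform(0.0, 360.0, n)
    depth = rng.uniform(lo, hi, n)
    seeds = rng.integers(0, 2**31 - 1, n)
    return [
        CandidateConfiguration(
            tilt=float(tilt[i]),
            azimuth=float(azimuth[i] % 360.0),
            depth=float(depth[i]),
            seed=int(seeds[i]),
        )
        for i in range(n)
    ]


TrajectoryProvider = Callable[[CandidateConfiguration], Trajectory]


def evaluate_candidate(
    cand: CandidateConfiguration,
    traj_provider: TrajectoryProvider,
    selections: Sequence[BondSelection],
    experimental: SplittingSet,
    chi: float = DEFAULT_CHI_HZ,
    geometry_factor: float = DEFAULT_GEOMETRY_FACTOR,
) -> CandidateConfiguration:
    """Realise a candidate, predict its splittings, and score it.

    Provider failures are re-raised as :class:`CandidateEvaluationError`
    carrying the candidate seed so a long search can report which placement
    broke.  Returns a scored copy; the input is untouched.
    """
    try:
        traj = traj_provider(cand)
    except Exception as exc:
        raise CandidateEvaluationError(
            f"trajectory provider failed for candidate seed {cand.seed}: {exc}",
            candidate_seed=cand.seed,
        ) from exc
    predicted = predict_splitting_set(traj, selections, chi=chi, geometry_factor=geometry_factor)
    score = rmsrd(predicted, experimental)
    return replace(cand, predicted=predicted, rmsrd=score)


def search(
    candidates: Sequence[CandidateConfiguration],
    traj_provider: TrajectoryProvider,
    selections: Sequence[BondSelection],
    experimental: SplittingSet,
    chi: float = DEFAULT_CHI_HZ,
    geometry_factor: float = DEFAULT_GEOMETRY_FACTOR,
    threshold: float = DEFAULT_RMSRD_THRESHOLD_PCT,
    stop_on_first: bool = False,
) -> list[CandidateConfiguration]:
    """Evaluate candidates in order and rank them by RMSRD.

    With ``stop_on_first``, evaluation halts at the first candidate whose
    RMSRD is at or below ``threshold`` — the sequential accept rule of a
    simulate-until-it-fits campaign.  All evaluated candidates are returned,
    sorted ascending by RMSRD with ties broken by candidate seed, so the
    ranking is deterministic regardless of evaluation strategy.
    """
    if not threshold > 0:
        raise InvalidParameterError(f"threshold must be positive, got {threshold}")
    evaluated: list[CandidateConfiguration] = []
    for cand in candidates:
        scored = evaluate_candidate(
            cand, traj_provider, selections, experimental, chi, geometry_factor
        )
        evaluated.append(scored)
        if stop_on_first and scored.rmsrd <= threshold:
            break
    return sorted(evaluated, key=lambda c: (c.rmsrd, c.seed))
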