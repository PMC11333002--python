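"""Trajectory helicity and extension statistics.

Operates on :class:`StateTrajectory` objects — per-frame helix/coil state
strings plus end-to-end distances — and computes the observables used to
characterise a helix under constant force: longest contiguous helical run,
the conditional fraction of time the chain holds a run of at least L
residues while extended beyond a threshold, total helical content, and
end-to-end distance summaries.  All statistics discard an initial burn-in
(time units), mirroring the practice of dropping the initial unfolding
transient of a constant-force production run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyAnalysisError, InvalidArgumentError, ParseError

__all__ = [
    "StateTrajectory",
    "RunStatSpec",
    "ExtensionSummary",
    "longest_run",
    "longest_runs",
    "conditional_run_fraction",
    "helicity_time_fraction",
    "helical_content",
    "extension_stats",
]


@dataclass
class StateTrajectory:
    """Frames × residues helix/coil states with end-to-end distances.

    Attributes
    ----------
    times_ns : (n_frames,) strictly increasing time stamps, ns.
    helix : (n_frames, n_residues) boolean, True where a residue is helical.
    e2e_nm : (n_frames,) end-to-end distance, nm (positive).
    force_pn : applied constant force, pN (metadata).
    label : free-text run label.
    production : True for a constant-force production run, where a default
        burn-in applies when building reports.
    """

    times_ns: np.ndarray
    helix: np.ndarray
    e2e_nm: np.ndarray
    force_pn: float = 0.0
    label: str = ""
    production: bool = False

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, float)
        self.helix = np.asarray(self.helix, bool)
        self.e2e_nm = np.asarray(self.e2e_nm, float)
        if self.helix.ndim != 2:
            raise InvalidArgumentError("helix must be 2-D (frames × residues)")
        nf = self.helix.shape[0]
        if self.times_ns.shape != (nf,) or self.e2e_nm.shape != (nf,):
            raise InvalidArgumentError("times/e2e lengths must match frames")
        if nf > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(self.e2e_nm <= 0):
            raise InvalidArgumentError("end-to-end distances must be positive")

    @property
    def n_frames(self) -> int:
        return self.helix.shape[0]

    @property
    def n_residues(self) -> int:
        return self.helix.shape[1]

    def state_strings(self) -> list[str]:
        return ["".join("H" if x else "C" for x in row) for row in self.helix]

    @classmethod
    def from_strings(cls, times_ns, states: list[str], e2e_nm,
                     **meta) -> "StateTrajectory":
        helix = np.array([_parse_states(s) for s in states], dtype=bool)
        return cls(np.asarray(times_ns, float), helix,
                   np.asarray(e2e_nm, float), **meta)


def _parse_states(s: str) -> np.ndarray:
    if not s or set(s) - {"H", "C"}:
        raise ParseError(f"invalid state string {s!r}: must be non-empty over H/C")
    return np.frombuffer(s.encode(), dtype="S1") == b"H"


@dataclass(frozen=True)
class RunStatSpec:
    """Parameters of the conditional run statistic."""

    min_run_length: int = 4
    extension_threshold_nm: float = 3.0
    burn_in_ns: float = 1000.0

    def __post_init__(self) -> None:
        if self.min_run_length < 1:
            raise InvalidArgumentError("min_run_length must be >= 1")
        if self.extension_threshold_nm <= 0:
            raise InvalidArgumentError("extension_threshold must be > 0")
        if self.burn_in_ns < 0:
            raise InvalidArgumentError("burn_in must be >= 0")


@dataclass(frozen=True)
class ExtensionSummary:
    mean_nm: float
    std_nm: float
    fraction_at_or_above_threshold: float  # percent


def longest_run(states: str) -> int:
    """Length of the longest contiguous 'H' substring (0 if none)."""
    mask = _parse_states(states)
    return int(_longest_runs_bool(mask[None, :])[0])


def longest_runs(traj: StateTrajectory) -> np.ndarray:
    """Per-frame longest contiguous helical run lengths."""
    return _longest_runs_bool(traj.helix)


def _longest_runs_bool(helix: np.ndarray) -> np.ndarray:
    run = np.zeros(helix.shape[0], dtype=np.int64)
    best = np.zeros(helix.shape[0], dtype=np.int64)
    for j in range(helix.shape[1]):
        run = (run + 1) * helix[:, j]
        np.maximum(best, run, out=best)
    return best


def _post_burn_in(traj: StateTrajectory, burn_in_ns: float) -> np.ndarray:
    keep = traj.times_ns >= burn_in_ns
    if not np.any(keep):
        raise EmptyAnalysisError(
            f"burn-in {burn_in_ns} ns leaves no frames "
            f"(trajectory ends at {traj.times_ns[-1]} ns)"
        )
    return keep


def conditional_run_fraction(traj: StateTrajectory, spec: RunStatSpec
                             ) -> float:
    """Percent of post-burn-in frames holding an uninterrupted helical run of
    at least ``min_run_length`` residues while the end-to-end distance is at
    or above the extension threshold.

    The denominator is *all* post-burn-in frames, not only the extended
    ones, so the result is bounded above by the plain extension fraction.
    """
    keep = _post_burn_in(traj, spec.burn_in_ns)
    runs = longest_runs(traj)[keep]
    e2e = traj.e2e_nm[keep]
    hit = (runs >= spec.min_run_length) & (e2e >= spec.extension_threshold_nm)
    return 100.0 * float(np.mean(hit))


def helicity_time_fraction(traj: StateTrajectory, min_run: int = 4,
                           burn_in_ns: float = 0.0) -> float:
    """Percent of post-burn-in frames whose longest helical run is >= min_run."""
    if min_run < 1:
        raise InvalidArgumentError("min_run must be >= 1")
    keep = _post_burn_in(traj, burn_in_ns)
    runs = longest_runs(traj)[keep]
    return 100.0 * float(np.mean(runs >= min_run))


def helical_content(traj: StateTrajectory, burn_in_ns: float = 0.0) -> float:
    """Percent of helical residue-frames among all post-burn-in residue-frames."""
    keep = _post_burn_in(traj, burn_in_ns)
    return 100.0 * float(np.mean(traj.helix[keep]))


def extension_stats(traj: StateTrajectory, threshold_nm: float = 3.0,
                    burn_in_ns: float = 0.0) -> ExtensionSummary:
    """Mean, population std, and inclusive threshold-exceedance percent of the
    post-burn-in end-to-end series."""
    keep = _post_burn_in(traj, burn_in_ns)
    e2e = traj.e2e_nm[keep]
    return ExtensionSummary(
        mean_nm=float(np.mean(e2e)),
        std_nm=float(np.std(e2e)),
        fraction_at_or_above_threshold=100.0 * float(np.mean(e2e >= threshold_nm)),
    )
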