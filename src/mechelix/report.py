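"""End-to-end helicity report: a run-length × force matrix of conditional
helicity fractions plus per-force extension and helicity summaries.

The matrix mirrors the standard presentation of constant-force helix
statistics: rows are minimum continuous-run lengths (residues), columns are
force magnitudes, and each cell is the percentage of post-burn-in frames in
which the chain holds an uninterrupted helical run of at least that length
while extended to at least the threshold distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import HelixCoilParams, simulate_helix_coil
from .errors import InvalidArgumentError
from .helicity import (ExtensionSummary, RunStatSpec, StateTrajectory,
                       conditional_run_fraction, extension_stats,
                       helical_content, helicity_time_fraction)

__all__ = ["ReportConfig", "AnalysisReport", "run_report"]

DEFAULT_RUN_THRESHOLDS = (4, 8, 12, 16, 20)


@dataclass(frozen=True)
class ReportConfig:
    """Configuration of a full helicity report."""

    forces_pn: tuple[float, ...] = (10.0, 15.0, 20.0)
    run_thresholds: tuple[int, ...] = DEFAULT_RUN_THRESHOLDS
    extension_threshold_nm: float = 3.0
    burn_in_ns: float = 1000.0
    n_frames: int = 5000
    frame_stride: int = 10
    seed: int = 0
    params: HelixCoilParams = field(default_factory=HelixCoilParams)

    def __post_init__(self) -> None:
        if not self.forces_pn:
            raise InvalidArgumentError("need at least one force")
        if any(l < 1 for l in self.run_thresholds):
            raise InvalidArgumentError("run thresholds must be >= 1")


@dataclass
class AnalysisReport:
    """Result bundle of :func:`run_report`."""

    conditional_matrix: pd.DataFrame  # rows: min run length; cols: force
    extension: dict[float, ExtensionSummary]
    helicity_fraction: dict[float, float]
    helical_content: dict[float, float]
    config: ReportConfig

    def to_tsv(self, path) -> None:
        self.conditional_matrix.to_csv(path, sep="\t",
                                       float_format="%.2f")

    def __str__(self) -> str:
        lines = ["Conditional helicity matrix (% of post-burn-in frames with "
                 f"run >= L and e2e >= {self.config.extension_threshold_nm:g} nm)",
                 self.conditional_matrix.to_string(float_format="%.1f"), ""]
        for f in self.config.forces_pn:
            s = self.extension[f]
            lines.append(
                f"{f:g} pN: e2e {s.mean_nm:.2f} ± {s.std_nm:.2f} nm, "
                f">= {self.config.extension_threshold_nm:g} nm "
                f"{s.fraction_at_or_above_threshold:.1f}% of frames; "
                f"helicity (run >= 4) {self.helicity_fraction[f]:.1f}%; "
                f"helical content {self.helical_content[f]:.1f}%")
        return "\n".join(lines)


def run_report(config: ReportConfig,
               trajectories: dict[float, StateTrajectory] | None = None,
               ) -> AnalysisReport:
    """Simulate (or accept) one trajectory per force and compute all
    helicity statistics.

    Any error (e.g. a burn-in longer than a trajectory) propagates; no
    partial report is produced.
    """
    if trajectories is None:
        trajectories = {
            f: simulate_helix_coil(
                config.params.with_force(f), config.n_frames,
                config.frame_stride, seed=config.seed + i)
            for i, f in enumerate(config.forces_pn)
        }
    matrix = {}
    extension = {}
    hfrac = {}
    content = {}
    for f in config.forces_pn:
        traj = trajectories[f]
        burn = config.burn_in_ns if traj.production else 0.0
        col = [conditional_run_fraction(
                   traj, RunStatSpec(L, config.extension_threshold_nm, burn))
               for L in config.run_thresholds]
        matrix[f"{f:g} pN"] = col
        extension[f] = extension_stats(
            traj, config.extension_threshold_nm, burn)
        hfrac[f] = helicity_time_fraction(traj, 4, burn)
        content[f] = helical_content(traj, burn)
    df = pd.DataFrame(
        matrix, index=pd.Index(
            [f">= {l}" for l in config.run_thresholds], name="run length"))
    return AnalysisReport(df, extension, hfrac, content, config)
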