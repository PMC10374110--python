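"""Substitutions-to-bacterial-generations calibration.

Simulation updates have no intrinsic wall-clock meaning, so runs are
anchored to microbial time with a Fermi estimate: count the substitutions
accumulated along a focal lineage (root-to-tip mutation count in the
genotype phylogeny), treat one fixed digital mutation as one E. coli
substitution, and divide by the per-generation substitution rate.  With
the default constants - about 400 substitutions along the lineage of the
final most abundant parasite over a 250,000-update run, and 1-2 x 10^-4
substitutions per E. coli generation - a full run corresponds to roughly
2-4 million bacterial generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import CommunityTrajectory, Phylogeny


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the generations-equivalence estimate.

    subs_per_run: substitutions along the focal lineage over a full run.
    run_length:   updates per full run.
    mu_low/high:  substitutions per bacterial generation (E. coli range).
    """

    subs_per_run: float = 400.0
    run_length: int = 250_000
    mu_low: float = 1e-4
    mu_high: float = 2e-4

    def __post_init__(self) -> None:
        if min(self.subs_per_run, self.run_length, self.mu_low, self.mu_high) <= 0:
            raise ValueError("all calibration constants must be positive")
        if self.mu_low > self.mu_high:
            raise ValueError("mu_low must not exceed mu_high")


def lineage_substitutions(phylogeny: Phylogeny, tip_id: int) -> int:
    """Substitutions along the lineage from a tip back to its root."""
    return int(sum(phylogeny.nmut[g] for g in phylogeny.root_path(tip_id)))


def observed_subs_per_run(trajectory: CommunityTrajectory) -> int | None:
    """Root-to-tip substitutions of the most abundant parasite in the
    last snapshot where pathogens are extant, the empirical analogue of
    ``CalibrationParams.subs_per_run`` (None when the run never had
    pathogens)."""
    for i in range(len(trajectory.updates) - 1, -1, -1):
        ids = trajectory.path_ids[i]
        if len(ids):
            top = int(ids[np.argmax(trajectory.path_counts[i])])
            return lineage_substitutions(trajectory.phylogeny, top)
    return None


def generations_equivalent(updates: float,
                           params: CalibrationParams = CalibrationParams()
                           ) -> tuple[float, float]:
    """Bacterial-generation equivalent of a span of updates.

    The span is converted to substitutions pro rata
    (updates x subs_per_run / run_length), then divided by the high and
    low per-generation rates to give the (low, high) generation bounds.
    Linear in ``updates``; low <= high always.
    """
    if updates <= 0:
        raise ValueError("updates must be positive")
    subs = updates * params.subs_per_run / params.run_length
    return subs / params.mu_high, subs / params.mu_low
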