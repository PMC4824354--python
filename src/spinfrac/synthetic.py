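"""Synthetic count tables with known ground truth.

Count tables are sampled per disk and class from a multinomial over
sections, so per-class totals are exact and retention fractions converge
to the generating probabilities.  A fixture helper converts a predicted
partition map into a near-deterministic probability spec, closing the
loop model -> expected partition -> sampled counts -> measured metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .device import CellSpecies, LaneDesign, SpinProtocol
from .metrics import CountTable
from .sedimentation import predict_partitions

__all__ = ["GenerationSpec", "generate_count_table", "generate_prediction_fixture"]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class GenerationSpec:
    """Ground truth for a synthetic count table.

    probabilities maps cell class -> (section -> probability); each
    class's probabilities must sum to 1.  totals gives the per-disk total
    count of each class.  One seed governs the whole spec; each disk uses
    a stream derived from it by a fixed increment, so disk d of a spec is
    reproducible independently of how many disks are generated.
    """

    probabilities: Mapping[str, Mapping[str, float]]
    totals: Mapping[str, int]
    n_disks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disks < 1:
            raise ValueError(f"n_disks must be >= 1, got {self.n_disks}")
        if set(self.probabilities) != set(self.totals):
            raise ValueError(
                f"classes in probabilities {sorted(self.probabilities)} and "
                f"totals {sorted(self.totals)} must match"
            )
        for cls, probs in self.probabilities.items():
            p = np.asarray(list(probs.values()), dtype=float)
            if (p < 0).any():
                raise ValueError(f"class {cls!r} has negative probabilities")
            if abs(p.sum() - 1.0) > _PROB_TOL:
                raise ValueError(
                    f"class {cls!r} probabilities sum to {p.sum():.12f}, expected 1"
                )
            if self.totals[cls] <= 0:
                raise ValueError(f"class {cls!r} total must be > 0, got {self.totals[cls]}")


def generate_count_table(spec: GenerationSpec) -> CountTable:
    """Sample a multi-disk count table from the spec (deterministic given
    the seed)."""
    rows: list[tuple[int, str, str, int]] = []
    for d in range(spec.n_disks):
        rng = np.random.default_rng(spec.seed + d)
        for cls, probs in spec.probabilities.items():
            sections = list(probs)
            p = np.asarray([probs[s] for s in sections], dtype=float)
            p = p / p.sum()  # renormalize away float slack
            counts = rng.multinomial(spec.totals[cls], p)
            rows.extend((d + 1, sec, cls, int(c)) for sec, c in zip(sections, counts))
    return CountTable.from_records(rows)


def generate_prediction_fixture(
    lane: LaneDesign,
    panel: Sequence[CellSpecies],
    protocol: SpinProtocol,
    totals: Mapping[str, int] | int = 100_000,
    n_disks: int = 3,
    epsilon: float = 0.02,
    seed: int = 0,
) -> GenerationSpec:
    """Build a GenerationSpec from the model's predicted partition.

    Each species gets probability 1 - epsilon on its predicted section
    and epsilon spread uniformly over the remaining sections of the lane
    (carry-over / imperfect banking).  `totals` may be a single per-class
    total or a per-class mapping.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    partition = predict_partitions(panel, lane, protocol)
    labels = list(lane.labels)
    n_other = len(labels) - 1
    probabilities: dict[str, dict[str, float]] = {}
    for species, target in partition.items():
        if n_other == 0:
            probabilities[species] = {target: 1.0}
            continue
        spread = epsilon / n_other
        probabilities[species] = {
            lab: (1.0 - epsilon) if lab == target else spread for lab in labels
        }
    if isinstance(totals, int):
        totals = {species: totals for species in probabilities}
    return GenerationSpec(
        probabilities=probabilities, totals=dict(totals), n_disks=n_disks, seed=seed
    )
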