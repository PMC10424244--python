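"""Experiment-design planning: compositions x replicates x production length.

Mirrors the production study matrix: five aminolipid fractions (10-50%),
three independent replicates each, 3 us of production per replicate, with
the final 1 us analysed.  These are microseconds of planned engine time, not
anything this package simulates; the planner only does the arithmetic and
enumerates reproducible per-job seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: SHA-256 of (master seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class StudyDesign:
    compositions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    replicates_per_composition: int = 3
    production_length_us: float = 3.0
    analysis_window_us: float = 1.0

    def __post_init__(self) -> None:
        if self.replicates_per_composition < 1:
            raise ValueError("replicates_per_composition must be >= 1")
        fr = self.compositions
        if any(not 0.0 < f < 1.0 for f in fr) or any(
            b <= a for a, b in zip(fr, fr[1:])
        ):
            raise ValueError("compositions must be strictly increasing fractions in (0, 1)")


@dataclass
class StudyPlan:
    per_composition_sampling_us: float
    total_sampling_us: float
    jobs: list[dict] = field(default_factory=list)


def plan_study(design: StudyDesign, master_seed: int = 0) -> StudyPlan:
    """Sampling arithmetic plus the (composition, replicate, seed) job list."""
    per_comp = design.replicates_per_composition * design.production_length_us
    total = per_comp * len(design.compositions)
    jobs = [
        {
            "l5_fraction": frac,
            "replicate": rep,
            "seed": derive_seed(master_seed, f"insert:{frac:.2f}:{rep}"),
            "production_us": design.production_length_us,
            "analysis_window_us": design.analysis_window_us,
        }
        for frac in design.compositions
        for rep in range(1, design.replicates_per_composition + 1)
    ]
    return StudyPlan(
        per_composition_sampling_us=per_comp, total_sampling_us=total, jobs=jobs
    )
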