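"""The study conditions exercised by the analysis scripts and tests.

The design mirrors the replicate structure of a depth-ladder simulation
experiment — many shallow replicates, one deepest sample (20/10/4/2/1
replicates at increasing depth) — run at desk scale: a 5,000-transcript
panel and depths of 0.1-2 million read pairs (the original ladder divided
by 100). A second, smaller ladder with disjoint 25%/50%/75% partitions of a
deep read pool stands in for the long-read subsampling arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synthetic_data import (
    ReferencePanel,
    SimulatedSample,
    SimulationConfig,
    generate_reference,
    simulate_depth_series,
)

PANEL_SIZE = 5_000
DEPTHS = (100_000, 200_000, 500_000, 1_000_000, 2_000_000)
REPLICATES = (20, 10, 4, 2, 1)
INCREMENT_STEP = 100_000  # 10 million reads scaled by the same /100 factor


def study_config(seed: int, n_transcripts: int = PANEL_SIZE) -> SimulationConfig:
    return SimulationConfig(n_transcripts=n_transcripts, seed=seed)


def study_panel(seed: int, n_transcripts: int = PANEL_SIZE) -> ReferencePanel:
    return generate_reference(study_config(seed, n_transcripts))


@dataclass
class StudyRun:
    config: SimulationConfig
    panel: ReferencePanel
    samples: list[SimulatedSample] = field(default_factory=list)

    @property
    def depths(self):
        return DEPTHS


def run_depth_ladder(seed: int, n_transcripts: int = PANEL_SIZE) -> StudyRun:
    """Simulate the full depth ladder (37 samples) at the study conditions."""
    config = study_config(seed, n_transcripts)
    panel = generate_reference(config)
    samples = simulate_depth_series(panel, DEPTHS, list(REPLICATES), config, seed)
    return StudyRun(config=config, panel=panel, samples=samples)
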