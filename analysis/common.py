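"""Shared configuration for the numbered analysis scripts.

One deterministic cohort is used across all stages: 8 subjects at the
full per-subject design (3 intensities x 120 pulses x 2 repetitions,
eight muscles). Every script rebuilds what it needs from this seed, so
the stages can also be run independently.
"""

from pathlib import Path

from tmsmap.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONFIG = RunConfig(seed=11, n_subjects=8)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
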