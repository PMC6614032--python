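"""Shared configuration for the analysis scripts.

One seed and one study configuration, so every script in the sequence
operates on the same synthetic world and the whole analysis re-runs
bit-identically.
"""
from pathlib import Path

import urbheat as uh

SEED = 2017

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"
STUDY = RESULTS / "study"
TABLES = RESULTS / "tables"


def study_config() -> uh.RunConfig:
    """The desk-scale study: 6 models of differing native resolution,
    2 emissions scenarios, 50 cities, 0.5 degC monthly noise."""
    return uh.default_config(seed=SEED)
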