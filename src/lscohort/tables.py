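"""Loaders for the versioned YAML band tables shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=None)
def load_score_bands() -> dict:
    """CONUT band points, tercile cut-offs, risk-category boundaries."""
    text = resources.files("lscohort.data").joinpath("score_bands.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=None)
def load_framingham_tables() -> dict:
    """Categorical Framingham point tables (1998 coefficients), TC and LDL modes."""
    text = (
        resources.files("lscohort.data")
        .joinpath("framingham_wilson1998.yaml")
        .read_text()
    )
    return yaml.safe_load(text)
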