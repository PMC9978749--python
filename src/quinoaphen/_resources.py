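"""Access to packaged reference tables (calibration ranges, amino-acid requirements)."""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    ref = resources.files("quinoaphen.resources").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def calibration_ranges_raw() -> dict:
    return _load("calibration_ranges.json")


def amino_acid_requirements_raw() -> dict:
    return _load("amino_acid_requirements.json")
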