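"""Bundled fixtures: the 14-solvent case-study panel and its solvent database.

``solvents.csv`` holds the 14 test solvents used for the PTPA163 case study
(a carboxylic-acid-functionalized polytriphenylamine porous polymer) with
their published HSPs; CAS numbers, synonyms and SMILES come from standard
registry data. ``case_study_measurements.csv`` holds the corresponding
UV/vis maximum absorbances (benzenoid band) and λmax values. Together they
are a complete worked input for :func:`hsplocate.locator.locate`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .database import SolventDatabase, load_database
from .locator import MeasurementSet, load_measurements

__all__ = [
    "bundled_database",
    "case_study_panel",
    "bundled_database_path",
    "case_study_measurements_path",
]


def _data_dir() -> Path:
    return Path(resources.files("hsplocate") / "data")


def bundled_database_path() -> Path:
    return _data_dir() / "solvents.csv"


def case_study_measurements_path() -> Path:
    return _data_dir() / "case_study_measurements.csv"


def bundled_database() -> SolventDatabase:
    """The 14-solvent fixture database (a subset of any full solvent handbook)."""
    return load_database(bundled_database_path())


def case_study_panel() -> MeasurementSet:
    """The complete case-study absorbance panel, HSPs resolved via the fixture DB."""
    return load_measurements(case_study_measurements_path(), bundled_database())
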