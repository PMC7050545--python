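"""Bundled study attribute tables and hooks for the deposited matrix.

The per-species attribute tables for the La Mancha EFN ant-plant community
(31 plants, 19 ants) are shipped with the package.  The raw interaction
matrix itself is deposited as supplementary material of the source study
and is not redistributed here; ``load_study_matrix`` reads it from a
user-supplied path.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .matrix_io import InteractionMatrix, SpeciesAttributes, read_attributes, read_matrix

#: Default location where users may drop the deposited interaction matrix.
STUDY_MATRIX_PATH = Path("data/appendix_s1_interaction_matrix.csv")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("antplantnet").joinpath("data", name)))


def load_plant_attributes() -> SpeciesAttributes:
    """Attributes of the 31 EFN-bearing plant species (EFN type, habitat, cover)."""
    return read_attributes(_data_path("plant_attributes.csv"), "plant")


def load_ant_attributes() -> SpeciesAttributes:
    """Attributes of the 19 ant species (invasive status, dominance, head length)."""
    return read_attributes(_data_path("ant_attributes.csv"), "ant")


def load_study_matrix(path: str | Path = STUDY_MATRIX_PATH) -> InteractionMatrix:
    """Read the deposited 31x19 interaction matrix from ``path``.

    Raises ``FileNotFoundError`` with guidance when the file is absent: the
    matrix is distributed only as the study's supplementary material.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"interaction matrix not found at {path}; download the study's "
            "supplementary interaction-matrix file and save it as a labeled CSV "
            "(rows = plant species, columns = ant species) at that path"
        )
    return read_matrix(path)
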