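"""Bundled reference dataset: the 2021 Lyon community-garden survey.

Small plain-text tables shipped with the package: the 23 surveyed gardens
(pollution-source distances, summed air-quality quartile scores and the
pollution variables as printed in the survey), and the per-sample field
measurements, dissolved-gas/TOC values and ionic composition of the 46 water
samples (23 noncolonized, 23 colonized).  These drive the worked examples and
the reproduction checks of the printed summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_gardens", "load_water_field", "load_water_gases", "load_water_ions"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("habitatlink.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_gardens() -> pd.DataFrame:
    """The 23 gardens: groups, distances (m), scores, printed variables."""
    return _read("gardens_lyon.csv")


def load_water_field() -> pd.DataFrame:
    """Per-sample container type and field probe measurements (46 samples)."""
    return _read("water_field.csv")


def load_water_gases() -> pd.DataFrame:
    """Per-sample dissolved gases (O2/N2 %, CH4/CO2/N2O ppm vol) and TOC."""
    return _read("water_gases.csv")


def load_water_ions() -> pd.DataFrame:
    """Per-sample anion/cation concentrations (mg/l)."""
    return _read("water_ions.csv")
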