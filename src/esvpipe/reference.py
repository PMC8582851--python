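"""Published regional summary tables for the Funiu Mountain study area.

Small reference tables shipped with the package: per-county and
per-service ESV totals for 2000–2015 (billion yuan), the first-level
influence-coefficient sums per year, and two socio-economic series
(regional GDP and urban population density). They are the inputs for
worked examples and consistency checks — e.g. the county totals summed
over 2015 reproduce the study-wide 65.754 billion yuan — not outputs
of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: The study's grid-cell count (1 km × 1 km units over 24,058 km²).
STUDY_N_CELLS = 24714

#: Years covered by the reference tables.
REFERENCE_YEARS = ["2000", "2005", "2010", "2015"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("esvpipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def county_esv() -> pd.DataFrame:
    """County × year ESV totals in billion yuan (index = county)."""
    return _read("reference_county_esv.csv").set_index("county")


def service_esv() -> pd.DataFrame:
    """Service × year ESV totals in billion yuan (index = service, with category)."""
    return _read("reference_service_esv.csv").set_index("service")


def service_totals() -> pd.Series:
    """Study-wide ESV per year in billion yuan, as printed in the structure table."""
    df = _read("reference_service_totals.csv")
    return df.set_index(df["year"].astype(str))["total"]


def influence_group_sums() -> pd.DataFrame:
    """First-level influence-coefficient sums (natural/humanistic/location) per year."""
    return _read("reference_influence_groups.csv").set_index("group")


def socioeconomic() -> pd.DataFrame:
    """Regional GDP and urban population density, 2000 vs 2015."""
    return _read("reference_socioeconomic.csv").set_index("quantity")
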