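"""Packaged reference fixtures.

The bacterial food-source chromatogram is a synthetic stand-in: the real
chromatogram of the cultured bacterial food is not publicly deposited, so
the packaged peak table was constructed by inverting the internal-standard
concentration formula from the culture's published PLFA composition
(C16:0 22.4 %, C18:1 59.9 %, C18:0 17.7 % of total PLFA carbon), with a
C19:0 internal standard record and natural-abundance δ13C values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .plfa import ExtractionRecord, PLFAPeak, parse_fatty_acid

__all__ = ["bacteria_food_chromatogram"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("spongeflux").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def bacteria_food_chromatogram() -> tuple[list[PLFAPeak], ExtractionRecord]:
    """The synthetic bacterial food-source peak table and extraction record."""
    peaks_df = _read("synthetic_bacteria_food_peaks.csv")
    ext_df = _read("synthetic_bacteria_food_extraction.csv")
    e = ext_df.iloc[0]
    ext = ExtractionRecord(
        sample_id=str(e["sample_id"]),
        sample_mass_mg=float(e["sample_mass_mg"]),
        dcm_fraction_recovered=float(e["f_recovered"]),
        standard_area=float(e["standard_area"]),
        standard_ug_c=float(e["standard_ug_c"]),
        delta13c_methanol=float(e["delta13c_methanol"]),
    )
    peaks = [
        PLFAPeak(str(r.sample_id), parse_fatty_acid(r.fatty_acid), float(r.area),
                 float(r.delta13c_fame))
        for r in peaks_df.itertuples()
    ]
    return peaks, ext
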