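"""Reference measurements for four channel proteins in Glyco-DIBMA nanodiscs.

Machine-readable transcription of the published summary values this
package's inference stage is meant to reproduce and cross-check: molecular
brightness, residence time, and diffusion coefficient per protein before
and after native PAGE (blue native, high-resolution clear native, or clear
native electrophoresis); reported particle radii; and the per-measurement
sample concentrations and monomer-fraction values quoted alongside the
correlation curves.

The proteins: GlpF, a homotetrameric aquaglyceroporin; NavMs and KvAP,
tetrameric voltage-gated cation channels; HpUreI, a hexameric urea channel.
All were labeled with Alexa Fluor 647 maleimide; the free dye's 7.5 kHz
brightness serves as the single-label ruler.

Note on the radii table: the source tabulates these under a "particle
radii" heading while the accompanying text discusses the same numbers as
hydrodynamic *diameters* (e.g. ~15 nm for the GlpF tetramer disc, vs D =
32.6 um^2/s). The values are kept verbatim under ``particle_radius_nm``;
consumers decide which reading to adopt.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["make_fixtures", "fixture_value"]

_COLS = ["protein", "gel_mode", "stage", "species", "quantity", "value", "sd", "units"]

# protein, gel_mode, stage, species, quantity, value, sd, units
_TABLE1 = [
    # GlpF tetramer, blue native PAGE
    ("GlpF", "BNE", "before", "tetramer", "brightness", 33.0, 2.0, "kHz"),
    ("GlpF", "BNE", "after", "tetramer", "brightness", 7.6, 0.9, "kHz"),
    ("GlpF", "BNE", "before", "tetramer", "residence_time", 817.0, 85.0, "us"),
    ("GlpF", "BNE", "after", "tetramer", "residence_time", 854.0, 240.0, "us"),
    ("GlpF", "BNE", "before", "tetramer", "diffusion_coefficient", 32.6, 3.8, "um^2/s"),
    ("GlpF", "BNE", "after", "tetramer", "diffusion_coefficient", 33.3, 8.1, "um^2/s"),
    # NavMs tetramer, high-resolution clear native PAGE
    ("NavMs", "hrCNE", "before", "tetramer", "brightness", 23.4, 0.4, "kHz"),
    ("NavMs", "hrCNE", "after", "tetramer", "brightness", 21.5, 0.9, "kHz"),
    ("NavMs", "hrCNE", "before", "tetramer", "residence_time", 726.0, 37.0, "us"),
    ("NavMs", "hrCNE", "after", "tetramer", "residence_time", 740.0, 62.0, "us"),
    ("NavMs", "hrCNE", "before", "tetramer", "diffusion_coefficient", 35.3, 2.1, "um^2/s"),
    ("NavMs", "hrCNE", "after", "tetramer", "diffusion_coefficient", 34.3, 2.9, "um^2/s"),
    # KvAP tetramer, high-resolution clear native PAGE
    ("KvAP", "hrCNE", "before", "tetramer", "brightness", 44.0, 0.5, "kHz"),
    ("KvAP", "hrCNE", "after", "tetramer", "brightness", 48.0, 1.7, "kHz"),
    ("KvAP", "hrCNE", "before", "tetramer", "residence_time", 880.0, 64.1, "us"),
    ("KvAP", "hrCNE", "after", "tetramer", "residence_time", 770.0, 107.0, "us"),
    ("KvAP", "hrCNE", "before", "tetramer", "diffusion_coefficient", 31.0, 3.2, "um^2/s"),
    ("KvAP", "hrCNE", "after", "tetramer", "diffusion_coefficient", 36.3, 5.1, "um^2/s"),
    # KvAP tetramer, detergent-free clear native PAGE
    ("KvAP", "CNE", "before", "tetramer", "brightness", 43.0, 1.8, "kHz"),
    ("KvAP", "CNE", "after", "tetramer", "brightness", 38.0, 1.5, "kHz"),
    ("KvAP", "CNE", "before", "tetramer", "residence_time", 747.0, 52.6, "us"),
    ("KvAP", "CNE", "after", "tetramer", "residence_time", 760.0, 20.0, "us"),
    ("KvAP", "CNE", "before", "tetramer", "diffusion_coefficient", 36.8, 2.5, "um^2/s"),
    ("KvAP", "CNE", "after", "tetramer", "diffusion_coefficient", 35.0, 2.6, "um^2/s"),
    # HpUreI hexamer, clear native PAGE
    ("HpUreI", "CNE", "before", "hexamer", "brightness", 36.0, 1.7, "kHz"),
    ("HpUreI", "CNE", "after", "hexamer", "brightness", 37.0, 0.6, "kHz"),
    ("HpUreI", "CNE", "before", "hexamer", "residence_time", 811.0, 58.7, "us"),
    ("HpUreI", "CNE", "after", "hexamer", "residence_time", 830.0, 84.2, "us"),
    ("HpUreI", "CNE", "before", "hexamer", "diffusion_coefficient", 34.0, 2.4, "um^2/s"),
    ("HpUreI", "CNE", "after", "hexamer", "diffusion_coefficient", 33.0, 3.5, "um^2/s"),
]

_TABLE2 = [
    ("GlpF", "BNE", "before", "tetramer", "particle_radius", 15.4, None, "nm"),
    ("GlpF", "BNE", "after", "tetramer", "particle_radius", 14.9, None, "nm"),
    ("NavMs", "hrCNE", "before", "tetramer", "particle_radius", 22.0, None, "nm"),
    ("NavMs", "hrCNE", "after", "tetramer", "particle_radius", 17.9, None, "nm"),
    ("KvAP", "hrCNE", "before", "tetramer", "particle_radius", 22.6, None, "nm"),
    ("KvAP", "hrCNE", "after", "tetramer", "particle_radius", 19.7, None, "nm"),
    ("KvAP", "CNE", "before", "tetramer", "particle_radius", 17.2, None, "nm"),
    ("KvAP", "CNE", "after", "tetramer", "particle_radius", 17.5, None, "nm"),
    ("HpUreI", "CNE", "before", "hexamer", "particle_radius", 16.9, None, "nm"),
    ("HpUreI", "CNE", "after", "hexamer", "particle_radius", 17.3, None, "nm"),
]

# Per-measurement values quoted with the correlation curves: sample
# concentrations (per purification route) and the monomer-fraction
# brightness/residence pairs that the summary table leaves out.
_CAPTIONS = [
    # GlpF: concentrations for tetramer/monomer after SEC, after BNE of the
    # total elution, and after BNE of SEC-purified fractions
    ("GlpF", "none", "sec", "tetramer", "concentration", 2.8, None, "nM"),
    ("GlpF", "none", "sec", "monomer", "concentration", 5.6, None, "nM"),
    ("GlpF", "BNE", "gel_total", "tetramer", "concentration", 0.16, None, "nM"),
    ("GlpF", "BNE", "gel_total", "monomer", "concentration", 2.6, None, "nM"),
    ("GlpF", "BNE", "gel_sec", "tetramer", "concentration", 0.17, None, "nM"),
    ("GlpF", "BNE", "gel_sec", "monomer", "concentration", 7.6, None, "nM"),
    ("GlpF", "BNE", "before", "monomer", "residence_time", 360.0, 72.6, "us"),
    ("GlpF", "BNE", "after", "monomer", "residence_time", 370.0, 48.2, "us"),
    ("GlpF", "BNE", "before", "monomer", "brightness", 8.5, 0.15, "kHz"),
    ("GlpF", "BNE", "after", "monomer", "brightness", 3.3, 0.2, "kHz"),
    # NavMs: concentrations after SEC, after hrCNE of the total elution,
    # and after hrCNE of SEC-purified fractions
    ("NavMs", "none", "sec", "tetramer", "concentration", 1.75, None, "nM"),
    ("NavMs", "hrCNE", "gel_total", "tetramer", "concentration", 3.1, None, "nM"),
    ("NavMs", "hrCNE", "gel_sec", "tetramer", "concentration", 0.2, None, "nM"),
    # HpUreI: hexamer/monomer concentrations for the same three routes
    ("HpUreI", "none", "sec", "hexamer", "concentration", 5.1, None, "nM"),
    ("HpUreI", "none", "sec", "monomer", "concentration", 40.0, None, "nM"),
    ("HpUreI", "CNE", "gel_total", "hexamer", "concentration", 1.6, None, "nM"),
    ("HpUreI", "CNE", "gel_total", "monomer", "concentration", 0.25, None, "nM"),
    ("HpUreI", "CNE", "gel_sec", "hexamer", "concentration", 0.16, None, "nM"),
    ("HpUreI", "CNE", "gel_sec", "monomer", "concentration", 0.5, None, "nM"),
    ("HpUreI", "CNE", "before", "monomer", "residence_time", 320.0, 32.5, "us"),
    ("HpUreI", "CNE", "after", "monomer", "residence_time", 270.0, 9.6, "us"),
    ("HpUreI", "CNE", "before", "monomer", "brightness", 9.0, 0.5, "kHz"),
    ("HpUreI", "CNE", "after", "monomer", "brightness", 7.0, 0.2, "kHz"),
]


def make_fixtures() -> dict[str, pd.DataFrame]:
    """Return the reference tables as tidy DataFrames.

    Keys: ``summary`` (brightness / residence time / diffusion coefficient
    per protein and stage), ``radii`` (reported particle radii), and
    ``captions`` (per-measurement concentrations and monomer-fraction
    values).
    """
    tables = {
        "summary": pd.DataFrame(_TABLE1, columns=_COLS),
        "radii": pd.DataFrame(_TABLE2, columns=_COLS),
        "captions": pd.DataFrame(_CAPTIONS, columns=_COLS),
    }
    for df in tables.values():
        df["sd"] = pd.to_numeric(df["sd"])
    return tables


def fixture_value(
    protein: str,
    gel_mode: str,
    stage: str,
    quantity: str,
    species: str | None = None,
) -> tuple[float, float | None]:
    """Look up one reference value, returning (value, sd).

    ``quantity`` is one of brightness, residence_time,
    diffusion_coefficient, particle_radius, concentration. ``species``
    (tetramer/hexamer/monomer) disambiguates where a protein has several
    fractions; by default the oligomer row is returned.
    """
    tables = make_fixtures()
    df = pd.concat(tables.values(), ignore_index=True)
    sel = (
        (df.protein == protein)
        & (df.gel_mode == gel_mode)
        & (df.stage == stage)
        & (df.quantity == quantity)
    )
    if species is not None:
        sel &= df.species == species
    else:
        sel &= df.species != "monomer"
    hits = df[sel]
    if len(hits) != 1:
        raise KeyError(
            f"{len(hits)} fixture rows match "
            f"({protein}, {gel_mode}, {stage}, {quantity}, {species})"
        )
    row = hits.iloc[0]
    sd = None if pd.isna(row.sd) else float(row.sd)
    return float(row.value), sd
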