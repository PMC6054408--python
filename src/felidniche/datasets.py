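"""Bundled published survey summaries used as worked-example inputs.

Two small tables from the Sabah (Malaysian Borneo) camera-trap literature
travel with the package: per-study-area independent detection counts (with
the printed detection frequencies per 100 trap-nights) for the five felids,
and adult body-mass summaries for the felid guild.  They let the arithmetic
stages of the pipeline (matrix totals, detection frequencies, body-mass
ratios) run on real printed numbers without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

FELID_SPECIES = ("clouded_leopard_pooled", "clouded_leopard_males",
                 "clouded_leopard_females", "leopard_cat", "bay_cat",
                 "marbled_cat", "flat_headed_cat")


def _read(name: str) -> pd.DataFrame:
    with resources.files("felidniche.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_survey_counts() -> pd.DataFrame:
    """Long table: study area, felid species, independent detection count and
    (where published) detection frequency per 100 trap-nights."""
    return _read("sabah_felid_survey_counts.csv")


def survey_count_matrix() -> pd.DataFrame:
    """Area x species matrix of independent detection counts."""
    long = load_survey_counts()
    return long.pivot(index="area", columns="species", values="count").astype(int)


def infer_area_effort(area: str, reference_species: str | None = None) -> float:
    """Trap-nights of one study area implied by a printed (count, frequency) pair.

    Frequency is per 100 trap-nights, so effort = 100 * count / frequency.
    By default the row with the largest count (most precise rounding) is used.
    """
    long = load_survey_counts()
    rows = long[(long["area"] == area) & long["frequency"].notna()
                & (long["frequency"] > 0)]
    if reference_species is not None:
        rows = rows[rows["species"] == reference_species]
    if rows.empty:
        raise ValueError(f"no usable (count, frequency) pair for area {area!r}")
    row = rows.loc[rows["count"].idxmax()]
    return 100.0 * float(row["count"]) / float(row["frequency"])


def load_body_mass() -> pd.DataFrame:
    """Mean adult body mass (kg) with SE and sample size per felid."""
    return _read("felid_body_mass.csv")


def body_mass_means() -> dict[str, float]:
    df = load_body_mass()
    return dict(zip(df["species"], df["mean_kg"]))
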