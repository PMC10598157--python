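"""Access to the bundled per-subject reference tables.

The package ships four small CSVs transcribed from the published per-subject
results for the eleven pigs: body mass and scan geometry (table1), head CoM
coordinates in the ACS plus principal MoI (table2), the same for the brain
(table3), and the AOJ coordinates (table4).  Coordinate tables carry the
published ``Mean``/``SD`` rows, which the loader splits off so derived
quantities can be recomputed from the per-subject rows and checked against
the printed summaries.

``data/rods_synthetic.csv`` is a synthetic calibration-rod table (plausible
HU / density pairs for a six-rod tissue phantom); the study's own rod
measurements are not published in the main text, so no real coefficients
are hard-coded anywhere.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table", "load_subject_table", "rod_table_path"]

_SUMMARY_ROWS = ("Mean", "SD")


def _data_path(name: str):
    return resources.files("ctbsp.data") / name


def load_table(which: int) -> pd.DataFrame:
    """Raw bundled table (1-4) including any Mean/SD rows."""
    return pd.read_csv(_data_path(f"table{which}.csv"))


def load_subject_table(which: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject rows and (possibly empty) printed Mean/SD summary rows.

    Returns ``(subjects, printed_summary)``; the summary frame is indexed by
    ``Mean`` / ``SD`` when the table prints them.
    """
    df = load_table(which)
    is_summary = df["subject"].astype(str).isin(_SUMMARY_ROWS)
    subjects = df[~is_summary].reset_index(drop=True)
    summary = df[is_summary].set_index("subject")
    return subjects, summary


def rod_table_path():
    """Path-like handle to the synthetic calibration-rod CSV."""
    return _data_path("rods_synthetic.csv")
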