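"""Packaged reference data: the seven-patient repaired-TOF cohort.

Three CSVs ship with the package:

* ``cohort_cmr.csv`` — per-patient demographics, peak RV pressure and
  CMR-derived RV EDV/ESV/EF (the clinical inputs of the study).
* ``reported_band_models_r20.csv`` — per-patient simulated outcomes of the
  five band plans at 20% contraction ratio.
* ``reported_plan_e_ratios.csv`` — per-patient outcomes of the three-band
  plan (E) at contraction ratios 0/10/15/20%.
* ``reported_cohort_summary.csv`` — cohort mean +/- SD rows for all 21
  model variants (baseline + 5 plans x 4 ratios).

These serve as inputs for table-arithmetic verification and as targets for
the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = (resources.files("ventriband.data") / name).read_text()
    return pd.read_csv(StringIO(text))


def cohort_cmr() -> pd.DataFrame:
    """Per-patient CMR volumes, EF and peak RV pressure."""
    return _read("cohort_cmr.csv")


def reported_band_models_r20() -> pd.DataFrame:
    """Per-patient reported outcomes, five plans at 20% contraction."""
    return _read("reported_band_models_r20.csv")


def reported_plan_e_ratios() -> pd.DataFrame:
    """Per-patient reported outcomes of the 3-band plan across ratios."""
    return _read("reported_plan_e_ratios.csv")


def reported_cohort_summary() -> pd.DataFrame:
    """Cohort mean +/- SD rows of all 21 model variants."""
    return _read("reported_cohort_summary.csv")


def baseline_ef() -> pd.Series:
    """Per-patient baseline model EF (%), reconstructed as plan-E EF minus
    plan-E delta EF (the baseline column is not printed per patient)."""
    t = reported_band_models_r20()
    e = t[t.plan == "E"].set_index("patient")
    return e.ef_pct - e.delta_ef_pct
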