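"""Published per-hemisphere detection outcomes for a surgical-epilepsy cohort.

The packaged table records, for 11 patients (13 lesional hemispheres) from
a previously reported cohort of epileptogenic cortical malformations, the
per-hemisphere categorical detections at z > 4 for cortical thickness,
gray/white contrast and their union, together with the extra-lesional
cluster burden in mm². It serves as a worked example for the categorical
metrics: the union sensitivity and the fraction of patients with abnormal
clusters outside the traced lesion are recomputed from the raw yes/no
entries rather than hard-coded.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

from .evaluation import sensitivity

__all__ = [
    "load_reference_cohort",
    "union_sensitivity_pct",
    "extra_lesional_fraction_pct",
    "printed_percent",
]


def load_reference_cohort() -> pd.DataFrame:
    """Per-hemisphere detection table (one row per lesional hemisphere)."""
    ref = importlib.resources.files("surfmorph.data") / "reference_cohort.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def printed_percent(numerator: int, denominator: int) -> int:
    """Whole-percent convention of the reference report (truncation)."""
    return int(100 * numerator / denominator)


def union_sensitivity_pct(table: pd.DataFrame | None = None) -> int:
    """Categorical union sensitivity over lesional hemispheres (whole %)."""
    if table is None:
        table = load_reference_cohort()
    flags = [v == "yes" for v in table["union_detected"]]
    sensitivity(flags)  # validates the flag list is nonempty
    return printed_percent(sum(flags), len(flags))


def extra_lesional_fraction_pct(table: pd.DataFrame | None = None) -> int:
    """Percent of patients with nonzero extra-lesional cluster area (union)."""
    if table is None:
        table = load_reference_cohort()
    per_patient = table.groupby("patient")["union_extra_mm2"].sum()
    n_nonzero = int((per_patient > 0).sum())
    return printed_percent(n_nonzero, len(per_patient))
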