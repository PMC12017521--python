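"""Bundled reference data.

``reference_cohort()`` returns the per-subject summary table of a
ten-subject healthy-adult walking cohort (mass, truncated foot length,
static NNHt, maximum arch displacement, and the three per-phase arch
stiffnesses in kN/mm). It is the canonical input for cohort-statistics
examples and for checking ``cohort_summary`` against known Mean/STD rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def reference_cohort() -> pd.DataFrame:
    with resources.files("archstiff.data").joinpath(
            "reference_cohort.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def default_pa_curve_path() -> str:
    """Path of the bundled placeholder plantar-aponeurosis tension curve."""
    return str(resources.files("archstiff.data") / "pa_tension_default.csv")
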