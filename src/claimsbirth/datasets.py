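"""Bundled reference data.

``reference_validation_counts`` ships the published woman-level confusion
counts (TP/TN/FN/FP) and rounded metrics for the 18 primary childbirth
algorithms from a nationwide Japanese claims validation cohort of 854,626
husband-identified women, 37,934 of them with a linkage-confirmed birth.
The counts are inputs for metric replication; the underlying claims
extract is proprietary and not redistributable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_validation_counts",
    "REFERENCE_N_WOMEN",
    "REFERENCE_N_POSITIVE",
]

#: Eligible cohort size behind the reference counts.
REFERENCE_N_WOMEN = 854_626
#: Linkage-confirmed childbirth (gold-positive) women in that cohort.
REFERENCE_N_POSITIVE = 37_934


def reference_validation_counts() -> pd.DataFrame:
    """Published confusion counts and rounded metrics, one row per algorithm."""
    with resources.files("claimsbirth.data").joinpath(
        "reference_validation_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)
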