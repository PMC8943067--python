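"""Published cluster-composition tables bundled as worked-example inputs.

These are the printed contingency tables from a serial-immunostaining study
of alveolar macrophages from surfactant-protein-A knockout mice, in which
female mice received exogenous SP-A1 ("SP-A1 rescue") or vehicle, and the
resulting single-cell CMP profiles were hierarchically clustered; a second
analysis pooled the female cells with a matched male cohort on the 7 markers
the two studies shared.  They serve as ready-made inputs for the 2/3-1/3
cluster-scoring rule and Cramér's V, since the scoring and association
statistics are exactly recomputable from the tables alone.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "female_study_composition",
    "sex_comparison_composition",
    "treatment_comparison_composition",
]


def female_study_composition() -> pd.DataFrame:
    """7-cluster treatment composition of the 103 female cells (2 x 7)."""
    return pd.DataFrame(
        {
            1: [6, 5], 2: [1, 16], 3: [23, 0], 4: [5, 9],
            5: [14, 6], 6: [0, 10], 7: [6, 2],
        },
        index=pd.Index(["Vehicle", "SP-A1 rescue"], name="group"),
    )


def sex_comparison_composition() -> pd.DataFrame:
    """12-cluster sex composition of the pooled 217 cells (2 x 12)."""
    return pd.DataFrame(
        {
            1: [0, 26], 2: [21, 3], 3: [17, 4], 4: [17, 7], 5: [12, 3],
            6: [3, 20], 7: [1, 21], 8: [3, 9], 9: [16, 0], 10: [1, 13],
            11: [6, 8], 12: [6, 0],
        },
        index=pd.Index(["Female", "Male"], name="sex"),
    )


def treatment_comparison_composition() -> pd.DataFrame:
    """12-cluster treatment composition of the pooled 217 cells (2 x 12).

    The per-cluster cells are taken as authoritative; the study's printed
    row totals disagree with their own cell sums by a few cells, but the
    per-cluster values are internally consistent with the published scoring
    and association results.
    """
    return pd.DataFrame(
        {
            1: [5, 21], 2: [10, 14], 3: [12, 9], 4: [19, 5], 5: [11, 4],
            6: [12, 11], 7: [10, 12], 8: [7, 5], 9: [8, 8], 10: [10, 4],
            11: [2, 12], 12: [2, 4],
        },
        index=pd.Index(["Vehicle", "SP-A1 rescue"], name="group"),
    )
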