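"""Shared statistical helpers: unequal-variance group comparisons.

Cross-cycle comparisons of pulse features and FRAP recovery rates use a
Welch ANOVA (no equal-variance assumption) followed by pairwise Welch t-tests
with a Sidak-style multiplicity correction — a practical approximation to
the Dunnett T3 procedure commonly used for this design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["welch_anova_pairwise"]


def welch_anova_pairwise(groups: dict[str, np.ndarray]) -> dict:
    """Welch ANOVA across ``groups`` plus Sidak-corrected pairwise Welch tests.

    Parameters
    ----------
    groups : mapping of group label to 1-d array of observations.
        At least two groups with at least three observations each.

    Returns
    -------
    dict with ``summary`` (per-group n/mean/sd DataFrame), ``anova_p``,
    ``pairwise`` (DataFrame with raw and corrected p-values) and
    ``zero_variance`` (labels of degenerate groups, flagged not rejected).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, values in groups.items():
        if len(values) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 observations")
    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [float(np.mean(v)) for v in groups.values()],
            "sd": [float(np.std(v, ddof=1)) for v in groups.values()],
        }
    )
    zero_variance = [g for g, v in groups.items() if np.std(v, ddof=1) == 0]
    long = pd.DataFrame(
        {
            "value": np.concatenate([np.asarray(v, float) for v in groups.values()]),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    anova_p = float(pg.welch_anova(data=long, dv="value", between="group")["p_unc"].iloc[0])
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "t": float(t),
                    "p_raw": float(p),
                    "p_corrected": float(1.0 - (1.0 - p) ** n_pairs),
                }
            )
    return {
        "summary": summary,
        "anova_p": anova_p,
        "pairwise": pd.DataFrame(rows),
        "zero_variance": zero_variance,
    }
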