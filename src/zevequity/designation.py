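"""Disadvantaged-community (DAC) designation.

Implements a CalEnviroScreen-style scoring rule: the overall score of a
census tract is the product of its pollution-burden and population-
characteristics component scores, expressed as a percentile rank across all
scored tracts.  Tracts in the top quarter of percentiles are designated
disadvantaged; tracts lacking a population-characteristics score are
designated when their pollution burden alone falls in the top 5%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def compute_ces_scores(tracts: pd.DataFrame) -> pd.DataFrame:
    """Overall score = pollution burden × population characteristics.

    A missing (NaN) population-characteristics score yields a missing
    overall score; negative component scores are rejected.
    """
    out = tracts.copy()
    burden = out["pollution_burden"]
    pchar = out["pop_characteristics"]
    if (burden.dropna() < 0).any() or (pchar.dropna() < 0).any():
        raise ValueError("component scores must be nonnegative")
    out["ces_score"] = burden * pchar
    return out


def assign_percentiles(tracts: pd.DataFrame) -> pd.DataFrame:
    """Percentile rank of the overall score, 100 × rank / n.

    Ties receive the average rank, so n equal scores all land on the same
    percentile.  Tracts with a missing score are left unranked (NaN).
    """
    if len(tracts) == 0:
        raise ValueError("empty tract table")
    out = tracts.copy()
    scores = out["ces_score"].to_numpy(dtype=float)
    valid = np.isfinite(scores)
    if valid.sum() == 0:
        raise ValueError("no tract has a computable overall score")
    pct = np.full(len(out), np.nan)
    pct[valid] = 100.0 * rankdata(scores[valid], method="average") / valid.sum()
    out["ces_percentile"] = pct
    return out


def designate_dac(tracts: pd.DataFrame, top_fraction: float = 0.25,
                  burden_top_fraction: float = 0.05) -> pd.DataFrame:
    """Flag DAC tracts by the two-rule designation.

    Rule 1: percentile strictly above 100 × (1 − top_fraction) — the "top
    25%" of overall scores (strict so that with n distinct scores exactly
    round(top_fraction × n) tracts qualify).  Rule 2: a tract with no
    overall score whose pollution burden ranks in the top
    ``burden_top_fraction`` of all tracts.
    """
    for name, frac in (("top_fraction", top_fraction),
                       ("burden_top_fraction", burden_top_fraction)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {frac}")
    if "ces_percentile" not in tracts:
        raise ValueError("assign_percentiles must run before designation")
    out = tracts.copy()
    pct = out["ces_percentile"].to_numpy(dtype=float)
    rule1 = pct > 100.0 * (1.0 - top_fraction)

    burden = out["pollution_burden"].to_numpy(dtype=float)
    burden_pct = 100.0 * rankdata(burden, method="average") / len(out)
    missing = ~np.isfinite(pct)
    rule2 = missing & (burden_pct > 100.0 * (1.0 - burden_top_fraction))

    out["dac"] = np.where(missing, rule2, rule1)
    return out


def designate(tracts: pd.DataFrame, top_fraction: float = 0.25,
              burden_top_fraction: float = 0.05) -> pd.DataFrame:
    """Score, rank and flag in one pass."""
    return designate_dac(
        assign_percentiles(compute_ces_scores(tracts)),
        top_fraction=top_fraction, burden_top_fraction=burden_top_fraction)
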