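"""Phenotype statistics: insect survival, trial QC and trait correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import PhenoMixedModel, SingularDesignError

__all__ = [
    "InsectRecord",
    "nts",
    "nts_table",
    "trial_qc",
    "trait_correlations",
]


@dataclass
class InsectRecord:
    """Living and total infested insect counts for one plant."""

    living: int
    total_infested: int = 6

    def __post_init__(self) -> None:
        if self.total_infested <= 0:
            raise ValueError("total_infested must be > 0")
        if not 0 <= self.living <= self.total_infested:
            raise ValueError("living must lie in [0, total_infested]")


def nts(record: InsectRecord | int, total_infested: int = 6) -> float:
    """Insect survival percentage: 100 * living / total infested.

    Reported to one decimal place; with the standard infestation of 6
    insects per plant the statistic takes discrete values 0.0, 16.7, 33.3,
    50.0, 66.7, 83.3, 100.0.
    """
    if not isinstance(record, InsectRecord):
        record = InsectRecord(living=int(record), total_infested=total_infested)
    return round(100.0 * record.living / record.total_infested, 1)


def nts_table(counts: pd.DataFrame) -> pd.Series:
    """Vectorised survival percentage from a living/total_infested table."""
    if (counts["total_infested"] <= 0).any():
        raise ValueError("total_infested must be > 0")
    pct = 100.0 * counts["living"] / counts["total_infested"]
    return pct.round(1).rename("nts")


def trial_qc(
    data: pd.DataFrame,
    threshold: float = 0.2,
    trait_col: str = "value",
    **model_kwargs,
) -> dict:
    """Per-trial quality control by Cullis heritability.

    Each trial is fitted on its own with genotype random; trials whose fit
    fails to converge or whose H2 falls below ``threshold`` are excluded.
    Returns retained/excluded trial lists with per-trial H2 and reasons.
    """
    trials = sorted(data["trial"].astype(str).unique())
    if not trials:
        raise ValueError("no trials in the data")
    retained, excluded = [], []
    h2s: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for t in trials:
        sub = data[data["trial"].astype(str) == t]
        try:
            fit = PhenoMixedModel(
                sub, trait_col=trait_col, genotype_effect="random", **model_kwargs
            ).fit()
        except (SingularDesignError, np.linalg.LinAlgError) as exc:
            excluded.append(t)
            reasons[t] = f"fit failed: {exc}"
            continue
        if not fit.converged:
            excluded.append(t)
            reasons[t] = "non-convergence"
            continue
        h2 = fit.cullis_h2()
        h2s[t] = h2
        if h2 < threshold:
            excluded.append(t)
            reasons[t] = f"H2 = {h2:.3f} < {threshold}"
        else:
            retained.append(t)
    if not retained:
        raise ValueError(f"all trials excluded by QC: {reasons}")
    return {"retained": retained, "excluded": excluded, "h2": h2s,
            "reasons": reasons}


def trait_correlations(
    blues: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between per-genotype trait values.

    ``blues`` is wide format (rows = genotypes, columns = traits), typically
    BLUEs since they carry no shrinkage. Missing values are handled
    pairwise-complete; a pair with fewer than ``min_pairs`` complete
    observations, or a constant trait, yields NaN (never a silent 0).
    Returns (correlations, two-sided p-values).
    """
    traits = list(blues.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x = blues[traits[i]].to_numpy(dtype=float)
            y = blues[traits[j]].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            rr, pp = stats.pearsonr(xs, ys)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )
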