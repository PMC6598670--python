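"""Group-comparison statistics for HK-vs-TS feature tables.

Features (element densities, GC content, substitution rates, ...) are
compared between gene classes with a two-sided Mann-Whitney U test and
summarized as mean +/- SEM rows, mirroring the usual promoter-survey
table layout.  Raw p-values are reported; no multiple-testing
correction is applied across feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: exact enumeration is used up to this combined sample size (no ties)
EXACT_LIMIT = 12


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    u_statistic: float
    pvalue: float
    error: str | None = None


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when the combined sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with midrank tie correction and continuity correction.  Returns the
    U statistic of the first sample and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def _sem(v: np.ndarray) -> float:
    return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def summarize_groups(
    features: dict[str, tuple[np.ndarray, np.ndarray]]
) -> list[GroupComparison]:
    """One mean +/- SEM + Mann-Whitney row per feature, in input order.

    A feature whose test fails (e.g. an empty group) yields a row with
    nan statistics and the error message; remaining features still run.
    """
    rows: list[GroupComparison] = []
    for name, (va, vb) in features.items():
        va = np.asarray(va, dtype=float)
        vb = np.asarray(vb, dtype=float)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        try:
            u, p = mann_whitney(va, vb)
            err = None
        except ValueError as exc:
            u, p, err = float("nan"), float("nan"), str(exc)
        rows.append(
            GroupComparison(
                feature=name,
                mean_a=float(va.mean()) if va.size else float("nan"),
                sem_a=_sem(va),
                n_a=int(va.size),
                mean_b=float(vb.mean()) if vb.size else float("nan"),
                sem_b=_sem(vb),
                n_b=int(vb.size),
                u_statistic=u,
                pvalue=p,
                error=err,
            )
        )
    return rows


def comparison_table(rows: list[GroupComparison], label_a="HK", label_b="TS") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            f"mean_{label_a}": [r.mean_a for r in rows],
            f"sem_{label_a}": [r.sem_a for r in rows],
            f"n_{label_a}": [r.n_a for r in rows],
            f"mean_{label_b}": [r.mean_b for r in rows],
            f"sem_{label_b}": [r.sem_b for r in rows],
            f"n_{label_b}": [r.n_b for r in rows],
            "U": [r.u_statistic for r in rows],
            "pvalue": [r.pvalue for r in rows],
        }
    )
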