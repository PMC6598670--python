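"""Expression-based housekeeping (HK) / tissue-specific (TS) classification.

A transcript is housekeeping-like when it is (i) detected in every tissue
of the panel, (ii) uniform across tissues by a Kolmogorov-Smirnov test on
the min-max-normalized profile (p > 0.1), and (iii) never abnormally
expressed in a single tissue, i.e. every value lies within the fourfold
range of the across-tissue mean.  A gene is HK only when all of its
transcripts pass (criterion iv).  A gene is TS when at least one
transcript is expressed and every expressed transcript is restricted to
1-3 tissues (and the gene is not HK); everything else is "other".

The detection threshold (default 1.0 FPKM) is a convention, not a value
fixed by the definition, and is exposed everywhere results depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqio import ExpressionMatrix

DEFAULT_FPKM_THRESHOLD = 1.0
DEFAULT_KS_CUTOFF = 0.1
DEFAULT_FOLD = 4.0
DEFAULT_TS_MAX_TISSUES = 3


@dataclass(frozen=True)
class TranscriptEvidence:
    transcript_id: str
    expressed_tissue_count: int
    ks_pvalue: float
    fold_range_ok: bool
    hk_pass: bool
    ts_like: bool


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    label: str  # HK | TS | other
    evidence: tuple[TranscriptEvidence, ...] = field(default_factory=tuple)


def expressed_tissue_count(values: np.ndarray, threshold: float) -> int:
    """Number of tissues in which the transcript reaches the threshold."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty expression vector")
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")
    return int((values >= threshold).sum())


def ks_uniformity_pvalue(values: np.ndarray) -> float:
    """Two-sided KS p-value of the min-max-normalized profile vs U(0,1).

    Scale-free by construction: rescaling all FPKM values by a positive
    constant leaves the normalized profile unchanged.  A constant vector
    has zero variance and is perfectly uniform by convention (p = 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 tissues for the uniformity test")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 1.0
    normalized = (values - lo) / (hi - lo)
    return float(stats.kstest(normalized, "uniform").pvalue)


def fold_range_check(values: np.ndarray, fold: float = DEFAULT_FOLD) -> bool:
    """True when every value lies in [mean/fold, fold*mean].

    The two-sided reading: a tissue with abnormally low expression
    violates uniform housekeeping expression just as a spike does.
    An all-zero vector fails (mean 0, nothing expressed).
    """
    values = np.asarray(values, dtype=float)
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if (values < 0).any():
        raise ValueError("negative expression values")
    mean = values.mean()
    if mean == 0:
        return False
    return bool(((values >= mean / fold) & (values <= fold * mean)).all())


def evaluate_transcript(
    values: np.ndarray,
    transcript_id: str,
    n_tissues: int,
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    ks_cutoff: float = DEFAULT_KS_CUTOFF,
    fold: float = DEFAULT_FOLD,
    ts_max_tissues: int = DEFAULT_TS_MAX_TISSUES,
) -> TranscriptEvidence:
    count = expressed_tissue_count(values, threshold)
    ks_p = ks_uniformity_pvalue(values)
    fold_ok = fold_range_check(values, fold)
    hk_pass = (count == n_tissues) and (ks_p > ks_cutoff) and fold_ok
    ts_like = 1 <= count <= ts_max_tissues
    return TranscriptEvidence(
        transcript_id=transcript_id,
        expressed_tissue_count=count,
        ks_pvalue=ks_p,
        fold_range_ok=fold_ok,
        hk_pass=hk_pass,
        ts_like=ts_like,
    )


def classify_genes(
    m: ExpressionMatrix,
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    ks_cutoff: float = DEFAULT_KS_CUTOFF,
    fold: float = DEFAULT_FOLD,
    ts_max_tissues: int = DEFAULT_TS_MAX_TISSUES,
) -> list[GeneClassification]:
    """Apply the four HK criteria and the 1-3-tissue TS rule per gene.

    Labels are mutually exclusive and exhaustive: HK when every
    transcript passes all HK criteria; TS when the gene is not HK, has at
    least one expressed transcript, and every expressed transcript is
    restricted to at most ``ts_max_tissues`` tissues; other otherwise.
    Output is sorted by gene id.
    """
    n_tissues = m.n_tissues
    results: list[GeneClassification] = []
    for gene_id, transcripts in sorted(m.transcripts_of_gene().items()):
        evidence = tuple(
            evaluate_transcript(
                m.values.loc[t].to_numpy(),
                t,
                n_tissues,
                threshold,
                ks_cutoff,
                fold,
                ts_max_tissues,
            )
            for t in sorted(transcripts)
        )
        expressed = [e for e in evidence if e.expressed_tissue_count >= 1]
        if evidence and all(e.hk_pass for e in evidence):
            label = "HK"
        elif expressed and all(e.ts_like for e in expressed):
            label = "TS"
        else:
            label = "other"
        results.append(GeneClassification(gene_id=gene_id, label=label, evidence=evidence))
    return results


def classification_table(results: list[GeneClassification]):
    """Per-gene summary rows (gene, label, n_transcripts, min KS p, flags)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "label": r.label,
                "n_transcripts": len(r.evidence),
                "min_ks_pvalue": min((e.ks_pvalue for e in r.evidence), default=np.nan),
                "all_detected": all(e.expressed_tissue_count > 0 for e in r.evidence),
                "all_fold_ok": all(e.fold_range_ok for e in r.evidence),
            }
        )
    return pd.DataFrame(rows)


def transcript_table(results: list[GeneClassification]):
    """Per-transcript evidence rows, including the transcript-level TS flag."""
    import pandas as pd

    rows = []
    for r in results:
        for e in r.evidence:
            rows.append(
                {
                    "transcript_id": e.transcript_id,
                    "gene_id": r.gene_id,
                    "gene_label": r.label,
                    "expressed_tissue_count": e.expressed_tissue_count,
                    "ks_pvalue": e.ks_pvalue,
                    "fold_range_ok": e.fold_range_ok,
                    "hk_pass": e.hk_pass,
                    "ts_like": e.ts_like,
                }
            )
    return pd.DataFrame(rows)
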