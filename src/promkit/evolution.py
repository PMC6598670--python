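"""Substitution-rate estimation for coding and promoter sequences.

Coding divergence follows the Nei-Gojobori (1986) unweighted-pathway
method: synonymous and nonsynonymous sites are counted per codon against
the standard genetic code, observed differences are partitioned over all
mutational pathways (excluding pathways through stop codons), and the
resulting proportions are Jukes-Cantor corrected into dS and dN.
Selection is tested with a Z-test on dN - dS whose variances come from a
codon-column bootstrap.  Promoter divergence (dP) is the per-site
p-distance with pairwise deletion of gap/N columns, optionally
Jukes-Cantor corrected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

from .seqio import Sequence

GAP = "-"
BASES = "ACGT"

_CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TO_AA))


class SaturationError(ValueError):
    """p-distance >= 3/4: the Jukes-Cantor distance is undefined."""


@dataclass(frozen=True)
class CodonPair:
    """An aligned pair of coding sequences (equal length, multiple of 3).

    Codons containing a gap or N in either sequence are skipped by every
    downstream count (pairwise deletion).  In-frame stop codons in either
    sequence are rejected.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) == 0 or len(a) % 3:
            raise ValueError("aligned length must be a positive multiple of 3")
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if GAP in codon or "N" in codon:
                    continue
                if codon in STOP_CODONS:
                    raise ValueError(f"in-frame stop codon {codon} at {i}")

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]

    def comparable_codons(self) -> list[tuple[str, str]]:
        """Codon pairs with no gap or ambiguity in either sequence."""
        ok = set("ACGT")
        return [
            (ca, cb)
            for ca, cb in self.codons()
            if set(ca) <= ok and set(cb) <= ok
        ]


@dataclass
class SubstitutionRates:
    dN: float
    dS: float
    omega: float  # nan when dS == 0 (undefined)
    z_pvalue: float | None = None
    dP: float | None = None
    dn_saturated: bool = False
    ds_saturated: bool = False


def _is_synonymous(c1: str, c2: str) -> bool:
    return _CODON_TO_AA[c1] == _CODON_TO_AA[c2]


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, stop_policy: str = "nonsynonymous") -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of a sense codon.

    Each position contributes one site split by the fraction of the three
    single-nucleotide changes at that position that are synonymous.
    ``stop_policy`` controls changes that create a stop codon:
    "nonsynonymous" counts them as nonsynonymous; "excluded" removes them
    from the per-position denominator.  Either way the counts sum to 3.
    """
    codon = codon.upper()
    if codon not in _CODON_TO_AA:
        raise ValueError(f"not a sense ACGT codon: {codon!r}")
    if stop_policy not in {"nonsynonymous", "excluded"}:
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    syn_sites = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                if stop_policy == "excluded":
                    continue
                considered += 1  # counted, as nonsynonymous
                continue
            considered += 1
            if _is_synonymous(codon, mutant):
                syn += 1
        syn_sites += syn / considered if considered else 0.0
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by unweighted pathway averaging.

    With d differing positions, the d! orderings of the single changes
    are enumerated; each step is synonymous or not by the code, pathways
    passing through a stop codon are excluded, and fractions are averaged
    over the remaining pathways.  If every pathway hits a stop, all
    pathways are used with stop-creating steps counted nonsynonymous.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0  # stop-creating step counted nonsynonymous
            elif _is_synonymous(cur, nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    results = [r for r in (walk(o, allow_stops=False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]  # type: ignore[misc]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def codon_contributions(
    pair: CodonPair, stop_policy: str = "nonsynonymous"
) -> np.ndarray:
    """Per-comparable-codon array of (Sd, Nd, S, N) contributions.

    S and N per codon are the means of the two sequences' site counts;
    summing rows reproduces :func:`pairwise_codon_differences`.
    """
    rows = []
    for ca, cb in pair.comparable_codons():
        sd, nd = _codon_pair_differences(ca, cb)
        sa = codon_site_counts(ca, stop_policy)
        sb = codon_site_counts(cb, stop_policy)
        rows.append((sd, nd, (sa[0] + sb[0]) / 2, (sa[1] + sb[1]) / 2))
    return np.asarray(rows, dtype=float)


def pairwise_codon_differences(
    pair: CodonPair, stop_policy: str = "nonsynonymous"
) -> tuple[float, float, float, float]:
    """Total (Sd, Nd, S, N) over comparable codons (pairwise deletion)."""
    contrib = codon_contributions(pair, stop_policy)
    if contrib.size == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    sd, nd, s, n = contrib.sum(axis=0)
    return float(sd), float(nd), float(s), float(n)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3), defined for p < 3/4."""
    if p < 0:
        raise ValueError("proportion of differences must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} >= 3/4: distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def nei_gojobori(
    pair: CodonPair, stop_policy: str = "nonsynonymous"
) -> SubstitutionRates:
    """dN, dS and omega = dN/dS by Nei-Gojobori counting with JC correction.

    A saturated rate (p >= 3/4) is reported as nan with its flag set;
    omega is nan when dS is 0 or either rate is saturated.
    """
    sd, nd, s, n = pairwise_codon_differences(pair, stop_policy)
    ps, pn = sd / s, nd / n
    dn_sat = ds_sat = False
    try:
        ds = jukes_cantor(ps)
    except SaturationError:
        ds, ds_sat = float("nan"), True
    try:
        dn = jukes_cantor(pn)
    except SaturationError:
        dn, dn_sat = float("nan"), True
    if ds_sat or dn_sat or ds == 0.0:
        omega = float("nan")
    else:
        omega = dn / ds
    return SubstitutionRates(
        dN=dn, dS=ds, omega=omega, dn_saturated=dn_sat, ds_saturated=ds_sat
    )


def selection_z_test(
    pair: CodonPair,
    reps: int = 500,
    seed: int | None = None,
    stop_policy: str = "nonsynonymous",
) -> tuple[float, float]:
    """Z-test of dN = dS with codon-column bootstrap variances.

    Codon columns are resampled with replacement ``reps`` times; the
    variance of dN and dS over replicates enters
    Z = (dN - dS) / sqrt(Var(dN) + Var(dS)), compared against the
    standard normal (two-sided).  Degenerate variance (e.g. identical
    sequences) returns p = 1.
    """
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    contrib = codon_contributions(pair, stop_policy)
    n_codons = contrib.shape[0]
    if n_codons < 10:
        raise ValueError("need at least 10 comparable codons")
    sd, nd, s, n = contrib.sum(axis=0)
    try:
        ds_hat = jukes_cantor(sd / s)
        dn_hat = jukes_cantor(nd / n)
    except SaturationError as exc:
        raise SaturationError(f"point estimate saturated: {exc}") from exc

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_codons, np.full(n_codons, 1.0 / n_codons), size=reps)
    sums = counts @ contrib  # (reps, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = sums[:, 0] / sums[:, 2]
        pn = sums[:, 1] / sums[:, 3]
    ds_reps = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(ps, 0.749999) / 3.0), np.nan)
    dn_reps = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(pn, 0.749999) / 3.0), np.nan)
    var = np.nanvar(ds_reps, ddof=1) + np.nanvar(dn_reps, ddof=1)
    if not np.isfinite(var) or var == 0.0:
        return 0.0, 1.0
    z = (dn_hat - ds_hat) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def promoter_distance(
    a: str, b: str, correction: str = "raw"
) -> float:
    """Promoter substitution rate dP: mismatches per comparable column.

    Columns with a gap or N in either sequence are excluded (pairwise
    deletion).  ``correction="jukes_cantor"`` applies the JC transform.
    """
    if len(a) != len(b):
        raise ValueError("aligned promoter pair must have equal length")
    a, b = a.upper(), b.upper()
    skip = set("N" + GAP)
    comparable = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    p = mismatches / comparable
    if correction == "raw":
        return p
    if correction == "jukes_cantor":
        return jukes_cantor(p)
    raise ValueError(f"unknown correction {correction!r}")


def align_global(
    a: Sequence | str,
    b: Sequence | str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[str, str, int]:
    """Needleman-Wunsch global alignment with linear gap scoring.

    Ties are broken deterministically: diagonal (substitution) preferred
    over up (gap in the second sequence) over left (gap in the first).
    Returns the two padded strings and the optimal score.  Quadratic in
    time and memory; intended for promoter/CDS-scale inputs.
    """
    sa = a.residues if isinstance(a, Sequence) else a
    sb = b.residues if isinstance(b, Sequence) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    n, m = len(sa), len(sb)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match if ai == sb[j - 1] else mismatch)
            up = row_prev[j] + gap
            left = row[j - 1] + gap
            best = diag
            move = 0
            if up > best:
                best, move = up, 1
            if left > best:
                best, move = left, 2
            row[j] = best
            ptr[i, j] = move
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


def rate_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation between two rate vectors, dropping non-finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rate vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a rate vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
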