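"""Rule-based promoter element detection.

Four element families are scanned with the thresholds conventional for
promoter surveys:

* CpG islands — sliding 100-bp windows with GC > 0.5 and observed/expected
  CpG ratio > 0.6, merged, trimmed to the outermost CpG, and re-validated
  at length >= 200 bp (the Gardiner-Garden & Frommer rule set).
* Perfect short tandem repeats (STRs) — maximal arrays of a primitive
  2-6 bp unit with at least ``min_copies`` head-to-tail copies;
  mononucleotide runs are never reported.
* Potential quadruplex-forming sequences (PQS) — four equal-length G-runs
  (>= 2 G each) separated by loops of >= 0 bases within a 30-bp span, on
  both strands, scored QGRS-style and resolved greedily to a
  non-overlapping set.
* IUPAC consensus motifs — exact degenerate-pattern matches on both
  strands, overlaps all reported.

Coordinates are 0-based half-open in promoter space; distance to the TSS
is ``len(promoter) - position`` (the TSS sits just 3' of the last base).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .seqio import (
    IUPAC_CODES,
    GenomicInterval,
    Sequence,
    reverse_complement,
)

#: loop-evenness reward ceiling in the QGRS-style score
MAX_LOOP_PENALTY = 10


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp: float


@dataclass(frozen=True)
class STRLocus:
    interval: GenomicInterval
    unit: str
    canonical_unit: str
    copies: int


@dataclass(frozen=True)
class PQSHit:
    interval: GenomicInterval
    g_run_starts: tuple[int, int, int, int]
    g_run_length: int
    loop_lengths: tuple[int, int, int]
    g_score: int


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    motif: str
    strand: str


# ---------------------------------------------------------------------------
# GC profile
# ---------------------------------------------------------------------------

def gc_profile(
    promoters: TypingSequence[Sequence], window: int = 100, step: int = 50
) -> pd.DataFrame:
    """Mean GC fraction in sliding windows, indexed by distance to the TSS.

    Windows start at offset 0 and advance by ``step``; each window's GC
    fraction excludes N bases from both numerator and denominator.  The
    returned frame has columns ``distance_to_tss`` (window center to TSS,
    in bp), ``mean_gc`` and ``sem``, averaged over promoters.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    per_distance: dict[float, list[float]] = {}
    for p in promoters:
        n = len(p)
        if window > n:
            raise ValueError(f"window {window} exceeds promoter length {n}")
        arr = np.frombuffer(p.residues.encode(), dtype=np.uint8)
        is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
        is_n = arr == ord("N")
        for start in range(0, n - window + 1, step):
            sl = slice(start, start + window)
            denom = window - int(is_n[sl].sum())
            if denom == 0:
                continue
            gc = float(is_gc[sl].sum()) / denom
            dist = n - (start + window / 2)
            per_distance.setdefault(dist, []).append(gc)
    rows = []
    for dist in sorted(per_distance, reverse=True):
        vals = np.asarray(per_distance[dist])
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append((dist, float(vals.mean()), sem))
    return pd.DataFrame(rows, columns=["distance_to_tss", "mean_gc", "sem"])


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

def _region_stats(s: str, start: int, end: int) -> tuple[float, float]:
    """(GC fraction, CpG observed/expected) of s[start:end]."""
    region = s[start:end]
    L = end - start
    c = region.count("C")
    g = region.count("G")
    n_cpg = region.count("CG")
    gc = (c + g) / L
    oe = (n_cpg * L / (c * g)) if c * g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    s: Sequence,
    window: int = 100,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Detect CpG islands by the windowed merge-trim-revalidate procedure.

    A 100-bp window sliding by 1 bp is island-like when its GC fraction
    exceeds ``min_gc`` and its CpG observed/expected ratio exceeds
    ``min_oe``; overlapping island-like windows are merged, each merged
    region is trimmed to its outermost CpG dinucleotides, and regions are
    reported when the trimmed length reaches ``min_len`` and the
    whole-region GC and O/E still exceed the thresholds.
    """
    seq = s.residues
    n = len(seq)
    if n < window:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    # CpG dinucleotide start positions
    is_cpg = np.zeros(n, dtype=np.int64)
    if n >= 2:
        is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    starts = np.arange(0, n - window + 1)
    c_w = cum_c[starts + window] - cum_c[starts]
    g_w = cum_g[starts + window] - cum_g[starts]
    # CpG pairs fully inside the window: starts in [i, i + window - 2]
    cpg_w = cum_cpg[starts + window - 1] - cum_cpg[starts]
    gc_ok = (c_w + g_w) / window > min_gc
    denom = c_w * g_w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_w = np.where(denom > 0, cpg_w * window / np.maximum(denom, 1), 0.0)
    island_like = gc_ok & (oe_w > min_oe)

    islands: list[CpGIsland] = []
    idx = np.flatnonzero(island_like)
    if idx.size == 0:
        return islands
    # merge overlapping island-like windows (step 1 => consecutive starts
    # always overlap; a gap > window-1 in starts breaks the region)
    breaks = np.flatnonzero(np.diff(idx) > window - 1)
    region_bounds = zip(
        np.concatenate([[0], breaks + 1]), np.concatenate([breaks, [idx.size - 1]])
    )
    for a, b in region_bounds:
        r_start, r_end = int(idx[a]), int(idx[b]) + window
        # trim to outermost CpG dinucleotide
        inside = np.flatnonzero(is_cpg[r_start : max(r_end - 1, r_start)])
        if inside.size == 0:
            continue
        t_start = r_start + int(inside[0])
        t_end = r_start + int(inside[-1]) + 2
        if t_end - t_start < min_len:
            continue
        gc, oe = _region_stats(seq, t_start, t_end)
        if gc > min_gc and oe > min_oe:
            islands.append(
                CpGIsland(
                    interval=GenomicInterval(s.id, t_start, t_end),
                    gc_fraction=gc,
                    obs_exp=oe,
                )
            )
    return islands


# ---------------------------------------------------------------------------
# Short tandem repeats
# ---------------------------------------------------------------------------

def is_primitive_unit(u: str) -> bool:
    """True when ``u`` is not a whole-number repetition of a shorter string."""
    k = len(u)
    for d in range(1, k):
        if k % d == 0 and u == u[:d] * (k // d):
            return False
    return True


def canonical_unit(u: str) -> str:
    """Lexicographic minimum over rotations of ``u`` and of its reverse
    complement; collapses the strand/phase ambiguity of a repeat unit."""
    rc = reverse_complement(u)
    candidates = [u[i:] + u[:i] for i in range(len(u))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_strs(
    s: Sequence,
    unit_sizes: Iterable[int] = range(2, 7),
    min_copies: int = 7,
) -> list[STRLocus]:
    """Find maximal perfect tandem arrays of primitive 2-6 bp units.

    For each unit size k, a maximal period-k run is a stretch where every
    base equals the base k positions earlier; a run of total length L
    yields ``L // k`` copies of the unit starting at the run's first base.
    Runs whose unit is itself periodic (including mononucleotide units)
    are skipped — they are reported at their primitive unit size instead.
    Overlapping arrays of different primitive units are each reported.
    """
    seq = s.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    loci: list[STRLocus] = []
    for k in unit_sizes:
        if n < 2 * k:
            continue
        match = arr[: n - k] == arr[k:]
        # maximal runs of True in `match`
        padded = np.concatenate([[False], match, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)  # exclusive in match space
        for a, b in zip(run_starts, run_ends):
            total = int(b - a) + k  # bases spanned by the period-k run
            copies = total // k
            if copies < min_copies:
                continue
            unit = seq[a : a + k]
            if "N" in unit or not is_primitive_unit(unit):
                continue
            loci.append(
                STRLocus(
                    interval=GenomicInterval(s.id, int(a), int(a) + copies * k),
                    unit=unit,
                    canonical_unit=canonical_unit(unit),
                    copies=int(copies),
                )
            )
    loci.sort(key=lambda x: (x.interval.start, x.interval.end, x.unit))
    return loci


# ---------------------------------------------------------------------------
# PQS / G-quadruplex
# ---------------------------------------------------------------------------

def _tract_starts(seq: str, g: int) -> list[int]:
    """Positions where a run of at least g consecutive G begins."""
    out = []
    run = 0
    for i, ch in enumerate(seq):
        run = run + 1 if ch == "G" else 0
        if run >= g:
            out.append(i - g + 1)
    return out


def _score(g: int, loops: tuple[int, int, int]) -> int:
    med = sorted(loops)[1]
    return sum(MAX_LOOP_PENALTY - abs(l - med) for l in loops) + 10 * (g - 2)


def pqs_candidates(
    seq: str,
    max_len: int = 30,
    n_runs: int = 4,
    min_run: int = 2,
    min_loop: int = 0,
) -> list[tuple[int, int, int, tuple[int, ...]]]:
    """Enumerate every PQS candidate on the given strand of ``seq``.

    A candidate is four G-tracts of a common length ``g`` (>= ``min_run``)
    separated by loops of >= ``min_loop`` bases, with total span <=
    ``max_len``.  Returns tuples ``(start, end, g, tract_starts)``.
    """
    n = len(seq)
    out: list[tuple[int, int, int, tuple[int, ...]]] = []
    max_g = (max_len - (n_runs - 1) * min_loop) // n_runs
    for g in range(min_run, max_g + 1):
        starts = _tract_starts(seq, g)
        starts_arr = starts
        for i1, t1 in enumerate(starts_arr):
            limit = t1 + max_len  # exclusive end bound
            for i2 in range(bisect.bisect_left(starts_arr, t1 + g + min_loop, i1), len(starts_arr)):
                t2 = starts_arr[i2]
                if t2 + 3 * g + 2 * min_loop > limit:
                    break
                for i3 in range(bisect.bisect_left(starts_arr, t2 + g + min_loop, i2), len(starts_arr)):
                    t3 = starts_arr[i3]
                    if t3 + 2 * g + min_loop > limit:
                        break
                    for i4 in range(bisect.bisect_left(starts_arr, t3 + g + min_loop, i3), len(starts_arr)):
                        t4 = starts_arr[i4]
                        if t4 + g > limit:
                            break
                        out.append((t1, t4 + g, g, (t1, t2, t3, t4)))
    return out


def find_pqs(
    s: Sequence,
    max_len: int = 30,
    n_runs: int = 4,
    min_run: int = 2,
    min_loop: int = 0,
    both_strands: bool = True,
) -> list[PQSHit]:
    """Detect PQS on both strands and resolve overlaps greedily by score.

    Candidates from :func:`pqs_candidates` (forward, and reverse
    complement mapped back to promoter coordinates with strand ``-``)
    compete; hits are kept in order of descending G-score, then ascending
    start, such that the reported set is mutually non-overlapping.
    """
    n = len(s.residues)
    raw: list[PQSHit] = []

    def add(cands, strand: str):
        for start, end, g, tracts in cands:
            if strand == "-":
                start, end = n - end, n - start
                tracts = tuple(sorted(n - t - g for t in tracts))
            loops = tuple(
                tracts[i + 1] - (tracts[i] + g) for i in range(3)
            )
            raw.append(
                PQSHit(
                    interval=GenomicInterval(s.id, start, end, strand),
                    g_run_starts=tuple(tracts),
                    g_run_length=g,
                    loop_lengths=loops,  # type: ignore[arg-type]
                    g_score=_score(g, loops),  # type: ignore[arg-type]
                )
            )

    add(pqs_candidates(s.residues, max_len, n_runs, min_run, min_loop), "+")
    if both_strands:
        add(
            pqs_candidates(
                reverse_complement(s.residues), max_len, n_runs, min_run, min_loop
            ),
            "-",
        )

    raw.sort(
        key=lambda h: (
            -h.g_score,
            h.interval.start,
            h.interval.end,
            h.interval.strand,
            h.g_run_length,
        )
    )
    kept: list[PQSHit] = []
    occupied: list[tuple[int, int]] = []
    for h in raw:
        if all(h.interval.end <= a or h.interval.start >= b for a, b in occupied):
            kept.append(h)
            occupied.append((h.interval.start, h.interval.end))
    kept.sort(key=lambda h: (h.interval.start, h.interval.end))
    return kept


# ---------------------------------------------------------------------------
# IUPAC motif scan
# ---------------------------------------------------------------------------

def _compile_iupac(motif: str) -> list[frozenset[str]]:
    classes = []
    for ch in motif.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
        classes.append(frozenset(IUPAC_CODES[ch]))
    return classes


def scan_motif(
    s: Sequence, motif: str, both_strands: bool = True
) -> list[MotifHit]:
    """Report every occurrence of an IUPAC consensus motif.

    Overlapping hits are all reported.  Reverse-strand hits are found by
    matching the reverse complement of the motif on the forward sequence
    and reported with strand ``-`` in forward coordinates.  An N in the
    sequence only matches motif positions that allow all four bases.
    """
    patterns = [(motif.upper(), "+", _compile_iupac(motif))]
    if both_strands:
        rc = reverse_complement(motif)
        patterns.append((motif.upper(), "-", _compile_iupac(rc)))
    seq = s.residues
    m = len(motif)
    n = len(seq)
    hits: list[MotifHit] = []
    if n >= m > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for motif_str, strand, classes in patterns:
            ok = np.ones(n - m + 1, dtype=bool)
            for j, cls in enumerate(classes):
                col = arr[j : n - m + 1 + j]
                # an N in the sequence only matches a fully degenerate class
                allowed_codes = [ord(b) for b in cls]
                col_ok = np.isin(col, allowed_codes)
                if len(cls) == 4:
                    col_ok |= col == ord("N")
                ok &= col_ok
                if not ok.any():
                    break
            for i in np.flatnonzero(ok):
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(s.id, int(i), int(i) + m, strand),
                        motif=motif_str,
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def element_density(hits_per_promoter: Iterable[list], n_promoters: int) -> tuple[int, float]:
    """Total hit count and hits per promoter over a promoter set."""
    if n_promoters <= 0:
        raise ValueError("n_promoters must be positive")
    total = sum(len(h) for h in hits_per_promoter)
    return total, total / n_promoters
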