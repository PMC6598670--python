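"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* an expression matrix over a tissue panel (default 21 tissues) holding
  housekeeping-like transcripts (detected everywhere, uniform across
  tissues, within the fourfold band), tissue-specific-like transcripts
  (expressed in 1-3 tissues) and "other" transcripts that each violate
  exactly one housekeeping criterion;
* promoter sequences (default 2 kb) with an i.i.d. GC-controlled
  background and planted CpG-island / STR / PQS / motif instances at
  recorded intervals, flanked so the planted element is maximal;
* divergent sequence pairs with known per-site substitution probability
  (promoter mode) or known dN/dS acceptance ratio (codon mode).

Every generator is deterministic given its seed, and the returned
:class:`SimTruth` makes planted structure exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import ExpressionMatrix, GenomicInterval, Sequence, IUPAC_CODES
from .evolution import SENSE_CODONS, STOP_CODONS, _is_synonymous

DEFAULT_N_TISSUES = 21
#: average housekeeping expression level reported for the pig panel
DEFAULT_HK_FPKM = 17.1
#: average tissue-specific expression level reported for the pig panel
DEFAULT_TS_FPKM = 6.43
DEFAULT_THRESHOLD = 1.0


@dataclass
class PlantSpec:
    """One element to write verbatim into a simulated promoter."""

    promoter: int
    kind: str  # cpg | str | pqs | motif
    offset: int
    payload: str  # concrete sequence to plant
    label: str = ""  # unit / motif / free-text descriptor


@dataclass
class SimTruth:
    true_label_of_gene: dict[str, str] = field(default_factory=dict)
    #: targeted HK-criterion violation per "other" transcript
    violation_of: dict[str, str] = field(default_factory=dict)
    planted_elements: list[tuple[str, str, GenomicInterval, str]] = field(
        default_factory=list
    )
    true_rates: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def _hk_profile(rng: np.random.Generator, n: int, base: float, cv: float) -> np.ndarray:
    """Mean-preserving stratified-uniform tissue effects around ``base``.

    Each tissue draws from one stratum of a bounded band of half-width
    cv*sqrt(3) (so the coefficient of variation is ``cv``), in shuffled
    order.  The stratification makes the across-tissue profile evenly
    spread, which is exactly the property the KS uniformity criterion
    declares housekeeping-like; i.i.d. noise would concentrate values
    centrally and fail that test for a large minority of true HK genes.
    """
    if cv == 0:
        return np.full(n, base)
    a = cv * np.sqrt(3.0)
    u = (np.arange(n) + rng.random(n)) / n
    rng.shuffle(u)
    return base * (1.0 + a * (2.0 * u - 1.0))


def _lognormal_level(rng: np.random.Generator, base: float, cv: float, size=None):
    """Mean-preserving log-normal draw around ``base``."""
    if cv == 0:
        return np.full(size or 1, base) if size else base
    sigma = np.sqrt(np.log1p(cv**2))
    return base * np.exp(rng.normal(-sigma**2 / 2, sigma, size))


def simulate_expression_matrix(
    n_hk: int,
    n_ts: int,
    n_other: int,
    n_tissues: int = DEFAULT_N_TISSUES,
    base_level: float = DEFAULT_HK_FPKM,
    ts_level: float = DEFAULT_TS_FPKM,
    noise_cv: float = 0.1,
    ts_tissues: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a transcript-by-tissue FPKM matrix with known labels.

    HK transcripts are expressed near ``base_level`` in every tissue with
    stratified multiplicative noise of coefficient of variation
    ``noise_cv``.  TS transcripts are expressed (log-normally around
    ``ts_level``, floored above ``threshold``) in ``ts_tissues`` tissues
    (uniform in 1-3 when None) and near zero elsewhere.  "Other"
    transcripts each violate exactly one HK criterion, recorded in
    ``truth.violation_of``: an evenly spaced profile dipping below the
    detection threshold ("detection"), a two-cluster profile inside the
    fourfold band ("ks"), or an evenly spaced grid whose low end breaks
    the fourfold bound ("fold").  One transcript per gene.
    """
    if min(n_hk, n_ts, n_other) < 0:
        raise ValueError("counts must be nonnegative")
    if n_tissues < 4:
        raise ValueError("need at least 4 tissues (fold/uniformity rules degenerate)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if ts_tissues is not None and not (1 <= ts_tissues <= 3):
        raise ValueError("ts_tissues must be in 1..3")
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    rows = []
    ids = []
    genes = {}

    def jitter(v: np.ndarray, rel: float = 0.01) -> np.ndarray:
        """Tiny multiplicative jitter that never reorders well-separated values."""
        if noise_cv == 0:
            return v
        return v * (1.0 + rel * rng.uniform(-1, 1, v.shape))

    for i in range(n_hk):
        tid = f"hk_t{i:05d}"
        rows.append(_hk_profile(rng, n_tissues, base_level, noise_cv))
        ids.append(tid)
        genes[tid] = f"hk_g{i:05d}"
        truth.true_label_of_gene[genes[tid]] = "HK"

    for i in range(n_ts):
        tid = f"ts_t{i:05d}"
        k = int(ts_tissues) if ts_tissues is not None else int(rng.integers(1, 4))
        on = rng.choice(n_tissues, size=k, replace=False)
        v = rng.uniform(0.0, 0.1 * threshold, n_tissues)
        v[on] = np.maximum(
            _lognormal_level(rng, ts_level, noise_cv, k), 1.5 * threshold
        )
        rows.append(v)
        ids.append(tid)
        genes[tid] = f"ts_g{i:05d}"
        truth.true_label_of_gene[genes[tid]] = "TS"

    violations = ["detection", "ks", "fold"]
    for i in range(n_other):
        tid = f"ot_t{i:05d}"
        mode = violations[i % 3]
        if mode == "detection":
            # evenly spaced 0.5t..2t: ~1/3 of tissues below threshold, KS
            # passes (even grid), fold passes (min >= mean/4)
            v = jitter(np.linspace(0.5 * threshold, 2.0 * threshold, n_tissues))
            rng.shuffle(v)
        elif mode == "ks":
            # two clusters inside the fourfold band: normalized profile
            # piles near 0 => KS rejects; detection and fold pass
            n_hi = max(2, n_tissues // 7)
            v = np.concatenate(
                [
                    np.full(n_tissues - n_hi, base_level),
                    np.full(n_hi, 3.5 * base_level),
                ]
            )
            v = jitter(v, 0.02)
            rng.shuffle(v)
        else:
            # evenly spaced 1.2t..12t: KS passes, all detected (margin
            # above the threshold), but the low end sits below mean/4
            # (7 * 1.2 < 12) so only the fold criterion fails
            v = jitter(np.linspace(1.2 * threshold, 12.0 * threshold, n_tissues))
            rng.shuffle(v)
        rows.append(v)
        ids.append(tid)
        genes[tid] = f"ot_g{i:05d}"
        truth.true_label_of_gene[genes[tid]] = "other"
        truth.violation_of[tid] = mode

    values = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, n_tissues)),
        index=pd.Index(ids, name="transcript_id"),
        columns=[f"tissue_{j:02d}" for j in range(n_tissues)],
    )
    return ExpressionMatrix(values=values, gene_of=genes), truth


# ---------------------------------------------------------------------------
# Promoters with planted elements
# ---------------------------------------------------------------------------

def make_str_payload(unit: str, copies: int) -> str:
    return unit * copies

def make_pqs_payload(g_run: int = 3, loop: str = "TTA", n_runs: int = 4) -> str:
    return ("G" * g_run + loop) * (n_runs - 1) + "G" * g_run

def make_cpg_payload(length: int = 300) -> str:
    """A CG-dinucleotide block: GC fraction 1.0, observed/expected ratio 2."""
    return ("CG" * (length // 2 + 1))[:length]

def make_motif_payload(motif: str, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(list(IUPAC_CODES[ch]))) for ch in motif.upper())


def simulate_promoter_set(
    n: int,
    length: int = 2000,
    gc_background: float = 0.45,
    plant: list[PlantSpec] | None = None,
    seed: int | None = None,
) -> tuple[list[Sequence], SimTruth]:
    """Simulate promoters with an i.i.d. GC-controlled background.

    Planted payloads are written verbatim at their recorded offsets; one
    guard base on each flank is chosen so a planted repeat or G-run
    cannot extend into the background (for an STR of unit ``u`` the left
    guard differs from ``u[-1]`` and the right guard from ``u[0]``, which
    is exactly the period-breaking condition; for other elements the
    guards avoid the adjacent payload edge).  Around each planted PQS the
    background is additionally sanitized within the scanner's span limit:
    G-G and C-C adjacencies outside payloads are broken so no competing
    quadruplex candidate can overlap and outscore the planted one.
    Overlapping plants (including their guard flanks) raise an error.
    """
    if not (0 <= gc_background <= 1):
        raise ValueError("gc_background must be a fraction")
    plant = plant or []
    rng = np.random.default_rng(seed)
    p_each = np.array(
        [
            (1 - gc_background) / 2,
            gc_background / 2,
            gc_background / 2,
            (1 - gc_background) / 2,
        ]
    )
    bases = np.array(list("ACGT"))
    truth = SimTruth()
    by_promoter: dict[int, list[PlantSpec]] = {}
    for spec in plant:
        if not (0 <= spec.promoter < n):
            raise ValueError(f"plant references promoter {spec.promoter} of {n}")
        if not (0 <= spec.offset and spec.offset + len(spec.payload) <= length):
            raise ValueError(f"planted element does not fit: {spec}")
        by_promoter.setdefault(spec.promoter, []).append(spec)
    for specs in by_promoter.values():
        specs.sort(key=lambda sp: sp.offset)
        for s1, s2 in zip(specs, specs[1:]):
            # each payload carries a one-base guard flank on both sides
            if s2.offset < s1.offset + len(s1.payload) + 2:
                raise ValueError(
                    f"planted elements overlap (including guard flanks): {s1} / {s2}"
                )

    promoters: list[Sequence] = []
    for i in range(n):
        pid = f"prom_{i:04d}"
        arr = rng.choice(bases, size=length, p=p_each)
        specs = by_promoter.get(i, [])
        payload_spans = [(sp.offset, sp.offset + len(sp.payload)) for sp in specs]

        def in_payload(pos: int) -> bool:
            return any(lo <= pos < hi for lo, hi in payload_spans)

        for spec in specs:
            a, b = spec.offset, spec.offset + len(spec.payload)
            arr[a:b] = list(spec.payload)
            if spec.kind == "str" and spec.label:
                unit = spec.label
                left_avoid, right_avoid = unit[-1], unit[0]
            else:
                left_avoid, right_avoid = spec.payload[0], spec.payload[-1]
            if a - 1 >= 0:
                arr[a - 1] = "T" if left_avoid in ("A", "G", "C") else "A"
            if b < length:
                arr[b] = "T" if right_avoid in ("A", "G", "C") else "A"
            truth.planted_elements.append(
                (pid, spec.kind, GenomicInterval(pid, a, b), spec.label or spec.payload)
            )
        # exclusion zone: no background G-runs / C-runs near a planted PQS
        for spec in specs:
            if spec.kind != "pqs":
                continue
            lo = max(0, spec.offset - 30)
            hi = min(length, spec.offset + len(spec.payload) + 30)
            for pos in range(lo + 1, hi):
                if in_payload(pos) or in_payload(pos - 1):
                    continue
                if arr[pos] == arr[pos - 1] and arr[pos] in ("G", "C"):
                    arr[pos] = "A" if arr[pos] == "G" else "T"
        promoters.append(Sequence(id=pid, residues="".join(arr)))
    return promoters, truth


# ---------------------------------------------------------------------------
# Divergent pairs
# ---------------------------------------------------------------------------

def simulate_divergent_pair(
    n_codons: int = 0,
    omega: float = 1.0,
    t_expected_subs_per_codon: float = 0.3,
    mode: str = "codon",
    p_site: float = 0.1,
    n_sites: int = 2000,
    seed: int | None = None,
) -> tuple[tuple[str, str], SimTruth]:
    """Simulate an aligned ancestor/descendant pair with known divergence.

    Codon mode: the ancestor is drawn from sense codons; candidate
    single-nucleotide changes are proposed (Poisson with mean
    ``t_expected_subs_per_codon`` per codon) and accepted with relative
    ratio omega : 1 for nonsynonymous : synonymous changes (i.e. the
    rarer class is accepted with probability min(1, omega) or
    min(1, 1/omega)); changes creating stop codons are rejected.

    Promoter mode: each of ``n_sites`` background sites independently
    substitutes to a uniformly chosen different base with probability
    ``p_site``; omega is ignored.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    if mode == "promoter":
        if not (0 <= p_site <= 1):
            raise ValueError("p_site must be a probability")
        anc = rng.choice(list("ACGT"), size=n_sites)
        der = anc.copy()
        hit = rng.random(n_sites) < p_site
        for idx in np.flatnonzero(hit):
            alternatives = [b for b in "ACGT" if b != anc[idx]]
            der[idx] = alternatives[rng.integers(3)]
        truth.true_rates["pair"] = (p_site, float("nan"))
        return ("".join(anc), "".join(der)), truth

    if mode != "codon":
        raise ValueError(f"unknown mode {mode!r}")
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    if omega <= 0:
        raise ValueError("omega must be positive")
    codons = list(SENSE_CODONS)
    anc_codons = [codons[k] for k in rng.integers(len(codons), size=n_codons)]
    der_codons = anc_codons.copy()
    accept_nonsyn = min(1.0, omega)
    accept_syn = min(1.0, 1.0 / omega)
    n_proposals = rng.poisson(t_expected_subs_per_codon * n_codons)
    for _ in range(n_proposals):
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        cur = der_codons[ci]
        base = "ACGT"[int(rng.integers(4))]
        if base == cur[pos]:
            continue
        mutant = cur[:pos] + base + cur[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        p_accept = accept_syn if _is_synonymous(cur, mutant) else accept_nonsyn
        if rng.random() < p_accept:
            der_codons[ci] = mutant
    truth.true_rates["pair"] = (float("nan"), omega)
    return ("".join(anc_codons), "".join(der_codons)), truth
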