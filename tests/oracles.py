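"""Independent brute-force reference implementations used only by tests.

These deliberately share no scanning code with the package: STRs are
found by naive per-offset character loops, PQS candidates by four nested
loops over naively computed G-tract positions, motif hits by expanding
the degenerate pattern into every concrete string, and the Mann-Whitney
null distribution by enumerating all label assignments.
"""

from __future__ import annotations

import itertools

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "X": "ACGT",
}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A",
              "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
              "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "X": "X"}


def rc(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def naive_strs(seq: str, unit_sizes=range(2, 7), min_copies: int = 7):
    """Every maximal perfect tandem array of a primitive unit, as a set of
    (start, end, unit, copies) tuples, by per-offset character scanning."""

    def primitive(u: str) -> bool:
        for d in range(1, len(u)):
            if len(u) % d == 0 and u == u[:d] * (len(u) // d):
                return False
        return True

    n = len(seq)
    found = set()
    for k in unit_sizes:
        a = 0
        while a + 2 * k <= n:
            # a must begin a maximal period-k run
            if a > 0 and a + k - 1 < n and seq[a - 1] == seq[a - 1 + k]:
                a += 1
                continue
            b = a + k
            while b < n and seq[b] == seq[b - k]:
                b += 1
            copies = (b - a) // k
            unit = seq[a : a + k]
            if copies >= min_copies and "N" not in unit and primitive(unit):
                found.add((a, a + copies * k, unit, copies))
            a += 1
    return found


def naive_g_tracts(seq: str, g: int):
    """Start positions of >= g consecutive G, by direct slicing."""
    return [
        i
        for i in range(len(seq) - g + 1)
        if seq[i : i + g] == "G" * g
    ]


def naive_pqs_candidates(seq: str, max_len=30, min_run=2, min_loop=0):
    """All (start, end, g, tracts) quadruplex candidates by nested loops."""
    out = set()
    max_g = (max_len - 3 * min_loop) // 4
    for g in range(min_run, max_g + 1):
        tracts = naive_g_tracts(seq, g)  # sorted ascending by construction
        for t1 in tracts:
            for t2 in tracts:
                if t2 < t1 + g + min_loop:
                    continue
                if t2 + 3 * g + 2 * min_loop > t1 + max_len:
                    break
                for t3 in tracts:
                    if t3 < t2 + g + min_loop:
                        continue
                    if t3 + 2 * g + min_loop > t1 + max_len:
                        break
                    for t4 in tracts:
                        if t4 < t3 + g + min_loop:
                            continue
                        if t4 + g > t1 + max_len:
                            break
                        out.add((t1, t4 + g, g, (t1, t2, t3, t4)))
    return out


def expand_motif(motif: str):
    """All concrete strings matching an IUPAC motif."""
    return {
        "".join(p) for p in itertools.product(*(IUPAC[c] for c in motif.upper()))
    }


def naive_motif_hits(seq: str, motif: str):
    """(start, strand) of every motif occurrence via full expansion."""
    m = len(motif)
    fwd = expand_motif(motif)
    rev = expand_motif(rc(motif))
    hits = set()
    for i in range(len(seq) - m + 1):
        word = seq[i : i + m]
        if word in fwd:
            hits.add((i, "+"))
        if word in rev:
            hits.add((i, "-"))
    return hits


def exact_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating label assignments."""
    pooled = sorted(list(x) + list(y))
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        us.append(u)
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))
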