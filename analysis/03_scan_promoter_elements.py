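#!/usr/bin/env python
"""Scan promoters for CpG islands, STRs, PQS and consensus motifs.

Compares element densities between the HK and TS promoter classes and
writes the density table, the STR-unit table and a GC-vs-TSS-distance
profile per class.
"""

from pathlib import Path

import pandas as pd

from promkit.elements import gc_profile
from promkit.pipeline import (
    density_table,
    read_motif_file,
    scan_promoters,
    str_unit_table,
)
from promkit.seqio import read_fasta

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "scratch" / "analysis" / "inputs"


def main() -> None:
    promoters = read_fasta(INPUTS / "promoters.fa")
    motifs = read_motif_file(INPUTS / "motifs.txt")
    prefix_to_label = {"hk": "HK", "ts": "TS", "ot": "other"}
    by_class = {"HK": [], "TS": [], "other": []}
    for p in promoters:
        by_class[prefix_to_label[p.id[:2]]].append(p)

    scans_by_class = {
        cls: scan_promoters(seqs, motifs) for cls, seqs in by_class.items()
    }
    results = ROOT / "results"
    dens = density_table(scans_by_class)
    dens.to_csv(results / "element_density.tsv", sep="\t", index=False)
    str_unit_table(scans_by_class).to_csv(
        results / "str_units.tsv", sep="\t", index=False
    )

    profiles = []
    for cls in ("HK", "TS"):
        prof = gc_profile(by_class[cls]).assign(cls=cls)
        profiles.append(prof)
    pd.concat(profiles).to_csv(results / "gc_profile.tsv", sep="\t", index=False)

    print(dens.pivot(index="element", columns="class", values="per_promoter").to_string())
    mean_gc = {
        cls: sum(p.gc_fraction() for p in by_class[cls]) / len(by_class[cls])
        for cls in ("HK", "TS")
    }
    print(f"\nmean promoter GC: HK {mean_gc['HK']:.3f}, TS {mean_gc['TS']:.3f}")


if __name__ == "__main__":
    main()
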