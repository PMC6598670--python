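"""A complete synthetic study bundle: every input the pipeline consumes.

The bundle emulates the structure of a pig-style promoter survey:
a transcript-by-tissue FPKM matrix over 21 tissues, 2-kb promoters per
gene whose element content differs by class (housekeeping promoters are
CpG-island- and STR-richer than tissue-specific ones), and orthologous
CDS / promoter pairs whose divergence differs by class (HK under
stronger purifying selection and with a lower promoter substitution
rate).  Class-level generator defaults are the values such surveys
report: HK/TS expression means 17.1 / 6.43 FPKM, CpG-island densities
0.47 / 0.30 per promoter with typical lengths 352 / 234 bp, STR
densities 0.31 / 0.15 per promoter, promoter GC 0.46 / 0.45, CDS
lengths 2181 / 1475 nt, and a TS promoter substitution rate of 0.64
per comparable site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqio import Sequence, write_expression_table, write_fasta
from .simulate import (
    PlantSpec,
    SimTruth,
    make_cpg_payload,
    make_motif_payload,
    make_str_payload,
    simulate_divergent_pair,
    simulate_expression_matrix,
    simulate_promoter_set,
)

#: consensus motifs planted in HK / TS promoters (shared zinc-finger-style
#: cores plus class-specific entries, as promoter surveys typically find)
HK_MOTIFS = ["GCYRCAGC", "GCTGTRGC", "AAAAWAAA", "CATATGS"]
TS_MOTIFS = ["GCYACAGC", "TATWTAT", "TTTTTYTT", "CCACTGAG"]

STR_UNITS = ["AC", "AG", "AT", "AAC", "AAT", "AAAG", "AAAT"]


@dataclass
class BundleSpec:
    n_hk: int = 150
    n_ts: int = 150
    n_other: int = 150
    n_tissues: int = 21
    noise_cv: float = 0.1
    promoter_length: int = 2000
    gc_hk: float = 0.46
    gc_ts: float = 0.45
    cpg_density_hk: float = 0.47
    cpg_density_ts: float = 0.30
    cpg_len_hk: int = 352
    cpg_len_ts: int = 234
    str_density_hk: float = 0.31
    str_density_ts: float = 0.15
    pqs_density_hk: float = 0.05
    pqs_density_ts: float = 0.04
    motifs_per_promoter: int = 2
    n_codons_hk: int = 727   # 2181 nt CDS
    n_codons_ts: int = 491   # 1475 nt CDS
    omega_hk: float = 0.1
    omega_ts: float = 0.3
    t_subs_per_codon: float = 0.6
    dp_hk: float = 0.45
    dp_ts: float = 0.64
    #: CV of the per-gene divergence modifier shared by a gene's promoter
    #: and CDS; induces the positive dP-vs-coding-rate correlation such
    #: surveys observe (promoters evolve in step with their genes)
    gene_rate_cv: float = 0.3


@dataclass
class BundlePaths:
    expression: Path
    promoters: Path
    motifs: Path
    cds_a: Path
    cds_b: Path
    prom_a: Path
    prom_b: Path
    config: Path
    truth: SimTruth = field(default_factory=SimTruth)
    true_rates: dict[str, tuple[float, float]] = field(default_factory=dict)


def _plant_promoters(
    gene_ids: list[str],
    cls: str,
    spec: BundleSpec,
    rng: np.random.Generator,
) -> list[Sequence]:
    n = len(gene_ids)
    if n == 0:
        return []
    hk = cls == "HK"
    plants: list[PlantSpec] = []
    if cls in ("HK", "TS"):
        cpg_p = spec.cpg_density_hk if hk else spec.cpg_density_ts
        cpg_len = spec.cpg_len_hk if hk else spec.cpg_len_ts
        str_p = spec.str_density_hk if hk else spec.str_density_ts
        pqs_p = spec.pqs_density_hk if hk else spec.pqs_density_ts
        motifs = HK_MOTIFS if hk else TS_MOTIFS
        for i in range(n):
            offset = 50
            if rng.random() < cpg_p:
                # CpG islands concentrate near the TSS-proximal end
                start = spec.promoter_length - cpg_len - 60
                plants.append(PlantSpec(i, "cpg", start, make_cpg_payload(cpg_len), "CpG"))
            if rng.random() < str_p:
                unit = STR_UNITS[rng.integers(len(STR_UNITS))]
                copies = int(rng.integers(7, 13))
                plants.append(
                    PlantSpec(i, "str", offset, make_str_payload(unit, copies), unit)
                )
                offset += len(unit) * copies + 4
            if rng.random() < pqs_p:
                plants.append(
                    PlantSpec(i, "pqs", offset + 40, "GGGTTAGGGTTAGGGTTAGGG", "G4")
                )
                offset += 70
            for _ in range(spec.motifs_per_promoter):
                motif = motifs[rng.integers(len(motifs))]
                plants.append(
                    PlantSpec(
                        i, "motif", offset + 120, make_motif_payload(motif, rng), motif
                    )
                )
                offset += 140
    gc = spec.gc_hk if hk else spec.gc_ts
    promoters, _ = simulate_promoter_set(
        n,
        length=spec.promoter_length,
        gc_background=gc,
        plant=plants,
        seed=int(rng.integers(2**31 - 1)),
    )
    return [
        Sequence(id=g, residues=p.residues) for g, p in zip(gene_ids, promoters)
    ]


def write_bundle(
    out_dir: str | Path, seed: int, spec: BundleSpec | None = None
) -> BundlePaths:
    """Generate and write the full input bundle plus a pipeline config."""
    spec = spec or BundleSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    matrix, truth = simulate_expression_matrix(
        spec.n_hk,
        spec.n_ts,
        spec.n_other,
        n_tissues=spec.n_tissues,
        noise_cv=spec.noise_cv,
        seed=int(rng.integers(2**31 - 1)),
    )
    expression = out / "expression.tsv"
    write_expression_table(matrix, expression)

    genes_by_class: dict[str, list[str]] = {"HK": [], "TS": [], "other": []}
    for gene, label in sorted(truth.true_label_of_gene.items()):
        genes_by_class[label].append(gene)

    promoters: list[Sequence] = []
    for cls in ("HK", "TS", "other"):
        promoters.extend(_plant_promoters(genes_by_class[cls], cls, spec, rng))
    promoter_path = out / "promoters.fa"
    write_fasta(promoters, promoter_path)

    motif_path = out / "motifs.txt"
    motif_path.write_text("".join(f"{m}\n" for m in sorted(set(HK_MOTIFS + TS_MOTIFS))))

    cds_a: list[Sequence] = []
    cds_b: list[Sequence] = []
    prom_a: list[Sequence] = []
    prom_b: list[Sequence] = []
    true_rates: dict[str, tuple[float, float]] = {}
    for cls, omega, n_codons, dp in (
        ("HK", spec.omega_hk, spec.n_codons_hk, spec.dp_hk),
        ("TS", spec.omega_ts, spec.n_codons_ts, spec.dp_ts),
    ):
        sigma = np.sqrt(np.log1p(spec.gene_rate_cv**2))
        for gene in genes_by_class[cls]:
            # mean-preserving per-gene modifier shared by CDS and promoter
            modifier = float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
            (a, b), _ = simulate_divergent_pair(
                n_codons=n_codons,
                omega=omega,
                t_expected_subs_per_codon=spec.t_subs_per_codon * modifier,
                seed=int(rng.integers(2**31 - 1)),
            )
            cds_a.append(Sequence(gene, a))
            cds_b.append(Sequence(gene, b))
            # scale the promoter divergence on the JC-corrected distance
            # scale, then map back: p stays below saturation by construction
            d_class = -0.75 * np.log1p(-4.0 * dp / 3.0)
            p_site = float(0.75 * (1.0 - np.exp(-4.0 * d_class * modifier / 3.0)))
            (pa, pb), _ = simulate_divergent_pair(
                mode="promoter",
                p_site=p_site,
                n_sites=spec.promoter_length,
                seed=int(rng.integers(2**31 - 1)),
            )
            prom_a.append(Sequence(gene, pa))
            prom_b.append(Sequence(gene, pb))
            true_rates[gene] = (p_site, omega)

    paths = BundlePaths(
        expression=expression,
        promoters=promoter_path,
        motifs=motif_path,
        cds_a=out / "cds_species_a.fa",
        cds_b=out / "cds_species_b.fa",
        prom_a=out / "promoters_species_a.fa",
        prom_b=out / "promoters_species_b.fa",
        config=out / "config.yaml",
        truth=truth,
        true_rates=true_rates,
    )
    write_fasta(cds_a, paths.cds_a)
    write_fasta(cds_b, paths.cds_b)
    write_fasta(prom_a, paths.prom_a)
    write_fasta(prom_b, paths.prom_b)

    config = {
        "expression_table": str(paths.expression),
        "promoter_fasta": str(paths.promoters),
        "motif_file": str(paths.motifs),
        "cds_a_fasta": str(paths.cds_a),
        "cds_b_fasta": str(paths.cds_b),
        "prom_a_fasta": str(paths.prom_a),
        "prom_b_fasta": str(paths.prom_b),
        "out_dir": str(out / "report"),
        "seed": int(seed),
    }
    paths.config.write_text(yaml.safe_dump(config, sort_keys=True))
    return paths
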