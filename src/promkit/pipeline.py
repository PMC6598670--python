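"""End-to-end pipeline: classify -> scan -> densities -> rates -> comparisons.

Driven by a YAML config naming the expression table, promoter FASTA,
optional orthologous CDS/promoter FASTA pairs, a motif list and all
thresholds.  Outputs are deterministic for a given config and seed:
per-class BED files of element hits, summary TSVs (classification,
STR-unit table, density table, rate table, group-comparison table) and a
plain-text run log (the only output carrying a timestamp).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import compare as _compare
from . import elements as _elements
from . import evolution as _evolution
from .seqio import (
    ExpressionMatrix,
    Sequence,
    read_expression_table,
    read_fasta,
    write_bed,
)


class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    expression_table: str
    promoter_fasta: str
    out_dir: str
    motif_file: str | None = None
    cds_a_fasta: str | None = None
    cds_b_fasta: str | None = None
    prom_a_fasta: str | None = None
    prom_b_fasta: str | None = None
    fpkm_threshold: float = _classify.DEFAULT_FPKM_THRESHOLD
    ks_cutoff: float = _classify.DEFAULT_KS_CUTOFF
    fold: float = _classify.DEFAULT_FOLD
    ts_max_tissues: int = _classify.DEFAULT_TS_MAX_TISSUES
    min_copies: int = 7
    cpg_window: int = 100
    cpg_min_len: int = 200
    cpg_min_gc: float = 0.5
    cpg_min_oe: float = 0.6
    pqs_max_len: int = 30
    pqs_min_run: int = 2
    pqs_min_loop: int = 0
    reps: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class ReportBundle:
    classification: pd.DataFrame
    transcript_evidence: pd.DataFrame
    densities: pd.DataFrame
    str_units: pd.DataFrame
    comparisons: pd.DataFrame
    rates: pd.DataFrame | None
    correlations: pd.DataFrame | None
    out_dir: Path
    log_path: Path


def _check_inputs(cfg: PipelineConfig) -> None:
    required = {
        "expression_table": cfg.expression_table,
        "promoter_fasta": cfg.promoter_fasta,
    }
    for name, p in required.items():
        if not p or not Path(p).exists():
            raise ConfigError(f"missing required input {name}: {p!r}")
    optional = {
        "motif_file": cfg.motif_file,
        "cds_a_fasta": cfg.cds_a_fasta,
        "cds_b_fasta": cfg.cds_b_fasta,
        "prom_a_fasta": cfg.prom_a_fasta,
        "prom_b_fasta": cfg.prom_b_fasta,
    }
    for name, p in optional.items():
        if p and not Path(p).exists():
            raise ConfigError(f"configured input {name} does not exist: {p!r}")
    ortholog = [cfg.cds_a_fasta, cfg.cds_b_fasta]
    if any(ortholog) and not all(ortholog):
        raise ConfigError("cds_a_fasta and cds_b_fasta must be given together")
    prom_pair = [cfg.prom_a_fasta, cfg.prom_b_fasta]
    if any(prom_pair) and not all(prom_pair):
        raise ConfigError("prom_a_fasta and prom_b_fasta must be given together")


def read_motif_file(path: str | Path) -> list[str]:
    """One IUPAC motif per line; blank lines and #-comments ignored."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                motifs.append(line.upper())
    return motifs


def scan_promoters(
    promoters: list[Sequence],
    motifs: list[str] | None = None,
    min_copies: int = 7,
    cpg_window: int = 100,
    cpg_min_len: int = 200,
    cpg_min_gc: float = 0.5,
    cpg_min_oe: float = 0.6,
    pqs_max_len: int = 30,
    pqs_min_run: int = 2,
    pqs_min_loop: int = 0,
) -> dict[str, dict[str, list]]:
    """All element hits per promoter: {promoter_id: {family: hits}}."""
    out: dict[str, dict[str, list]] = {}
    for p in promoters:
        hits = {
            "cpg": _elements.find_cpg_islands(
                p, cpg_window, cpg_min_len, cpg_min_gc, cpg_min_oe
            ),
            "str": _elements.find_strs(p, min_copies=min_copies),
            "pqs": _elements.find_pqs(
                p, max_len=pqs_max_len, min_run=pqs_min_run, min_loop=pqs_min_loop
            ),
            "motif": [
                h for m in (motifs or []) for h in _elements.scan_motif(p, m)
            ],
        }
        out[p.id] = hits
    return out


def hits_to_bed_records(scans: dict[str, dict[str, list]]):
    records = []
    for pid, families in scans.items():
        for island in families["cpg"]:
            records.append((island.interval, "CpG", 0))
        for locus in families["str"]:
            records.append((locus.interval, f"STR:{locus.canonical_unit}", locus.copies))
        for hit in families["pqs"]:
            records.append((hit.interval, "PQS", hit.g_score))
        for hit in families["motif"]:
            records.append((hit.interval, f"motif:{hit.motif}", 0))
    return records


def density_table(
    scans_by_class: dict[str, dict[str, dict[str, list]]]
) -> pd.DataFrame:
    rows = []
    for cls, scans in scans_by_class.items():
        n = len(scans)
        for family in ("cpg", "str", "pqs", "motif"):
            per_prom = [scans[pid][family] for pid in scans]
            total, dens = _elements.element_density(per_prom, n) if n else (0, 0.0)
            rows.append(
                {
                    "class": cls,
                    "element": family,
                    "n_promoters": n,
                    "total": total,
                    "per_promoter": dens,
                }
            )
    return pd.DataFrame(rows)


def str_unit_table(
    scans_by_class: dict[str, dict[str, dict[str, list]]]
) -> pd.DataFrame:
    """STR counts and per-promoter frequency by canonical unit and class."""
    rows = []
    for cls, scans in scans_by_class.items():
        n = max(len(scans), 1)
        counts: dict[str, int] = {}
        for pid in scans:
            for locus in scans[pid]["str"]:
                counts[locus.canonical_unit] = counts.get(locus.canonical_unit, 0) + 1
        for unit in sorted(counts, key=lambda u: (len(u), u)):
            rows.append(
                {
                    "class": cls,
                    "unit": unit,
                    "count": counts[unit],
                    "frequency_per_promoter": counts[unit] / n,
                }
            )
    return pd.DataFrame(rows, columns=["class", "unit", "count", "frequency_per_promoter"])


def rates_table(
    cds_a: list[Sequence],
    cds_b: list[Sequence],
    prom_a: list[Sequence] | None,
    prom_b: list[Sequence] | None,
    reps: int,
    seed: int,
) -> pd.DataFrame:
    """Per-gene dN, dS, omega, Z, p and dP for matched ortholog records."""
    b_cds = {s.id: s for s in cds_b}
    b_prom = {s.id: s for s in (prom_b or [])}
    a_prom = {s.id: s for s in (prom_a or [])}
    rows = []
    rng = np.random.default_rng(seed)
    for sa in cds_a:
        if sa.id not in b_cds:
            continue
        pair = _evolution.CodonPair(sa.residues, b_cds[sa.id].residues)
        rates = _evolution.nei_gojobori(pair)
        try:
            z, p = _evolution.selection_z_test(
                pair, reps=reps, seed=int(rng.integers(2**31 - 1))
            )
        except ValueError:
            z, p = float("nan"), float("nan")
        dp = float("nan")
        if sa.id in a_prom and sa.id in b_prom:
            dp = _evolution.promoter_distance(
                a_prom[sa.id].residues, b_prom[sa.id].residues
            )
        rows.append(
            {
                "gene_id": sa.id,
                "dN": rates.dN,
                "dS": rates.dS,
                "omega": rates.omega,
                "Z": z,
                "z_pvalue": p,
                "dP": dp,
            }
        )
    return pd.DataFrame(rows)


def rate_correlations(rates: pd.DataFrame, label_of: dict[str, str]) -> pd.DataFrame:
    """Pearson r of dP against dN, dS and omega, per gene class."""
    rows = []
    rates = rates.assign(label=[label_of.get(g, "other") for g in rates["gene_id"]])
    for cls, sub in rates.groupby("label"):
        for col in ("dN", "dS", "omega"):
            try:
                r, p = _evolution.rate_correlation(sub["dP"], sub[col])
            except ValueError:
                r, p = float("nan"), float("nan")
            rows.append({"class": cls, "pair": f"dP~{col}", "r": r, "pvalue": p})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under ``out_dir``.

    Stages: expression classification; per-class element scans and BED;
    density and STR-unit summaries; substitution rates and correlations
    when ortholog inputs are configured (skipped and logged otherwise);
    HK-vs-TS group comparisons.  Rerunning with the same config and seed
    reproduces every TSV/BED byte for byte.
    """
    _check_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"# pipeline run log", f"started: {time.strftime('%Y-%m-%dT%H:%M:%S')}"]
    for k, v in asdict(cfg).items():
        log_lines.append(f"param {k} = {v}")

    matrix = read_expression_table(cfg.expression_table)
    results = _classify.classify_genes(
        matrix, cfg.fpkm_threshold, cfg.ks_cutoff, cfg.fold, cfg.ts_max_tissues
    )
    gene_table = _classify.classification_table(results)
    tx_table = _classify.transcript_table(results)
    label_of = dict(zip(gene_table["gene_id"], gene_table["label"]))
    gene_table.to_csv(out / "classification.tsv", sep="\t", index=False)
    tx_table.to_csv(out / "transcript_evidence.tsv", sep="\t", index=False)
    counts = gene_table["label"].value_counts()
    log_lines.append(
        "classified genes: "
        + ", ".join(f"{lbl}={int(counts.get(lbl, 0))}" for lbl in ("HK", "TS", "other"))
    )

    promoters = read_fasta(cfg.promoter_fasta)
    motifs = read_motif_file(cfg.motif_file) if cfg.motif_file else []
    by_class: dict[str, list[Sequence]] = {"HK": [], "TS": [], "other": []}
    for p in promoters:
        by_class.setdefault(label_of.get(p.id, "other"), []).append(p)
    scans_by_class = {}
    for cls in ("HK", "TS", "other"):
        scans = scan_promoters(
            by_class[cls],
            motifs,
            cfg.min_copies,
            cfg.cpg_window,
            cfg.cpg_min_len,
            cfg.cpg_min_gc,
            cfg.cpg_min_oe,
            cfg.pqs_max_len,
            cfg.pqs_min_run,
            cfg.pqs_min_loop,
        )
        scans_by_class[cls] = scans
        write_bed(hits_to_bed_records(scans), out / f"elements_{cls}.bed")
    densities = density_table(scans_by_class)
    densities.to_csv(out / "element_density.tsv", sep="\t", index=False)
    str_units = str_unit_table(scans_by_class)
    str_units.to_csv(out / "str_units.tsv", sep="\t", index=False)

    rates_df = None
    corr_df = None
    if cfg.cds_a_fasta:
        rates_df = rates_table(
            read_fasta(cfg.cds_a_fasta),
            read_fasta(cfg.cds_b_fasta),
            read_fasta(cfg.prom_a_fasta) if cfg.prom_a_fasta else None,
            read_fasta(cfg.prom_b_fasta) if cfg.prom_b_fasta else None,
            cfg.reps,
            cfg.seed,
        )
        rates_df.to_csv(out / "substitution_rates.tsv", sep="\t", index=False)
        corr_df = rate_correlations(rates_df, label_of)
        corr_df.to_csv(out / "rate_correlations.tsv", sep="\t", index=False)
        log_lines.append(f"rates computed for {len(rates_df)} ortholog pairs")
    else:
        log_lines.append("evolution stage skipped: no ortholog inputs configured")

    features: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gc_by_class = {
        cls: np.array([p.gc_fraction() for p in by_class[cls]])
        for cls in ("HK", "TS")
    }
    features["promoter_gc_fraction"] = (gc_by_class["HK"], gc_by_class["TS"])
    for family in ("cpg", "str", "pqs", "motif"):
        features[f"{family}_per_promoter"] = tuple(
            np.array([len(scans_by_class[cls][pid][family]) for pid in scans_by_class[cls]])
            for cls in ("HK", "TS")
        )  # type: ignore[assignment]
    if rates_df is not None and len(rates_df):
        labeled = rates_df.assign(
            label=[label_of.get(g, "other") for g in rates_df["gene_id"]]
        )
        for col in ("dN", "dS", "omega", "dP"):
            features[col] = (
                labeled.loc[labeled["label"] == "HK", col].to_numpy(),
                labeled.loc[labeled["label"] == "TS", col].to_numpy(),
            )
    comparisons = _compare.comparison_table(
        _compare.summarize_groups(features)
    )
    comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    return ReportBundle(
        classification=gene_table,
        transcript_evidence=tx_table,
        densities=densities,
        str_units=str_units,
        comparisons=comparisons,
        rates=rates_df,
        correlations=corr_df,
        out_dir=out,
        log_path=log_path,
    )
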