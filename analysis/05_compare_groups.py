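#!/usr/bin/env python
"""Full pipeline run: HK-vs-TS group comparisons on every feature.

Runs the complete config-driven pipeline (classification, element scans,
densities, substitution rates, Mann-Whitney comparisons) and copies the
comparison table into results/.
"""

import shutil
from pathlib import Path

from promkit.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "scratch" / "analysis" / "inputs"


def main() -> None:
    cfg = PipelineConfig.from_yaml(INPUTS / "config.yaml")
    cfg.out_dir = str(ROOT / "scratch" / "analysis" / "report")
    report = run_pipeline(cfg)

    results = ROOT / "results"
    shutil.copy(report.out_dir / "group_comparisons.tsv", results)
    print(report.comparisons.to_string(index=False))
    print(f"\nfull report bundle under {report.out_dir}")


if __name__ == "__main__":
    main()
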