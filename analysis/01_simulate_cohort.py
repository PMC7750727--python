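#!/usr/bin/env python
"""Simulate the demo cohort: ancestral panels plus nine triploid
accessions drawn from three founding HE patterns (three clonal
accessions each), written as multi-sample VCFs with known truth.

Simulated read data is bulky and fully regenerable, so it goes under
scratch/cohort/ (panels.vcf, targets.vcf, chromosomes.tsv,
pipeline.json); downstream scripts read it from there and write their
summary tables under results/.
"""

import json
from pathlib import Path

from musakaryo.pipeline import make_demo_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "cohort"


def main() -> None:
    config = make_demo_cohort(OUT, seed=1)
    (OUT / "pipeline.json").write_text(json.dumps(vars(config), indent=2) + "\n")
    print(f"cohort simulated under {OUT}")
    print(f"  panels: {len(config.panel_a_samples)} A-pool + {len(config.panel_b_samples)} B-pool accessions")
    print(f"  targets: {len(config.target_samples)} triploid accessions "
          f"({', '.join(config.target_samples)})")


if __name__ == "__main__":
    main()
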