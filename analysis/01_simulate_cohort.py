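#!/usr/bin/env python
"""Simulate the synthetic SNP-array cohort with known ground truth.

Writes one per-SNP table per sample plus metadata and truth tables under
scratch/cohort/, and a small cohort overview under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, RESULTS, SCRATCH  # noqa: E402

from cnloh import simulate_cohort  # noqa: E402


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    meta = simulate_cohort(CONFIG, out_dir=SCRATCH, overwrite=True)
    truth = pd.read_csv(SCRATCH / "truth_segments.tsv", sep="\t")
    events = truth[truth.origin != "background"]
    overview = (meta.groupby("group")["sample_id"].count()
                .rename("n_samples").to_frame())
    overview["truth_events"] = events.merge(meta, on="sample_id") \
        .groupby("group")["chrom"].count()
    overview["truth_events"] = overview["truth_events"].fillna(0).astype(int)
    overview.to_csv(RESULTS / "cohort_overview.tsv", sep="\t")
    print(f"simulated {len(meta)} samples "
          f"({CONFIG.n_tumors} tumors, {CONFIG.n_cell_lines} cell lines, "
          f"{CONFIG.n_controls} controls) at "
          f"{CONFIG.marker_spacing_bp // 1000} kb marker spacing")
    print(overview)


if __name__ == "__main__":
    main()
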