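#!/usr/bin/env python
"""Compare the related cell-line trio (parent + two subclones).

Matches aberrations across the three profiles by reciprocal overlap and
identical allelic state, labeling each event shared-by-all /
shared-by-subset / unique, and flags overlapping-but-distinct events.
Writes results/cell_line_comparison.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH  # noqa: E402

from cnloh.loh_caller import LohCall, compare_profiles  # noqa: E402
from cnloh.state_fit import AllelicState  # noqa: E402


def main() -> None:
    meta = pd.read_csv(SCRATCH / "metadata.tsv", sep="\t")
    calls = pd.read_csv(RESULTS / "loh_calls.tsv", sep="\t")
    trio_meta = meta[meta.related_group.fillna("") != ""]
    if trio_meta.empty:
        print("no related cell-line group in this cohort")
        return
    trio_ids = list(trio_meta.sample_id)
    by_sample = {}
    for sid in trio_ids:
        sub = calls[calls["sample"] == sid]
        by_sample[sid] = [
            LohCall(sample_id=sid, chrom=r.chrom, start_bp=int(r.start),
                    end_bp=int(r.end), state=AllelicState(int(r.major),
                                                          int(r.minor)),
                    category=r.category, extent=r.extent)
            for r in sub.itertuples()
        ]
    out = compare_profiles(by_sample)
    out.to_csv(RESULTS / "cell_line_comparison.tsv", sep="\t", index=False)
    if out.empty:
        print("no reportable aberrations in the trio")
        return
    counts = out["label"].value_counts().to_dict()
    print(f"trio {', '.join(trio_ids)}: {len(out)} aberration clusters "
          f"({counts.get('shared_by_all', 0)} shared by all, "
          f"{counts.get('shared_by_subset', 0)} shared by a subset, "
          f"{counts.get('unique', 0)} unique)")
    print(out[["chrom", "start_bp", "end_bp", "state", "label", "samples"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
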