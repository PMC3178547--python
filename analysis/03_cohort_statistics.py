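#!/usr/bin/env python
"""Group-level statistics: exclusions, prevalence, burden, spectra, outcome.

Reads the per-sample summaries from results/, applies the inclusion rules
(one representative per related cell-line group; stroma-like tumor profiles
removed) and writes results/cohort_stats.json plus the exclusion log.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH  # noqa: E402

from cnloh.cohort_stats import run_cohort_stats  # noqa: E402
from cnloh.loh_caller import EXTENTS, SampleSummary  # noqa: E402


def main() -> None:
    meta = pd.read_csv(SCRATCH / "metadata.tsv", sep="\t")
    rows = pd.read_csv(RESULTS / "sample_summaries.tsv", sep="\t")
    summaries = [
        SampleSummary(
            sample_id=r.sample_id,
            near_cn_loh_count=int(r.near_cn_loh_count),
            counts_by_extent={e: int(getattr(r, e.lower())) for e in EXTENTS},
            aberrant_segment_count=int(r.aberrant_segments),
            flat_profile=bool(r.flat_profile),
            mycn_amp_only=bool(r.mycn_amp_only),
            cn_loh_only=bool(r.cn_loh_only),
        )
        for r in rows.itertuples()
    ]
    res = run_cohort_stats(summaries, meta)
    with open(RESULTS / "cohort_stats.json", "w") as fh:
        json.dump(res.to_json_dict(), fh, indent=2)
    res.exclusion_log.to_csv(RESULTS / "exclusions.tsv", sep="\t", index=False)

    print("analyzed groups:", res.n_per_group)
    for g, p in res.prevalence.items():
        print(f"  {g}: {p['count']}/{p['n']} with >= 1 near-CN-LOH "
              f"({100 * p['fraction']:.0f}%), "
              f"burden median {res.burden[g]['median']:.0f} "
              f"mean {res.burden[g]['mean']:.2f}")
    for pair, p in res.fisher_p.items():
        print(f"  Fisher {pair}: p = {p:.4f}; "
              f"Mann-Whitney: p = {res.mann_whitney_p[pair]:.4f}")
    for g, spec in res.spectrum.items():
        if spec:
            txt = ", ".join(f"{e.lower()} {100 * f:.0f}%" for e, f in spec.items())
            print(f"  {g} extent spectrum: {txt}")
    if res.outcome_p:
        print("  outcome comparison (DOD vs NED), overall p =",
              f"{res.outcome_p['overall']:.3f}" if res.outcome_p["overall"]
              is not None else "n/a")
    print(f"excluded {len(res.exclusion_log)} samples "
          "(see results/exclusions.tsv)")


if __name__ == "__main__":
    main()
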