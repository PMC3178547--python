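"""Shared configuration for the numbered analysis scripts.

The analysis runs a moderately sized cohort (60 tumors, 10 cell lines with
one related trio, 20 controls) at 50 kb marker spacing so the whole pipeline
finishes in a couple of minutes; scripts/acceptance.py repeats the analysis
at the full study scale and density.
"""

from pathlib import Path

from cnloh import CohortConfig
from cnloh.genome import make_marker_map

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

CONFIG = CohortConfig(
    n_tumors=60,
    n_cell_lines=10,
    n_controls=20,
    marker_spacing_bp=50_000,
    seed=17,
)


def marker_map():
    return make_marker_map(marker_spacing_bp=CONFIG.marker_spacing_bp)
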