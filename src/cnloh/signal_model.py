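"""Per-sample observable tracks from SNP-array tables.

Two tracks drive everything downstream: the normalized total intensity ratio
t (sample over a pool of best-matched references, median-centered to 1), and
the mirrored allele fraction max(BAF, 1 - BAF) of markers with a heterozygous
genotype call. Contaminating normal cells regenerate heterozygous-looking
calls inside somatically LOH regions, which is exactly what makes those
regions readable on the mirrored track in impure samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SnpTable",
    "AlleleTracks",
    "read_snp_table",
    "write_snp_table",
    "select_references",
    "normalized_total_ratio",
    "allele_fraction_tracks",
]

SNP_COLUMNS = ["chrom", "pos", "total_ratio", "baf", "call"]
_CALLS = {"AA", "AB", "BB", "NoCall"}


@dataclass
class SnpTable:
    """Per-marker observed signals for one sample.

    ``df`` columns: chrom, pos (1-based), total_ratio (>= 0), baf ([0, 1]),
    call (AA/AB/BB/NoCall); sorted by (chrom, pos) with chromosome order as
    first encountered.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SNP_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SnpTable missing columns: {missing}")
        bad = set(self.df["call"].unique()) - _CALLS
        if bad:
            raise ValueError(f"unknown genotype calls: {sorted(bad)}")
        if ((self.df["baf"] < 0) | (self.df["baf"] > 1)).any():
            raise ValueError("baf outside [0, 1]")
        if not np.isfinite(self.df["total_ratio"]).all():
            raise ValueError("non-finite total_ratio")

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def autosomal_mask(self) -> np.ndarray:
        return (self.df["chrom"] != "chrX").to_numpy()


def read_snp_table(path: str | Path, sample_id: str | None = None) -> SnpTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return SnpTable(sample_id=sample_id or path.stem, df=df)


def write_snp_table(table: SnpTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# reference selection and normalization

def select_references(
    sample: SnpTable, candidates: list[SnpTable], k: int = 6
) -> tuple[list[SnpTable], pd.DataFrame]:
    """Pick the ``k`` candidates minimizing SD of log2(sample/candidate).

    The SD is computed over autosomal markers with positive signal in both
    tables; ranking is invariant to a global rescaling of the sample (a scale
    factor only shifts the log-ratio). Ties break deterministically by
    candidate sample_id. Returns (chosen candidates, per-candidate SD table).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(candidates) < k:
        raise ValueError(f"need at least k={k} candidates, got {len(candidates)}")
    auto = sample.autosomal_mask()
    s = sample.df["total_ratio"].to_numpy()
    rows = []
    for cand in candidates:
        c = cand.df["total_ratio"].to_numpy()
        if len(c) != len(s):
            raise ValueError(f"marker sets differ between sample and {cand.sample_id}")
        ok = auto & (s > 0) & (c > 0)
        ratio = np.log2(s[ok] / c[ok])
        rows.append((cand.sample_id, float(np.std(ratio))))
    sd_table = pd.DataFrame(rows, columns=["candidate", "sd"]).sort_values(
        ["sd", "candidate"], kind="mergesort", ignore_index=True
    )
    chosen_ids = set(sd_table.head(k)["candidate"])
    chosen = [c for c in candidates if c.sample_id in chosen_ids]
    return chosen, sd_table


def normalized_total_ratio(sample: SnpTable, references: list[SnpTable]) -> pd.Series:
    """Sample ratio over the marker-wise reference-pool mean, rescaled so the
    autosomal genome-wide median equals 1. Markers with zero pooled reference
    signal are dropped (NaN) with a warning."""
    if not references:
        raise ValueError("at least one reference required")
    ref = np.mean([r.df["total_ratio"].to_numpy() for r in references], axis=0)
    s = sample.df["total_ratio"].to_numpy(dtype=float)
    t = np.full(len(s), np.nan)
    ok = ref > 0
    if (~ok).any():
        log.warning("%d markers dropped: zero reference signal", int((~ok).sum()))
    t[ok] = s[ok] / ref[ok]
    med = np.nanmedian(t[sample.autosomal_mask()])
    if not np.isfinite(med) or med <= 0:
        raise ValueError("cannot normalize: non-positive autosomal median")
    return pd.Series(t / med, index=sample.df.index, name="t")


@dataclass
class AlleleTracks:
    """Joint per-marker tracks for one sample, ready for segmentation.

    ``strong``/``weak`` are mirrored fractions (strong + weak = 1,
    strong >= 0.5); they are meaningful only where ``het_informative`` is
    True (genotype call AB). ``t`` covers all markers.
    """

    sample_id: str
    chrom: np.ndarray
    pos: np.ndarray
    t: np.ndarray
    strong: np.ndarray
    weak: np.ndarray
    het_informative: np.ndarray
    homozygous_only: bool = False  # no AB calls anywhere in the sample

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.chrom.tolist()))

    def chromosome_arrays(self, chrom: str):
        m = self.chrom == chrom
        return self.pos[m], self.t[m], self.strong[m], self.het_informative[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "t": self.t,
             "strong": self.strong, "weak": self.weak}
        )


def allele_fraction_tracks(sample: SnpTable, t: pd.Series | np.ndarray | None = None) -> AlleleTracks:
    """Build mirrored allele-fraction tracks from genotype calls.

    Markers called AB are het-informative: strong = max(baf, 1 - baf). All
    other markers keep the total-ratio track only. If the sample has no AB
    call at all, the tracks are flagged ``homozygous_only``. Output is
    invariant under baf -> 1 - baf.
    """
    df = sample.df
    baf = df["baf"].to_numpy(dtype=float)
    het = (df["call"] == "AB").to_numpy()
    strong = np.where(het, np.maximum(baf, 1.0 - baf), 1.0)
    if t is None:
        t_arr = df["total_ratio"].to_numpy(dtype=float)
    else:
        t_arr = np.asarray(t, dtype=float)
    keep = np.isfinite(t_arr)
    if not het.any():
        log.warning("sample %s has no heterozygous calls; mirrored track empty",
                    sample.sample_id)
    return AlleleTracks(
        sample_id=sample.sample_id,
        chrom=df["chrom"].to_numpy()[keep],
        pos=df["pos"].to_numpy()[keep],
        t=t_arr[keep],
        strong=strong[keep],
        weak=1.0 - strong[keep],
        het_informative=het[keep],
        homozygous_only=not bool(het.any()),
    )
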