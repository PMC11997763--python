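"""Primary-target classification and responsive-TSS calling.

A differentially transcribed gene is a *primary* hormone target when its
locus, flanked by +/-5 kb, contains at least one receptor (EcR) peak — the
hormone can act on it directly.  Genes whose transcription drops upon
hormone depletion are the hormone-ACTIVATED set (and vice versa).

Responsive TSSs are called from read counts in the 500 bp strand-aware
window downstream of each TSS, with the same machinery as the gene-level
test but thresholded on the raw p-value (FC >= |1.5|, P <= .05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .genomic_core import GeneModel, Interval, Peak, downstream_window, flank, overlap_matrix


@dataclass(frozen=True)
class TargetGene:
    gene_id: str
    direction: str  # activated | suppressed
    primary: bool
    ecr_peak_ids: tuple[str, ...]

    def __post_init__(self):
        if self.primary != bool(self.ecr_peak_ids):
            raise ValueError("primary <=> ecr_peak_ids non-empty")


@dataclass(frozen=True)
class ResponsiveTSS:
    gene_id: str
    tss: int
    strand: str
    window: Interval
    log2fc: float
    p: float
    call: str


def call_primary_targets(
    de_results: pd.DataFrame,
    gene_models: list[GeneModel],
    ecr_peaks: list[Peak],
    pad_bp: int = 5000,
) -> list[TargetGene]:
    """Classify DE genes as primary (>=1 EcR peak in locus +/- pad_bp).

    ``de_results`` must carry gene-level calls; ``down`` genes (reduced upon
    depletion) are hormone-activated, ``up`` genes hormone-suppressed.  A
    peak overlapping two flanked loci counts for both genes.
    """
    models = {g.gene_id: g for g in gene_models}
    de = de_results[de_results.call.isin(["down", "up"])]
    missing = sorted(set(de.feature_id) - set(models))
    if missing:
        raise KeyError(f"DE genes absent from annotation: {missing}")
    flanked = [flank(models[gid].locus, pad_bp) for gid in de.feature_id]
    peak_ivs = [p.interval for p in ecr_peaks]
    hits = overlap_matrix(flanked, peak_ivs)
    out = []
    for (_, row), idx in zip(de.iterrows(), hits):
        direction = "activated" if row.call == "down" else "suppressed"
        names = tuple(ecr_peaks[i].name for i in idx)
        out.append(TargetGene(row.feature_id, direction, bool(names), names))
    return out


def _parse_tss_feature(feature_id: str):
    gene_id, loc = feature_id.split("@")
    chrom, pos, strand = loc.rsplit(":", 2)
    return gene_id, chrom, int(pos), strand


def call_responsive_tss(
    tss_counts: pd.DataFrame,
    design: pd.DataFrame,
    direction: str = "activated",
    tissue: str | None = "SG",
    contrast: tuple[str, str] = ("HS", "NHS"),
    width: int = 500,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> list[ResponsiveTSS]:
    """TSSs whose downstream-window signal responds to depletion.

    Uses the raw p-value (not BH-adjusted).  TSS features are identified as
    ``gene@chrom:pos:strand``; TSSs shared by transcripts deduplicate on
    (chrom, pos, strand).  ``direction="activated"`` keeps TSSs reduced
    under treatment (call ``down`` for contrast HS over NHS).
    """
    if direction not in ("activated", "suppressed"):
        raise ValueError("direction must be 'activated' or 'suppressed'")
    keys = pd.Index([_parse_tss_feature(f)[1:] for f in tss_counts.index])
    dedup = tss_counts.loc[~keys.duplicated()]
    res = diffexpr.test_differential(
        dedup,
        design,
        contrast,
        tissue=tissue,
        lfc_threshold=fc_threshold,
        alpha=alpha,
        adjust=False,
    )
    wanted = "down" if direction == "activated" else "up"
    out = []
    for row in res.itertuples():
        if row.call != wanted:
            continue
        gene_id, chrom, pos, strand = _parse_tss_feature(row.feature_id)
        out.append(
            ResponsiveTSS(
                gene_id,
                pos,
                strand,
                downstream_window(chrom, pos, strand, width),
                row.log2fc,
                row.p,
                row.call,
            )
        )
    return out


def fisher_enrichment(foreground_ids, background_ids, flags: dict):
    """Two-sided Fisher exact test of a boolean annotation in a foreground
    set against the rest of its background.

    Returns ``(odds_ratio, p)``; the odds ratio uses a Haldane 0.5
    correction when any cell of the 2x2 table is zero.
    """
    fg = list(foreground_ids)
    bg = set(background_ids)
    if not fg:
        raise ValueError("empty foreground")
    if not set(fg) <= bg:
        raise ValueError("foreground must be a subset of background")
    rest = bg - set(fg)
    a = sum(bool(flags[i]) for i in fg)
    b = len(fg) - a
    c = sum(bool(flags[i]) for i in rest)
    d = len(rest) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
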