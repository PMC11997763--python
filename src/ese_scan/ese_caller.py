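"""Ecdysone-sensitive element (ESE) calling and classification.

An ESE is a genomic site co-bound by the hormone receptor (EcR) and the
CBP/Nejire acetyltransferase inside a target locus +/-5 kb.  Elements split
two ways:

* location: *proximal* when the summit lies within +/-250 bp of a TSS of an
  assigned locus (boundary inclusive), else *distal*;
* activity: *active* vs *poised* by 2-way agglomerative clustering (Ward,
  Euclidean) on the log input-subtracted H3K27Ac level in a +/-500 bp
  summit window — the H3K27Ac mark is the signature of active enhancers,
  and its distribution over co-bound sites is bimodal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .genomic_core import (
    CoverageTrack,
    GeneModel,
    Interval,
    Peak,
    centered_window,
    flank,
    overlap_matrix,
    window_mean,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ESERecord:
    ese_id: str
    interval: Interval  # intersection footprint (merged over co-bound pairs)
    summit: int
    locus_ids: tuple[str, ...]
    location_class: str | None = None  # proximal | distal
    activity_class: str | None = None  # active | poised
    h3k27ac_level: float | None = None


def call_eses(
    ecr_peaks: list[Peak],
    cbp_peaks: list[Peak],
    target_loci: list[GeneModel],
    pad_bp: int = 5000,
) -> list[ESERecord]:
    """Intersect receptor and coactivator peaks within target loci +/-5 kb.

    Each EcR peak overlapping >=1 CBP peak yields a candidate footprint (the
    pairwise intersection); overlapping candidate footprints merge by union.
    A footprint is retained when it overlaps the flanked locus of >=1 target
    gene.  Summit: the EcR summit when it falls inside the footprint, else
    the footprint midpoint.
    """
    if not ecr_peaks or not cbp_peaks:
        log.warning("empty peak set: no ESEs can be called")
        return []
    cbp_ivs = [p.interval for p in cbp_peaks]
    hits = overlap_matrix([p.interval for p in ecr_peaks], cbp_ivs)
    candidates = []  # (footprint, ecr_peak)
    for ecr, idx in zip(ecr_peaks, hits):
        for i in idx:
            footprint = ecr.interval.intersect(cbp_ivs[i])
            candidates.append((footprint, ecr))
    candidates.sort(key=lambda c: (c[0].chrom, c[0].start, c[0].end))

    merged: list[tuple[Interval, list[Peak]]] = []
    for footprint, ecr in candidates:
        if merged and merged[-1][0].overlaps(footprint):
            merged[-1] = (merged[-1][0].union(footprint), merged[-1][1] + [ecr])
        else:
            merged.append((footprint, [ecr]))

    flanked = [flank(g.locus, pad_bp) for g in target_loci]
    locus_hits = overlap_matrix([m[0] for m in merged], flanked)
    records = []
    for (footprint, ecrs), idx in zip(merged, locus_hits):
        if not idx:
            continue
        summit = None
        for ecr in ecrs:
            if footprint.start <= ecr.summit_pos < footprint.end:
                summit = ecr.summit_pos
                break
        if summit is None:
            summit = footprint.start + len(footprint) // 2
        records.append(
            ESERecord(
                f"ese{len(records) + 1:04d}",
                footprint,
                summit,
                tuple(target_loci[i].gene_id for i in idx),
            )
        )
    return records


def classify_location(
    eses: list[ESERecord],
    gene_models: list[GeneModel],
    proximal_half: int = 250,
) -> list[ESERecord]:
    """Proximal iff |summit - tss| <= proximal_half for a TSS of an assigned
    locus (inclusive boundary); else distal."""
    tss_by_gene = {g.gene_id: g.tss_list for g in gene_models}
    out = []
    for e in eses:
        tss = [t for gid in e.locus_ids for t in tss_by_gene.get(gid, ())]
        proximal = any(abs(e.summit - t) <= proximal_half for t in tss)
        out.append(replace(e, location_class="proximal" if proximal else "distal"))
    return out


def acetylation_level(
    ese: ESERecord,
    h3k27ac_tracks: list[CoverageTrack],
    input_tracks: list[CoverageTrack],
    window_half: int = 500,
) -> float:
    """Replicate-mean input-subtracted H3K27Ac in the summit window,
    floored at 0."""
    window = centered_window(ese.interval.chrom, ese.summit, window_half)
    vals = [
        max(window_mean(t, window) - window_mean(i, window), 0.0)
        for t, i in zip(h3k27ac_tracks, input_tracks, strict=True)
    ]
    return float(np.mean(vals))


def classify_activity(
    eses: list[ESERecord],
    h3k27ac_tracks: list[CoverageTrack],
    input_tracks: list[CoverageTrack],
    window_half: int = 500,
) -> list[ESERecord]:
    """Split ESEs into active/poised by Ward clustering at k=2 on the log
    acetylation level; the cluster with the higher mean is active."""
    if len(eses) < 2:
        raise ValueError("need >=2 ESEs to cluster")
    levels = np.array(
        [acetylation_level(e, h3k27ac_tracks, input_tracks, window_half) for e in eses]
    )
    feats = np.log1p(levels)
    if np.allclose(feats, feats[0]):
        log.warning("all acetylation levels identical; labelling all poised")
        labels = np.zeros(len(eses), dtype=int)
        active_label = -1
    else:
        order = np.argsort(feats, kind="stable")  # input-order invariance
        clust = AgglomerativeClustering(n_clusters=2, linkage="ward")
        sorted_labels = clust.fit_predict(feats[order].reshape(-1, 1))
        labels = np.empty(len(eses), dtype=int)
        labels[order] = sorted_labels
        active_label = max((feats[labels == k].mean(), k) for k in (0, 1))[1]
    return [
        replace(
            e,
            activity_class="active" if lab == active_label else "poised",
            h3k27ac_level=float(lev),
        )
        for e, lab, lev in zip(eses, labels, levels)
    ]
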