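"""Metaprofiles around anchors, aggregate window fold-changes, and PCA.

Profiles are matrices of normalized signal (ratio-to-input for ChIP,
input-subtracted for FAIRE/H3K27Ac) over a symmetric bp grid around anchor
points (TSSs or element summits).  Minus-strand anchors are orientation-
flipped so positive offsets always read "downstream".  Panel summaries are
the per-offset median with its standard error, and a single fold change per
window computed as the ratio of condition-level means of per-anchor window
means, tested with a paired t across anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .diffbind_windows import EPSILON
from .genomic_core import CoverageTrack

log = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    anchor_ids: list[str]
    offsets: np.ndarray  # bp grid, strand-corrected
    values: np.ndarray  # anchors x offsets


def build_profile(
    sample_tracks: list[CoverageTrack],
    input_tracks: list[CoverageTrack] | None,
    anchors: list[tuple[str, str, int, str]],
    assay: str = "chip",
    half_span: int = 2000,
) -> ProfileMatrix:
    """Replicate-averaged normalized signal around anchors.

    ``anchors`` are ``(anchor_id, chrom, center, strand)``.  Anchors whose
    span leaves the covered region are dropped (logged).  Minus-strand rows
    are flipped.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    bw = sample_tracks[0].bin_bp
    offsets = np.arange(-half_span, half_span, bw) + bw // 2
    kept_ids, rows = [], []
    n_off = len(offsets)
    for anchor_id, chrom, center, strand in anchors:
        if chrom not in sample_tracks[0].bins:
            log.debug("anchor %s dropped: chrom %s not covered", anchor_id, chrom)
            continue
        first = (center - half_span) // bw
        if first < 0 or first + n_off > len(sample_tracks[0].bins[chrom]):
            log.debug("anchor %s dropped: window clipped", anchor_id)
            continue
        sl = slice(first, first + n_off)
        sig = np.mean([t.bins[chrom][sl] for t in sample_tracks], axis=0).astype(float)
        if input_tracks is not None:
            inp = np.mean([t.bins[chrom][sl] for t in input_tracks], axis=0).astype(float)
            if assay == "chip":
                sig = (sig + EPSILON) / (inp + EPSILON)
            else:
                sig = np.maximum(sig - inp, 0.0)
        if strand == "-":
            sig = sig[::-1]
        kept_ids.append(anchor_id)
        rows.append(sig)
    if not rows:
        raise ValueError("all anchors dropped (clipped or uncovered)")
    return ProfileMatrix(kept_ids, offsets, np.array(rows))


def summarize_profile(profile: ProfileMatrix) -> pd.DataFrame:
    """Per-offset median across anchors and its standard error (sd/sqrt(n))."""
    if profile.values.shape[0] < 2:
        raise ValueError("need >=2 anchors to summarise")
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "median": np.median(profile.values, axis=0),
            "se": profile.values.std(axis=0, ddof=1) / np.sqrt(profile.values.shape[0]),
        }
    )


def window_fc_test(
    profile_a: ProfileMatrix,
    profile_b: ProfileMatrix,
    window_half: int = 250,
):
    """Aggregate fold change of condition A over B in a central window.

    Per-anchor means over offsets within +/-window_half feed a paired t
    across anchors; the reported FC is the ratio of the condition-level
    means of those per-anchor means.  Returns ``(fc, p, per_anchor_fc)``.
    """
    if profile_a.anchor_ids != profile_b.anchor_ids:
        raise ValueError("profiles must share anchors")
    sel = np.abs(profile_a.offsets) <= window_half
    wa = profile_a.values[:, sel].mean(axis=1)
    wb = profile_b.values[:, sel].mean(axis=1)
    fc = float(wa.mean() / wb.mean())
    if np.allclose(wa, wb):
        p = 1.0
    else:
        p = float(stats.ttest_rel(wa, wb).pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_anchor = wa / wb
    return fc, p, per_anchor


def pca_on_windows(window_score_matrix: pd.DataFrame, n_components: int | None = None):
    """PCA of samples (rows) over per-region window scores (columns).

    Columns are centered.  Returns ``(coordinates, explained_variance_ratio)``
    with coordinates indexed like the input rows.
    """
    x = window_score_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 regions")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant matrix has no principal components")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(centered)
    frame = pd.DataFrame(
        coords,
        index=window_score_matrix.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_
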