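"""Differential binding / accessibility / acetylation calls per window.

Window scores follow the assay convention: ChIP enrichment is the ratio of
sample to input coverage (with a small stabiliser epsilon); FAIRE and
H3K27Ac are input-subtracted, floored at 0.  Scores from replicate pairs in
two conditions feed a paired t-test on log2 scores, producing per-region
fold changes and the five-way state call: down / up / flat from the
statistics (|log2FC| >= 1 and P <= .05 by default), overridden by absent
(no peak in either condition's peak set over the window) and acquired
(peak only under treatment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import CoverageTrack, Interval, Peak, overlap_matrix, window_mean

EPSILON = 0.25  # fraction of the background unit stabilising ratio scores
LOG_FLOOR = 0.25  # pseudo-signal added before log2 of subtractive scores

CALLS = ("down", "up", "flat", "absent", "acquired")


def score_windows(
    regions: list[tuple[str, Interval]],
    sample_tracks: list[CoverageTrack],
    input_tracks: list[CoverageTrack] | None,
    assay: str,
) -> pd.DataFrame:
    """Normalized per-region, per-sample window scores.

    ``regions`` are ``(region_id, window)`` pairs.  ``assay="chip"`` scores
    (sample+eps)/(input+eps); ``"faire"``/``"h3k27ac"`` score sample-input
    floored at 0.  ``input_tracks=None`` (explicit opt-out) scores the raw
    sample window mean.
    """
    if input_tracks is not None and len(input_tracks) != len(sample_tracks):
        raise ValueError("need one input track per sample track (or None)")
    data = {}
    for k, track in enumerate(sample_tracks):
        inp = input_tracks[k] if input_tracks is not None else None
        col = []
        for _, window in regions:
            s = window_mean(track, window)
            if inp is None:
                col.append(s)
            elif assay == "chip":
                col.append((s + EPSILON) / (window_mean(inp, window) + EPSILON))
            elif assay in ("faire", "h3k27ac"):
                col.append(max(s - window_mean(inp, window), 0.0))
            else:
                raise ValueError(f"unknown assay {assay!r}")
        data[track.sample_id] = col
    return pd.DataFrame(data, index=pd.Index([r for r, _ in regions], name="region_id"))


def paired_log_fc(scores_a: np.ndarray, scores_b: np.ndarray):
    """Row-wise log2(mean_a/mean_b) and paired-t p across replicate pairs."""
    la = np.log2(scores_a + LOG_FLOOR)
    lb = np.log2(scores_b + LOG_FLOOR)
    d = la - lb
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    p = np.where(sd_d > 0, 2 * stats.t.sf(np.abs(np.where(sd_d > 0, t, 0)), n - 1), np.where(mean_d == 0, 1.0, 0.0))
    log2fc = np.log2(scores_a.mean(axis=1) + LOG_FLOOR) - np.log2(
        scores_b.mean(axis=1) + LOG_FLOOR
    )
    return log2fc, p


def differential_call(
    scores_by_condition: dict[str, pd.DataFrame],
    peak_presence: dict[str, np.ndarray] | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    control: str = "NHS",
    treatment: str = "HS",
) -> pd.DataFrame:
    """Per-region WindowStat table with down/up/flat/absent/acquired calls.

    log2fc is control over treatment, so binding LOST upon treatment gives
    log2fc >= +lfc_threshold and the call ``down``.  Replicates pair by
    column index; unequal replicate counts are an error.  ``peak_presence``
    maps condition -> boolean array (peak called over the region) and
    overrides the statistical call with absent/acquired.
    """
    a = scores_by_condition[control]
    b = scores_by_condition[treatment]
    if a.shape != b.shape or not a.index.equals(b.index):
        raise ValueError("conditions must share regions and replicate counts")
    if a.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition")
    log2fc, p = paired_log_fc(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    call = np.full(len(a), "flat", dtype=object)
    call[(log2fc >= lfc_threshold) & (p <= alpha)] = "down"
    call[(log2fc <= -lfc_threshold) & (p <= alpha)] = "up"
    if peak_presence is not None:
        present_ctl = np.asarray(peak_presence[control], dtype=bool)
        present_trt = np.asarray(peak_presence[treatment], dtype=bool)
        call[~present_ctl & ~present_trt] = "absent"
        call[~present_ctl & present_trt] = "acquired"
    out = pd.DataFrame(
        {"region_id": a.index, "log2fc": log2fc, "p": p, "call": call}
    ).reset_index(drop=True)
    for cond, df in scores_by_condition.items():
        for k, col in enumerate(df.columns, start=1):
            out[f"score_{cond}_r{k}"] = df[col].to_numpy()
    return out


def peak_presence_for_windows(
    regions: list[tuple[str, Interval]], peaks_by_condition: dict[str, list[Peak]]
) -> dict[str, np.ndarray]:
    """Boolean per-region peak presence per condition (>=1 bp overlap)."""
    windows = [w for _, w in regions]
    out = {}
    for cond, peaks in peaks_by_condition.items():
        hits = overlap_matrix(windows, [p.interval for p in peaks])
        out[cond] = np.array([bool(h) for h in hits])
    return out


def state_chart(window_stats: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Contingency table of call x group; row sums equal group sizes."""
    g = groups.reindex(window_stats.region_id).to_numpy()
    table = pd.crosstab(pd.Series(g, name="group"), window_stats.call.to_numpy())
    for c in CALLS:
        if c not in table.columns:
            table[c] = 0
    return table[list(CALLS)]


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percent, ties rounded up (27/135 -> 20, 105/258 -> 41)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def fraction_reduced(window_stats: pd.DataFrame, groups: pd.Series, group: str):
    """(count_down, total, percent) for one group of regions."""
    g = groups.reindex(window_stats.region_id).to_numpy()
    sel = window_stats[g == group]
    if len(sel) == 0:
        raise ValueError(f"group {group!r} is empty")
    count = int((sel.call == "down").sum())
    return count, len(sel), round_half_up_percent(count, len(sel))
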