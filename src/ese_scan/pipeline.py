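"""End-to-end orchestration: counts + peaks + tracks -> classified targets,
responsive TSSs, ESEs, window statistics, state charts and profile FCs.

The stages mirror the analysis flow of a hormone-depletion experiment:

1. gene-level differential transcription (treatment HS over control NHS;
   genes down upon depletion are hormone-activated);
2. primary-target classification by receptor-peak overlap (locus +/-5 kb);
3. responsive-TSS calling from 500 bp downstream windows (raw p);
4. ESE calling in activated primary loci, proximal/distal and
   active/poised classification;
5. per-ESE differential binding/accessibility/acetylation calls and state
   charts, plus reduced-fraction summaries per ESE group;
6. metaprofile window fold-changes per group.

``run_all`` reads every input from disk (the formats the synthetic
generator writes) and writes TSV outputs plus a manifest; ``analyze`` is
the in-memory core the tests and the acceptance script drive directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, ese_caller, target_classifier
from .diffbind_windows import (
    differential_call,
    fraction_reduced,
    peak_presence_for_windows,
    score_windows,
    state_chart,
)
from .genomic_core import (
    Interval,
    Peak,
    centered_window,
    downstream_window,
    read_bed,
    read_bedgraph,
    read_gff_genes,
    write_bed,
)
from .profiles import build_profile, window_fc_test

log = logging.getLogger(__name__)

ASSAY_KIND = {"ecr": "chip", "cbp": "chip", "rpb3": "chip", "tbp": "chip", "faire": "faire", "h3k27ac": "h3k27ac"}


@dataclass
class Params:
    """Threshold surface; defaults are the study's printed values."""

    lfc_gene: float = 1.5
    lfc_binding: float = 1.0
    alpha: float = 0.05
    pad_bp: int = 5000
    tss_window: int = 500
    proximal_half: int = 250
    summit_half: int = 250  # 500 bp windows around summits (chip, FAIRE)
    ac_half: int = 500  # 1000 bp windows for H3K27Ac

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    annotation: str
    counts_genes: str
    counts_tss: str
    design: str
    peaks_dir: str
    tracks_dir: str
    out_dir: str
    tissue: str = "SG"
    contrast: tuple[str, str] = ("HS", "NHS")
    seed: int = 0
    params: Params = field(default_factory=Params)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = Params(**raw.pop("params", {}))
        raw["contrast"] = tuple(raw.get("contrast", ("HS", "NHS")))
        return cls(params=params, **raw)

    def validate(self):
        missing = [
            p
            for p in (self.annotation, self.counts_genes, self.counts_tss, self.design, self.peaks_dir, self.tracks_dir)
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


@dataclass
class ResultBundle:
    de_genes: pd.DataFrame
    targets: pd.DataFrame
    responsive_tss: pd.DataFrame
    eses: pd.DataFrame
    window_stats: dict
    state_charts: dict
    fractions: pd.DataFrame
    profile_fcs: pd.DataFrame
    summary: dict


def _targets_frame(targets) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in targets],
            "direction": [t.direction for t in targets],
            "primary": [t.primary for t in targets],
            "n_ecr_peaks": [len(t.ecr_peak_ids) for t in targets],
        }
    )


def _ese_frame(eses) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ese_id": [e.ese_id for e in eses],
            "chrom": [e.interval.chrom for e in eses],
            "start": [e.interval.start for e in eses],
            "end": [e.interval.end for e in eses],
            "summit": [e.summit for e in eses],
            "locus_ids": [",".join(e.locus_ids) for e in eses],
            "location_class": [e.location_class for e in eses],
            "activity_class": [e.activity_class for e in eses],
            "h3k27ac_level": [e.h3k27ac_level for e in eses],
        }
    )


def analyze(
    annotation,
    gene_counts: pd.DataFrame,
    tss_counts: pd.DataFrame,
    design: pd.DataFrame,
    peaks: dict,
    tracks: dict,
    params: Params | None = None,
    tissue: str = "SG",
    contrast: tuple[str, str] = ("HS", "NHS"),
    reps: int | None = None,
) -> ResultBundle:
    """Run stages 1-6 on in-memory inputs.

    ``peaks``: (factor, condition) -> list[Peak]; ``tracks``: (factor,
    condition, rep) -> CoverageTrack, factors ecr/cbp/rpb3/tbp/input/faire/
    h3k27ac.
    """
    P = params or Params()
    treatment, control = contrast
    reps = reps or max(r for (_, _, r) in tracks)

    def track_set(factor, cond):
        return [tracks[(factor, cond, r)] for r in range(1, reps + 1)]

    # 1. differential transcription -------------------------------------
    de = diffexpr.test_differential(
        gene_counts, design, contrast, tissue=tissue, lfc_threshold=P.lfc_gene, alpha=P.alpha
    )
    log.info("stage diffexpr: %d genes, %d down, %d up", len(de), (de.call == "down").sum(), (de.call == "up").sum())

    # 2. primary targets -------------------------------------------------
    targets = target_classifier.call_primary_targets(
        de, annotation, peaks[("ecr", control)], pad_bp=P.pad_bp
    )
    tframe = _targets_frame(targets)

    # 3. responsive TSSs -------------------------------------------------
    rtss = target_classifier.call_responsive_tss(
        tss_counts, design, "activated", tissue=tissue, contrast=contrast,
        width=P.tss_window, fc_threshold=P.lfc_gene, alpha=P.alpha,
    )
    rtss_frame = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in rtss],
            "chrom": [t.window.chrom for t in rtss],
            "tss": [t.tss for t in rtss],
            "strand": [t.strand for t in rtss],
            "log2fc": [t.log2fc for t in rtss],
            "p": [t.p for t in rtss],
        }
    )
    log.info("stage tss: %d responsive TSSs", len(rtss_frame))

    # 4. ESEs -------------------------------------------------------------
    primary_activated = set(
        tframe.loc[(tframe.direction == "activated") & tframe.primary, "gene_id"]
    )
    models = {g.gene_id: g for g in annotation}
    loci = [models[g] for g in sorted(primary_activated)]
    eses = ese_caller.call_eses(
        peaks[("ecr", control)], peaks[("cbp", control)], loci, pad_bp=P.pad_bp
    )
    eses = ese_caller.classify_location(eses, loci, proximal_half=P.proximal_half)
    if len(eses) >= 2:
        eses = ese_caller.classify_activity(
            eses, track_set("h3k27ac", control), track_set("input", control), window_half=P.ac_half
        )
    eframe = _ese_frame(eses)
    log.info("stage eses: %d ESEs (%d active)", len(eframe), (eframe.activity_class == "active").sum())

    # 5. differential windows + charts ------------------------------------
    groups = pd.Series(
        (eframe.location_class + "-" + eframe.activity_class).to_numpy(),
        index=eframe.ese_id,
    )
    window_stats, charts, fraction_rows = {}, {}, []
    for factor in ("ecr", "cbp", "faire", "h3k27ac"):
        half = P.ac_half if factor == "h3k27ac" else P.summit_half
        regions = [
            (e.ese_id, centered_window(e.interval.chrom, e.summit, half)) for e in eses
        ]
        if not regions:
            continue
        kind = ASSAY_KIND[factor]
        scores = {
            cond: score_windows(regions, track_set(factor, cond), track_set("input", cond), kind)
            for cond in (control, treatment)
        }
        presence = None
        if (factor, control) in peaks:
            presence = peak_presence_for_windows(
                regions, {c: peaks[(factor, c)] for c in (control, treatment)}
            )
        stats_ = differential_call(
            scores, presence, lfc_threshold=P.lfc_binding, alpha=P.alpha,
            control=control, treatment=treatment,
        )
        window_stats[factor] = stats_
        charts[factor] = state_chart(stats_, groups)
        for grp in sorted(groups.unique()):
            count, total, pct = fraction_reduced(stats_, groups, grp)
            fraction_rows.append(
                {"assay": factor, "group": grp, "reduced": count, "total": total, "percent": pct}
            )
    fractions = pd.DataFrame(fraction_rows)

    # 6. profile window FCs ------------------------------------------------
    fc_rows = []
    for factor in ("ecr", "cbp", "faire", "h3k27ac"):
        half = P.ac_half if factor == "h3k27ac" else P.summit_half
        kind = ASSAY_KIND[factor]
        for grp in sorted(groups.unique()):
            ids = set(groups[groups == grp].index)
            anchors = [
                (e.ese_id, e.interval.chrom, e.summit, "+") for e in eses if e.ese_id in ids
            ]
            if len(anchors) < 2:
                continue
            prof = {
                cond: build_profile(
                    track_set(factor, cond), track_set("input", cond), anchors, kind
                )
                for cond in (control, treatment)
            }
            fc, p, _ = window_fc_test(prof[control], prof[treatment], window_half=half)
            fc_rows.append({"assay": factor, "group": grp, "fc": fc, "p": p, "n": len(anchors)})
    profile_fcs = pd.DataFrame(fc_rows)

    summary = summarize(tframe, rtss_frame, eframe, fractions)
    return ResultBundle(de, tframe, rtss_frame, eframe, window_stats, charts, fractions, profile_fcs, summary)


def summarize(tframe, rtss_frame, eframe, fractions) -> dict:
    """Count summary: targets by direction, primary counts, ESE partition."""
    s = {
        "n_activated": int((tframe.direction == "activated").sum()),
        "n_suppressed": int((tframe.direction == "suppressed").sum()),
        "n_primary_activated": int(((tframe.direction == "activated") & tframe.primary).sum()),
        "n_primary_suppressed": int(((tframe.direction == "suppressed") & tframe.primary).sum()),
        "n_responsive_tss": int(len(rtss_frame)),
        "n_eses": int(len(eframe)),
    }
    for loc in ("proximal", "distal"):
        for act in ("active", "poised"):
            s[f"n_{loc}_{act}"] = int(
                ((eframe.location_class == loc) & (eframe.activity_class == act)).sum()
            )
    s["n_active"] = s["n_proximal_active"] + s["n_distal_active"]
    s["n_poised"] = s["n_proximal_poised"] + s["n_distal_poised"]
    return s


def summary_report(bundle: ResultBundle) -> str:
    """Markdown report of counts per class, reduced fractions and FCs."""
    lines = ["# Run summary", "", "## Counts", ""]
    for k, v in bundle.summary.items():
        lines.append(f"- {k}: {v}")
    if len(bundle.fractions):
        lines += ["", "## Reduced fraction per ESE group", ""]
        lines.append(bundle.fractions.to_markdown(index=False))
    if len(bundle.profile_fcs):
        lines += ["", "## Window fold-changes (control over treatment)", ""]
        lines.append(
            bundle.profile_fcs.assign(
                fc=lambda d: d.fc.round(3), p=lambda d: d.p.map(lambda x: f"{x:.3g}")
            ).to_markdown(index=False)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# File-based entry point
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: RunConfig):
    annotation = read_gff_genes(config.annotation)
    gene_counts = pd.read_csv(config.counts_genes, sep="\t", index_col=0)
    tss_counts = pd.read_csv(config.counts_tss, sep="\t", index_col=0)
    design = pd.read_csv(config.design, sep="\t")
    peaks = {}
    for bed in sorted(Path(config.peaks_dir).glob("*.bed")):
        factor, cond = bed.stem.rsplit("_", 1)
        peaks[(factor, cond)] = read_bed(bed)
    tracks = {}
    for bg in sorted(Path(config.tracks_dir).glob("*.bedgraph")):
        factor, cond, rep = bg.stem.rsplit("_", 2)
        tracks[(factor, cond, int(rep.lstrip("r")))] = read_bedgraph(
            bg, sample_id=bg.stem, assay=ASSAY_KIND.get(factor, factor)
        )
    return annotation, gene_counts, tss_counts, design, peaks, tracks


def run_all(config: RunConfig) -> ResultBundle:
    """Validate, load, analyze, write outputs + manifest. Deterministic."""
    config.validate()
    annotation, gene_counts, tss_counts, design, peaks, tracks = load_inputs(config)
    bundle = analyze(
        annotation, gene_counts, tss_counts, design, peaks, tracks,
        params=config.params, tissue=config.tissue, contrast=config.contrast,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.de_genes.to_csv(out / "de_genes.tsv", sep="\t", index=False)
    bundle.targets.to_csv(out / "targets.tsv", sep="\t", index=False)
    bundle.responsive_tss.to_csv(out / "responsive_tss.tsv", sep="\t", index=False)
    _write_tss_bed(bundle.responsive_tss, out / "responsive_tss.bed", config.params.tss_window)
    bundle.eses.to_csv(out / "eses.tsv", sep="\t", index=False)
    _write_ese_bed(bundle.eses, out / "eses.bed")
    for factor, stats_ in sorted(bundle.window_stats.items()):
        stats_.to_csv(out / f"window_stats_{factor}.tsv", sep="\t", index=False)
    for factor, chart in sorted(bundle.state_charts.items()):
        chart.to_csv(out / f"state_chart_{factor}.tsv", sep="\t")
    bundle.fractions.to_csv(out / "fractions.tsv", sep="\t", index=False)
    bundle.profile_fcs.to_csv(out / "profile_fcs.tsv", sep="\t", index=False)
    (out / "summary.md").write_text(summary_report(bundle))
    manifest = {
        "config": {**{k: str(v) for k, v in asdict(config).items() if k != "params"},
                   "params": asdict(config.params)},
        "input_hashes": {
            name: _sha256(getattr(config, name))
            for name in ("annotation", "counts_genes", "counts_tss", "design")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return bundle


def _write_tss_bed(frame: pd.DataFrame, path, width: int):
    peaks = []
    for r in frame.itertuples():
        w = downstream_window(r.chrom, r.tss, r.strand, width)
        peaks.append(Peak(w, f"{r.gene_id}_tss"))
    write_bed(peaks, path)


def _write_ese_bed(frame: pd.DataFrame, path):
    peaks = []
    for r in frame.itertuples():
        name = f"{r.ese_id}|{r.location_class}|{r.activity_class}"
        iv = Interval(r.chrom, int(r.start), int(r.end))
        peaks.append(Peak(iv, name, int(r.summit) - int(r.start)))
    write_bed(peaks, path)
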