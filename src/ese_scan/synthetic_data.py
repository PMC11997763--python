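"""Ground-truth-labeled synthetic hormone-depletion experiment.

Emulates the structure of a salivary-gland (SG) / brain (BR) steroid-
depletion study: two tissues x two conditions (NHS control, HS = hormone-
depleted) x 2 replicates, with

* planted hormone-activated and hormone-suppressed genes (negative-binomial
  RNA counts, log-normal baselines, tissue-biased means),
* receptor (EcR) / coactivator (CBP) co-bound elements (ESEs) planted in
  activated loci (~3 per locus, ~24% proximal to a TSS),
* bimodal H3K27Ac across ESEs (an "active" fraction with order-of-magnitude
  higher acetylation),
* condition-dependent collapse of active elements: under HS the local
  chip/FAIRE/H3K27Ac coverage at active ESEs is multiplied by
  ``signal_drop_hs`` (poised ESEs lose accessibility only), and Pol II
  (Rpb3) / TBP signal drops at activated TSSs.

Coverage tracks are Gaussian bumps (sd 150 bp) on a flat background of 1.0
with i.i.d. multiplicative log-normal bin noise; input tracks are
background-only.  Tracks are simulated for the salivary-gland arm, where
all binding/accessibility contrasts are evaluated; the brain arm lives in
the count matrices as a tissue-bias structure.

Everything is deterministic under ``SimConfig.seed``; each artifact
(annotation, labels, counts, peaks+tracks) draws from its own child RNG
stream so one output can be regenerated without disturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import (
    CoverageTrack,
    GeneModel,
    Interval,
    Peak,
    write_bed,
    write_bedgraph,
    write_gff_genes,
)

TISSUES = ("SG", "BR")
CONDITIONS = ("NHS", "HS")
CHIP_FACTORS = ("ecr", "cbp", "rpb3", "tbp")
TRACK_FACTORS = CHIP_FACTORS + ("input", "faire", "h3k27ac")

_BUMP_SD = 150.0  # bp, Gaussian bump width on all tracks
_HS_REGION_HALF = 1250  # bp around a summit over which the HS multiplier acts
_GAUSS_WINDOW_FRACTION = 0.376  # mean of a sd-150 Gaussian over +/-500 bp


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    seed: int = 0
    n_genes: int = 500
    n_activated: int = 60
    n_suppressed: int = 50
    reps: int = 2
    genome: tuple = (("chr2L", 6_000_000), ("chr2R", 6_000_000))
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.5
    active_ese_fraction: float = 0.4  # mirrors the 322/826 active share
    eses_per_locus_mean: float = 3.0
    proximal_fraction: float = 0.24  # mirrors (64+135)/826
    signal_drop_hs: float = 0.5
    bin_bp: int = 10
    two_tss_fraction: float = 0.2
    track_noise_sd: float = 0.2
    baseline_mean: float = 200.0  # log-normal baseline expression, counts
    baseline_sigma: float = 1.0

    def __post_init__(self):
        if self.n_activated + self.n_suppressed > self.n_genes:
            raise ValueError("n_activated + n_suppressed must be <= n_genes")
        for name in ("active_ese_fraction", "proximal_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if min(self.n_genes, self.reps, self.bin_bp) < 0 or self.reps < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted labels: per-gene direction, per-ESE classes, per-peak effects."""

    gene_labels: pd.DataFrame  # gene_id, label in {activated, suppressed, null}
    eses: pd.DataFrame | None = None  # filled by simulate_peaks_and_tracks
    peak_effects: pd.DataFrame | None = None


@dataclass
class SimResult:
    config: SimConfig
    annotation: list
    truth: GroundTruth
    gene_counts: pd.DataFrame
    tss_counts: pd.DataFrame
    design: pd.DataFrame
    peaks: dict  # (factor, condition) -> list[Peak]
    tracks: dict  # (factor, condition, rep) -> CoverageTrack


_STREAMS = {"annotation": 0, "labels": 1, "counts": 2, "peaks": 3}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping 2-10 kb loci with >=12 kb gaps, ~50/50 strands."""
    rng = _rng(config, "annotation")
    # mean locus 6 kb + 12 kb fixed gap + ~2 kb jitter per placed gene
    required = config.n_genes * 20_000 + 12_000 * len(config.genome)
    total = sum(length for _, length in config.genome)
    if config.n_genes > 0 and total < required:
        raise ValueError(
            f"genome too small for {config.n_genes} loci: have {total} bp, "
            f"need about {required} bp"
        )
    genes: list[GeneModel] = []
    margin = 6_000  # keeps locus +/-5 kb flanks and bump tails on-chromosome
    for chrom, chrom_len in config.genome:
        pos = margin
        while len(genes) < config.n_genes:
            length = int(rng.integers(2_000, 10_001))
            if pos + length + margin > chrom_len:
                break
            start, end = pos, pos + length
            strand = "+" if rng.random() < 0.5 else "-"
            main_tss = start if strand == "+" else end - 1
            tss = [main_tss]
            if rng.random() < config.two_tss_fraction:
                offset = int(rng.integers(300, max(301, length // 2)))
                tss.append(start + offset if strand == "+" else end - 1 - offset)
            gene_id = f"g{len(genes) + 1:04d}"
            genes.append(
                GeneModel(gene_id, Interval(chrom, start, end, strand), tuple(sorted(tss)))
            )
            pos = end + 12_000 + int(rng.integers(0, 4_001))
        if len(genes) >= config.n_genes:
            break
    if len(genes) < config.n_genes:
        raise ValueError(
            f"genome too small: placed {len(genes)} of {config.n_genes} loci"
        )
    return genes


def assign_gene_labels(config: SimConfig, annotation: list[GeneModel]) -> GroundTruth:
    """Randomly partition genes into activated / suppressed / null."""
    rng = _rng(config, "labels")
    ids = [g.gene_id for g in annotation]
    perm = rng.permutation(len(ids))
    labels = np.full(len(ids), "null", dtype=object)
    labels[perm[: config.n_activated]] = "activated"
    labels[perm[config.n_activated : config.n_activated + config.n_suppressed]] = (
        "suppressed"
    )
    return GroundTruth(pd.DataFrame({"gene_id": ids, "label": labels}))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (Poisson limit at 0)."""
    mu = np.maximum(mu, 1e-8)
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def design_table(config: SimConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{tissue}_{cond}_r{rep}",
            "tissue": tissue,
            "condition": cond,
            "replicate": rep,
        }
        for tissue in TISSUES
        for cond in CONDITIONS
        for rep in range(1, config.reps + 1)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimConfig, annotation: list[GeneModel], truth: GroundTruth
):
    """Gene-level and TSS-window NB count matrices plus the design table.

    Activated genes: mean x 2^de_log2fc in SG/NHS over SG/HS (depletion
    reduces them) and low in brain; suppressed genes the reverse.  TSS-window
    counts are proportional to gene counts (split 0.7/0.3 over dual TSSs).
    """
    rng = _rng(config, "counts")
    design = design_table(config)
    labels = truth.gene_labels.set_index("gene_id")["label"]
    n = len(annotation)
    baseline = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, n)
    depth = rng.lognormal(0.0, 0.15, len(design))
    fc = 2.0 ** config.de_log2fc

    mu = np.empty((n, len(design)))
    for j, row in design.iterrows():
        col = baseline.copy()
        act = (labels.values == "activated")
        sup = (labels.values == "suppressed")
        if row.tissue == "SG":
            if row.condition == "NHS":
                col[act] *= fc
            else:
                col[sup] *= fc
        else:  # brain: activated genes low, suppressed genes elevated
            col[act] *= 0.5
            col[sup] *= 2.0
        mu[:, j] = col * depth[j]

    gene_ids = [g.gene_id for g in annotation]
    gene_counts = pd.DataFrame(
        _nb_sample(rng, mu, config.nb_dispersion),
        index=pd.Index(gene_ids, name="feature_id"),
        columns=design.sample_id.tolist(),
    )

    tss_rows, tss_mu = [], []
    for i, g in enumerate(annotation):
        shares = [1.0] if len(g.tss_list) == 1 else [0.7, 0.3]
        order = g.tss_list if g.strand == "+" else tuple(reversed(g.tss_list))
        for tss, share in zip(order, shares):
            tss_rows.append(f"{g.gene_id}@{g.locus.chrom}:{tss}:{g.strand}")
            tss_mu.append(0.25 * share * mu[i])
    tss_counts = pd.DataFrame(
        _nb_sample(rng, np.array(tss_mu), config.nb_dispersion),
        index=pd.Index(tss_rows, name="feature_id"),
        columns=design.sample_id.tolist(),
    )
    return gene_counts, tss_counts, design


# ---------------------------------------------------------------------------
# Peaks and coverage tracks
# ---------------------------------------------------------------------------


def _place_eses(config, annotation, truth, rng) -> pd.DataFrame:
    """Plant co-bound elements in activated loci: ~Poisson(mean) per locus
    (min 1), proximal with probability ``proximal_fraction``, >=1.2 kb apart."""
    activated = set(
        truth.gene_labels.loc[truth.gene_labels.label == "activated", "gene_id"]
    )
    chrom_len = dict(config.genome)
    rows = []
    for g in annotation:
        if g.gene_id not in activated:
            continue
        n_e = int(min(6, max(1, rng.poisson(config.eses_per_locus_mean))))
        placed: list[int] = []
        lo = max(2_000, g.locus.start - 4_500)
        hi = min(chrom_len[g.locus.chrom] - 2_000, g.locus.end + 4_500)
        for _ in range(n_e):
            for _attempt in range(200):
                if rng.random() < config.proximal_fraction:
                    tss = int(rng.choice(g.tss_list))
                    s = tss + int(rng.integers(-250, 251))
                else:
                    s = int(rng.integers(lo, hi))
                    if any(abs(s - t) <= 400 for t in g.tss_list):
                        continue
                if all(abs(s - p) >= 1_200 for p in placed):
                    break
            else:
                continue
            placed.append(s)
            proximal = any(abs(s - t) <= 250 for t in g.tss_list)
            active = rng.random() < config.active_ese_fraction
            rows.append(
                {
                    "ese_id": f"ese{len(rows) + 1:04d}",
                    "chrom": g.locus.chrom,
                    "summit": s,
                    "locus_id": g.gene_id,
                    "location_class": "proximal" if proximal else "distal",
                    "activity_class": "active" if active else "poised",
                }
            )
    return pd.DataFrame(rows)


def _add_bump(arr: np.ndarray, bin_bp: int, center: int, amp: float, sd: float = _BUMP_SD):
    half = int(4 * sd)
    lo = max((center - half) // bin_bp, 0)
    hi = min((center + half) // bin_bp + 1, len(arr))
    if lo >= hi:
        return
    x = (np.arange(lo, hi) + 0.5) * bin_bp - center
    arr[lo:hi] += amp * np.exp(-(x * x) / (2 * sd * sd))


def _apply_drop(arr: np.ndarray, bin_bp: int, center: int, mult: float):
    lo = max((center - _HS_REGION_HALF) // bin_bp, 0)
    hi = min((center + _HS_REGION_HALF) // bin_bp + 1, len(arr))
    arr[lo:hi] *= mult


def simulate_peaks_and_tracks(
    config: SimConfig, annotation: list[GeneModel], truth: GroundTruth
):
    """Peak sets (EcR/CBP/Rpb3/TBP, per condition) and per-sample tracks.

    Fills ``truth.eses`` and ``truth.peak_effects``.  Under HS the local
    coverage around affected summits is multiplied by ``signal_drop_hs``:
    active ESEs on chip/FAIRE/H3K27Ac, poised ESEs on FAIRE only, and
    hormone-activated TSSs on Rpb3/TBP.
    """
    rng = _rng(config, "peaks")
    eses = _place_eses(config, annotation, truth, rng)
    truth.eses = eses
    chrom_len = dict(config.genome)
    labels = truth.gene_labels.set_index("gene_id")["label"]

    # (factor, chrom, summit, amp, hs_mult)
    bumps: list[tuple[str, str, int, float, float]] = []
    peaks: dict[tuple[str, str], list[Peak]] = {
        (f, c): [] for f in CHIP_FACTORS for c in CONDITIONS
    }

    def add_peak(factor, chrom, start, end, summit, name):
        for cond in CONDITIONS:
            peaks[(factor, cond)].append(
                Peak(Interval(chrom, start, end), name, summit - start)
            )

    drop = config.signal_drop_hs
    for r in eses.itertuples():
        s = r.summit
        shift = int(rng.integers(-40, 41))
        add_peak("ecr", r.chrom, s - 75, s + 75, s, f"EcR_{r.ese_id}")
        add_peak("cbp", r.chrom, s + shift - 110, s + shift + 110, s + shift, f"CBP_{r.ese_id}")
        ecr_amp = 8.0 * rng.lognormal(0, 0.3)
        cbp_amp = 8.0 * rng.lognormal(0, 0.3)
        k27_amp = (12.0 if r.activity_class == "active" else 1.2) * rng.lognormal(0, 0.35)
        faire_amp = 4.0 * rng.lognormal(0, 0.3)
        if r.activity_class == "active":
            mults = {"ecr": drop, "cbp": drop, "faire": drop, "h3k27ac": drop}
        else:
            mults = {"ecr": 1.0, "cbp": 1.0, "faire": drop, "h3k27ac": 1.0}
        bumps.append(("ecr", r.chrom, s, ecr_amp, mults["ecr"]))
        bumps.append(("cbp", r.chrom, s + shift, cbp_amp, mults["cbp"]))
        bumps.append(("faire", r.chrom, s, faire_amp, mults["faire"]))
        bumps.append(("h3k27ac", r.chrom, s, k27_amp, mults["h3k27ac"]))

    # decoy single-factor peaks, kept clear of planted elements
    planted = {c: eses.loc[eses.chrom == c, "summit"].to_numpy() for c in chrom_len}
    def clear_of_planted(chrom, s):
        arr = planted.get(chrom)
        return arr is None or len(arr) == 0 or np.min(np.abs(arr - s)) > 1_500

    decoys: dict[str, list[int]] = {"ecr": [], "cbp": []}
    for factor in ("ecr", "cbp"):
        target = config.n_genes // 2
        guard = 0
        while len(decoys[factor]) < target and guard < 50 * target:
            guard += 1
            chrom = config.genome[int(rng.integers(len(config.genome)))][0]
            s = int(rng.integers(2_000, chrom_len[chrom] - 2_000))
            others = decoys["cbp" if factor == "ecr" else "ecr"]
            if not clear_of_planted(chrom, s):
                continue
            if any(abs(s - o) < 1_000 for o in others[-200:]):
                continue
            decoys[factor].append(s)
            name = f"{factor}_decoy{len(decoys[factor]):04d}"
            add_peak(factor, chrom, s - 75, s + 75, s, name)
            bumps.append((factor, chrom, s, 6.0 * rng.lognormal(0, 0.3), 1.0))

    # promoter machinery: Rpb3 at activated + 60% of null TSSs, TBP at 60%
    for g in annotation:
        lab = labels[g.gene_id]
        expressed = lab == "activated" or (lab == "null" and rng.random() < 0.6)
        if not expressed:
            continue
        tss = g.tss_list[0] if g.strand == "+" else g.tss_list[-1]
        mult = drop if lab == "activated" else 1.0
        add_peak("rpb3", g.locus.chrom, tss - 150, tss + 150, tss, f"Rpb3_{g.gene_id}")
        bumps.append(("rpb3", g.locus.chrom, tss, 6.0 * rng.lognormal(0, 0.3), mult))
        bumps.append(("faire", g.locus.chrom, tss, 3.0 * rng.lognormal(0, 0.3), mult))
        if rng.random() < 0.6:
            add_peak("tbp", g.locus.chrom, tss - 100, tss + 100, tss, f"TBP_{g.gene_id}")
            bumps.append(("tbp", g.locus.chrom, tss, 4.0 * rng.lognormal(0, 0.3), mult))

    truth.peak_effects = pd.DataFrame(
        bumps, columns=["factor", "chrom", "summit", "amplitude", "hs_multiplier"]
    )

    # --- rasterise tracks ---------------------------------------------------
    bw = config.bin_bp
    n_bins = {c: -(-length // bw) for c, length in config.genome}
    tracks: dict[tuple[str, str, int], CoverageTrack] = {}
    noise_mu = -(config.track_noise_sd ** 2) / 2  # E[noise] = 1
    by_factor: dict[str, list] = {f: [] for f in TRACK_FACTORS}
    for b in bumps:
        by_factor[b[0]].append(b)

    for factor in TRACK_FACTORS:
        base = {c: np.ones(n, dtype=float) for c, n in n_bins.items()}
        for _, chrom, s, amp, _m in by_factor[factor]:
            _add_bump(base[chrom], bw, s, amp)
        hs = {c: a.copy() for c, a in base.items()}
        for _, chrom, s, _amp, mult in by_factor[factor]:
            if mult != 1.0:
                _apply_drop(hs[chrom], bw, s, mult)
        assay = "chip" if factor in CHIP_FACTORS else factor
        for cond, signal in (("NHS", base), ("HS", hs)):
            for rep in range(1, config.reps + 1):
                bins = {}
                for chrom, arr in signal.items():
                    noise = rng.lognormal(noise_mu, config.track_noise_sd, len(arr))
                    bins[chrom] = (arr * noise).astype(np.float32)
                tracks[(factor, cond, rep)] = CoverageTrack(
                    sample_id=f"{factor}_{cond}_r{rep}",
                    assay=assay,
                    bin_bp=bw,
                    bins=bins,
                )
    return peaks, tracks


def simulate_all(config: SimConfig) -> SimResult:
    """Run all generator stages under one seed."""
    annotation = simulate_annotation(config)
    truth = assign_gene_labels(config, annotation)
    gene_counts, tss_counts, design = simulate_counts(config, annotation, truth)
    peaks, tracks = simulate_peaks_and_tracks(config, annotation, truth)
    return SimResult(
        config, annotation, truth, gene_counts, tss_counts, design, peaks, tracks
    )


# ---------------------------------------------------------------------------
# Writers: the exact formats the pipeline reads
# ---------------------------------------------------------------------------


def write_simulation(sim: SimResult, outdir, include_tracks: bool = True) -> list[Path]:
    """Write GFF3 + BED + bedGraph + TSV artifacts; returns written paths."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    written: list[Path] = []

    def _w(path):
        written.append(path)
        return path

    write_gff_genes(sim.annotation, _w(out / "annotation.gff3"))
    sim.gene_counts.to_csv(_w(out / "counts_genes.tsv"), sep="\t")
    sim.tss_counts.to_csv(_w(out / "counts_tss.tsv"), sep="\t")
    sim.design.to_csv(_w(out / "design.tsv"), sep="\t", index=False)
    sim.truth.gene_labels.to_csv(_w(out / "truth_genes.tsv"), sep="\t", index=False)
    if sim.truth.eses is not None:
        sim.truth.eses.to_csv(_w(out / "truth_eses.tsv"), sep="\t", index=False)
    if sim.truth.peak_effects is not None:
        sim.truth.peak_effects.to_csv(
            _w(out / "truth_peak_effects.tsv"), sep="\t", index=False
        )
    for (factor, cond), plist in sorted(sim.peaks.items()):
        write_bed(plist, _w(out / "peaks" / f"{factor}_{cond}.bed"))
    if include_tracks:
        for (factor, cond, rep), track in sorted(sim.tracks.items()):
            write_bedgraph(
                track, _w(out / "tracks" / f"{factor}_{cond}_r{rep}.bedgraph")
            )
    return written
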