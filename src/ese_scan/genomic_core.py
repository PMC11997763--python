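"""Coordinate-safe interval arithmetic, strand-aware windows, and flat-file IO.

All coordinates are 0-based half-open internally.  GFF3/GTF (1-based closed)
is converted on read.  BED and bedGraph keep their native half-open
convention verbatim.  A single convention everywhere eliminates off-by-one
drift between the locus, TSS-window and summit-window arithmetic used
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class Interval:
    """Genomic region, 0-based half-open: [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "Interval") -> "Interval | None":
        if not self.overlaps(other):
            return None
        return Interval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def union(self, other: "Interval") -> "Interval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return Interval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


@dataclass(frozen=True)
class Peak:
    """Called peak: an interval with an optional summit (offset from start)."""

    interval: Interval
    name: str = ""
    summit: int | None = None  # offset from interval.start
    score: float | None = None

    def __post_init__(self):
        if self.summit is not None and not 0 <= self.summit < len(self.interval):
            raise ValueError(
                f"summit offset {self.summit} outside peak of length {len(self.interval)}"
            )

    @property
    def summit_pos(self) -> int:
        """Absolute summit position; interval midpoint (floor) when unset."""
        if self.summit is not None:
            return self.interval.start + self.summit
        return self.interval.start + len(self.interval) // 2


@dataclass(frozen=True)
class GeneModel:
    """Gene locus with one or more transcription start sites."""

    gene_id: str
    locus: Interval
    tss_list: tuple[int, ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.locus.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for tss in self.tss_list:
            if not self.locus.start <= tss < self.locus.end:
                raise ValueError(
                    f"gene {self.gene_id}: TSS {tss} outside locus "
                    f"[{self.locus.start}, {self.locus.end})"
                )

    @property
    def strand(self) -> str:
        return self.locus.strand


@dataclass
class CoverageTrack:
    """Binned per-base signal for one sample.

    ``bins`` maps chrom -> fixed-width bin values (value = mean per-base
    signal over the bin).  ``raw`` tracks are per-million scaled by
    :func:`window_mean` using ``library_size``.
    """

    sample_id: str
    assay: str  # chip | input | faire | h3k27ac | rna
    bin_bp: int = 10
    bins: dict[str, np.ndarray] = field(default_factory=dict)
    library_size: int | None = None
    raw: bool = False

    def chrom_length(self, chrom: str) -> int:
        return len(self.bins[chrom]) * self.bin_bp


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


def flank(interval: Interval, pad_bp: int) -> Interval:
    """Extend an interval by ``pad_bp`` on both sides, clamped at 0."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    return replace(interval, start=max(0, interval.start - pad_bp), end=interval.end + pad_bp)


def downstream_window(chrom: str, tss: int, strand: str, width_bp: int = 500) -> Interval:
    """Window of ``width_bp`` downstream of a TSS, strand-aware.

    Plus strand: [tss, tss+width); minus strand: [tss-width+1, tss+1).
    Clamped at position 0 (the window may shrink at a chromosome start).
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be > 0")
    if strand == "+":
        start, end = tss, tss + width_bp
    elif strand == "-":
        start, end = tss - width_bp + 1, tss + 1
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if start < 0:
        log.debug("downstream window clamped at chrom start (tss=%d)", tss)
        start = 0
    return Interval(chrom, start, end, strand)


def centered_window(chrom: str, center: int, half_width_bp: int) -> Interval:
    """Symmetric window [center-half, center+half) of total width 2*half."""
    if half_width_bp < 1:
        raise ValueError("half_width_bp must be >= 1")
    start = center - half_width_bp
    if start < 0:
        log.debug("centered window clamped at chrom start (center=%d)", center)
        start = 0
    return Interval(chrom, start, center + half_width_bp)


def overlaps(query: Interval, targets: list[Interval]) -> list[int]:
    """Indices of targets sharing >=1 bp with query (half-open semantics)."""
    return [
        i
        for i, t in enumerate(targets)
        if t.chrom == query.chrom and t.start < query.end and query.start < t.end
    ]


def overlap_matrix(queries: list[Interval], targets: list[Interval]) -> "list[list[int]]":
    """Per-query target indices; vectorised over targets per chromosome."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in targets}:
        idx = np.array([i for i, t in enumerate(targets) if t.chrom == chrom])
        starts = np.array([targets[i].start for i in idx])
        ends = np.array([targets[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)
    out = []
    for q in queries:
        if q.chrom not in by_chrom:
            out.append([])
            continue
        idx, starts, ends = by_chrom[q.chrom]
        hit = (starts < q.end) & (q.start < ends)
        out.append([int(i) for i in idx[hit]])
    return out


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def window_mean(track: CoverageTrack, interval: Interval) -> float:
    """Mean signal over a window, bins weighted by base-pair overlap.

    Equals the per-base mean of the bin-expanded track.  Raw tracks are
    per-million scaled by the track library size.
    """
    if interval.chrom not in track.bins:
        raise KeyError(f"chromosome {interval.chrom!r} not covered by track {track.sample_id}")
    values = track.bins[interval.chrom]
    bw = track.bin_bp
    start, end = interval.start, min(interval.end, len(values) * bw)
    if start >= end:
        raise ValueError("window lies outside covered region")
    first, last = start // bw, (end - 1) // bw
    sel = values[first : last + 1].astype(float)
    weights = np.full(sel.shape, float(bw))
    weights[0] -= start - first * bw
    weights[-1] -= (last + 1) * bw - end
    mean = float(np.sum(sel * weights) / np.sum(weights))
    if track.raw:
        if not track.library_size:
            raise ValueError("raw track requires a library_size for per-million scaling")
        mean *= 1e6 / track.library_size
    return mean


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> list[Peak]:
    """Read BED3+ peaks.

    Column 7 (when the file has exactly 7 columns) is an absolute summit
    position; narrowPeak files (10 columns) carry the summit as an offset in
    column 10 (-1 = unset).  Order and coordinates are preserved verbatim.
    """
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 else f"peak_{ln}"
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] in STRANDS else "."
            summit = None
            if len(cols) == 7 and cols[6] not in (".", ""):
                summit = int(cols[6]) - start  # absolute -> offset
            elif len(cols) >= 10 and cols[9] not in (".", "-1", ""):
                summit = int(cols[9])
            try:
                peaks.append(
                    Peak(Interval(cols[0], start, end, strand), name, summit, score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return peaks


def write_bed(peaks: list[Peak], path) -> None:
    """Write peaks as BED6, with an absolute-summit 7th column when set."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            score = "0" if p.score is None else f"{p.score:g}"
            cols = [iv.chrom, str(iv.start), str(iv.end), p.name, score, iv.strand]
            if p.summit is not None:
                cols.append(str(p.summit_pos))
            fh.write("\t".join(cols) + "\n")


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3/GTF via an in-memory gffutils database.

    Coordinates convert from 1-based closed to 0-based half-open.  TSSs come
    from transcript/mRNA children (locus start on +, locus end-1 position on
    -); duplicated TSSs collapse.  Genes without transcripts fall back to
    their own boundary TSS.  Transcripts without a parent gene are skipped
    (counted in a warning).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_types = ("mRNA", "transcript")
    orphans = 0
    for t in [f for tt in tx_types for f in db.features_of_type(tt)]:
        if not list(db.parents(t, featuretype="gene")):
            orphans += 1
    if orphans:
        log.warning("%d transcripts without a parent gene were skipped", orphans)

    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id} has no strand")
        locus = Interval(g.seqid, g.start - 1, g.end, g.strand)
        tss = set()
        for t in db.children(g, featuretype=tx_types):
            tss.add(t.start - 1 if g.strand == "+" else t.end - 1)
        if not tss:
            tss.add(locus.start if g.strand == "+" else locus.end - 1)
        biotype = g.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(GeneModel(g.id, locus, tuple(sorted(tss)), biotype))
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + one mRNA per TSS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.locus
            fh.write(
                f"{iv.chrom}\tese_scan\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for k, tss in enumerate(g.tss_list):
                if iv.strand == "+":
                    t_start, t_end = tss + 1, iv.end
                else:
                    t_start, t_end = iv.start + 1, tss + 1
                fh.write(
                    f"{iv.chrom}\tese_scan\tmRNA\t{t_start}\t{t_end}\t.\t"
                    f"{iv.strand}\t.\tID={g.gene_id}.t{k + 1};Parent={g.gene_id}\n"
                )


def read_bedgraph(path, bin_bp: int = 10, sample_id: str = "", assay: str = "chip") -> CoverageTrack:
    """Read a bedGraph into a fixed-width binned track.

    Records aligned to the bin grid map directly; unaligned records are
    distributed over bins by base-pair overlap.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            records.setdefault(cols[0], []).append(
                (int(cols[1]), int(cols[2]), float(cols[3]))
            )
    bins: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        n_bins = -(-max(e for _, e, _ in recs) // bin_bp)
        acc = np.zeros(n_bins)
        for s, e, v in recs:
            first, last = s // bin_bp, (e - 1) // bin_bp
            if first == last:
                acc[first] += v * (e - s)
            else:
                acc[first] += v * ((first + 1) * bin_bp - s)
                acc[first + 1 : last] += v * bin_bp
                acc[last] += v * (e - last * bin_bp)
        bins[chrom] = (acc / bin_bp).astype(np.float32)
    return CoverageTrack(sample_id or str(path), assay, bin_bp, bins)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a binned track as bedGraph, collapsing equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            values = track.bins[chrom]
            if len(values) == 0:
                continue
            breaks = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(values)]))
            bw = track.bin_bp
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{values[s]:.6g}\n")
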