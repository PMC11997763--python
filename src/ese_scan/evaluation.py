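"""Ground-truth evaluation of a pipeline run on synthetic data.

Recovery metrics (sensitivity/FDR of planted labels), null-calibration
rates of the two tests, and determinism checks.  These are the quantities
the package's own validation is judged on; they are computed from a
:class:`~ese_scan.synthetic_data.SimResult` and the analysis bundle, never
assumed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, synthetic_data as sd
from .diffbind_windows import differential_call, score_windows
from .genomic_core import centered_window


def match_eses(truth_eses: pd.DataFrame, called_eses: pd.DataFrame) -> pd.DataFrame:
    """Join called ESEs to planted truth on (chrom, summit)."""
    return called_eses.merge(
        truth_eses, on=["chrom", "summit"], suffixes=("_called", "_true")
    )


def recovery_metrics(sim: sd.SimResult, bundle) -> dict:
    """Sensitivity/FDR/agreement of every planted structure."""
    truth = sim.truth.gene_labels.set_index("gene_id").label
    planted = set(truth[truth == "activated"].index)
    called = set(
        bundle.de_genes.loc[bundle.de_genes.call == "down", "feature_id"]
    )
    out = {
        "de_sensitivity": len(called & planted) / len(planted),
        "de_fdr": len(called - planted) / max(len(called), 1),
    }
    tss_called = set(bundle.responsive_tss.gene_id)
    out["tss_sensitivity"] = len(tss_called & planted) / len(planted)

    m = match_eses(sim.truth.eses, bundle.eses)
    out["n_eses_matched"] = len(m)
    out["ese_activity_agreement"] = float(
        (m.activity_class_called == m.activity_class_true).mean()
    )
    out["ese_location_agreement"] = float(
        (m.location_class_called == m.location_class_true).mean()
    )

    ws = bundle.window_stats["h3k27ac"].set_index("region_id")
    active_ids = m.loc[m.activity_class_true == "active", "ese_id_called"]
    out["down_sensitivity_h3k27ac_active"] = float(
        (ws.loc[active_ids].call == "down").mean()
    )
    faire = bundle.window_stats["faire"].set_index("region_id")
    out["down_sensitivity_faire_all"] = float(
        (faire.loc[m.ese_id_called].call == "down").mean()
    )
    targets = bundle.targets
    act = targets[targets.direction == "activated"]
    out["primary_fraction_activated"] = float(act.primary.mean()) if len(act) else 0.0
    return out


def null_gene_p_rate(seed: int, n_runs: int = 100, n_genes: int = 150) -> tuple[float, int]:
    """Fraction of raw p <= 0.05 for the gene test over null simulations
    (no planted effect)."""
    base = sd.SimConfig(
        seed=seed, n_genes=n_genes, n_activated=1, n_suppressed=1, de_log2fc=0.0,
        genome=(("c1", 11_000 * n_genes), ("c2", 11_000 * n_genes)),
    )
    ann = sd.simulate_annotation(base)
    ps = []
    for run in range(n_runs):
        cfg = sd.SimConfig(
            seed=seed + 1_000 + run, n_genes=n_genes, n_activated=1,
            n_suppressed=1, de_log2fc=0.0, genome=base.genome,
        )
        truth = sd.assign_gene_labels(cfg, ann)
        counts, _, design = sd.simulate_counts(cfg, ann, truth)
        res = diffexpr.test_differential(counts, design, ("HS", "NHS"), tissue="SG")
        ps.append(res.p.to_numpy())
    ps = np.concatenate(ps)
    return float((ps <= 0.05).mean()), len(ps)


def null_window_p_rate(seed: int, n_runs: int = 100) -> tuple[float, int]:
    """Fraction of raw p <= 0.05 for the paired window test when the
    treatment leaves all tracks untouched (signal_drop_hs = 1)."""
    ps = []
    for run in range(n_runs):
        cfg = sd.SimConfig(
            seed=seed + 5_000 + run, n_genes=20, n_activated=12, n_suppressed=2,
            signal_drop_hs=1.0, genome=(("c", 500_000),),
        )
        ann = sd.simulate_annotation(cfg)
        truth = sd.assign_gene_labels(cfg, ann)
        _, tracks = sd.simulate_peaks_and_tracks(cfg, ann, truth)
        regions = [
            (r.ese_id, centered_window(r.chrom, r.summit, 500))
            for r in truth.eses.itertuples()
        ]
        scores = {
            cond: score_windows(
                regions,
                [tracks[("h3k27ac", cond, k)] for k in (1, 2)],
                [tracks[("input", cond, k)] for k in (1, 2)],
                "h3k27ac",
            )
            for cond in ("NHS", "HS")
        }
        ps.append(differential_call(scores).p.to_numpy())
    ps = np.concatenate(ps)
    return float((ps <= 0.05).mean()), len(ps)


def hash_directory(d) -> dict:
    d = Path(d)
    return {
        p.relative_to(d).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.rglob("*"))
        if p.is_file()
    }


def determinism_check(config: sd.SimConfig, workdir) -> bool:
    """Two generator runs from one seed write byte-identical artifacts."""
    workdir = Path(workdir)
    hashes = []
    for sub in ("run1", "run2"):
        sim = sd.simulate_all(config)
        sd.write_simulation(sim, workdir / sub)
        hashes.append(hash_directory(workdir / sub))
    return bool(hashes[0]) and hashes[0] == hashes[1]
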