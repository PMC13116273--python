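"""Full comparative pipeline: composition -> gene order -> tRNA -> codon usage.

``run_pipeline`` runs every analysis stage over a genome set and writes the
summary tables: a per-genome composition table (length, GC%, skews, gene
counts, skew regime), windowed skew profiles, gene orders with a pairwise
breakpoint-distance matrix and (given a tree and outgroup) the inferred
ancestral order plus per-genome rearranged segments, the tRNA presence
matrix and shared clusters, and the RSCU matrix with its PCA. Stages are
independent: a failure in one is recorded in the manifest without aborting
the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import composition, gene_order, trna_profile, codon_usage
from .genome_io import PCG, RRNA, TRNA

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.4f"  # single wide precision avoids TSV round-trip loss


@dataclass
class PipelineParams:
    window: int = composition.DEFAULT_WINDOW
    step: int = composition.DEFAULT_STEP
    regime_hi: float = composition.DEFAULT_HI
    regime_lo: float = composition.DEFAULT_LO
    order_classes: tuple = (PCG,)
    anchor: str = "COX1"
    strand_aware: bool = True
    ignore_cluster_strand: bool = False


@dataclass
class ReportBundle:
    composition: pd.DataFrame | None = None
    skew_profiles: pd.DataFrame | None = None
    regimes: dict = field(default_factory=dict)
    orders: dict = field(default_factory=dict)
    distance_matrix: dict = field(default_factory=dict)
    ancestral_order: list | None = None
    ancestral_fallback: bool | None = None
    rearranged: dict = field(default_factory=dict)
    presence: pd.DataFrame | None = None
    clusters: list = field(default_factory=list)
    rscu: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    explained_variance: list = field(default_factory=list)
    warnings: dict = field(default_factory=dict)


def _order_frame(orders: dict) -> pd.DataFrame:
    rows = [
        {"genome_id": gid, "position": i + 1, "label": lbl, "sign": s}
        for gid, o in sorted(orders.items())
        for i, (lbl, s) in enumerate(o.genes)
    ]
    return pd.DataFrame(rows)


def run_pipeline(genomes, groups: dict | None = None, tree=None,
                 outgroup_id: str | None = None,
                 params: PipelineParams | None = None,
                 out_dir=None) -> ReportBundle:
    """Run all comparison stages; optionally write TSV/JSON outputs."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes to compare")
    params = params or PipelineParams()
    bundle = ReportBundle()
    warn = bundle.warnings

    # composition + skew regimes
    try:
        rows, profile_frames = [], []
        for g in genomes:
            row = composition.genome_composition(g)
            counts = {PCG: 0, TRNA: 0, RRNA: 0}
            for f in g.features:
                if f.cls in counts:
                    counts[f.cls] += 1
            row.update(n_pcg=counts[PCG], n_trna=counts[TRNA],
                       n_rrna=counts[RRNA])
            try:
                prof = composition.sliding_window_profile(
                    g, params.window, params.step, anchor=params.anchor)
                row["regime"] = composition.classify_regime(
                    prof, params.regime_hi, params.regime_lo)
                bundle.regimes[g.id] = {
                    "regime": row["regime"],
                    "fraction_positive": prof.fraction_positive,
                }
                profile_frames.append(prof.to_frame())
            except Exception as e:  # genome-local problem; keep the row
                warn.setdefault("composition", []).append(f"{g.id}: {e}")
                row["regime"] = "undetermined"
            rows.append(row)
        bundle.composition = pd.DataFrame(rows)
        if profile_frames:
            bundle.skew_profiles = pd.concat(profile_frames,
                                             ignore_index=True)
    except Exception as e:
        warn.setdefault("composition", []).append(str(e))

    # gene order and rearrangement
    try:
        orders = {}
        for g in genomes:
            try:
                orders[g.id] = gene_order.order_from_genome(
                    g, classes=params.order_classes, anchor=params.anchor)
            except gene_order.GeneOrderError as e:
                warn.setdefault("gene_order", []).append(f"{g.id}: {e}")
        bundle.orders = orders
        comparable = {gid: o for gid, o in orders.items()}
        label_sets = {o.labels for o in comparable.values()}
        if len(label_sets) == 1 and len(comparable) >= 2:
            bundle.distance_matrix = gene_order.pairwise_distance_matrix(
                comparable, strand_aware=params.strand_aware)
        else:
            warn.setdefault("gene_order", []).append(
                "pairwise distances skipped: differing gene sets")
        if tree is not None and outgroup_id in comparable and \
                len(label_sets) == 1:
            anc, fb = gene_order.infer_ancestral_order(
                comparable, tree, outgroup_id, anchor=params.anchor)
            bundle.ancestral_order = [[lbl, s] for lbl, s in anc.genes]
            bundle.ancestral_fallback = fb
            for gid, o in comparable.items():
                segs = gene_order.rearranged_segments(
                    o, anc, strand_aware=params.strand_aware)
                bundle.rearranged[gid] = {
                    "distance": gene_order.breakpoint_distance(
                        o, anc, strand_aware=params.strand_aware),
                    "segments": [[[lbl, s] for lbl, s in seg]
                                 for seg in segs],
                }
        elif tree is not None:
            warn.setdefault("gene_order", []).append(
                "ancestral stage skipped: outgroup order unavailable")
    except Exception as e:
        warn.setdefault("gene_order", []).append(str(e))

    # tRNA repertoire
    try:
        bundle.presence = trna_profile.presence_matrix(genomes)
        if groups:
            full_orders = {}
            for g in genomes:
                try:
                    full_orders[g.id] = gene_order.order_from_genome(
                        g, classes=(PCG, RRNA, TRNA), anchor=params.anchor)
                except gene_order.GeneOrderError as e:
                    warn.setdefault("trna", []).append(f"{g.id}: {e}")
            bundle.clusters = trna_profile.shared_clusters(
                full_orders, groups,
                ignore_strand=params.ignore_cluster_strand)
    except Exception as e:
        warn.setdefault("trna", []).append(str(e))

    # codon usage
    try:
        bundle.rscu = codon_usage.rscu_matrix(genomes)
        if bundle.rscu.shape[0] >= 3:
            bundle.pca_scores, ratios = codon_usage.rscu_pca(bundle.rscu)
            bundle.explained_variance = [float(r) for r in ratios]
        else:
            warn.setdefault("codon_usage", []).append(
                "PCA skipped: fewer than 3 RSCU rows")
    except Exception as e:
        warn.setdefault("codon_usage", []).append(str(e))

    if out_dir is not None:
        write_bundle(bundle, params, out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, params: PipelineParams,
                 out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.composition is not None:
        bundle.composition.to_csv(out / "composition.tsv", sep="\t",
                                  index=False, float_format=FLOAT_FORMAT)
    if bundle.skew_profiles is not None:
        bundle.skew_profiles.to_csv(out / "skew_profiles.tsv", sep="\t",
                                    index=False, float_format=FLOAT_FORMAT)
    (out / "regimes.json").write_text(json.dumps(bundle.regimes, indent=1,
                                                 sort_keys=True))
    if bundle.orders:
        _order_frame(bundle.orders).to_csv(out / "gene_order.tsv", sep="\t",
                                           index=False)
    rearrangement = {
        "pairwise_breakpoint_distance": bundle.distance_matrix,
        "ancestral_order": bundle.ancestral_order,
        "ancestral_fallback_used": bundle.ancestral_fallback,
        "rearranged_vs_ancestor": bundle.rearranged,
    }
    (out / "rearrangement.json").write_text(
        json.dumps(rearrangement, indent=1, sort_keys=True))
    if bundle.presence is not None:
        bundle.presence.to_csv(out / "trna_presence.tsv", sep="\t")
    (out / "trna_clusters.json").write_text(json.dumps(
        trna_profile.clusters_to_records(bundle.clusters), indent=1))
    if bundle.rscu is not None:
        bundle.rscu.to_csv(out / "rscu.tsv", sep="\t",
                           float_format=FLOAT_FORMAT)
    if bundle.pca_scores is not None:
        bundle.pca_scores.to_csv(out / "pca_scores.tsv", sep="\t",
                                 float_format=FLOAT_FORMAT)
        pd.DataFrame({
            "component": [f"PC{i + 1}"
                          for i in range(len(bundle.explained_variance))],
            "explained_variance_fraction": bundle.explained_variance,
        }).to_csv(out / "explained_variance.tsv", sep="\t", index=False,
                  float_format=FLOAT_FORMAT)
    manifest = {
        "package": "mitoremodel",
        "version": __version__,
        "params": asdict(params) | {
            "order_classes": list(params.order_classes)},
        "warnings": bundle.warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
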