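"""Stage orchestration: each stage reads its upstream artifacts from the
output directory, writes its own, and records a manifest entry (inputs,
config hash, package version) so re-runs are reproducible byte for byte."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    AnnotationDB,
    annotation_summary,
    infer_protein_annotations,
    protoname_table,
    protonames_for_tree,
)
from .cluster_tree import (
    MergeTree,
    StabilityParams,
    build_tree,
    stable_clusters,
)
from .config import PipelineConfig
from .mapping import MappingResult, map_proteome, self_query_rows, venn_partition
from .paralog_scores import (
    amplification_table,
    build_guide_tree,
    find_paralogs,
    taxonomy_balance_table,
    tree_score,
    ts_summary,
)
from .similarity import (
    all_vs_all,
    filter_full_length,
    load_pairwise_scores,
    read_fasta,
    write_fasta,
    write_pairwise_scores,
)
from .synthetic_data import GroundTruth, gen_annotations, gen_sequences

log = logging.getLogger(__name__)

STAGES = ("simulate", "score", "cluster", "map", "annotate", "scores", "report")

#: artifacts each stage needs before it can run, and the stage producing them
_REQUIRES = {
    "simulate": {},
    "score": {"proteome.fasta": "simulate"},
    "cluster": {"proteome.fasta": "simulate", "scores.tsv": "score"},
    "map": {"tree.json": "cluster", "stable.json": "cluster", "scores.tsv": "score"},
    "annotate": {
        "annotations.tsv": "simulate",
        "tree.json": "cluster",
        "mappings.json": "map",
    },
    "scores": {"tree.json": "cluster", "mappings.json": "map"},
    "report": {"annotation_summary.json": "annotate", "scores.json": "scores"},
}


class StageOrderError(RuntimeError):
    pass


def _check_upstream(stage: str, outdir: Path) -> None:
    for artifact, producer in _REQUIRES[stage].items():
        if not (outdir / artifact).exists():
            raise StageOrderError(
                f"stage {stage!r} needs {artifact!r}; run stage {producer!r} first"
            )


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_manifest(stage: str, config: PipelineConfig, outdir: Path, inputs, outputs) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = {
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "config_hash": _config_hash(config),
        "version": __version__,
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    records, truth = gen_sequences(config.synthetic, config.seed)
    db = gen_annotations(truth, config.synthetic, config.seed)
    write_fasta(records, outdir / "proteome.fasta")
    db.write(outdir / "annotations.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
    _write_manifest(
        "simulate", config, outdir, [],
        ["proteome.fasta", "annotations.tsv", "truth.json"],
    )


def stage_score(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("score", outdir)
    proteome = filter_full_length(read_fasta(outdir / "proteome.fasta"))
    m = all_vs_all(proteome, cap=config.cap, k=config.k, s=config.s)
    write_pairwise_scores(m, outdir / "scores.tsv", precision=None)
    _write_manifest("score", config, outdir, ["proteome.fasta"], ["scores.tsv"])


def _stability(config: PipelineConfig) -> StabilityParams:
    return StabilityParams(
        lt_min=config.lt_min,
        pl_root=config.pl_root,
        merge_cutoff=config.merge_cutoff,
    )


def _load_matrix(config: PipelineConfig, outdir: Path):
    proteome = filter_full_length(read_fasta(outdir / "proteome.fasta"))
    ids = [p.id for p in proteome]
    m = load_pairwise_scores(outdir / "scores.tsv", ids, cap=config.cap)
    return proteome, m


def stage_cluster(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("cluster", outdir)
    _, m = _load_matrix(config, outdir)
    params = _stability(config)
    tree = build_tree(m, params)
    stable = stable_clusters(tree, params)
    _json_dump(tree.to_json_dict(), outdir / "tree.json")
    (outdir / "tree.nwk").write_text(tree.to_newick())
    tree.node_table().to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    _json_dump(sorted(stable), outdir / "stable.json")
    _write_manifest(
        "cluster", config, outdir, ["proteome.fasta", "scores.tsv"],
        ["tree.json", "tree.nwk", "nodes.tsv", "stable.json"],
    )


def _load_tree(outdir: Path) -> MergeTree:
    return MergeTree.from_json_dict(json.loads((outdir / "tree.json").read_text()))


def _load_mappings(outdir: Path, tree: MergeTree) -> dict:
    """Per-species MappingResult, reconstructed from the mapping tables."""
    from .cluster_tree import EXCLUDED
    from .mapping import ProteinMapping, UNMAPPED

    payload = json.loads((outdir / "mappings.json").read_text())
    out = {}
    for sp, rows in payload.items():
        assignments = {}
        for pid, cluster, score, root in rows:
            cluster = UNMAPPED if cluster is None else cluster
            root = EXCLUDED if root == "EXCLUDED" else root
            assignments[pid] = ProteinMapping(pid, cluster, score, root)
        n = len(assignments)
        n_unmapped = sum(1 for a in assignments.values() if not a.is_mapped)
        n_excluded = sum(1 for a in assignments.values() if a.is_excluded)
        out[sp] = MappingResult(
            assignments,
            {
                "n_queries": n,
                "n_mapped": n - n_unmapped,
                "n_unmapped": n_unmapped,
                "n_excluded": n_excluded,
                "fraction_mapped": (n - n_unmapped) / n if n else 0.0,
                "fraction_unmapped": n_unmapped / n if n else 0.0,
                "fraction_excluded": n_excluded / n if n else 0.0,
            },
        )
    return out


def stage_map(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("map", outdir)
    proteome, m = _load_matrix(config, outdir)
    tree = _load_tree(outdir)
    stable = set(json.loads((outdir / "stable.json").read_text()))
    params = _stability(config)
    by_species: dict = {}
    for p in proteome:
        by_species.setdefault(p.species, []).append(p.id)
    payload = {}
    for sp in sorted(by_species):
        result = map_proteome(
            self_query_rows(m, by_species[sp]),
            tree,
            stable,
            params,
            tau_map=config.tau_map,
            prefer=config.prefer,
            cap=config.cap,
        )
        result.to_frame().to_csv(outdir / f"mapping_{sp}.tsv", sep="\t", index=False)
        payload[sp] = [
            [
                a.protein_id,
                a.cluster if a.is_mapped else None,
                a.score,
                "EXCLUDED" if a.is_excluded else (a.root if a.is_mapped else None),
            ]
            for a in result
        ]
    _json_dump(payload, outdir / "mappings.json")
    outputs = ["mappings.json"] + [f"mapping_{sp}.tsv" for sp in sorted(by_species)]
    mappings = _load_mappings(outdir, tree)
    if len(by_species) == 3:
        venn = venn_partition(mappings, sorted(by_species))
        _json_dump(venn, outdir / "venn.json")
        outputs.append("venn.json")
    _write_manifest(
        "map", config, outdir,
        ["proteome.fasta", "scores.tsv", "tree.json", "stable.json"], outputs,
    )


def stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("annotate", outdir)
    proteome = filter_full_length(read_fasta(outdir / "proteome.fasta"))
    tree = _load_tree(outdir)
    db = AnnotationDB.load(
        outdir / "annotations.tsv",
        universe=[p.id for p in proteome],
        blacklist=config.blacklist,
    )
    mappings = _load_mappings(outdir, tree)
    focal = mappings.get(config.species_of_interest)
    if focal is None:  # fall back to everything mapped
        merged = {}
        for res in mappings.values():
            merged.update(res.assignments)
        focal = MappingResult(merged, {})
    # name only nodes that can contribute: mapped clusters and their chains
    needed = set()
    for res in mappings.values():
        for a in res:
            if not a.is_mapped or a.is_excluded:
                continue
            needed.add(a.cluster)
            if a.root != a.cluster:
                for anc in tree.ancestors(a.cluster):
                    needed.add(anc)
                    if anc == a.root:
                        break
    names = protonames_for_tree(
        tree, db, needed,
        min_size=config.min_size, min_spec=config.min_spec,
        blacklist=config.blacklist,
    )
    protoname_table(names).to_csv(outdir / "protonames.tsv", sep="\t", index=False)
    inferences = {
        a.protein_id: infer_protein_annotations(a, tree, names, config.pl_root)
        for a in focal
    }
    with open(outdir / "protein_annotations.tsv", "w") as fh:
        fh.write("protein_id\tsource\tterm_id\tterm_label\n")
        for pid in sorted(inferences):
            for source, term_id, label in sorted(inferences[pid]):
                fh.write(f"{pid}\t{source}\t{term_id}\t{label}\n")
    summary = annotation_summary(focal, names, inferences)
    _json_dump(summary, outdir / "annotation_summary.json")
    _write_manifest(
        "annotate", config, outdir,
        ["proteome.fasta", "annotations.tsv", "tree.json", "mappings.json"],
        ["protonames.tsv", "protein_annotations.tsv", "annotation_summary.json"],
    )


def stage_scores(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("scores", outdir)
    proteome = filter_full_length(read_fasta(outdir / "proteome.fasta"))
    seq_of = {p.id: p for p in proteome}
    tree = _load_tree(outdir)
    mappings = _load_mappings(outdir, tree)
    focal_sp = config.species_of_interest
    report: dict = {}
    if focal_sp in mappings:
        focal = mappings[focal_sp]
        paralogs_map = find_paralogs(focal, "map", config.min_paralogs)
        paralogs_root = find_paralogs(focal, "root", config.min_paralogs)
        report["paralogs"] = {
            "map": {"buckets": paralogs_map.buckets, "n_proteins": paralogs_map.n_proteins},
            "root": {"buckets": paralogs_root.buckets, "n_proteins": paralogs_root.n_proteins},
        }
        # guide trees + TS per paralog-bearing stable cluster; the tree spans
        # the cluster's proteins plus the focal queries mapped onto it
        mapped_to: dict = {}
        for a in focal:
            if a.is_mapped:
                mapped_to.setdefault(a.cluster, set()).add(a.protein_id)
        ts_entries = []
        for cluster_id, count in paralogs_map.clusters:
            leaves = sorted(tree.node(cluster_id).members | mapped_to[cluster_id])
            if len(leaves) < 2:
                continue
            d = _kmer_distances([seq_of[pid] for pid in leaves], config.k)
            gtree = build_guide_tree(
                d, leaves, species={pid: seq_of[pid].species for pid in leaves}
            )
            ts_entries.append((count, tree_score(gtree, focal_sp).ts))
        report["tree_score"] = ts_summary(
            ts_entries,
            strata=config.ts_strata,
            bin_width=config.ts_bin_width,
            divergence_cutoff=config.ts_divergence_cutoff,
        )
        amp = amplification_table(focal)
        amp.to_csv(outdir / "ratio_table.tsv", sep="\t", index=False)
        report["amplification"] = {
            "n_roots": int(len(amp)),
            "max_ratio": float(amp["ratio"].max()) if len(amp) else None,
        }
        if config.reference_species in mappings:
            tb = taxonomy_balance_table(
                mappings, focal_sp, config.reference_species,
                high=config.tb_high, low=config.tb_low,
            )
            tb["table"].to_csv(outdir / "tb_table.tsv", sep="\t", index=False)
            report["taxonomy_balance"] = {
                "n_shared_roots": tb["n_shared_roots"],
                "n_high_extremes": len(tb["high_extremes"]),
                "n_low_extremes": len(tb["low_extremes"]),
                "high_threshold": tb["high_threshold"],
                "low_threshold": tb["low_threshold"],
            }
    _json_dump(report, outdir / "scores.json")
    _write_manifest(
        "scores", config, outdir, ["proteome.fasta", "tree.json", "mappings.json"],
        ["scores.json", "ratio_table.tsv", "tb_table.tsv"],
    )


def _kmer_distances(records, k: int) -> np.ndarray:
    """1 - k-mer Jaccard distances; the guide-tree substrate in sequence mode."""
    kmer_sets = [r.kmers(k) for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(kmer_sets[i] | kmer_sets[j])
            jac = len(kmer_sets[i] & kmer_sets[j]) / union if union else 0.0
            d[i, j] = d[j, i] = 1.0 - jac
    return d


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    _check_upstream("report", outdir)
    report = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "annotation": json.loads((outdir / "annotation_summary.json").read_text()),
        "scores": json.loads((outdir / "scores.json").read_text()),
    }
    tree = _load_tree(outdir)
    mappings = _load_mappings(outdir, tree)
    report["mapping"] = {sp: res.summary for sp, res in mappings.items()}
    if (outdir / "venn.json").exists():
        report["venn"] = json.loads((outdir / "venn.json").read_text())
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        report["recovery"] = _recovery_metrics(outdir, tree, mappings, config)
    _json_dump(report, outdir / "report.json")
    (outdir / "summary.txt").write_text(_render_summary(report))
    _write_manifest(
        "report", config, outdir,
        ["annotation_summary.json", "scores.json", "mappings.json"],
        ["report.json", "summary.txt"],
    )


def _recovery_metrics(outdir: Path, tree, mappings, config) -> dict:
    """Truth-aware metrics: family-recovery ARI and planted-term recall."""
    from sklearn.metrics import adjusted_rand_score

    truth = GroundTruth.from_json((outdir / "truth.json").read_text())
    assignments = {}
    for res in mappings.values():
        assignments.update(res.assignments)
    pids = sorted(assignments)
    predicted = [
        str(assignments[pid].cluster) if assignments[pid].is_mapped else f"un:{pid}"
        for pid in pids
    ]
    ari = adjusted_rand_score(truth.partition_labels(pids), predicted)
    recall_hits = 0
    recall_total = 0
    ann_path = outdir / "protein_annotations.tsv"
    inferred: dict = {}
    if ann_path.exists():
        table = pd.read_csv(ann_path, sep="\t")
        for row in table.itertuples(index=False):
            inferred.setdefault(row.protein_id, set()).add(
                (row.source, row.term_id)
            )
    for fam, term in truth.term_of_family.items():
        for pid in truth.families[fam]:
            a = assignments.get(pid)
            if a is None or not a.is_mapped or a.is_excluded:
                continue
            recall_total += 1
            if (term[0], term[1]) in inferred.get(pid, set()):
                recall_hits += 1
    return {
        "family_ari": ari,
        "term_recall": recall_hits / recall_total if recall_total else None,
        "n_orphans_planted": len(truth.orphans),
    }


def _render_summary(report: dict) -> str:
    lines = ["protofam pipeline summary", "=" * 25]
    for sp, s in report.get("mapping", {}).items():
        lines.append(
            f"{sp}: {s['n_mapped']}/{s['n_queries']} mapped "
            f"({100 * s['fraction_mapped']:.1f}%), "
            f"{s['n_excluded']} excluded, {s['n_unmapped']} unmapped"
        )
    ann = report.get("annotation", {})
    if ann:
        lines.append(
            f"annotation: {100 * ann['fraction_roots_named']:.1f}% of roots named, "
            f"{100 * ann['fraction_proteome_annotated']:.1f}% of proteome annotated"
        )
    rec = report.get("recovery")
    if rec:
        lines.append(
            f"recovery vs truth: ARI={rec['family_ari']:.3f}, "
            f"term recall={rec['term_recall']}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "cluster": stage_cluster,
    "map": stage_map,
    "annotate": stage_annotate,
    "scores": stage_scores,
    "report": stage_report,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running stage %s -> %s", stage, outdir)
    _STAGE_FUNCS[stage](config, outdir)


def run_all(config: PipelineConfig, outdir) -> None:
    for stage in STAGES:
        run_stage(stage, config, outdir)
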