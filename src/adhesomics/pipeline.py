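"""Configuration handling and end-to-end orchestration.

A run is described by a flat YAML config (unknown keys rejected, every
parameter defaulted to the published analysis values: two-fold / q<0.05
differential calls, 5% score FDR, 250-bp window flank, 75% minimum peak
quantile, 0.0005 stepping, 15 shuffle iterations). Stages hand data to
each other through files in the output directory; the fully resolved
config and a machine-readable summary are written beside the outputs,
so identical configs reproduce byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities, damid, enrich, netscore, proteomics, synthio
from .synthio import AbundanceMatrix

__all__ = ["DEFAULT_CONFIG", "validate_config", "load_config", "run_pipeline"]

logger = logging.getLogger("adhesomics")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results",
    "stages": ["simulate", "prep", "module", "cluster"],
    "simulate": {
        "n_proteins": 2000,
        "n_per_group": 3,
        "frac_diff": 0.1,
        "effect_log2fc": 2.0,
        "noise_sd": 0.3,
        "mnar_quantile": 0.25,
        "n_nodes": 200,
        "mean_degree": 4.0,
        "module_size": 20,
    },
    "prep": {
        "fold": 2.0,
        "q": 0.05,
        "donors": 5,
        "chains_iters": 10,
        "min_present": 2,
        "linear_scale": False,
    },
    "module": {"fdr": 0.05, "max_exact_nodes": 20, "default_p": 0.5},
    "cluster": {
        "method": "modularity",
        "gamma_grid": [round(g, 6) for g in np.geomspace(0.01, 2.0, 25).tolist()],
    },
    "enrich": {"q": 0.05, "min_ratio": 1.0, "top_k": 2},
    "damid": {
        "flank": 250,
        "eps": 0.5,
        "min_quantile": 0.75,
        "step": 0.0005,
        "iterations": 15,
        "fdr": 0.05,
        "min_run": 2,
    },
    "imaging": {"top": 1500.0},
    "inputs": {},
}

_KNOWN_STAGES = ("simulate", "prep", "module", "cluster", "enrich", "damid", "imaging")


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        full = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            if path == "inputs":  # input paths are free-form
                out[key] = value
            else:
                errors.append(f"unknown key {full}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, full, errors)
        else:
            out[key] = value
    return out


def validate_config(cfg: dict) -> tuple[dict, list[str]]:
    """Fill defaults, reject unknown keys, enforce cross-field constraints.

    Returns the resolved config and a list of every violation found.
    """
    errors: list[str] = []
    resolved = _merge(DEFAULT_CONFIG, cfg or {}, "", errors)

    for stage in resolved["stages"]:
        if stage not in _KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}")
    p = resolved["prep"]
    if p["fold"] < 1:
        errors.append(f"prep.fold must be >= 1, got {p['fold']}")
    if not 0 < p["q"] < 1:
        errors.append(f"prep.q must lie in (0, 1), got {p['q']}")
    if p["donors"] < 1:
        errors.append("prep.donors must be >= 1")
    mod = resolved["module"]
    if not 0 < mod["fdr"] < 1:
        errors.append(f"module.fdr must lie in (0, 1), got {mod['fdr']}")
    cl = resolved["cluster"]
    if cl["method"] not in ("modularity", "cpm"):
        errors.append(f"cluster.method must be modularity or cpm, got {cl['method']!r}")
    d = resolved["damid"]
    if not 0 <= d["min_quantile"] < 1:
        errors.append(f"damid.min_quantile must lie in [0, 1), got {d['min_quantile']}")
    if d["step"] <= 0:
        errors.append(f"damid.step must be positive, got {d['step']}")
    if d["iterations"] < 1:
        errors.append("damid.iterations must be >= 1")
    if not 0 < d["fdr"] < 1:
        errors.append(f"damid.fdr must lie in (0, 1), got {d['fdr']}")
    s = resolved["simulate"]
    if not 0 <= s["frac_diff"] <= 1:
        errors.append(f"simulate.frac_diff must lie in [0, 1], got {s['frac_diff']}")
    if s["n_nodes"] > s["n_proteins"]:
        errors.append("simulate.n_nodes must not exceed simulate.n_proteins")
    if s["module_size"] > s["n_nodes"]:
        errors.append("simulate.module_size must not exceed simulate.n_nodes")
    return resolved, errors


def load_config(path: str | Path) -> tuple[dict, list[str]]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        return DEFAULT_CONFIG, ["config root must be a mapping"]
    return validate_config(cfg)


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _table_header(stage: str, params: dict) -> str:
    return f"stage={stage} params={_params_hash(params)}"


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stage chain; returns the summary dictionary."""
    resolved, errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(outdir if outdir is not None else resolved["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seed = int(resolved["seed"])
    summary: dict = {"seed": seed, "stages": list(resolved["stages"])}
    logger.info("adhesomics run, seed=%d, stages=%s", seed, resolved["stages"])
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    try:
        for stage in resolved["stages"]:
            _STAGE_FUNCS[stage](resolved, out, seed, summary)
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    s = cfg["simulate"]
    m, truth = synthio.gen_lfq_matrix(
        n_proteins=s["n_proteins"],
        n_per_group=s["n_per_group"],
        frac_diff=s["frac_diff"],
        effect_log2fc=s["effect_log2fc"],
        noise_sd=s["noise_sd"],
        mnar_quantile=s["mnar_quantile"],
        seed=seed,
    )
    proteomics.write_abundance_tsv(m, out / "abundance.tsv", _table_header("simulate", s))
    (out / "groups.json").write_text(json.dumps(m.groups, indent=1))
    synthio.truth_to_json(truth, out / "lfq_truth.json")

    # interaction graph over a subset of simulated proteins
    edges, net_truth = synthio.gen_ppi_network(
        n_nodes=s["n_nodes"],
        mean_degree=s["mean_degree"],
        module_size=s["module_size"],
        seed=seed,
    )
    ids = list(m.values.index)
    rename = {f"N{i:04d}": ids[i] for i in range(s["n_nodes"])}
    with open(out / "edges.tsv", "w") as fh:
        fh.write(f"# {_table_header('simulate', s)}\n")
        for u, v in edges:
            fh.write(f"{rename[u]}\t{rename[v]}\n")
    synthio.truth_to_json(
        synthio.NetworkTruth({rename[n] for n in net_truth.planted_members}),
        out / "network_truth.json",
    )
    summary["simulate"] = {
        "n_proteins": s["n_proteins"],
        "n_differential_true": len(truth.differential_ids),
        "n_edges": len(edges),
    }
    logger.info("simulate: %d proteins, %d edges", s["n_proteins"], len(edges))


def _load_abundance(cfg: dict, out: Path) -> AbundanceMatrix:
    inputs = cfg["inputs"]
    ab_path = inputs.get("abundance", out / "abundance.tsv")
    gr_path = inputs.get("groups", out / "groups.json")
    if not Path(ab_path).exists():
        raise FileNotFoundError(
            f"prep needs an abundance matrix; missing upstream artifact {ab_path}"
        )
    groups = json.loads(Path(gr_path).read_text())
    df = pd.read_csv(ab_path, sep="\t", index_col=0, comment="#")
    return AbundanceMatrix(df.astype(float), groups)


def _stage_prep(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    p = cfg["prep"]
    m = _load_abundance(cfg, out)
    imputed, table = proteomics.run_prep(
        m,
        linear_scale=p["linear_scale"],
        min_present=p["min_present"],
        fold=p["fold"],
        q_thr=p["q"],
        donors=p["donors"],
        chains_iters=p["chains_iters"],
        seed=seed,
    )
    proteomics.write_abundance_tsv(imputed, out / "imputed.tsv", _table_header("prep", p))
    with open(out / "differential.tsv", "w") as fh:
        fh.write(f"# {_table_header('prep', p)}\n")
        table.to_csv(fh, sep="\t")
    summary["prep"] = {
        "n_tested": int(len(table)),
        "n_significant": int(table["significant"].sum()),
    }
    logger.info("prep: %d tested, %d significant", len(table), int(table["significant"].sum()))


def _stage_module(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    mod = cfg["module"]
    table_path = cfg["inputs"].get("differential", out / "differential.tsv")
    edges_path = cfg["inputs"].get("edges", out / "edges.tsv")
    for path, name in ((table_path, "differential table"), (edges_path, "edge list")):
        if not Path(path).exists():
            raise FileNotFoundError(f"module needs a {name}; missing upstream artifact {path}")
    table = pd.read_csv(table_path, sep="\t", index_col=0, comment="#")
    edges = [
        tuple(line.split("\t")[:2])
        for line in Path(edges_path).read_text().splitlines()
        if line and not line.startswith("#")
    ]
    fit = netscore.fit_bum(table["p"].to_numpy())
    nodes = {u for e in edges for u in e}
    scores = netscore.score_nodes(
        fit,
        {pid: p for pid, p in table["p"].items() if pid in nodes},
        fdr=mod["fdr"],
        nodes=nodes,
        default_p=mod["default_p"],
    )
    g = netscore.build_scored_graph(edges, scores)
    if g.number_of_nodes() <= mod["max_exact_nodes"]:
        module = netscore.solve_mwcs_exact(g, max_nodes=mod["max_exact_nodes"])
    else:
        module = netscore.solve_mwcs_heuristic(g)
    with open(out / "module_nodes.tsv", "w") as fh:
        fh.write(f"# {_table_header('module', mod)}\n")
        fh.write("node\tp\tscore\n")
        for n in module.members:
            pval = table["p"].get(n, float("nan"))
            fh.write(f"{n}\t{pval:.6g}\t{scores[n]:.6g}\n")
    with open(out / "module_tree.sif", "w") as fh:
        for u, v in module.tree_edges:
            fh.write(f"{u}\tpp\t{v}\n")
    summary["module"] = {
        "bum_lam": round(fit.lam, 6),
        "bum_a": round(fit.a, 6),
        "n_members": len(module.members),
        "total_score": round(module.total_score, 6),
    }
    logger.info("module: %d members, score %.3f", len(module.members), module.total_score)


def _stage_cluster(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    cl = cfg["cluster"]
    nodes_path = out / "module_nodes.tsv"
    edges_path = cfg["inputs"].get("edges", out / "edges.tsv")
    if not nodes_path.exists():
        raise FileNotFoundError(f"cluster needs module nodes; missing upstream artifact {nodes_path}")
    module_nodes = list(
        pd.read_csv(nodes_path, sep="\t", comment="#")["node"].astype(str)
    )
    edges = [
        tuple(line.split("\t")[:2])
        for line in Path(edges_path).read_text().splitlines()
        if line and not line.startswith("#")
    ]
    members = set(module_nodes)
    sub_edges = [(u, v) for u, v in edges if u in members and v in members]
    m = _load_abundance(cfg, out)
    import networkx as nx

    mode = cl["method"]
    weighted = communities.abundance_edge_weights(m, sub_edges, mode=mode)
    g = nx.Graph()
    g.add_nodes_from(module_nodes)
    g.add_weighted_edges_from(weighted)
    if mode == "modularity":
        part = communities.louvain_modularity(g, seed=seed)
    else:
        part = communities.scan_gamma(g, cl["gamma_grid"], seed=seed)
    with open(out / "partition.tsv", "w") as fh:
        fh.write(f"# {_table_header('cluster', cl)}\n")
        fh.write("node\tcommunity\n")
        for n in sorted(part.community_of_node):
            fh.write(f"{n}\t{part.community_of_node[n]}\n")
    quality = {
        "kind": part.quality_kind.value,
        "value": part.quality,
        "gamma": part.gamma,
    }
    (out / "quality.json").write_text(json.dumps(quality, indent=1))
    hubs = communities.classify_hubs(g, part)
    with open(out / "hubs.tsv", "w") as fh:
        fh.write("node\tz\tP\tlabel\n")
        for h in hubs:
            fh.write(f"{h.node}\t{h.within_module_z:.4f}\t{h.participation_P:.4f}\t{h.label}\n")
    summary["cluster"] = {
        "n_communities": len(set(part.community_of_node.values())),
        "quality": round(part.quality, 6),
        "kind": part.quality_kind.value,
    }
    logger.info("cluster: %d communities (%s)", summary["cluster"]["n_communities"], mode)


def _stage_enrich(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    en = cfg["enrich"]
    gmt_path = cfg["inputs"].get("gmt")
    part_path = out / "partition.tsv"
    if gmt_path is None or not Path(gmt_path).exists():
        raise FileNotFoundError("enrich needs inputs.gmt; missing upstream artifact gmt")
    if not part_path.exists():
        raise FileNotFoundError(f"enrich needs a partition; missing upstream artifact {part_path}")
    gsc = enrich.read_gmt(gmt_path)
    pt = pd.read_csv(part_path, sep="\t", comment="#")
    membership = dict(zip(pt["node"].astype(str), pt["community"].astype(int)))
    universe = set(membership)
    annotations = enrich.annotate_clusters(
        membership, universe, gsc, top_k=en["top_k"], q_thr=en["q"]
    )
    (out / "annotations.json").write_text(json.dumps(annotations, indent=1, sort_keys=True))
    summary["enrich"] = {
        "n_annotated": sum(1 for v in annotations.values() if v != ["unannotated"])
    }
    logger.info("enrich: %d communities annotated", summary["enrich"]["n_annotated"])


def _stage_damid(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    d = cfg["damid"]
    inputs = cfg["inputs"]
    fasta = inputs.get("fasta", out / "genome.fa")
    fusion_bed = inputs.get("fusion_bed", out / "fusion.bed")
    control_bed = inputs.get("control_bed", out / "control.bed")
    for path, name in (
        (fasta, "genome FASTA"),
        (fusion_bed, "fusion BED"),
        (control_bed, "control BED"),
    ):
        if not Path(path).exists():
            raise FileNotFoundError(f"damid needs a {name}; missing upstream artifact {path}")
    genome = damid.read_fasta(fasta)
    track = damid.build_gatc_map(genome, flank=d["flank"])
    fusion = damid.read_bed_starts(fusion_bed)
    control = damid.read_bed_starts(control_bed)
    damid.count_reads(track, fusion, "fusion")
    damid.count_reads(track, control, "control")
    damid.normalize_rpm(track, {"fusion": len(fusion), "control": len(control)})
    damid.log_ratio(track, eps=d["eps"])
    peaks = damid.call_peaks(
        track,
        min_quantile=d["min_quantile"],
        step=d["step"],
        iterations=d["iterations"],
        fdr_thr=d["fdr"],
        min_run=d["min_run"],
        seed=seed,
    )
    damid.write_bedgraph(track, out / "log2_ratio.bedgraph")
    damid.write_peaks_bed(peaks, out / "peaks.bed")
    summary["damid"] = {"n_windows": len(track), "n_peaks": len(peaks)}
    logger.info("damid: %d windows, %d peaks", len(track), len(peaks))


def _stage_imaging(cfg: dict, out: Path, seed: int, summary: dict) -> None:
    from . import imaging as im

    cfg_im = cfg["imaging"]
    inputs = cfg["inputs"]
    a_path = inputs.get("image_a", out / "image_a.npy")
    b_path = inputs.get("image_b", out / "image_b.npy")
    for path, name in ((a_path, "channel A"), (b_path, "channel B")):
        if not Path(path).exists():
            raise FileNotFoundError(f"imaging needs {name}; missing upstream artifact {path}")
    a = np.load(a_path)
    b = np.load(b_path)
    mask = None
    mask_path = inputs.get("mask")
    if mask_path is not None:
        mask = np.load(mask_path).astype(bool)
    a_n = im.linear_normalize(a, top=cfg_im["top"])
    b_n = im.linear_normalize(b, top=cfg_im["top"])
    m_a, m_b = im.manders_cooccurrence(a_n, b_n, region_mask=mask)
    metrics = {"M_a": m_a, "M_b": m_b, "top": cfg_im["top"]}
    (out / "imaging_metrics.json").write_text(json.dumps(metrics, indent=1))
    summary["imaging"] = metrics
    logger.info("imaging: M_a=%.4f, M_b=%.4f", m_a, m_b)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "module": _stage_module,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "damid": _stage_damid,
    "imaging": _stage_imaging,
}
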