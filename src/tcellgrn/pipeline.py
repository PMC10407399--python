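"""End-to-end orchestration of the discovery pipeline.

``run_all`` executes preprocess -> clusters -> de -> modules -> gsea -> grn ->
consensus -> prioritize on one expression compendium, each stage reading only
the files written by earlier stages, so any suffix of the chain can be re-run
from the retained intermediates.  A single global seed makes repeated runs
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tcellgrn import consensus as cns
from tcellgrn import coexpression as coex
from tcellgrn import differential as de_mod
from tcellgrn import grn as grn_mod
from tcellgrn import io_preprocess as iop
from tcellgrn import prioritize as pri
from tcellgrn import sample_structure as ss
from tcellgrn import synthetic as syn

__all__ = ["DEFAULT_CONFIG", "PipelineError", "DependencyError",
           "load_config", "validate_config", "run_all"]

STAGES = ["preprocess", "clusters", "de", "modules", "gsea", "grn", "consensus", "prioritize"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "expression": None,       # TSV path; when null, the synthetic generator runs
    "samples": None,
    "tf_catalogue": None,     # plain-text gene list, one per line
    "annotations": None,      # TSV gene<TAB>term (one row per pair)
    "motifs": None,           # TSV gene x TF 0/1 table
    "reference_condition": "resting",
    "target_condition": None,  # condition whose module/regulon is dissected; default: last
    "stages": {s: True for s in STAGES},
    "simulate": {},           # SyntheticConfig overrides
    "preprocess": {"tau": None, "quantile": True, "batch_center": True},
    "clusters": {"n_ccm_clusters": None, "kmeans_range": [2, 6], "n_init": 5},
    "de": {"fc": 2.0, "q": 0.05},
    "modules": {"beta": 15, "min_module_size": 10, "cut_height": 0.99},
    "gsea": {"n_perm": 200},
    "grn": {"methods": ["pearson", "aracne", "tinge", "clr", "genie3"],
            "n_trees": 100, "pearson_cutoff": 0.7, "mi_p": 0.05,
            "dpi_tolerance": 0.01, "top_k": None},
    "consensus": {"k": 500, "hub_fraction": 0.20, "inflation": 2.0},
    "prioritize": {"training": None, "head": 15, "top_n": 6, "fc_threshold": 1.0},
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    user = yaml.safe_load(Path(path).read_text()) or {}
    errors = validate_config(user)
    if errors:
        raise PipelineError("invalid config: " + "; ".join(errors))
    return _merge(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> list[str]:
    """Schema validation with precise messages; unknown keys are rejected."""
    errors = []
    unknown = set(config) - set(DEFAULT_CONFIG)
    for k in sorted(unknown):
        errors.append(f"unknown key {k!r}")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    for key in ("expression", "samples", "tf_catalogue", "annotations", "motifs"):
        path = config.get(key)
        if path is not None and not Path(path).exists():
            errors.append(f"{key} path {path!r} does not exist")
    if config.get("expression") and not config.get("samples"):
        errors.append("samples path required when expression is given")
    stages = config.get("stages", {})
    for s in set(stages) - set(STAGES):
        errors.append(f"unknown stage {s!r}")
    return errors


def _meta_line(stage: str, seed: int, params: dict) -> str:
    digest = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return f"# generated-by tcellgrn stage={stage} seed={seed} params={digest}\n"


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, seed: int, params: dict, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(stage, seed, params))
        df.to_csv(fh, sep="\t", float_format="%.10g", **kw)


def _require(outdir: Path, filename: str, stage: str, needed_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(f"stage {needed_by!r} requires output of stage {stage!r} ({filename})")
    return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_input(config: dict, outdir: Path) -> None:
    if config["expression"] is not None:
        matrix = iop.read_expression(config["expression"])
        annotation = iop.read_samples(config["samples"])
        iop.write_expression(matrix, outdir / "expression.tsv")
        iop.write_samples(annotation, outdir / "samples.tsv")
        return
    sim = dict(config["simulate"])
    sim.setdefault("seed", config["seed"])
    sim_config = syn.SyntheticConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in sim.items()})
    truth = syn.generate_ground_truth(sim_config)
    matrix, annotation = syn.simulate_expression(truth, sim_config)
    syn.write_fixture(matrix, annotation, truth, outdir)
    hits = syn.motif_hit_table(truth, sim_config)
    pri.write_motif_table(hits, outdir / "motifs.tsv")
    (outdir / "tf_catalogue.txt").write_text("\n".join(truth.regulators) + "\n")
    terms = syn.annotation_terms(truth)
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(terms):
            for term in sorted(terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    config["tf_catalogue"] = str(outdir / "tf_catalogue.txt")
    config["annotations"] = str(outdir / "annotations.tsv")
    config["motifs"] = str(outdir / "motifs.tsv")


def _stage_preprocess(config: dict, outdir: Path) -> dict:
    params = config["preprocess"]
    matrix = iop.read_expression(outdir / "expression.tsv")
    annotation = iop.read_samples(outdir / "samples.tsv")
    n_in = matrix.shape[0]
    if params["quantile"]:
        matrix = iop.quantile_normalize(matrix)
    tau = iop.estimate_background(matrix, override=params["tau"])
    matrix = iop.filter_expressed(matrix, tau)
    n_expressed = matrix.shape[0]
    if matrix.gene_map is not None:
        matrix = iop.collapse_probes(matrix)
    if params["batch_center"]:
        matrix = iop.center_batches(matrix, annotation)
    out = outdir / "expression.preprocessed.tsv"
    with open(out, "w") as fh:
        fh.write(_meta_line("preprocess", config["seed"], params))
        matrix.values.to_csv(fh, sep="\t", index_label="id", float_format="%.10g")
    report = {"tau": tau, "rows_in": n_in, "rows_expressed": n_expressed,
              "genes_out": matrix.shape[0]}
    (outdir / "preprocess_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _stage_clusters(config: dict, outdir: Path) -> dict:
    params = config["clusters"]
    matrix = iop.read_expression(_require(outdir, "expression.preprocessed.tsv", "preprocess", "clusters"))
    annotation = iop.read_samples(outdir / "samples.tsv")
    ccm = ss.correlation_matrix(matrix, annotation, group_by_condition=True)
    n_cc = params["n_ccm_clusters"] or len(ccm)
    assignment = ss.hierarchical_cluster(ccm, min(n_cc, len(ccm)))
    _write_tsv(ccm, outdir / "ccm.tsv", "clusters", config["seed"], params, index_label="condition")
    _write_tsv(assignment.labels.rename("cluster").to_frame(), outdir / "clusters.tsv",
               "clusters", config["seed"], params, index_label="condition")
    k = min(5, min(matrix.shape) - 1)
    scores = ss.pca(matrix, max(k, 1)).scores
    _write_tsv(scores, outdir / "pca_scores.tsv", "clusters", config["seed"], params,
               index_label="sample")
    ref = config["reference_condition"]
    cond = annotation.loc[matrix.samples, "condition"]
    ref_samples = list(cond.index[cond == ref])
    if ref_samples:
        ref_mean = matrix.values[ref_samples].mean(axis=1)
        fc = matrix.values.sub(ref_mean, axis=0).T  # samples x genes, log2 differences
        lo, hi = params["kmeans_range"]
        ks = range(lo, min(hi, len(fc) - 1) + 1)
        best_k, km_assign, curve = ss.kmeans_davies_bouldin(
            fc, ks, n_init=params["n_init"], seed=config["seed"])
        _write_tsv(curve, outdir / "db_curve.tsv", "clusters", config["seed"], params)
        _write_tsv(km_assign.labels.rename("kmeans_cluster").to_frame(),
                   outdir / "kmeans_clusters.tsv", "clusters", config["seed"], params,
                   index_label="sample")
    else:
        warnings.warn(f"clusters: reference condition {ref!r} absent; k-means skipped")
        best_k = None
    return {"n_ccm_clusters": int(assignment.labels.max()), "kmeans_best_k": best_k}


def _stage_de(config: dict, outdir: Path) -> dict:
    params = config["de"]
    matrix = iop.read_expression(_require(outdir, "expression.preprocessed.tsv", "preprocess", "de"))
    annotation = iop.read_samples(outdir / "samples.tsv")
    ref = config["reference_condition"]
    cond = annotation.loc[matrix.samples, "condition"]
    ref_samples = list(cond.index[cond == ref])
    if len(ref_samples) < 2:
        raise PipelineError(f"reference condition {ref!r} needs >= 2 samples")
    records, sets = [], {}
    for c in sorted(cond.unique()):
        if c == ref:
            continue
        group = list(cond.index[cond == c])
        rec = de_mod.t_test_contrast(matrix, group, ref_samples, contrast=f"{c}_vs_{ref}")
        records.append(rec.reset_index())
        sets[c] = de_mod.de_genes(rec, params["fc"], params["q"])
    table = pd.concat(records, ignore_index=True)
    _write_tsv(table, outdir / "de_results.tsv", "de", config["seed"], params, index=False)
    union = sorted(set().union(*sets.values())) if sets else []
    (outdir / "de_union.txt").write_text("\n".join(union) + ("\n" if union else ""))
    upset = de_mod.upset_intersections(sets) if sets else pd.DataFrame()
    _write_tsv(upset, outdir / "upset.tsv", "de", config["seed"], params, index=False)
    return {"contrasts": len(sets), "de_union": len(union),
            "per_contrast": {c: len(s) for c, s in sets.items()}}


def _condition_indicators(annotation: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    cond = annotation.loc[samples, "condition"]
    return pd.get_dummies(cond).astype(float)


def _stage_modules(config: dict, outdir: Path) -> dict:
    params = config["modules"]
    matrix = iop.read_expression(_require(outdir, "expression.preprocessed.tsv", "preprocess", "modules"))
    annotation = iop.read_samples(outdir / "samples.tsv")
    union_path = _require(outdir, "de_union.txt", "de", "modules")
    union = [g for g in union_path.read_text().splitlines() if g]
    union = [g for g in union if g in matrix.values.index]
    if len(union) < params["min_module_size"]:
        raise PipelineError("DE union smaller than min_module_size; no module detection possible")
    assignment = coex.wgcna_modules(matrix, union, beta=params["beta"],
                                    min_module_size=params["min_module_size"],
                                    cut_height=params["cut_height"])
    _write_tsv(assignment.labels.rename("module").to_frame(), outdir / "modules.tsv",
               "modules", config["seed"], params, index_label="gene")
    module_ids = sorted(m for m in assignment.labels.unique() if m != 0)
    if not module_ids:
        raise PipelineError("no co-expression module reached min_module_size; "
                            "consider a lower soft power or cut height")
    eigs = {}
    for m in module_ids:
        eigs[f"ME{m}"] = coex.module_eigengene(matrix, assignment.genes_of(m), m).scores
    eig = pd.DataFrame(eigs, index=matrix.samples)
    _write_tsv(eig, outdir / "eigengenes.tsv", "modules", config["seed"], params,
               index_label="sample")
    traits = _condition_indicators(annotation, matrix.samples)
    r, p = coex.module_trait_correlation(eig, traits)
    mt = pd.concat({"r": r, "p": p}, axis=1)
    mt.columns = [f"{a}_{b}" for a, b in mt.columns]
    _write_tsv(mt, outdir / "module_trait.tsv", "modules", config["seed"], params,
               index_label="module")
    return {"n_modules": len(module_ids),
            "module_sizes": {int(m): int((assignment.labels == m).sum()) for m in module_ids}}


def _stage_gsea(config: dict, outdir: Path) -> dict:
    params = config["gsea"]
    matrix = iop.read_expression(outdir / "expression.preprocessed.tsv")
    annotation = iop.read_samples(outdir / "samples.tsv")
    modules = pd.read_csv(_require(outdir, "modules.tsv", "modules", "gsea"),
                          sep="\t", index_col=0, comment="#")["module"]
    cond = annotation.loc[matrix.samples, "condition"]
    rows = []
    for c in sorted(cond.unique()):
        mask = (cond == c).to_numpy()
        stats_ = coex._pooled_t(matrix.values.to_numpy(float), mask)
        ranked = pd.Series(stats_, index=matrix.genes)
        for m in sorted(set(modules) - {0}):
            genes = set(modules.index[modules == m]) & set(matrix.genes)
            if not genes:
                continue
            res = coex.gsea(ranked, genes, n_perm=params["n_perm"],
                            seed=config["seed"] + m, set_name=f"module_{m}")
            rows.append({"condition": c, "module": m, "es": res.es,
                         "nes": res.nes, "p": res.p})
    table = pd.DataFrame(rows)
    _write_tsv(table, outdir / "gsea.tsv", "gsea", config["seed"], params, index=False)
    return {"n_tests": len(table)}


def _grn_universe(config: dict, outdir: Path, matrix: iop.ExpressionMatrix) -> list[str]:
    union = [g for g in (outdir / "de_union.txt").read_text().splitlines() if g]
    genes = set(union) & set(matrix.genes)
    if config["tf_catalogue"]:
        tfs = [g for g in Path(config["tf_catalogue"]).read_text().split() if g]
        genes |= set(tfs) & set(matrix.genes)
    return sorted(genes)


def _stage_grn(config: dict, outdir: Path) -> dict:
    params = config["grn"]
    matrix = iop.read_expression(_require(outdir, "expression.preprocessed.tsv", "preprocess", "grn"))
    _require(outdir, "de_union.txt", "de", "grn")
    universe = _grn_universe(config, outdir, matrix)
    if len(universe) < 3:
        raise PipelineError("GRN universe has fewer than 3 genes")
    sub = iop.ExpressionMatrix(values=matrix.values.loc[universe])
    regulators = universe
    if config["tf_catalogue"]:
        catalogue = set(Path(config["tf_catalogue"]).read_text().split())
        regulators = [g for g in universe if g in catalogue] or universe
    estimate = None
    counts = {}
    for method in params["methods"]:
        if method == "pearson":
            result = grn_mod.pearson_network(sub, cutoff=params["pearson_cutoff"])
        elif method in ("aracne", "tinge", "clr"):
            if estimate is None:
                estimate = grn_mod.mi_matrix(sub, seed=config["seed"])
            if method == "aracne":
                p = grn_mod.mi_significance(estimate, method="chi2")
                result = grn_mod.aracne(estimate, p, p_threshold=params["mi_p"],
                                        dpi_tolerance=params["dpi_tolerance"])
            elif method == "tinge":
                result = grn_mod.tinge_like(estimate)
            else:
                result = grn_mod.clr(estimate, top_k=params["top_k"])
        elif method == "genie3":
            result = grn_mod.genie3_like(sub, regulators, n_trees=params["n_trees"],
                                         seed=config["seed"], top_k=params["top_k"])
        else:
            raise PipelineError(f"unknown GRN method {method!r}")
        edges = result.edges.copy()
        edges["method"] = method
        edges["direction"] = "directed" if result.directed else "undirected"
        _write_tsv(edges, outdir / f"edges_{method}.tsv", "grn", config["seed"], params,
                   index=False)
        counts[method] = len(edges)
    (outdir / "grn_universe.txt").write_text("\n".join(universe) + "\n")
    return {"universe": len(universe), "edges": counts}


def _load_edge_list(path: Path) -> grn_mod.RankedEdgeList:
    df = pd.read_csv(path, sep="\t", comment="#")
    directed = bool(len(df)) and (df["direction"] == "directed").any()
    method = df["method"].iloc[0] if len(df) else path.stem.replace("edges_", "")
    edges = df[["gene_a", "gene_b", "score"]].copy()
    # ranks are recomputed: decimal formatting on disk may merge near-ties
    from scipy import stats as _stats
    edges["rank"] = _stats.rankdata(-edges["score"].to_numpy(), method="average") if len(edges) else []
    return grn_mod.RankedEdgeList(method=method, directed=directed,
                                  edges=edges, universe=0)


def _stage_consensus(config: dict, outdir: Path) -> dict:
    params = config["consensus"]
    universe_path = _require(outdir, "grn_universe.txt", "grn", "consensus")
    universe = [g for g in universe_path.read_text().splitlines() if g]
    lists = []
    for method in config["grn"]["methods"]:
        lists.append(_load_edge_list(_require(outdir, f"edges_{method}.tsv", "grn", "consensus")))
    network = cns.average_rank_consensus(lists, universe)
    network = cns.top_k(network, k=params["k"])
    _write_tsv(network.edges, outdir / "consensus_edges.tsv", "consensus",
               config["seed"], params, index=False)
    hub_genes, hub_edges = cns.hubs(network, fraction=params["hub_fraction"])
    deg = network.degrees
    hub_table = pd.DataFrame({"gene": hub_genes,
                              "degree": [deg[g] for g in hub_genes]})
    _write_tsv(hub_table, outdir / "hubs.tsv", "consensus", config["seed"], params, index=False)
    clusters = cns.mcl(network, inflation=params["inflation"])
    mcl_table = pd.DataFrame(sorted(clusters.items()), columns=["gene", "cluster"])
    _write_tsv(mcl_table, outdir / "mcl_clusters.tsv", "consensus", config["seed"],
               params, index=False)
    return {"edges": len(network), "nodes": len(network.nodes),
            "hubs": len(hub_genes), "hub_edges": hub_edges,
            "mcl_clusters": int(mcl_table["cluster"].max()) if len(mcl_table) else 0}


def _read_annotation_terms(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    terms: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        terms.setdefault(str(gene), set()).add(str(term))
    return terms


def _stage_prioritize(config: dict, outdir: Path) -> dict:
    params = config["prioritize"]
    matrix = iop.read_expression(_require(outdir, "expression.preprocessed.tsv", "preprocess", "prioritize"))
    hubs_path = _require(outdir, "hubs.tsv", "consensus", "prioritize")
    hub_genes = list(pd.read_csv(hubs_path, sep="\t", comment="#")["gene"])
    if not config["tf_catalogue"]:
        raise PipelineError("prioritize requires a TF catalogue")
    catalogue = [g for g in Path(config["tf_catalogue"]).read_text().split() if g]
    candidates = pri.filter_tfs(hub_genes, catalogue)
    if not candidates:
        raise PipelineError("no hub gene is in the TF catalogue")
    training = params["training"]
    if not training:
        present = [g for g in catalogue if g in matrix.values.index and g not in candidates]
        training = (present or [g for g in catalogue if g in matrix.values.index])[:4]
    rank_a = pri.coexpression_similarity_rank(matrix, candidates, training)
    rankings = [rank_a]
    if config["annotations"]:
        terms = _read_annotation_terms(config["annotations"])
        for t in training:
            terms.setdefault(t, set())
        rankings.append(pri.annotation_similarity_rank(terms, candidates, training))
    combined = pri.borda_combine(rankings) if len(rankings) > 1 else rank_a.assign(
        borda=lambda d: len(d) - d["position"]).sort_values("position")
    head = min(params["head"], len(combined))
    top_n = min(params["top_n"], head)
    central = pri.expression_filter(list(combined.index), matrix, top_n, head=head)
    table = combined.copy()
    table["central"] = [g in set(central) for g in table.index]
    _write_tsv(table, outdir / "prioritization.tsv", "prioritize", config["seed"],
               params, index_label="gene")

    report: dict = {"candidates": len(candidates), "training": training, "central": central}
    if config["motifs"]:
        hits = pri.read_motif_table(config["motifs"])
        target_cond = config["target_condition"]
        mt = pd.read_csv(_require(outdir, "module_trait.tsv", "modules", "prioritize"),
                         sep="\t", index_col=0, comment="#")
        r_cols = [c for c in mt.columns if c.startswith("r_")]
        if target_cond is None:
            # default: the non-reference condition with the strongest module association
            ref = config["reference_condition"]
            eligible = [c for c in r_cols if c[2:] != ref] or r_cols
            target_cond = max(eligible, key=lambda c: mt[c].abs().max())[2:]
        best_module = mt[f"r_{target_cond}"].abs().idxmax()
        modules = pd.read_csv(outdir / "modules.tsv", sep="\t", index_col=0, comment="#")["module"]
        module_id = int(best_module.replace("ME", ""))
        module_genes = [g for g in modules.index[modules == module_id] if g in matrix.values.index]
        universe = [g for g in matrix.genes if g in hits.index]
        gene_set = [g for g in module_genes if g in universe]
        enrichment = pri.motif_enrichment(gene_set, hits, universe)
        _write_tsv(enrichment, outdir / "enrichment.tsv", "prioritize", config["seed"],
                   params, index_label="tf")
        top_tf = enrichment.index[0]
        de_records = pd.read_csv(outdir / "de_results.tsv", sep="\t", comment="#")
        contrast = f"{target_cond}_vs_{config['reference_condition']}"
        rec = de_records[de_records["contrast"] == contrast].set_index("gene")
        module_in_rec = [g for g in gene_set if g in rec.index]
        targets = pri.target_filter(hits, top_tf, module_in_rec, rec,
                                    fc_threshold=params["fc_threshold"])
        pd.DataFrame({"gene": targets}).to_csv(outdir / "regulon_targets.tsv",
                                               sep="\t", index=False)
        report.update({"target_condition": target_cond, "module": module_id,
                       "top_tf": top_tf, "regulon_targets": targets})
    return report


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "clusters": _stage_clusters,
    "de": _stage_de,
    "modules": _stage_modules,
    "gsea": _stage_gsea,
    "grn": _stage_grn,
    "consensus": _stage_consensus,
    "prioritize": _stage_prioritize,
}


def run_all(config: dict, out_dir) -> dict:
    """Run the enabled stages in order and return the run report.

    The report lists, per stage, the key row counts, the parameters and the
    wall time; it is also written to ``report.json``.  A stage failure aborts
    the run with the failing stage named; outputs written so far are retained
    under ``failed/`` inside the output directory.
    """
    config = _merge(DEFAULT_CONFIG, config)
    errors = validate_config({k: v for k, v in config.items() if k in DEFAULT_CONFIG})
    if errors:
        raise PipelineError("invalid config: " + "; ".join(errors))
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config["seed"], "stages": {}}
    _stage_input(config, outdir)
    for stage in STAGES:
        if not config["stages"].get(stage, True):
            report["stages"][stage] = {"skipped": True}
            continue
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](config, outdir)
        except DependencyError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            (failed / "stage.txt").write_text(stage)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        info = dict(info or {})
        info["seconds"] = round(time.perf_counter() - t0, 3)
        info["params"] = config.get(stage, {})
        report["stages"][stage] = info
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
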