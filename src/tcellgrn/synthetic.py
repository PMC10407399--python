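"""Synthetic microarray-like expression data with planted regulatory structure.

The generator emulates a log2-scale expression compendium of labelled
CD4+ T-cell-like conditions: a low-intensity background population of
never-expressed genes, duplicated probes per gene, per-batch offsets, and a
planted directed TF -> target network with linear effects plus Gaussian noise.
One designated *lineage* TF (the FOXP3 analog) is expressed in exactly one
condition and regulates a *hidden target* (the MEOX1 analog) through that
target's sole incoming edge, so regulator recovery is unambiguous.

Every downstream stage of the pipeline is testable by recovery against the
emitted :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tcellgrn.io_preprocess import (
    ExpressionMatrix,
    read_expression,
    read_samples,
    write_expression,
    write_samples,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_expression",
    "motif_hit_table",
    "annotation_terms",
    "write_fixture",
    "load_truth",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    All expression quantities are in log2 intensity units.  ``seed`` fully
    determines the output (one seeded generator, no global RNG state).
    """

    n_tf: int = 10
    n_targets: int = 90
    n_background: int = 50
    targets_per_tf: tuple[int, int] = (1, 3)  # in-degree range per target
    effect_range: tuple[float, float] = (0.8, 1.6)
    negative_effect_prob: float = 0.25
    noise_sd: float = 0.3
    conditions: tuple[str, ...] = ("resting", "activated", "lineage")
    lineage_condition: str = "lineage"
    activity_offset: float = 2.0    # lineage TF boost above baseline when "on"
    modulation_offset: float = 1.0  # mild preferred-condition boost of other TFs
    samples_per_condition: int = 20
    n_probes_per_gene: int = 2
    probe_sd: float = 0.05
    n_batches: int = 2
    batch_offset_sd: float = 0.5
    background_floor: float = 6.0
    signal_baseline: float = 9.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tf, self.n_targets, self.n_background) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_targets > 0 and self.n_tf == 0:
            raise ValueError("targets requested but n_tf is 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_tf range must satisfy 1 <= lo <= hi")
        if self.lineage_condition not in self.conditions:
            raise ValueError("lineage_condition must be one of conditions")
        if self.samples_per_condition < 1 or self.n_batches < 1:
            raise ValueError("samples_per_condition and n_batches must be >= 1")
        if self.n_probes_per_gene < 1:
            raise ValueError("n_probes_per_gene must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure emitted by the generator; the recovery oracle.

    ``module_of`` maps each non-background gene to the module of its
    strongest regulator (TFs anchor their own modules).  ``condition_specific``
    lists the genes expressed only in one condition; the lineage pair is in the
    set of exactly one condition.
    """

    regulators: list[str]
    edges: list[tuple[str, str, float]]  # (tf, target, effect in log2 units)
    module_of: dict[str, int]
    condition_specific: dict[str, list[str]]
    lineage_pair: tuple[str, str]
    background_genes: list[str]
    tf_condition: dict[str, str] = field(default_factory=dict)

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(tf, tg) for tf, tg, _ in self.edges}

    def all_genes(self) -> list[str]:
        seen = dict.fromkeys(self.regulators)
        for _, target, _ in self.edges:
            seen.setdefault(target)
        for g in self.background_genes:
            seen.setdefault(g)
        return list(seen)


def generate_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw the planted directed acyclic TF -> target network.

    Each target receives 1-3 incoming edges (range configurable) from distinct
    TFs; the hidden target receives a single positive-effect edge from the
    lineage TF.  Modules are the target sets of each TF plus the TF itself;
    multi-regulated targets belong to the module of their strongest regulator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tf)]
    targets = [f"G{i + 1:03d}" for i in range(config.n_targets)]
    background = [f"BG{i + 1:03d}" for i in range(config.n_background)]

    if not tfs:
        return GroundTruth(regulators=[], edges=[], module_of={},
                           condition_specific={}, lineage_pair=("", ""),
                           background_genes=background)

    lineage_tf = tfs[-1]
    other_conditions = [c for c in config.conditions if c != config.lineage_condition]
    tf_condition: dict[str, str] = {}
    for i, tf in enumerate(tfs):
        if tf == lineage_tf:
            tf_condition[tf] = config.lineage_condition
        else:
            tf_condition[tf] = other_conditions[i % len(other_conditions)] if other_conditions else config.lineage_condition

    lo, hi = config.targets_per_tf
    eff_lo, eff_hi = config.effect_range
    edges: list[tuple[str, str, float]] = []
    hidden_target = targets[-1] if targets else ""
    for target in targets:
        if target == hidden_target:
            effect = float(rng.uniform(eff_lo, eff_hi))
            edges.append((lineage_tf, target, effect))
            continue
        in_degree = int(rng.integers(lo, hi + 1))
        in_degree = min(in_degree, len(tfs))
        parents = rng.choice(len(tfs), size=in_degree, replace=False)
        for p in sorted(parents):
            effect = float(rng.uniform(eff_lo, eff_hi))
            if rng.random() < config.negative_effect_prob:
                effect = -effect
            edges.append((tfs[p], target, effect))

    module_id = {tf: i + 1 for i, tf in enumerate(tfs)}
    module_of: dict[str, int] = dict(module_id)
    by_target: dict[str, list[tuple[str, float]]] = {}
    for tf, target, effect in edges:
        by_target.setdefault(target, []).append((tf, effect))
    for target, parents in by_target.items():
        strongest = max(parents, key=lambda te: (abs(te[1]), te[0]))[0]
        module_of[target] = module_id[strongest]

    lineage_only = [lineage_tf] + sorted(
        t for t, ps in by_target.items() if {tf for tf, _ in ps} == {lineage_tf}
    )
    condition_specific = {config.lineage_condition: lineage_only}

    return GroundTruth(
        regulators=tfs,
        edges=edges,
        module_of=module_of,
        condition_specific=condition_specific,
        lineage_pair=(lineage_tf, hidden_target),
        background_genes=background,
        tf_condition=tf_condition,
    )


def simulate_expression(truth: GroundTruth, config: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the probe-level expression matrix and sample annotation.

    TF profiles are a condition-specific baseline plus N(0, sd) per sample;
    target profiles are the signal baseline plus the sum of effect x (TF
    deviation from the signal baseline) plus independent noise; background
    genes sit at the low-intensity floor.  Each gene is measured by
    ``n_probes_per_gene`` probes (gene profile plus small probe noise) and each
    batch adds a per-gene offset.
    """
    config.validate()
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    conditions = list(config.conditions)
    samples, cond_labels, batch_labels = [], [], []
    for ci, cond in enumerate(conditions):
        for k in range(config.samples_per_condition):
            idx = ci * config.samples_per_condition + k
            samples.append(f"s{idx + 1:03d}")
            cond_labels.append(cond)
            batch_labels.append(f"batch{idx % config.n_batches + 1}")
    n_samples = len(samples)
    cond_arr = np.array(cond_labels)

    lineage_tf, _ = truth.lineage_pair
    profiles: dict[str, np.ndarray] = {}
    for tf in truth.regulators:
        level = np.full(n_samples, config.signal_baseline)
        preferred = truth.tf_condition.get(tf, conditions[0])
        if tf == lineage_tf:
            level[:] = config.background_floor
            level[cond_arr == preferred] = config.signal_baseline + config.activity_offset
        else:
            level[cond_arr == preferred] += config.modulation_offset
        profiles[tf] = level + rng.normal(0.0, config.noise_sd, n_samples)

    by_target: dict[str, list[tuple[str, float]]] = {}
    for tf, target, effect in truth.edges:
        by_target.setdefault(target, []).append((tf, effect))
    for target in sorted(by_target):
        value = np.full(n_samples, config.signal_baseline)
        for tf, effect in by_target[target]:
            value = value + effect * (profiles[tf] - config.signal_baseline)
        profiles[target] = value + rng.normal(0.0, config.noise_sd, n_samples)

    for g in truth.background_genes:
        profiles[g] = config.background_floor + rng.normal(0.0, config.noise_sd, n_samples)

    genes = truth.all_genes()
    batch_arr = np.array(batch_labels)
    batch_names = sorted(set(batch_labels))
    probe_rows, probe_ids, gene_ids = [], [], []
    for gene in genes:
        base = profiles[gene]
        for p in range(config.n_probes_per_gene):
            row = base if config.probe_sd == 0 else base + rng.normal(0.0, config.probe_sd, n_samples)
            probe_rows.append(row)
            probe_ids.append(f"{gene}_p{p + 1}")
            gene_ids.append(gene)
    values = np.asarray(probe_rows)
    for b in batch_names:
        offsets = rng.normal(0.0, config.batch_offset_sd, len(probe_ids))
        values[:, batch_arr == b] += offsets[:, None]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        gene_map=pd.Series(gene_ids, index=probe_ids),
    )
    annotation = pd.DataFrame(
        {"condition": cond_labels, "batch": batch_labels}, index=pd.Index(samples, name="sample")
    )
    return matrix, annotation


def motif_hit_table(truth: GroundTruth, config: SyntheticConfig,
                    false_positive_rate: float = 0.02) -> pd.DataFrame:
    """Boolean gene x TF promoter motif-hit table consistent with the truth.

    A gene carries a hit for every planted regulator, plus random false
    positives.  The hidden target is kept clean: its only hit is the lineage
    TF, mirroring an unambiguous promoter annotation.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 2))
    genes = truth.all_genes()
    hits = pd.DataFrame(False, index=genes, columns=truth.regulators)
    for tf, target, _ in truth.edges:
        hits.loc[target, tf] = True
    noise = rng.random(hits.shape) < false_positive_rate
    hits = hits | pd.DataFrame(noise, index=hits.index, columns=hits.columns)
    for tf, target, _ in truth.edges:
        hits.loc[target, tf] = True
    _, hidden = truth.lineage_pair
    if hidden:
        hits.loc[hidden, :] = False
        hits.loc[hidden, truth.lineage_pair[0]] = True
    return hits


def annotation_terms(truth: GroundTruth) -> dict[str, set[str]]:
    """Gene -> annotation-term sets derived from the planted structure.

    Every non-background gene carries its module term; regulators additionally
    carry a shared transcription-regulator term, so annotation similarity to
    known regulators favours TFs.
    """
    terms: dict[str, set[str]] = {}
    for gene in truth.all_genes():
        terms[gene] = set()
        if gene in truth.module_of:
            terms[gene].add(f"module_{truth.module_of[gene]}")
    for tf in truth.regulators:
        terms[tf].add("transcription_regulator")
        terms[tf].add("dna_binding")
    return terms


def write_fixture(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                  truth: GroundTruth, dir_path) -> dict[str, Path]:
    """Write expression.tsv, samples.tsv and truth.json under ``dir_path``.

    The files round-trip losslessly through the io layer; the directory must
    already exist.
    """
    out = Path(dir_path)
    if not out.is_dir():
        raise FileNotFoundError(f"fixture directory {out} does not exist")
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    write_expression(matrix, paths["expression"])
    write_samples(annotation, paths["samples"])
    payload = asdict(truth)
    payload["edges"] = [[tf, tg, eff] for tf, tg, eff in truth.edges]
    payload["lineage_pair"] = list(truth.lineage_pair)
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def load_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        regulators=list(payload["regulators"]),
        edges=[(tf, tg, float(eff)) for tf, tg, eff in payload["edges"]],
        module_of={g: int(m) for g, m in payload["module_of"].items()},
        condition_specific={c: list(gs) for c, gs in payload["condition_specific"].items()},
        lineage_pair=tuple(payload["lineage_pair"]),
        background_genes=list(payload["background_genes"]),
        tf_condition=dict(payload.get("tf_condition", {})),
    )


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def read_fixture(dir_path) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    out = Path(dir_path)
    matrix = read_expression(out / "expression.tsv")
    annotation = read_samples(out / "samples.tsv")
    truth = load_truth(out / "truth.json")
    return matrix, annotation, truth
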