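"""Greedy coordinate-ascent optimization of the active-gene configuration.

Each run starts from either a best-guess configuration (evidence priority
Mendelian > exome > colocalized, defaulting to the nearest gene) or a
uniform random one, then repeats passes that visit the non-singleton loci
in a fresh random order, re-selecting the highest-scoring gene at each
locus with all other loci frozen.  At the end of every pass the shared
parameters (distance scale gamma, categorical log-odds S_f) are refit by
maximum likelihood from the current active genes.  A run converges when a
full pass changes no active gene; since the parameter updates depend only
on the active genes, the parameters are then stationary too.

Multiple independent restarts are aggregated into per-gene selection
frequencies (fraction of runs the gene ends active) and mean final
softmax weights — deliberately distinct summaries: a gene whose weight
exceeds 0.5 is always selected, giving selection frequency 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import RunConfig
from .locus_model import GeneAssignment, Locus, LocusSet
from .network_model import NetworkModel
from .scoring import (
    FEATURES,
    DistanceModel,
    FeatureModel,
    gene_total_score,
    locus_weights,
    update_feature_counts,
    update_gamma,
)

__all__ = [
    "RunRecord",
    "RunSummary",
    "initialize_best_guess",
    "initialize_random",
    "sweep",
    "update_parameters",
    "run_single",
    "run_multi",
    "extract_gene_lists",
]

Configuration = dict[str, str]  # locus_id -> active gene symbol


@dataclass
class RunRecord:
    """Outcome of one sampler run."""

    run_index: int
    seed: int
    config: Configuration
    weights: dict[str, float]  # symbol -> final softmax weight
    passes: int
    converged: bool
    gamma: float
    feature_scores: dict[str, float]


@dataclass
class RunSummary:
    """Aggregate over independent restarts."""

    selection_frequency: dict[str, float]
    mean_weight: dict[str, float]
    runs: list[RunRecord]
    signet: dict[str, str] = field(default_factory=dict)
    signet_plus: dict[str, list[str]] = field(default_factory=dict)
    mindist: dict[str, str] = field(default_factory=dict)
    signet_tie: dict[str, bool] = field(default_factory=dict)


def validate_configuration(config: Configuration, locus_set: LocusSet) -> None:
    """Assert one active gene per locus, singletons pinned to their gene."""
    if set(config) != {l.locus_id for l in locus_set.loci}:
        raise ValueError("configuration loci do not match the locus set")
    for locus in locus_set.loci:
        sym = config[locus.locus_id]
        members = {ga.gene.symbol for ga in locus.member_genes}
        if sym not in members:
            raise ValueError(f"active gene {sym} not a member of {locus.locus_id}")
        if locus.is_singleton_mendelian and sym != locus.member_genes[0].gene.symbol:
            raise ValueError(f"singleton locus {locus.locus_id} not pinned")


def _priority_pick(locus: Locus, rng: np.random.Generator) -> str:
    """Best-guess choice: Mendelian > exome > colocalized > nearest TSS."""
    for attr in ("has_mendelian", "has_exome", "has_coloc"):
        tier = sorted(
            (ga.gene.symbol for ga in locus.member_genes if getattr(ga, attr))
        )
        if tier:
            return tier[int(rng.integers(len(tier)))]
    return next(ga.gene.symbol for ga in locus.member_genes if ga.is_mindist)


def initialize_best_guess(locus_set: LocusSet, rng: np.random.Generator) -> Configuration:
    """Evidence-priority initialization; ties broken uniformly at random."""
    config: Configuration = {}
    for locus in locus_set.loci:
        if locus.is_singleton_mendelian:
            config[locus.locus_id] = locus.member_genes[0].gene.symbol
        else:
            config[locus.locus_id] = _priority_pick(locus, rng)
    return config


def initialize_random(locus_set: LocusSet, rng: np.random.Generator) -> Configuration:
    """Uniform random gene per locus; singleton loci stay pinned."""
    config: Configuration = {}
    for locus in locus_set.loci:
        if locus.is_singleton_mendelian:
            config[locus.locus_id] = locus.member_genes[0].gene.symbol
        else:
            idx = int(rng.integers(locus.n_genes))
            config[locus.locus_id] = locus.member_genes[idx].gene.symbol
    return config


def _score_locus(
    locus: Locus,
    config: Configuration,
    distance_model: DistanceModel,
    feature_models: Mapping[str, FeatureModel],
    networks: Mapping[str, NetworkModel],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    symbols = [ga.gene.symbol for ga in locus.member_genes]
    scores = np.array(
        [
            gene_total_score(
                ga, locus, config, distance_model, feature_models, networks
            ).total
            for ga in locus.member_genes
        ]
    )
    return symbols, scores, locus_weights(scores)


def sweep(
    config: Configuration,
    locus_set: LocusSet,
    distance_model: DistanceModel,
    feature_models: Mapping[str, FeatureModel],
    networks: Mapping[str, NetworkModel],
    rng: np.random.Generator,
) -> tuple[Configuration, bool, dict[str, float]]:
    """One pass over the non-singleton loci in random order.

    At each locus the active gene is replaced by the argmax-score gene
    (ties broken uniformly at random) with all other loci frozen.  Returns
    the new configuration, whether anything changed, and the softmax
    weights recorded at each visit.
    """
    config = dict(config)
    weights: dict[str, float] = {}
    gwas = locus_set.gwas_loci
    order = rng.permutation(len(gwas))
    changed = False
    for idx in order:
        locus = gwas[idx]
        symbols, scores, w = _score_locus(
            locus, config, distance_model, feature_models, networks
        )
        for sym, wi in zip(symbols, w):
            weights[sym] = float(wi)
        best = np.flatnonzero(scores == scores.max())
        pick = symbols[int(best[int(rng.integers(len(best)))])]
        if pick != config[locus.locus_id]:
            changed = True
            config[locus.locus_id] = pick
    return config, changed, weights


def update_parameters(
    config: Configuration,
    locus_set: LocusSet,
    distance_model: DistanceModel,
    pseudocount: float = 1.0,
) -> tuple[DistanceModel, dict[str, FeatureModel]]:
    """End-of-pass maximum-likelihood refit of gamma and the S_f scores."""
    active_gwas = [
        next(ga for ga in locus.member_genes if ga.gene.symbol == config[locus.locus_id])
        for locus in locus_set.gwas_loci
    ]
    gamma = update_gamma(active_gwas, previous=distance_model.gamma)
    counts = update_feature_counts(config, locus_set)
    feature_models = {
        name: FeatureModel(name, *counts[name], pseudocount=pseudocount)
        for name in FEATURES
    }
    return DistanceModel(gamma=gamma), feature_models


def _final_weights(
    config: Configuration,
    locus_set: LocusSet,
    distance_model: DistanceModel,
    feature_models: Mapping[str, FeatureModel],
    networks: Mapping[str, NetworkModel],
) -> dict[str, float]:
    """Scoring-only sweep: weights for every gene under the converged state."""
    weights: dict[str, float] = {}
    for locus in locus_set.loci:
        if locus.is_singleton_mendelian:
            weights[locus.member_genes[0].gene.symbol] = 1.0
            continue
        symbols, _, w = _score_locus(
            locus, config, distance_model, feature_models, networks
        )
        for sym, wi in zip(symbols, w):
            weights[sym] = float(wi)
    return weights


def run_single(
    locus_set: LocusSet,
    networks: Mapping[str, NetworkModel],
    cfg: RunConfig,
    run_seed: int,
    run_index: int = 0,
) -> RunRecord:
    """One restart: initialize, iterate sweeps + parameter updates to a
    fixed point (or the pass cap), then compute final weights."""
    rng = np.random.default_rng(run_seed)
    if cfg.init_mode == "random":
        config = initialize_random(locus_set, rng)
    else:
        config = initialize_best_guess(locus_set, rng)
    distance_model, feature_models = update_parameters(
        config, locus_set, DistanceModel(), cfg.pseudocount
    )
    converged = False
    passes = 0
    for _ in range(cfg.max_passes):
        config, changed, _ = sweep(
            config, locus_set, distance_model, feature_models, networks, rng
        )
        distance_model, feature_models = update_parameters(
            config, locus_set, distance_model, cfg.pseudocount
        )
        passes += 1
        if not changed:
            converged = True
            break
    validate_configuration(config, locus_set)
    weights = _final_weights(
        config, locus_set, distance_model, feature_models, networks
    )
    return RunRecord(
        run_index=run_index,
        seed=run_seed,
        config=config,
        weights=weights,
        passes=passes,
        converged=converged,
        gamma=distance_model.gamma,
        feature_scores={name: fm.score for name, fm in feature_models.items()},
    )


def run_multi(
    locus_set: LocusSet,
    networks: Mapping[str, NetworkModel],
    cfg: RunConfig,
) -> RunSummary:
    """Independent restarts aggregated into selection frequencies and mean
    weights; per-locus SigNet / SigNet+ / MinDist gene lists extracted."""
    runs = [
        run_single(locus_set, networks, cfg, run_seed=cfg.seed + i, run_index=i)
        for i in range(cfg.n_runs)
    ]
    n = float(len(runs))
    freq: dict[str, float] = {}
    mean_w: dict[str, float] = {}
    for locus in locus_set.loci:
        for ga in locus.member_genes:
            sym = ga.gene.symbol
            freq[sym] = sum(r.config[locus.locus_id] == sym for r in runs) / n
            mean_w[sym] = sum(r.weights.get(sym, 0.0) for r in runs) / n
    summary = RunSummary(selection_frequency=freq, mean_weight=mean_w, runs=runs)
    extract_gene_lists(summary, locus_set)
    return summary


def extract_gene_lists(summary: RunSummary, locus_set: LocusSet) -> RunSummary:
    """Fill per-locus SigNet (most-selected gene, ties lexicographic and
    flagged), SigNet+ (SigNet union all flagged genes), MinDist lists."""
    for locus in locus_set.loci:
        syms = [ga.gene.symbol for ga in locus.member_genes]
        best_f = max(summary.selection_frequency[s] for s in syms)
        top = sorted(s for s in syms if summary.selection_frequency[s] == best_f)
        summary.signet[locus.locus_id] = top[0]
        summary.signet_tie[locus.locus_id] = len(top) > 1
        flagged = {ga.gene.symbol for ga in locus.member_genes if ga.has_any_evidence}
        summary.signet_plus[locus.locus_id] = sorted({top[0]} | flagged)
        summary.mindist[locus.locus_id] = next(
            ga.gene.symbol for ga in locus.member_genes if ga.is_mindist
        )
    return summary
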