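"""Assessment machinery: overlap tests, gene-set enrichment, hidden-evidence
recovery, subset robustness, and within-locus rank concordance."""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RunConfig
from .locus_model import LocusSet
from .network_model import NetworkModel, build_network_model
from .scoring import FEATURES

__all__ = [
    "OverlapResult",
    "fisher_overlap",
    "three_way_overlap_test",
    "geneset_enrichment",
    "hide_information_experiment",
    "subset_robustness",
    "rank_concordance",
]

_FLAG_ATTR = {"mendelian": "has_mendelian", "exome": "has_exome", "coloc": "has_coloc"}


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    universe_size: int
    pvalue: float
    test: str


def fisher_overlap(set_a: set[str], set_b: set[str], universe_size: int) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test on the overlap of two sets.

    Equivalent to the hypergeometric tail P(X >= observed overlap) with
    |A| draws from a universe containing |B| successes.
    """
    k = len(set_a & set_b)
    if k > min(len(set_a), len(set_b)) or max(len(set_a), len(set_b)) > universe_size:
        raise ValueError("sets must fit inside the universe")
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_b), len(set_a)))
    return OverlapResult(overlap=k, universe_size=universe_size, pvalue=min(p, 1.0), test="fisher_greater")


def three_way_overlap_test(
    set_a: set[str], set_b: set[str], set_c: set[str], universe_size: int
) -> OverlapResult:
    """Binomial tail test of a triple overlap.

    Under independence the chance a universe gene lies in all three sets
    is the product of the marginal rates; the p-value is
    P(Bin(N, rate_product) >= observed triple overlap).
    """
    k = len(set_a & set_b & set_c)
    n = universe_size
    p0 = (len(set_a) / n) * (len(set_b) / n) * (len(set_c) / n)
    p = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return OverlapResult(overlap=k, universe_size=n, pvalue=min(p, 1.0), test="binomial_three_way")


def geneset_enrichment(
    selected: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of the selected genes in each gene set.

    Sets are intersected with the universe before testing; sets disjoint
    from the universe are dropped with a warning.  Benjamini-Hochberg
    q-values are added.  Rows are sorted by p-value.
    """
    if not universe:
        raise ValueError("enrichment universe must be non-empty")
    sel = selected & universe
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        if not members:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; dropped")
            continue
        k = len(sel & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(sel)))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["qvalue"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["pvalue", "set"]).reset_index(drop=True)
    else:
        df["qvalue"] = []
    return df


def hide_information_experiment(
    locus_set: LocusSet,
    networks: Mapping[str, NetworkModel],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Hide each single-evidence gene's flags in turn and test recovery.

    For every non-singleton locus with exactly one flagged gene, that
    gene's flags are cleared, the sampler is rerun, and the gene counts
    as recovered if it is still the most-selected gene at its locus.
    The input locus set is never modified (each trial works on a copy).
    Returns per-category recovered/total counts, categories ordered by
    evidence priority of the hidden gene.
    """
    from . import sampler

    trials = []
    for locus in locus_set.gwas_loci:
        flagged = [ga for ga in locus.member_genes if ga.has_any_evidence]
        if len(flagged) == 1:
            ga = flagged[0]
            category = next(n for n in FEATURES if getattr(ga, _FLAG_ATTR[n]))
            trials.append((locus.locus_id, ga.gene.symbol, category))

    counts = {name: {"total": 0, "recovered": 0} for name in FEATURES}
    for locus_id, symbol, category in trials:
        hidden = copy.deepcopy(locus_set)
        ga = hidden.assignment(symbol)
        ga.has_mendelian = ga.has_exome = ga.has_coloc = False
        nets = {
            name: build_network_model(net.edges, hidden, net.directed)
            for name, net in networks.items()
        }
        summary = sampler.run_multi(hidden, nets, cfg)
        counts[category]["total"] += 1
        if summary.signet[locus_id] == symbol:
            counts[category]["recovered"] += 1
    return pd.DataFrame(
        [
            {"category": name, "total": c["total"], "recovered": c["recovered"]}
            for name, c in counts.items()
        ]
    )


def subset_robustness(
    locus_set: LocusSet,
    networks: Mapping[str, NetworkModel],
    cfg: RunConfig,
    fraction: float = 0.8,
    n_subsets: int = 100,
) -> pd.DataFrame:
    """Parameter dispersion over random locus subsets.

    Each subset keeps ceil(fraction * (L+M)) loci sampled without
    replacement; one run on each subset records the final distance scale
    and feature scores.  Returns mean and standard deviation per
    parameter across subsets.
    """
    from . import sampler

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_total = len(locus_set.loci)
    n_keep = math.ceil(fraction * n_total)
    records = []
    for s in range(n_subsets):
        idx = sorted(rng.choice(n_total, size=n_keep, replace=False))
        sub = copy.deepcopy(LocusSet(loci=[locus_set.loci[i] for i in idx], flank_D=locus_set.flank_D))
        sub.validate()
        nets = {
            name: build_network_model(net.edges, sub, net.directed)
            for name, net in networks.items()
        }
        rec = sampler.run_single(sub, nets, cfg, run_seed=cfg.seed + 1000 + s)
        row = {"subset": s, "gamma": rec.gamma}
        row.update({f"S_{name}": score for name, score in rec.feature_scores.items()})
        records.append(row)
    df = pd.DataFrame(records).drop(columns="subset")
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def rank_concordance(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    locus_set: LocusSet,
) -> dict:
    """Within-locus baseline-subtracted score and rank agreement.

    For each method the per-locus maximum score is subtracted, so the
    top gene scores 0 and others are negative; ranks are integer,
    descending in score within each locus.  Returns global Pearson
    correlation of baseline-subtracted scores, Spearman correlation of
    scores, per-locus ranks, and the count of genes dropped because they
    were missing from either table.
    """
    shared_rows = []
    dropped = 0
    for locus in locus_set.loci:
        syms = [ga.gene.symbol for ga in locus.member_genes]
        present = [s for s in syms if s in scores_a and s in scores_b]
        dropped += len(syms) - len(present)
        if not present:
            continue
        base_a = max(scores_a[s] for s in present)
        base_b = max(scores_b[s] for s in present)
        adj_a = np.array([scores_a[s] - base_a for s in present])
        adj_b = np.array([scores_b[s] - base_b for s in present])
        rank_a = stats.rankdata(-adj_a, method="min").astype(int)
        rank_b = stats.rankdata(-adj_b, method="min").astype(int)
        for s, aa, bb, ra, rb in zip(present, adj_a, adj_b, rank_a, rank_b):
            shared_rows.append(
                {"locus_id": locus.locus_id, "gene": s, "score_a": aa, "score_b": bb, "rank_a": ra, "rank_b": rb}
            )
    if not shared_rows:
        raise ValueError("no genes shared between the two score tables")
    table = pd.DataFrame(shared_rows)
    if len(table) > 1 and table["score_a"].std() > 0 and table["score_b"].std() > 0:
        pearson_r, pearson_p = stats.pearsonr(table["score_a"], table["score_b"])
        spearman_r, spearman_p = stats.spearmanr(table["score_a"], table["score_b"])
    else:
        pearson_r = pearson_p = spearman_r = spearman_p = float("nan")
    return {
        "table": table,
        "pearson_r": float(pearson_r),
        "pearson_p": float(pearson_p),
        "spearman_r": float(spearman_r),
        "spearman_p": float(spearman_p),
        "n_dropped": dropped,
    }
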