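"""Score functions of the model and their maximum-likelihood updates.

A configuration (one active gene per locus) is scored as a sum of
independent log-likelihood contributions under a naive-Bayes factorization:

    S_i = S_Distance + S_Mendelian + S_Exome + S_Colocalization
          + S_PPI + S_GRI

The distance term is a two-sided exponential density in the signed
SNP-to-TSS distance x with scale gamma, ln[exp(-|x|/gamma) / (2 gamma)].
Each categorical evidence term contributes a learned log-odds S_f when
the active gene carries the feature and 0 otherwise.  The two network
terms compare the observed edge count E among active genes with the
degree-corrected expectation E0 through a Poisson log-likelihood ratio,
reflected so that only edge enrichment (E > E0), never depletion, is
rewarded.

Per-locus constants (the inactive-gene distance term and the categorical
baseline S0) cancel when comparing genes within a locus and are omitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, softmax

from .locus_model import GeneAssignment, Locus, LocusSet
from .network_model import NetworkModel

__all__ = [
    "GAMMA_FLOOR",
    "FEATURES",
    "DistanceModel",
    "FeatureModel",
    "GeneScore",
    "distance_log_density",
    "update_gamma",
    "feature_score",
    "categorical_contribution",
    "network_log_likelihood_ratio",
    "network_score",
    "gene_total_score",
    "locus_weights",
    "update_feature_counts",
    "configuration_score",
]

GAMMA_FLOOR = 1.0  # bp; guards the MLE update against degenerate |x| = 0 data

FEATURES = ("mendelian", "exome", "coloc")

_FLAG_ATTR = {
    "mendelian": "has_mendelian",
    "exome": "has_exome",
    "coloc": "has_coloc",
}


@dataclass
class DistanceModel:
    """Exponential SNP-to-TSS distance density with scale gamma (bp)."""

    gamma: float = 150_000.0

    def __post_init__(self) -> None:
        if self.gamma < GAMMA_FLOOR:
            self.gamma = GAMMA_FLOOR


@dataclass
class FeatureModel:
    """Log-odds score state for one categorical evidence feature.

    Counts follow the 2x2 active-by-feature table: n00 inactive without,
    n01 inactive with, n10 active without, n11 active with the feature.
    The conditional feature probabilities (alpha for inactive, beta for
    active genes) are implied by the counts and never stored.
    """

    feature: str
    n00: float = 0.0
    n01: float = 0.0
    n10: float = 0.0
    n11: float = 0.0
    pseudocount: float = 1.0

    @property
    def score(self) -> float:
        return feature_score(self.n00, self.n01, self.n10, self.n11, self.pseudocount)


@dataclass
class GeneScore:
    """Score components for one candidate gene, their total, and its weight."""

    distance: float
    mendelian: float
    exome: float
    coloc: float
    ppi: float
    gri: float
    weight: float = float("nan")

    @property
    def total(self) -> float:
        return (
            self.distance + self.mendelian + self.exome + self.coloc + self.ppi + self.gri
        )


def distance_log_density(x: float, gamma: float) -> float:
    """ln of the two-sided exponential density at signed distance x."""
    return -math.log(2.0 * gamma) - abs(x) / gamma


def update_gamma(
    active_assignments: Iterable[GeneAssignment], previous: float | None = None
) -> float:
    """MLE update of gamma: mean |x| over active genes at GWAS loci.

    Singleton Mendelian genes (x = 0 by construction) are excluded.  With
    no eligible gene the previous value is kept with a warning.  The
    result is floored at 1 bp.
    """
    xs = [abs(ga.x) for ga in active_assignments]
    if not xs:
        warnings.warn("no eligible genes for gamma update; keeping previous value")
        return previous if previous is not None else GAMMA_FLOOR
    return max(GAMMA_FLOOR, float(np.mean(xs)))


def feature_score(
    n00: float, n01: float, n10: float, n11: float, pseudocount: float = 1.0
) -> float:
    """Log-odds score from the active-by-feature 2x2 table.

    ln[(n11 + c)/(n10 + c)] - ln[(n01 + c)/(n00 + c)] with additive
    smoothing c.  Fractional counts are legal.
    """
    c = pseudocount
    return math.log((n11 + c) / (n10 + c)) - math.log((n01 + c) / (n00 + c))


def categorical_contribution(
    assignment: GeneAssignment, feature_models: Mapping[str, FeatureModel]
) -> dict[str, float]:
    """Per-feature score contributions: S_f if the gene has the feature else 0."""
    return {
        name: (feature_models[name].score if getattr(assignment, _FLAG_ATTR[name]) else 0.0)
        for name in FEATURES
    }


def network_log_likelihood_ratio(E: float, E0: float, T: int) -> float:
    """Poisson vs flat-alternative log-likelihood ratio Lambda(E).

    lnGamma(E+1) - E ln E0 + E0 - ln(T+1), with the 0 ln 0 := 0 convention.
    E may be real-valued (the continuous lnGamma extension is used when
    evaluating at E = E0).
    """
    if E0 < 0 or E < 0:
        raise ValueError("E and E0 must be nonnegative")
    if E0 == 0.0:
        if E > 0:
            raise ValueError(
                "E > 0 with E0 = 0 violates the degree model: an observed edge "
                "implies both endpoint degrees are positive"
            )
        return -math.log(T + 1)
    return float(gammaln(E + 1.0)) - E * math.log(E0) + E0 - math.log(T + 1)


def network_score(E: float, E0: float, T: int) -> float:
    """Enrichment-only network score.

    Lambda(E0) + sgn(E - E0) |Lambda(E) - Lambda(E0)|: edge excess over the
    degree-corrected expectation raises the score, edge depletion lowers
    it below the baseline, so the sampler is never drawn toward
    edge-depleted configurations.
    """
    lam0 = network_log_likelihood_ratio(E0, E0, T)
    lam = network_log_likelihood_ratio(E, E0, T)
    return lam0 + math.copysign(1.0, E - E0) * abs(lam - lam0) if E != E0 else lam0


def gene_total_score(
    assignment: GeneAssignment,
    locus: Locus,
    config: Mapping[str, str],
    distance_model: DistanceModel,
    feature_models: Mapping[str, FeatureModel],
    networks: Mapping[str, NetworkModel],
) -> GeneScore:
    """Score a candidate gene as the active gene of its locus.

    All other loci's active genes are frozen; the network components are
    evaluated on the active set with this gene substituted in.
    """
    active = {
        sym for lid, sym in config.items() if lid != locus.locus_id
    }
    active.add(assignment.gene.symbol)
    cat = categorical_contribution(assignment, feature_models)
    ppi = networks["ppi"].cached_score(active, network_score) if "ppi" in networks else 0.0
    gri = networks["gri"].cached_score(active, network_score) if "gri" in networks else 0.0
    return GeneScore(
        distance=distance_log_density(assignment.x, distance_model.gamma),
        mendelian=cat["mendelian"],
        exome=cat["exome"],
        coloc=cat["coloc"],
        ppi=ppi,
        gri=gri,
    )


def locus_weights(scores: Iterable[float]) -> np.ndarray:
    """Softmax of gene scores within one locus (max-subtracted)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("locus_weights requires at least one score")
    return softmax(arr)


def update_feature_counts(
    config: Mapping[str, str], locus_set: LocusSet
) -> dict[str, tuple[float, float, float, float]]:
    """Tally the active-by-feature 2x2 tables over genes in GWAS loci.

    Singleton Mendelian loci are excluded entirely.  For each feature the
    counts partition the G genes: n10 + n11 = L and n00 + n01 = G - L.
    """
    counts = {name: [0.0, 0.0, 0.0, 0.0] for name in FEATURES}  # n00,n01,n10,n11
    for locus in locus_set.gwas_loci:
        active_symbol = config[locus.locus_id]
        for ga in locus.member_genes:
            is_active = ga.gene.symbol == active_symbol
            for name in FEATURES:
                has = getattr(ga, _FLAG_ATTR[name])
                idx = 2 * int(is_active) + int(has)
                counts[name][idx] += 1.0
    return {name: tuple(c) for name, c in counts.items()}


def configuration_score(
    config: Mapping[str, str],
    locus_set: LocusSet,
    distance_model: DistanceModel,
    feature_models: Mapping[str, FeatureModel],
    networks: Mapping[str, NetworkModel],
) -> float:
    """Total score of a full configuration (network terms counted once).

    This is the objective the per-locus greedy updates ascend: the sum of
    active-gene distance and categorical terms plus one network score per
    network over the whole active set.
    """
    total = 0.0
    active: set[str] = set()
    for locus in locus_set.loci:
        sym = config[locus.locus_id]
        ga = next(g for g in locus.member_genes if g.gene.symbol == sym)
        active.add(sym)
        total += distance_log_density(ga.x, distance_model.gamma)
        total += sum(categorical_contribution(ga, feature_models).values())
    for net in networks.values():
        total += net.cached_score(active, network_score)
    return total
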