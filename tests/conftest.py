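"""Shared fixtures: compact builders for toy loci and networks."""

from __future__ import annotations

import numpy as np
import pytest

from signet.io_formats import GeneRecord, RunConfig, SnpRecord
from signet.locus_model import GeneAssignment, Locus, LocusSet
from signet.network_model import NetworkModel


def make_gene(symbol, chrom="chr1", strand="+", tss=1000, length=500):
    if strand == "+":
        return GeneRecord(symbol, chrom, strand, tss, tss, tss + length)
    return GeneRecord(symbol, chrom, strand, tss, tss - length, tss)


def toy_locus_set(spec, flank_D=250_000):
    """Build a LocusSet from a compact description.

    spec: list of loci; each locus is a list of gene tuples
    (symbol, x, flags) where flags is a string containing any of
    'm' (Mendelian), 'e' (exome), 'c' (colocalized).  A locus given as
    ("singleton", symbol) becomes a singleton Mendelian locus.
    """
    loci = []
    for i, locus_spec in enumerate(spec):
        if locus_spec and locus_spec[0] == "singleton":
            sym = locus_spec[1]
            locus_id = f"M{i:04d}_{sym}"
            ga = GeneAssignment(
                gene=make_gene(sym, chrom=f"chrM{i}"),
                locus_id=locus_id,
                x=0,
                has_mendelian=True,
                is_mindist=True,
            )
            loci.append(
                Locus(locus_id, [ga], snps=[], is_singleton_mendelian=True)
            )
            continue
        locus_id = f"L{i + 1:04d}"
        chrom = f"chr{i + 1}"
        snp = SnpRecord(f"rs{i}", chrom, 1_000_000, "T", 1e-9)
        gas = []
        for symbol, x, flags in locus_spec:
            gene = make_gene(symbol, chrom=chrom, strand="+", tss=snp.pos - x)
            gas.append(
                GeneAssignment(
                    gene=gene,
                    locus_id=locus_id,
                    x=x,
                    has_mendelian="m" in flags,
                    has_exome="e" in flags,
                    has_coloc="c" in flags,
                )
            )
        min(gas, key=lambda g: (abs(g.x), g.gene.symbol)).is_mindist = True
        loci.append(Locus(locus_id, gas, snps=[snp]))
    ls = LocusSet(loci=loci, flank_D=flank_D)
    ls.validate()
    return ls


def toy_network(edges, locus_set, directed=False):
    return NetworkModel(
        edges=set(edges),
        genes=locus_set.all_symbols(),
        n_loci=locus_set.L + locus_set.M,
        n_genes=locus_set.G + locus_set.M,
        directed=directed,
    )


def brute_force_optimum(locus_set, networks, pseudocount=1.0):
    """Exhaustive profile-likelihood oracle: enumerate every configuration,
    set the shared parameters to their MLE for it, and return the maximum
    total score.  Independent of the greedy sampler's search path."""
    import itertools

    from signet.sampler import update_parameters
    from signet.scoring import DistanceModel, configuration_score

    choices = []
    for locus in locus_set.loci:
        if locus.is_singleton_mendelian:
            choices.append([locus.member_genes[0].gene.symbol])
        else:
            choices.append([ga.gene.symbol for ga in locus.member_genes])
    ids = [l.locus_id for l in locus_set.loci]
    best = -np.inf
    for combo in itertools.product(*choices):
        config = dict(zip(ids, combo))
        dm, fms = update_parameters(config, locus_set, DistanceModel(), pseudocount)
        best = max(best, configuration_score(config, locus_set, dm, fms, networks))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def run_cfg():
    return RunConfig(n_runs=3, seed=7, max_passes=30)
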