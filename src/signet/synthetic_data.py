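"""Synthetic GWAS studies with planted causal genes.

The generator emulates the statistical structure the model assumes: one
genome-wide-significant SNP per locus; a planted causal gene whose signed
SNP-to-TSS distance follows a two-sided exponential with scale
gamma_true; decoy genes at uniform distances within the flank; sparse
evidence flags concentrated on planted genes; and PPI/GRI edges enriched
among the planted genes relative to a background rate.  Each synthetic
locus lives on its own chromosome so locus merging is exercised
separately with hand-built fixtures.

All files are written in the same tab-delimited dialects the readers
expect, and the same seed yields a byte-identical bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats, locus_model, network_model
from .io_formats import RunConfig

__all__ = ["SimConfig", "GroundTruth", "StudyBundle", "generate_study", "load_study", "recovery_experiment"]


@dataclass
class SimConfig:
    """Conditions of a synthetic study.

    Defaults mirror a cardiac-electrophysiology-sized analysis: ~226 GWAS
    loci with a handful of candidate genes each, a 250 kb flank, a 150 kb
    distance scale, rare evidence flags concentrated on causal genes, and
    network edges enriched among causal genes over a sparse background.
    """

    n_loci: int = 226
    genes_per_locus: int = 5
    flank_D: int = 250_000
    gamma_true: float = 150_000.0
    p_mendelian: float = 0.05
    p_exome: float = 0.05
    p_coloc: float = 0.15
    background_evidence_rate: float = 0.0
    planted_edge_prob: float = 0.05
    background_edge_prob: float = 0.002
    n_gri_edges: int = 40
    n_singleton_mendelian: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_mendelian",
            "p_exome",
            "p_coloc",
            "background_evidence_rate",
            "planted_edge_prob",
            "background_edge_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if self.genes_per_locus < 1:
            raise ValueError("genes_per_locus must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass
class GroundTruth:
    """Planted causal gene per locus and the true generative parameters."""

    planted: dict[str, str]  # chromosome -> planted gene symbol
    planted_genes: set[str]
    singleton_genes: set[str]
    gamma_true: float


@dataclass
class StudyBundle:
    """Paths of one generated study."""

    gwas: Path
    genes: Path
    ppi: Path
    gri: Path
    mendelian: Path
    exome: Path
    coloc: Path
    truth: Path


_SNP_POS = 10_000_000  # every synthetic SNP sits here on its own chromosome
_GENE_LEN = 20_000


def _two_sided_exponential(rng: np.random.Generator, scale: float) -> int:
    mag = rng.exponential(scale)
    sign = 1 if rng.random() < 0.5 else -1
    return int(round(sign * max(mag, 1.0)))


def _gene_record_fields(chrom: str, symbol: str, strand: str, x: int) -> tuple:
    # invert the signed-distance convention: x = pos - tss (+ strand),
    # x = tss - pos (- strand)
    if strand == "+":
        tss = _SNP_POS - x
        start, end = tss, tss + _GENE_LEN
    else:
        tss = _SNP_POS + x
        start, end = tss - _GENE_LEN, tss
    return (symbol, chrom, strand, start, end)


def generate_study(sim: SimConfig, out_dir: str | Path) -> tuple[StudyBundle, GroundTruth]:
    """Write a complete synthetic study to out_dir and return its truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)

    gene_rows: list[tuple] = []
    gwas_rows: list[tuple] = []
    planted: dict[str, str] = {}
    all_symbols: list[str] = []
    planted_symbols: list[str] = []
    mendelian: set[str] = set()
    exome: set[str] = set()
    coloc: set[str] = set()

    for i in range(sim.n_loci):
        chrom = f"chr{i + 1}"
        rsid = f"rs{i + 1:06d}"
        pval = 10 ** (-rng.uniform(8.0, 20.0))
        gwas_rows.append((rsid, chrom, _SNP_POS, "SIM", f"{pval:.3e}"))
        planted_sym = f"L{i + 1:04d}G00"
        strand = "+" if rng.random() < 0.5 else "-"
        x = _two_sided_exponential(rng, sim.gamma_true)
        gene_rows.append(_gene_record_fields(chrom, planted_sym, strand, x))
        planted[chrom] = planted_sym
        planted_symbols.append(planted_sym)
        all_symbols.append(planted_sym)
        if rng.random() < sim.p_mendelian:
            mendelian.add(planted_sym)
        if rng.random() < sim.p_exome:
            exome.add(planted_sym)
        if rng.random() < sim.p_coloc:
            coloc.add(planted_sym)
        for j in range(1, sim.genes_per_locus):
            sym = f"L{i + 1:04d}G{j:02d}"
            strand = "+" if rng.random() < 0.5 else "-"
            xj = 0
            while xj == 0:
                xj = int(round(rng.uniform(-sim.flank_D, sim.flank_D)))
            gene_rows.append(_gene_record_fields(chrom, sym, strand, xj))
            all_symbols.append(sym)
            for rate, bucket in (
                (sim.background_evidence_rate, mendelian),
                (sim.background_evidence_rate, exome),
                (sim.background_evidence_rate, coloc),
            ):
                if rng.random() < rate:
                    bucket.add(sym)

    singleton_genes: set[str] = set()
    for k in range(sim.n_singleton_mendelian):
        sym = f"MEND{k + 1:03d}"
        chrom = f"chrM{k + 1}"
        gene_rows.append((sym, chrom, "+", 1_000_000, 1_000_000 + _GENE_LEN))
        mendelian.add(sym)
        singleton_genes.add(sym)

    # network genes: planted genes at loci plus the always-active singletons
    enriched = sorted(planted_symbols) + sorted(singleton_genes)
    ppi_edges: set[tuple[str, str]] = set()
    for a_i in range(len(enriched)):
        for b_i in range(a_i + 1, len(enriched)):
            if rng.random() < sim.planted_edge_prob:
                a, b = enriched[a_i], enriched[b_i]
                ppi_edges.add((min(a, b), max(a, b)))
    # background applies to every pair that is not planted-planted, so the
    # planted pair rate is exactly planted_edge_prob
    universe = sorted(all_symbols) + sorted(singleton_genes)
    enriched_set = set(enriched)
    if sim.background_edge_prob > 0:
        n_all = len(universe) * (len(universe) - 1) // 2
        n_enriched = len(enriched) * (len(enriched) - 1) // 2
        n_bg = rng.binomial(n_all - n_enriched, sim.background_edge_prob)
        guard = 0
        while n_bg > 0 and guard < 100 * (n_bg + 100):
            guard += 1
            a, b = rng.choice(len(universe), size=2, replace=False)
            pair = (universe[min(a, b)], universe[max(a, b)])
            if pair[0] in enriched_set and pair[1] in enriched_set:
                continue
            if pair not in ppi_edges:
                ppi_edges.add(pair)
                n_bg -= 1

    gri_edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(gri_edges) < sim.n_gri_edges and attempts < 50 * (sim.n_gri_edges + 1):
        attempts += 1
        if len(enriched) < 2:
            break
        i, j = rng.choice(len(enriched), size=2, replace=False)
        gri_edges.add((enriched[i], enriched[j]))
    if sim.background_edge_prob > 0:
        n_bg = rng.binomial(
            len(universe) * (len(universe) - 1), sim.background_edge_prob / 2.0
        )
        guard = 0
        while n_bg > 0 and guard < 100 * (n_bg + 100):
            guard += 1
            i, j = rng.choice(len(universe), size=2, replace=False)
            edge = (universe[i], universe[j])
            if edge[0] in enriched_set and edge[1] in enriched_set:
                continue
            if edge not in gri_edges:
                gri_edges.add(edge)
                n_bg -= 1

    # -- write files (sorted -> byte-identical for a given seed) ------------
    gwas_path = out / "gwas.tsv"
    with gwas_path.open("w") as fh:
        fh.write("rsid\tchrom\tpos\ttrait\tpvalue\n")
        for row in gwas_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    genes_path = out / "genes.tsv"
    with genes_path.open("w") as fh:
        fh.write("symbol\tchrom\tstrand\tstart\tend\n")
        for row in sorted(gene_rows):
            fh.write("\t".join(str(v) for v in row) + "\n")
    ppi_path = out / "ppi.tsv"
    ppi_path.write_text("".join(f"{a}\t{b}\n" for a, b in sorted(ppi_edges)))
    gri_path = out / "gri.tsv"
    gri_path.write_text("".join(f"{a}\t{b}\n" for a, b in sorted(gri_edges)))
    mend_path = out / "mendelian.txt"
    mend_path.write_text("".join(f"{s}\n" for s in sorted(mendelian)))
    exome_path = out / "exome.txt"
    exome_path.write_text("".join(f"{s}\n" for s in sorted(exome)))
    coloc_path = out / "coloc.txt"
    coloc_path.write_text("".join(f"{s}\n" for s in sorted(coloc)))
    truth_path = out / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("chrom\tplanted_gene\n")
        for chrom in sorted(planted, key=lambda c: int(c[3:])):
            fh.write(f"{chrom}\t{planted[chrom]}\n")

    bundle = StudyBundle(
        gwas=gwas_path,
        genes=genes_path,
        ppi=ppi_path,
        gri=gri_path,
        mendelian=mend_path,
        exome=exome_path,
        coloc=coloc_path,
        truth=truth_path,
    )
    truth = GroundTruth(
        planted=planted,
        planted_genes=set(planted_symbols),
        singleton_genes=singleton_genes,
        gamma_true=sim.gamma_true,
    )
    return bundle, truth


def load_study(
    bundle: StudyBundle, cfg: RunConfig
) -> tuple[locus_model.LocusSet, dict[str, network_model.NetworkModel]]:
    """Read a generated bundle back through the standard readers and build
    the locus set and both network models."""
    snps = io_formats.read_gwas_associations(bundle.gwas, cfg)
    genes = io_formats.read_gene_annotation(bundle.genes)
    locus_set = locus_model.build_locus_set(snps, genes, cfg.flank_D)
    locus_model.attach_evidence(
        locus_set,
        io_formats.read_gene_list(bundle.mendelian),
        io_formats.read_gene_list(bundle.exome),
        io_formats.read_gene_list(bundle.coloc),
        genes,
    )
    networks = {
        "ppi": network_model.build_network_model(
            io_formats.read_edge_list(bundle.ppi, directed=False), locus_set, directed=False
        ),
        "gri": network_model.build_network_model(
            io_formats.read_edge_list(bundle.gri, directed=True), locus_set, directed=True
        ),
    }
    return locus_set, networks


def _recovery_rate(
    chosen: dict[str, str], locus_set: locus_model.LocusSet, truth: GroundTruth
) -> float:
    """Fraction of GWAS loci whose planted gene is a member and was chosen."""
    hits = 0
    total = 0
    for locus in locus_set.gwas_loci:
        members = {ga.gene.symbol for ga in locus.member_genes}
        locus_planted = members & truth.planted_genes
        if not locus_planted:
            continue  # planted gene fell outside the window
        total += 1
        if chosen[locus.locus_id] in locus_planted:
            hits += 1
    return hits / total if total else float("nan")


def recovery_experiment(
    sim: SimConfig,
    cfg: RunConfig,
    out_dir: str | Path,
    variants: tuple[str, ...] = ("signet", "mindist", "best_guess", "no_network", "shuffled"),
) -> dict[str, float]:
    """Generate a study and measure planted-gene recovery for each variant.

    Variants: 'signet' (full model), 'mindist', 'best_guess'
    (initialization only), 'no_network' (empty networks), 'shuffled'
    (degree-preserving network shuffle).
    """
    from . import sampler

    bundle, truth = generate_study(sim, out_dir)
    locus_set, networks = load_study(bundle, cfg)
    results: dict[str, float] = {}
    for variant in variants:
        if variant == "mindist":
            chosen = {
                l.locus_id: next(ga.gene.symbol for ga in l.member_genes if ga.is_mindist)
                for l in locus_set.loci
            }
        elif variant == "best_guess":
            rng = np.random.default_rng(cfg.seed)
            chosen = sampler.initialize_best_guess(locus_set, rng)
        else:
            if variant == "no_network":
                nets = {}
            elif variant == "shuffled":
                nets = {
                    name: net.shuffle_degree_preserving(cfg.seed + 17 + k)
                    for k, (name, net) in enumerate(sorted(networks.items()))
                }
            else:
                nets = networks
            summary = sampler.run_multi(locus_set, nets, cfg)
            chosen = summary.signet
        results[variant] = _recovery_rate(chosen, locus_set, truth)
    return results
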