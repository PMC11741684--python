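"""Locus construction from GWAS summary associations.

Each significant SNP defines a window of genes whose TSS lies within a
flank distance D; windows sharing a gene are merged transitively into a
locus.  Mendelian disease genes outside every GWAS locus become singleton
loci whose gene is permanently active.  Every gene carries a signed
distance x to the nearest locus SNP: negative when the SNP lies 5' of the
TSS on the gene's sense strand, positive when 3' or inside the gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .io_formats import GeneRecord, SnpRecord

__all__ = [
    "GeneAssignment",
    "Locus",
    "LocusSet",
    "EmptyChromosomeError",
    "snp_window",
    "merge_windows",
    "attach_evidence",
    "signed_distance",
    "build_locus_set",
]


class EmptyChromosomeError(ValueError):
    """A SNP sits on a chromosome with no annotated genes."""


@dataclass
class GeneAssignment:
    """A gene's membership in one locus, with evidence flags."""

    gene: GeneRecord
    locus_id: str
    x: int  # signed bp distance to nearest locus SNP; 0 for singletons
    has_mendelian: bool = False
    has_exome: bool = False
    has_coloc: bool = False
    is_mindist: bool = False

    @property
    def has_any_evidence(self) -> bool:
        return self.has_mendelian or self.has_exome or self.has_coloc


@dataclass
class Locus:
    locus_id: str
    member_genes: list[GeneAssignment]
    snps: list[SnpRecord]
    is_singleton_mendelian: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.member_genes)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"locus {self.locus_id} has no genes")
        if self.is_singleton_mendelian and (self.n_genes != 1 or self.snps):
            raise ValueError(
                f"singleton Mendelian locus {self.locus_id} must have exactly "
                "one gene and no SNPs"
            )


@dataclass
class LocusSet:
    """The L merged GWAS loci plus M singleton Mendelian loci."""

    loci: list[Locus]
    flank_D: int

    @property
    def gwas_loci(self) -> list[Locus]:
        return [l for l in self.loci if not l.is_singleton_mendelian]

    @property
    def singleton_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.is_singleton_mendelian]

    @property
    def L(self) -> int:
        return len(self.gwas_loci)

    @property
    def M(self) -> int:
        return len(self.singleton_loci)

    @property
    def G(self) -> int:
        return sum(l.n_genes for l in self.gwas_loci)

    def locus_by_id(self, locus_id: str) -> Locus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def all_symbols(self) -> set[str]:
        return {ga.gene.symbol for l in self.loci for ga in l.member_genes}

    def assignment(self, symbol: str) -> GeneAssignment:
        for l in self.loci:
            for ga in l.member_genes:
                if ga.gene.symbol == symbol:
                    return ga
        raise KeyError(symbol)

    def validate(self) -> None:
        """Check the partition invariants: no gene in two loci, G consistent."""
        seen: set[str] = set()
        for l in self.loci:
            for ga in l.member_genes:
                if ga.gene.symbol in seen:
                    raise ValueError(f"gene {ga.gene.symbol} appears in two loci")
                seen.add(ga.gene.symbol)
        assert self.G == sum(l.n_genes for l in self.gwas_loci)


def signed_distance(gene: GeneRecord, snps: list[SnpRecord]) -> int:
    """Signed distance of minimum magnitude from the gene's TSS to a SNP.

    Negative when the SNP is 5' of the TSS on the sense strand.
    """
    if not snps:
        raise ValueError("signed_distance requires at least one SNP")
    best = None
    for snp in snps:
        if snp.chrom != gene.chrom:
            continue
        if gene.strand == "+":
            d = snp.pos - gene.tss
        else:
            d = gene.tss - snp.pos
        if best is None or abs(d) < abs(best):
            best = d
    if best is None:
        raise ValueError("no SNP on the gene's chromosome")
    return best


def snp_window(snp: SnpRecord, genes: list[GeneRecord], D: int) -> list[GeneRecord]:
    """Genes whose TSS lies within D bp of the SNP (inclusive boundary).

    If no gene falls in the window, the single nearest-TSS gene on the
    chromosome is returned instead, so every SNP maps to at least one gene.
    """
    on_chrom = [g for g in genes if g.chrom == snp.chrom]
    if not on_chrom:
        raise EmptyChromosomeError(f"no genes annotated on chromosome {snp.chrom}")
    within = [g for g in on_chrom if abs(g.tss - snp.pos) <= D]
    if within:
        return sorted(within, key=lambda g: g.symbol)
    nearest = min(on_chrom, key=lambda g: (abs(g.tss - snp.pos), g.symbol))
    return [nearest]


def merge_windows(
    windows: list[tuple[SnpRecord, list[GeneRecord]]], flank_D: int
) -> LocusSet:
    """Aggregate SNP windows sharing at least one gene into loci.

    Transitive closure under the shared-gene relation (union-find); the
    result is independent of window order.  Loci never span chromosomes.
    """
    parent = list(range(len(windows)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    gene_to_window: dict[tuple[str, str], int] = {}
    for i, (snp, genes) in enumerate(windows):
        for g in genes:
            key = (g.chrom, g.symbol)
            if key in gene_to_window:
                union(i, gene_to_window[key])
            else:
                gene_to_window[key] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(windows)):
        groups.setdefault(find(i), []).append(i)

    # deterministic locus ids: order groups by (chrom, min SNP position)
    keyed = []
    for members in groups.values():
        snps = [windows[i][0] for i in members]
        anchor = min((s.chrom, s.pos, s.rsid) for s in snps)
        keyed.append((anchor, members))
    keyed.sort()

    loci: list[Locus] = []
    for idx, (_, members) in enumerate(keyed):
        locus_id = f"L{idx + 1:04d}"
        snp_seen: set[tuple[str, str, int]] = set()
        snps: list[SnpRecord] = []
        for i in members:
            s = windows[i][0]
            k = (s.rsid, s.chrom, s.pos)
            if k not in snp_seen:
                snp_seen.add(k)
                snps.append(s)
        snps.sort(key=lambda s: (s.chrom, s.pos, s.rsid, s.trait))
        genes: dict[str, GeneRecord] = {}
        for i in members:
            for g in windows[i][1]:
                genes[g.symbol] = g
        assignments = [
            GeneAssignment(gene=g, locus_id=locus_id, x=signed_distance(g, snps))
            for g in sorted(genes.values(), key=lambda g: g.symbol)
        ]
        mindist = min(assignments, key=lambda ga: (abs(ga.x), ga.gene.symbol))
        mindist.is_mindist = True
        loci.append(Locus(locus_id=locus_id, member_genes=assignments, snps=snps))
    ls = LocusSet(loci=loci, flank_D=flank_D)
    ls.validate()
    return ls


def attach_evidence(
    locus_set: LocusSet,
    mendelian: set[str],
    exome: set[str],
    coloc: set[str],
    annotation: list[GeneRecord],
) -> LocusSet:
    """Set evidence flags and create singleton loci for outside Mendelian genes.

    A Mendelian gene absent from every GWAS locus becomes its own
    single-gene locus with x = 0 and its gene permanently active.
    Evidence symbols missing from the annotation are warned about and
    skipped.
    """
    by_symbol = {g.symbol: g for g in annotation}
    in_loci = locus_set.all_symbols()
    for name, symbols in (("mendelian", mendelian), ("exome", exome), ("coloc", coloc)):
        unknown = sorted(s for s in symbols if s not in by_symbol and s not in in_loci)
        if unknown:
            warnings.warn(f"{name} evidence symbols not in annotation: {unknown}")
    for locus in locus_set.loci:
        for ga in locus.member_genes:
            sym = ga.gene.symbol
            ga.has_mendelian = sym in mendelian
            ga.has_exome = sym in exome
            ga.has_coloc = sym in coloc
    n_single = locus_set.M
    for sym in sorted(mendelian):
        if sym in in_loci or sym not in by_symbol:
            continue
        n_single += 1
        locus_id = f"M{n_single:04d}_{sym}"
        ga = GeneAssignment(
            gene=by_symbol[sym],
            locus_id=locus_id,
            x=0,
            has_mendelian=True,
            has_exome=sym in exome,
            has_coloc=sym in coloc,
            is_mindist=True,
        )
        locus_set.loci.append(
            Locus(
                locus_id=locus_id,
                member_genes=[ga],
                snps=[],
                is_singleton_mendelian=True,
            )
        )
        in_loci.add(sym)
    locus_set.validate()
    return locus_set


def build_locus_set(
    snps: list[SnpRecord], genes: list[GeneRecord], flank_D: int
) -> LocusSet:
    """Window every SNP (all traits pooled) and merge into a LocusSet."""
    windows = [(snp, snp_window(snp, genes, flank_D)) for snp in snps]
    return merge_windows(windows, flank_D)
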