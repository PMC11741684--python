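"""Readers and writers for the external file formats the tool touches.

All tables are plain tab-delimited text.  Column mapping is by header name
(case-insensitive, with common synonyms), not by position, because GWAS
summary exports differ across releases.  Coordinates are 1-based inclusive
throughout and distances are reported in base pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "SnpRecord",
    "GeneRecord",
    "RunConfig",
    "read_gwas_associations",
    "read_gene_annotation",
    "read_gene_list",
    "read_edge_list",
    "read_gmt",
    "write_summary_table",
    "read_summary_table",
    "write_parameter_log",
    "write_run_metadata",
]


class FormatError(ValueError):
    """A file violated its column or value contract."""


@dataclass(frozen=True)
class SnpRecord:
    """One genome-wide-significant association."""

    rsid: str
    chrom: str
    pos: int  # 1-based bp
    trait: str
    pvalue: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise FormatError("rsid must be non-empty")
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not 0.0 <= self.pvalue <= 1.0:
            raise FormatError(f"p-value must be in [0,1], got {self.pvalue}")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene.

    The TSS follows the maximal-gene-boundary convention: ``start`` for
    + strand genes, ``end`` for - strand genes.
    """

    symbol: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise FormatError(f"gene {self.symbol}: start > end")
        if not self.start <= self.tss <= self.end:
            raise FormatError(f"gene {self.symbol}: TSS outside gene bounds")


@dataclass
class RunConfig:
    """Run-level settings shared across the pipeline.

    flank_D
        Maximum SNP-to-TSS distance for locus membership, in bp.
    p_threshold
        Genome-wide significance cutoff on association p-values.
    n_runs
        Number of independent restarts of the greedy sampler.
    max_passes
        Cap on coordinate-ascent passes per run.
    pseudocount
        Additive smoothing for the categorical feature counts.
    init_mode
        'best_guess' (evidence priority, then nearest gene) or 'random'.
    """

    flank_D: int = 250_000
    p_threshold: float = 5e-8
    n_runs: int = 100
    max_passes: int = 100
    seed: int = 0
    pseudocount: float = 1.0
    init_mode: str = "best_guess"

    def __post_init__(self) -> None:
        if self.flank_D <= 0:
            raise ValueError("flank_D must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.init_mode not in ("best_guess", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


# Header synonyms, all matched case-insensitively after stripping
# non-alphanumeric characters.
_GWAS_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "rsid": ("rsid", "snp", "rsids", "variantid", "snps"),
    "chrom": ("chrom", "chr", "chromosome", "chrid"),
    "pos": ("pos", "position", "bp", "chrpos", "basepairlocation"),
    "trait": ("trait", "phenotype", "diseasetrait"),
    "pvalue": ("pvalue", "p", "pval"),
}

_GENE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "symbol": ("symbol", "gene", "genesymbol", "name"),
    "chrom": ("chrom", "chr", "chromosome"),
    "strand": ("strand",),
    "start": ("start", "genestart", "txstart"),
    "end": ("end", "geneend", "txend"),
}


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _resolve_columns(
    header: Sequence[str], spec: Mapping[str, tuple[str, ...]], path: Path
) -> dict[str, str]:
    canon_to_raw = {_canon(c): c for c in header}
    resolved: dict[str, str] = {}
    for target, synonyms in spec.items():
        for syn in synonyms:
            if syn in canon_to_raw:
                resolved[target] = canon_to_raw[syn]
                break
        else:
            raise FormatError(
                f"{path}: missing required column {target!r} "
                f"(accepted names: {', '.join(synonyms)})"
            )
    return resolved


def read_gwas_associations(path: str | Path, cfg: RunConfig) -> list[SnpRecord]:
    """Read a tab-delimited GWAS summary table and keep significant rows.

    Rows with p-value above ``cfg.p_threshold`` are dropped; duplicated
    (rsid, trait) rows are collapsed keeping the smallest p-value.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, _GWAS_COLUMNS, path)
    records: list[SnpRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            pos = int(row[cols["pos"]])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{line_no}: unparseable position {row[cols['pos']]!r}"
            ) from None
        try:
            pvalue = float(row[cols["pvalue"]])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{line_no}: unparseable p-value {row[cols['pvalue']]!r}"
            ) from None
        records.append(
            SnpRecord(
                rsid=str(row[cols["rsid"]]),
                chrom=str(row[cols["chrom"]]),
                pos=pos,
                trait=str(row[cols["trait"]]),
                pvalue=pvalue,
            )
        )
    records = [r for r in records if r.pvalue <= cfg.p_threshold]
    best: dict[tuple[str, str], SnpRecord] = {}
    for rec in records:
        key = (rec.rsid, rec.trait)
        if key not in best or rec.pvalue < best[key].pvalue:
            best[key] = rec
    # preserve first-occurrence order
    seen: set[tuple[str, str]] = set()
    out: list[SnpRecord] = []
    for rec in records:
        key = (rec.rsid, rec.trait)
        if key not in seen:
            seen.add(key)
            out.append(best[key])
    return out


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation table (symbol, chrom, strand, start, end).

    The TSS is derived from the strand (maximal gene boundary); duplicate
    symbols are collapsed to the widest bounds.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, _GENE_COLUMNS, path)
    merged: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2
        strand = str(row[cols["strand"]])
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{line_no}: strand must be '+' or '-', got {strand!r}")
        try:
            start = int(row[cols["start"]])
            end = int(row[cols["end"]])
        except (TypeError, ValueError):
            raise FormatError(f"{path}:{line_no}: unparseable gene bounds") from None
        symbol = str(row[cols["symbol"]])
        chrom = str(row[cols["chrom"]])
        if symbol in merged:
            prev = merged[symbol]
            if prev["chrom"] != chrom:
                warnings.warn(
                    f"{path}: gene {symbol} annotated on multiple chromosomes; "
                    f"keeping {prev['chrom']}"
                )
                continue
            prev["start"] = min(prev["start"], start)
            prev["end"] = max(prev["end"], end)
        else:
            merged[symbol] = {
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": end,
            }
    genes = []
    for symbol, g in merged.items():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        genes.append(
            GeneRecord(
                symbol=symbol,
                chrom=g["chrom"],
                strand=g["strand"],
                tss=tss,
                start=g["start"],
                end=g["end"],
            )
        )
    return genes


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line evidence gene list."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.add(sym.split("\t")[0])
    return out


def read_edge_list(path: str | Path, directed: bool) -> set[tuple[str, str]]:
    """Read a two-column TSV of gene-symbol pairs.

    Undirected mode stores each pair in sorted order; duplicates are
    collapsed and self-edges dropped in both modes.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{line_no}: expected at least 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            continue
        edges.add((a, b) if directed else (min(a, b), max(a, b)))
    return edges


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: set name, description, member symbols."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{line_no}: GMT rows need name, description, members")
        sets[fields[0]] = {f for f in fields[2:] if f}
    return sets


_SUMMARY_COLUMNS = [
    "locus_id",
    "gene",
    "distance_bp",
    "mendelian",
    "exome",
    "coloc",
    "mean_weight",
    "selection_frequency",
    "signet",
    "signet_plus",
    "mindist",
]


def summary_frame(run_summary, locus_set) -> pd.DataFrame:
    """Assemble the per-gene summary table as a DataFrame.

    One row per gene: locus, signed distance, evidence flags, mean weight,
    selection frequency, and indicator columns for the three gene lists.
    Rows are ordered by locus id, then |distance|, then symbol.
    """
    rows = []
    for locus in locus_set.loci:
        signet_gene = run_summary.signet.get(locus.locus_id)
        plus = set(run_summary.signet_plus.get(locus.locus_id, []))
        for ga in locus.member_genes:
            sym = ga.gene.symbol
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "gene": sym,
                    "distance_bp": ga.x,
                    "mendelian": int(ga.has_mendelian),
                    "exome": int(ga.has_exome),
                    "coloc": int(ga.has_coloc),
                    "mean_weight": round(run_summary.mean_weight.get(sym, 0.0), 6),
                    "selection_frequency": round(
                        run_summary.selection_frequency.get(sym, 0.0), 6
                    ),
                    "signet": int(sym == signet_gene),
                    "signet_plus": int(sym in plus),
                    "mindist": int(ga.is_mindist),
                }
            )
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    if len(df):
        df = df.assign(_absx=df["distance_bp"].abs())
        df = df.sort_values(["locus_id", "_absx", "gene"]).drop(columns="_absx")
        df = df.reset_index(drop=True)
    return df


def write_summary_table(run_summary, locus_set, path: str | Path) -> None:
    """Write the per-gene summary table as TSV (re-readable bit-identically)."""
    summary_frame(run_summary, locus_set).to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing summary columns {missing}")
    return df


def write_parameter_log(run_records: Iterable, path: str | Path) -> None:
    """Write one row per run: seed, passes, convergence, final parameters."""
    rows = []
    for rec in run_records:
        row = {
            "run": rec.run_index,
            "seed": rec.seed,
            "passes": rec.passes,
            "converged": int(rec.converged),
            "gamma": rec.gamma,
        }
        for name, score in rec.feature_scores.items():
            row[f"S_{name}"] = score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_run_metadata(path: str | Path, cfg: RunConfig, **extra) -> None:
    import signet

    meta = {
        "signet_version": signet.__version__,
        "config": {
            "flank_D": cfg.flank_D,
            "p_threshold": cfg.p_threshold,
            "n_runs": cfg.n_runs,
            "max_passes": cfg.max_passes,
            "seed": cfg.seed,
            "pseudocount": cfg.pseudocount,
            "init_mode": cfg.init_mode,
        },
    }
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
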