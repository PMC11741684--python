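"""Degree-corrected network models over the locus genes.

The PPI network is undirected; the gene-regulatory network is directed
(TF -> target).  Edges are restricted to genes that belong to a locus;
degrees and the normalized-degree weights delta are computed on that
restricted network.  delta_i = d_i / (2 E_tot) for undirected networks,
and delta'_in = d'_in / E'_tot, delta'_out = d'_out / E'_tot for directed
ones, so that the degree-corrected probability of an (unordered or
ordered) edge between active genes i, j is delta_i * delta_j.

The expected edge count E0 among an active gene set is the sum of these
pairwise probabilities, computed in factorized form:

    E0  = 1/2 (sum delta)^2 - 1/2 sum delta^2          (undirected)
    E0' = (sum delta_in)(sum delta_out) - sum delta_in delta_out  (directed)

The total pair count T, which only shifts scores by a constant within a
run, is (L+M)(L+M-1)/2 for the undirected network (pairs of active genes,
one per locus) and (G+M)(G+M-1) for the directed network (ordered pairs
over all genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .locus_model import LocusSet

__all__ = ["NetworkModel", "EdgeCountResult", "build_network_model"]


@dataclass(frozen=True)
class EdgeCountResult:
    E: int
    E0: float


class NetworkModel:
    """Holds one network (PPI or GRI) restricted to locus genes."""

    def __init__(
        self,
        edges: set[tuple[str, str]],
        genes: set[str],
        n_loci: int,
        n_genes: int,
        directed: bool,
    ):
        self.directed = directed
        self.genes = set(genes)
        self.n_loci = n_loci
        self.n_genes = n_genes
        self._cache: dict[frozenset, float] = {}

        restricted: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b or a not in self.genes or b not in self.genes:
                continue
            restricted.add((a, b) if directed else (min(a, b), max(a, b)))
        self.edges = restricted
        self.E_tot = len(restricted)

        if directed:
            self.out_adj: dict[str, set[str]] = {}
            self.in_adj: dict[str, set[str]] = {}
            for src, tgt in restricted:
                self.out_adj.setdefault(src, set()).add(tgt)
                self.in_adj.setdefault(tgt, set()).add(src)
            self.d_out = {g: len(s) for g, s in self.out_adj.items()}
            self.d_in = {g: len(s) for g, s in self.in_adj.items()}
            if self.E_tot:
                self.delta_in = {g: d / self.E_tot for g, d in self.d_in.items()}
                self.delta_out = {g: d / self.E_tot for g, d in self.d_out.items()}
            else:
                self.delta_in, self.delta_out = {}, {}
            self.T = n_genes * (n_genes - 1)
        else:
            self.adj: dict[str, set[str]] = {}
            for a, b in restricted:
                self.adj.setdefault(a, set()).add(b)
                self.adj.setdefault(b, set()).add(a)
            self.d = {g: len(s) for g, s in self.adj.items()}
            if self.E_tot:
                self.delta = {g: d / (2 * self.E_tot) for g, d in self.d.items()}
            else:
                self.delta = {}
            self.T = n_loci * (n_loci - 1) // 2

    # -- degree bookkeeping -------------------------------------------------

    def degree(self, gene: str) -> int:
        if self.directed:
            return self.d_in.get(gene, 0) + self.d_out.get(gene, 0)
        return self.d.get(gene, 0)

    # -- edge counting ------------------------------------------------------

    def count_active_edges(self, active: Iterable[str]) -> int:
        """Observed edges among the active genes (self-edges excluded)."""
        aset = set(active)
        if self.directed:
            return sum(
                len(self.out_adj[g] & aset) for g in aset if g in self.out_adj
            )
        twice = sum(len(self.adj[g] & aset) for g in aset if g in self.adj)
        return twice // 2

    def expected_active_edges(self, active: Iterable[str]) -> float:
        """Expected edges among the active genes under the degree-corrected null."""
        aset = set(active)
        if self.directed:
            din = np.array([self.delta_in.get(g, 0.0) for g in aset])
            dout = np.array([self.delta_out.get(g, 0.0) for g in aset])
            return float(din.sum() * dout.sum() - (din * dout).sum())
        d = np.array([self.delta.get(g, 0.0) for g in aset])
        s = d.sum()
        return float(0.5 * s * s - 0.5 * (d * d).sum())

    def expected_active_edges_pairwise(self, active: Iterable[str]) -> float:
        """O(n^2) double-sum evaluation of E0, kept as a cross-check."""
        genes = sorted(set(active))
        total = 0.0
        if self.directed:
            for i in genes:
                for j in genes:
                    if i != j:
                        total += self.delta_in.get(i, 0.0) * self.delta_out.get(j, 0.0)
        else:
            for a in range(len(genes)):
                for b in range(a + 1, len(genes)):
                    total += self.delta.get(genes[a], 0.0) * self.delta.get(
                        genes[b], 0.0
                    )
        return total

    def edge_counts(self, active: Iterable[str]) -> EdgeCountResult:
        aset = set(active)
        return EdgeCountResult(
            E=self.count_active_edges(aset), E0=self.expected_active_edges(aset)
        )

    # -- score caching ------------------------------------------------------

    def cache_key(self, active: Iterable[str]) -> frozenset:
        """Active genes with nonzero degree; zero-degree genes cannot change
        E or E0, so they are dropped from the key."""
        return frozenset(g for g in active if self.degree(g) > 0)

    def cached_score(
        self, active: Iterable[str], score_fn: Callable[[int, float, int], float]
    ) -> float:
        """Evaluate score_fn(E, E0, T) with memoization on the active set."""
        key = self.cache_key(active)
        if key in self._cache:
            return self._cache[key]
        value = score_fn(self.count_active_edges(key), self.expected_active_edges(key), self.T)
        self._cache[key] = value
        return value

    @property
    def cache_size(self) -> int:
        return len(self._cache)

    # -- randomization ------------------------------------------------------

    def shuffle_degree_preserving(self, seed: int) -> "NetworkModel":
        """Configuration-model resample preserving the degree sequence.

        Stub matching: each vertex contributes one stub per edge endpoint;
        stubs are paired at random.  Self-edges and multi-edges arising
        from the matching are dropped afterwards (standard practice; the
        degree sequence of the sampled multigraph equals the original
        exactly before this collapse).
        """
        rng = np.random.default_rng(seed)
        if self.directed:
            out_stubs: list[str] = []
            in_stubs: list[str] = []
            for g in sorted(self.d_out):
                out_stubs.extend([g] * self.d_out[g])
            for g in sorted(self.d_in):
                in_stubs.extend([g] * self.d_in[g])
            in_stubs = list(np.array(in_stubs)[rng.permutation(len(in_stubs))]) if in_stubs else []
            edges = {
                (src, tgt)
                for src, tgt in zip(out_stubs, in_stubs)
                if src != tgt
            }
        else:
            stubs: list[str] = []
            for g in sorted(self.d):
                stubs.extend([g] * self.d[g])
            order = rng.permutation(len(stubs))
            shuffled = [stubs[i] for i in order]
            edges = set()
            for k in range(0, len(shuffled) - 1, 2):
                a, b = shuffled[k], shuffled[k + 1]
                if a != b:
                    edges.add((min(a, b), max(a, b)))
        return NetworkModel(
            edges, self.genes, self.n_loci, self.n_genes, self.directed
        )


def build_network_model(
    edges: set[tuple[str, str]], locus_set: LocusSet, directed: bool
) -> NetworkModel:
    """Restrict an edge list to the locus genes and precompute degrees."""
    return NetworkModel(
        edges=edges,
        genes=locus_set.all_symbols(),
        n_loci=locus_set.L + locus_set.M,
        n_genes=locus_set.G + locus_set.M,
        directed=directed,
    )
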