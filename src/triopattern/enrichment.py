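"""Hypergeometric over-representation analysis of gene lists.

Given a query gene list (e.g. one hybrid's specific genes) and a collection
of annotated gene sets over a background universe of N genes, each set with
K members is scored by the upper-tail hypergeometric probability of seeing
at least the observed overlap k in a query of size n:

    p = P[X >= k],  X ~ Hypergeom(N, K, n)

computed in log space from log-gamma terms.  p values for all sets hit by
the query (k >= 1) form one multiple-testing family and are adjusted by
Benjamini-Hochberg; sets with adjusted q <= 0.05 are flagged significant.
Only over-representation is tested.  Annotations are consumed as flat files
(GMT or a two-column gene/set TSV); any ontology-graph propagation is
assumed to be pre-applied in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    """Raised on inputs that violate the enrichment contract."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Annotated gene sets restricted to an explicit background universe.

    Members outside the universe are dropped at construction; the count of
    dropped members is kept in ``n_dropped``.
    """

    sets: dict[str, GeneSet]
    universe: frozenset[str]
    n_dropped: int = 0

    @classmethod
    def from_sets(
        cls, raw: dict[str, tuple[str, Iterable[str]]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise EnrichmentError("empty universe")
        sets = {}
        dropped = 0
        for set_id, (name, genes) in raw.items():
            g = frozenset(genes)
            dropped += len(g - uni)
            kept = g & uni
            sets[set_id] = GeneSet(set_id=set_id, name=name, genes=kept)
        return cls(sets=sets, universe=uni, n_dropped=dropped)

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str]) -> "GeneSetCollection":
        """Read GMT (tab-separated: set_id, description, member genes...)."""
        raw: dict[str, tuple[str, list[str]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise EnrichmentError(f"{path}: GMT line with fewer than 3 fields")
            raw[fields[0]] = (fields[1], fields[2:])
        return cls.from_sets(raw, universe)

    @classmethod
    def from_long_tsv(cls, path, universe: Iterable[str]) -> "GeneSetCollection":
        """Read a two-column long table with header ``gene_id<TAB>set_id``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "set_id"} <= set(df.columns):
            raise EnrichmentError(f"{path}: need columns gene_id, set_id")
        raw = {
            sid: (sid, list(genes))
            for sid, genes in df.groupby("set_id")["gene_id"]
        }
        return cls.from_sets(raw, universe)


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    k: int  # query genes in the set
    n: int  # query size
    K: int  # universe genes in the set
    N: int  # universe size
    p_value: float
    fdr: float
    fold_enrichment: float
    significant: bool


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts annotated genes in a draw of n from a universe of N genes of
    which K are annotated.  The tail is summed in log space (log-gamma
    binomials + logsumexp) so small p values keep full relative precision.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise EnrichmentError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    if k > min(n, K):  # unreachable via the bounds check, kept for clarity
        return 0.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = (
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, aligned with the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise EnrichmentError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every gene set hit by the query; BH-adjust; sort by p ascending.

    Query genes outside the universe are dropped (the paper-style background
    is explicit); sets with zero overlap are omitted from the results and
    from the multiple-testing family.
    """
    if not collection.sets:
        raise EnrichmentError("empty gene-set collection")
    q = set(query) & collection.universe
    n = len(q)
    N = len(collection.universe)

    hits = []
    for set_id in sorted(collection.sets):
        gs = collection.sets[set_id]
        k = len(q & gs.genes)
        if k == 0:
            continue
        K = len(gs.genes)
        p = hypergeom_test(k, n, K, N)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        hits.append((gs, k, K, p, fold))

    qvals = bh_fdr([h[3] for h in hits])
    results = [
        EnrichmentResult(
            set_id=gs.set_id,
            name=gs.name,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            fdr=float(fdr),
            fold_enrichment=fold,
            significant=bool(fdr <= fdr_threshold),
        )
        for (gs, k, K, p, fold), fdr in zip(hits, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_id, r.name, r.k, r.n, r.K, r.N, r.p_value, r.fdr,
             r.fold_enrichment, r.significant)
            for r in results
        ],
        columns=["set_id", "name", "k", "n", "K", "N", "p", "fdr",
                 "fold_enrichment", "significant"],
    )
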