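"""Hypergeometric over-representation screening of predicted target sets.

The second layer of the pipeline checks that a predicted target set is
functionally coherent: each annotation term (GO/KEGG-style gene set) is
scored by the upper-tail hypergeometric probability of observing at least
the seen number of query hits, and terms with raw P < alpha (default 0.01)
are flagged as selected. No multiple-testing correction enters the
selection; a Benjamini–Hochberg column is emitted alongside for inspection.

The annotation universe defaults to all genes annotated in the loaded
database — an explicit, configurable stand-in for the tool-defined
backgrounds of web enrichment services.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationDB:
    """Flat term → member-set annotations over an explicit universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")
            if not members <= self.universe:
                raise ValueError(f"term {tid!r} has members outside the universe")

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "AnnotationDB":
        """Read GMT (term_id <TAB> term_name <TAB> member...).

        When ``universe`` is omitted it is the union of all term members.
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            tid, name, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
            terms[tid] = (name, members)
        if universe is None:
            uni = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
        else:
            uni = frozenset(universe)
        return cls(terms=terms, universe=uni)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.terms):
                name, members = self.terms[tid]
                fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics."""

    term_id: str
    term_name: str
    k: int  # hits in query
    K: int  # term size
    n: int  # annotatable query size
    N: int  # universe size
    p_value: float
    bh_q: float = float("nan")
    selected: bool = False


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Evaluated through the survival function of the hypergeometric
    distribution, which works in log space internally; ``k = 0`` returns
    exactly 1.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    db: AnnotationDB,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Score every annotation term against a query gene set.

    Only terms with at least one query hit are reported; results are sorted
    by p ascending (ties by term id) and flagged ``selected`` when
    ``p < alpha``. Query ids outside the universe are ignored; an empty
    intersection yields an empty result with a warning.
    """
    qset = set(query) & db.universe
    if not qset:
        logger.warning("query has no overlap with the annotation universe")
        return []
    N = len(db.universe)
    n = len(qset)
    results: list[tuple[str, str, int, int, float]] = []
    for tid in sorted(db.terms):
        name, members = db.terms[tid]
        k = len(qset & members)
        if k == 0:
            continue
        p = hypergeom_upper(k, len(members), n, N)
        results.append((tid, name, k, len(members), p))
    results.sort(key=lambda r: (r[4], r[0]))

    pvals = np.array([r[4] for r in results])
    qvals = _benjamini_hochberg(pvals)
    return [
        EnrichmentResult(
            term_id=tid, term_name=name, k=k, K=K, n=n, N=N,
            p_value=p, bh_q=float(q), selected=bool(p < alpha),
        )
        for (tid, name, k, K, p), q in zip(results, qvals)
    ]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_value": r.p_value, "bh_q": r.bh_q, "selected": r.selected,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "bh_q", "selected"],
    )
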