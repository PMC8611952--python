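"""Per-compound over-representation analysis of functional terms.

For every compound, the set of protein entries it is bioactive on is
tested against GO, pathway (KEGG) and disease-ontology term memberships
with the one-sided hypergeometric tail, exactly as classical
over-representation tools do.  Only terms sharing at least
``min_term_overlap`` proteins with the compound (two by default) are
tested; raw p-values are Bonferroni-adjusted within each compound and
namespace, and calls are significant below the adjusted cutoff (0.1 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .config import PipelineConfig
from .records import AnnotationMap


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested (compound, term) pair.

    ``k`` of the compound's ``n`` annotated proteins fall in the term's
    ``K`` members out of the ``N``-protein universe.
    """

    molecule_id: str
    term_id: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a random size-``n`` draw from a universe of
    ``N`` proteins, ``K`` of which carry the annotation, contains at
    least ``k`` annotated ones.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function is P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: p -> min(1, p * m) for a family of m tests."""
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than the number of p-values")
    out = []
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(min(1.0, p * m))
    return out


def enrich_compound(
    molecule_id: str,
    targets: Iterable[str],
    annotations: Sequence[AnnotationMap],
    cfg: PipelineConfig,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test one compound's target set against one namespace's terms.

    The universe defaults to every protein annotated to any term of the
    given collection (the annotated-universe convention of standard
    enrichment tools); pass ``universe`` to widen it to e.g. all network
    proteins.  Returns results sorted by adjusted p-value; compounds with
    fewer than ``min_term_overlap`` annotated targets yield no results.
    """
    if universe is None:
        universe_set: set[str] = set()
        for ann in annotations:
            universe_set |= ann.members
    else:
        universe_set = set(universe)
    target_set = set(targets) & universe_set
    n = len(target_set)
    N = len(universe_set)
    tested = []
    for ann in annotations:
        members = ann.members & universe_set
        k = len(target_set & members)
        if k < cfg.min_term_overlap:
            continue
        tested.append((ann, k, len(members)))
    if not tested:
        return []
    m = len(tested)
    results = []
    for ann, k, K in tested:
        p_raw = hypergeom_upper_tail(k, n, K, N)
        p_adj = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(
                molecule_id=molecule_id,
                term_id=ann.term_id,
                term_name=ann.term_name,
                namespace=ann.namespace,
                k=k,
                n=n,
                K=K,
                N=N,
                p_raw=p_raw,
                p_adj=p_adj,
                significant=p_adj < cfg.p_cutoff,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return results


def enrich_library(
    molecule_targets: Mapping[str, set[str]],
    annotations: Sequence[AnnotationMap],
    cfg: PipelineConfig,
) -> list[EnrichmentResult]:
    """Run per-compound enrichment for every namespace present.

    Families are adjusted separately per compound and namespace.
    """
    by_namespace: dict[str, list[AnnotationMap]] = {}
    for ann in annotations:
        by_namespace.setdefault(ann.namespace, []).append(ann)
    results: list[EnrichmentResult] = []
    for molecule_id in sorted(molecule_targets):
        for ns in sorted(by_namespace):
            results.extend(
                enrich_compound(
                    molecule_id,
                    molecule_targets[molecule_id],
                    by_namespace[ns],
                    cfg,
                )
            )
    return results


def results_table(results: Sequence[EnrichmentResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "namespace": r.namespace,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "molecule_id", "term_id", "term_name", "namespace",
            "k", "n", "K", "N", "p_raw", "p_adj", "significant",
        ],
    )
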