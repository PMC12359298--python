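"""Stage 3: over-representation analysis and transaction construction.

Each per-direction target-gene set is tested against every pathway of a
gene-set library with the one-sided hypergeometric (Fisher) test: given a
universe of N genes of which K lie in the pathway, the p-value of an
overlap of k genes out of an n-gene query is P(X >= k) for
X ~ Hypergeom(N, K, n).  P-values are Benjamini-Hochberg adjusted across
the library.  Significant pathways not matching any exclusion keyword
(disease categories foreign to the study question: infections, rheumatic
disease, cancer, cell cycle) become the *transactions* for itemset mining,
each carrying its overlap with the query.

Defaults: ``adj_threshold = 1e-5`` (pathways with adjusted p up to E-05);
transactions carry overlap genes (query ∩ pathway) rather than the full
pathway membership — both are supported via ``transaction_genes``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Pathway-name substrings excluded by default (case-insensitive).
DEFAULT_EXCLUSION_KEYWORDS = (
    "infection", "infectious", "rheumat", "cancer", "carcinoma",
    "leukemia", "melanoma", "cell cycle", "cell_cycle",
)

DEFAULT_ADJ_THRESHOLD = 1e-5


@dataclass
class GeneSetLibrary:
    """A named pathway -> gene-set mapping with a background universe size."""

    name: str
    pathways: dict[str, frozenset[str]]
    universe_size: int | None = None

    def __post_init__(self):
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")
        union = self.gene_union()
        if self.universe_size is None:
            self.universe_size = len(union)
        elif self.universe_size < len(union):
            raise ValidationError(
                f"universe_size {self.universe_size} smaller than the union "
                f"of library genes ({len(union)})")

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap_genes: frozenset[str]
    k: int  # overlap size
    K: int  # pathway size
    n: int  # effective query size
    N: int  # universe size
    p_value: float
    adj_p: float = 1.0

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValidationError(
                f"overlap {self.k} exceeds min(K={self.K}, n={self.n})")


@dataclass
class TransactionDB:
    """Ordered (pathway id, gene set) pairs mined as market baskets."""

    transactions: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self):
        ids = [pid for pid, _ in self.transactions]
        if len(ids) != len(set(ids)):
            raise ValidationError("transaction pathway ids are not unique")

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.transactions:
            out |= genes
        return frozenset(out)


def enrich(query: set[str], library: GeneSetLibrary,
           universe_size: int | None = None) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in every pathway.

    Query genes outside the library's gene union are dropped (count logged).
    Results cover all pathways, including k = 0 overlaps (p = 1), and carry
    BH-adjusted p-values across the whole library.
    """
    if not query:
        raise ValidationError("query gene set is empty")
    union = library.gene_union()
    effective = frozenset(query) & union
    dropped = len(query) - len(effective)
    if dropped:
        logger.info("enrich: dropped %d/%d query genes outside the %s universe",
                    dropped, len(query), library.name)
    if not effective:
        raise ValidationError(
            "no query gene lies in the library universe; nothing to test")

    N = universe_size if universe_size is not None else library.universe_size
    if N < len(union):
        raise ValidationError(
            f"universe_size {N} smaller than library gene union {len(union)}")
    n = len(effective)

    results = []
    for pid in sorted(library.pathways):
        genes = library.pathways[pid]
        overlap = effective & genes
        k, K = len(overlap), len(genes)
        # upper tail P(X >= k); k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0) or 5e-324  # clamp; keep p in (0, 1]
        results.append(EnrichmentResult(
            pathway_id=pid, overlap_genes=overlap, k=k, K=K, n=n, N=N,
            p_value=p))

    adjusted = bh_adjust([r.p_value for r in results])
    return [
        EnrichmentResult(pathway_id=r.pathway_id, overlap_genes=r.overlap_genes,
                         k=r.k, K=r.K, n=r.n, N=r.N, p_value=r.p_value,
                         adj_p=adj)
        for r, adj in zip(results, adjusted)
    ]


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-aligned with the input."""
    if not p_values:
        return []
    for p in p_values:
        if not (0 < p <= 1):
            raise ValidationError(f"p-value outside (0,1]: {p}")
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(a) for a in adj]


def filter_pathways(results: list[EnrichmentResult],
                    adj_threshold: float = DEFAULT_ADJ_THRESHOLD,
                    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS,
                    transaction_genes: str = "overlap",
                    library: GeneSetLibrary | None = None) -> TransactionDB:
    """Significance cut + keyword exclusion -> mining transactions.

    Keeps results with adj_p <= ``adj_threshold`` whose pathway id contains
    no exclusion keyword (case-insensitive substring), ordered by ascending
    adj_p with ties broken by pathway id.  ``transaction_genes`` selects
    whether a transaction carries the overlap genes ("overlap") or the full
    pathway membership ("full", requires ``library``).
    """
    if not (0 < adj_threshold < 1):
        raise ValidationError(f"adj_threshold must be in (0,1): {adj_threshold}")
    if transaction_genes not in ("overlap", "full"):
        raise ValidationError(
            f"transaction_genes must be 'overlap' or 'full': {transaction_genes!r}")
    if transaction_genes == "full" and library is None:
        raise ValidationError("transaction_genes='full' requires the library")
    keywords = tuple(k.lower() for k in exclusion_keywords)

    kept = []
    for r in results:
        if r.adj_p > adj_threshold:
            continue
        pid_lower = r.pathway_id.lower()
        hit = next((kw for kw in keywords if kw in pid_lower), None)
        if hit is not None:
            logger.info("filter_pathways: excluded %s (keyword %r)",
                        r.pathway_id, hit)
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.adj_p, r.pathway_id))

    transactions = []
    for r in kept:
        genes = (r.overlap_genes if transaction_genes == "overlap"
                 else library.pathways[r.pathway_id])
        if genes:
            transactions.append((r.pathway_id, frozenset(genes)))
    return TransactionDB(transactions=transactions)
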