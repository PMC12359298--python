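"""Stage 4: Apriori mining of gene combinations across enriched pathways.

Each enriched pathway is a transaction and each gene an item.  The support
of a gene set is the fraction of transactions containing every gene of the
set; by anti-monotonicity a superset is never more frequent than its
subsets, which is what the level-wise Apriori search exploits.

Two thresholds govern the search, following the two-stage rule of the
analysis this package implements:

* ``min_item_support`` prunes *individual genes* (0.40 for the pathways of
  downregulated miRNAs, 0.15 for upregulated — pair supports near 0.25-0.29
  on the down set are only consistent with gene-level pruning, since a
  0.40 floor on pairs would empty the output);
* ``min_rule_support`` (default 0.01) is the floor for itemsets of size
  >= 2 and for association rules.

Supports are kept as exact rationals (count / n_transactions); 4-decimal
half-up rounding happens only at the reporting boundary, so float drift
can never reorder results.  Pathways are ranked by the arithmetic mean of
their genes' individual supports computed over the full, unpruned database.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import chain, combinations

from .enrichment import TransactionDB
from .errors import ValidationError

DEFAULT_MIN_RULE_SUPPORT = Fraction(1, 100)
DEFAULT_MIN_ITEM_SUPPORT_UP = Fraction(15, 100)
DEFAULT_MIN_ITEM_SUPPORT_DOWN = Fraction(40, 100)
DEFAULT_CANDIDATE_CEILING = 2_000_000


def render_support(support: Fraction, places: int = 4) -> str:
    """Round-half-up decimal rendering used in all report tables."""
    d = decimal.Decimal(support.numerator) / decimal.Decimal(support.denominator)
    q = decimal.Decimal(1).scaleb(-places)
    return str(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ItemsetSupport:
    itemset: frozenset[str]
    count: int
    support: Fraction

    def __post_init__(self):
        if not self.itemset:
            raise ValidationError("itemset is empty")
        if self.count < 0:
            raise ValidationError("count is negative")
        if not 0 <= self.support <= 1:
            raise ValidationError(f"support outside [0,1]: {self.support}")

    def sort_key(self):
        return (-self.support, len(self.itemset), tuple(sorted(self.itemset)))


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: Fraction
    confidence: Fraction

    def __post_init__(self):
        if self.antecedent & self.consequent:
            raise ValidationError("rule antecedent and consequent overlap")
        if not (0 <= self.confidence <= 1):
            raise ValidationError(f"confidence outside [0,1]: {self.confidence}")

    def sort_key(self):
        return (-self.support, -self.confidence,
                tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))


@dataclass(frozen=True)
class PathwayScore:
    pathway_id: str
    score: Fraction
    rank: int
    gene_supports: tuple[tuple[str, Fraction], ...]


@dataclass
class MiningParams:
    """Thresholds for the level-wise search.

    ``min_item_support`` applies to single genes, ``min_rule_support`` to
    itemsets of size >= 2 and to rules; invariant
    0 < min_rule_support <= min_item_support <= 1.
    """

    min_item_support: Fraction = DEFAULT_MIN_ITEM_SUPPORT_UP
    min_rule_support: Fraction = DEFAULT_MIN_RULE_SUPPORT
    max_itemset_size: int | None = None
    candidate_ceiling: int = DEFAULT_CANDIDATE_CEILING

    def __post_init__(self):
        self.min_item_support = Fraction(self.min_item_support).limit_denominator(10**9)
        self.min_rule_support = Fraction(self.min_rule_support).limit_denominator(10**9)
        if not (0 < self.min_rule_support <= self.min_item_support <= 1):
            raise ValidationError(
                "need 0 < min_rule_support <= min_item_support <= 1, got "
                f"{self.min_rule_support} / {self.min_item_support}")
        if self.max_itemset_size is not None and self.max_itemset_size < 1:
            raise ValidationError("max_itemset_size must be >= 1")


def support(itemset: frozenset[str] | set[str],
            db: TransactionDB) -> ItemsetSupport:
    """Exact support of one itemset: |{t : itemset ⊆ t}| / |db|."""
    items = frozenset(itemset)
    if not items:
        raise ValidationError("support of an empty itemset is undefined")
    if db.n_transactions == 0:
        raise ValidationError("transaction database is empty")
    count = sum(1 for _, genes in db.transactions if items <= genes)
    return ItemsetSupport(itemset=items, count=count,
                          support=Fraction(count, db.n_transactions))


def _counts(db: TransactionDB, candidates: list[frozenset[str]]) -> dict:
    out = {c: 0 for c in candidates}
    for _, genes in db.transactions:
        for c in candidates:
            if c <= genes:
                out[c] += 1
    return out


def apriori(db: TransactionDB, params: MiningParams) -> list[ItemsetSupport]:
    """Level-wise frequent-itemset search with gene-level pruning.

    Level 1 keeps genes with support >= ``min_item_support``.  Level k >= 2
    joins frequent (k-1)-itemsets sharing k-2 items, discards candidates
    with any infrequent (k-1)-subset (anti-monotone pruning) and keeps
    those with support >= ``min_rule_support``.  Iteration stops when no
    candidate survives.  Output sorted by (descending support, ascending
    size, lexicographic items).
    """
    if db.n_transactions == 0:
        raise ValidationError("transaction database is empty")
    n = db.n_transactions

    gene_counts: dict[str, int] = {}
    for _, genes in db.transactions:
        for g in genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1

    frequent: list[ItemsetSupport] = []
    level: dict[frozenset[str], int] = {}
    for g, c in gene_counts.items():
        if Fraction(c, n) >= params.min_item_support:
            level[frozenset([g])] = c
    frequent.extend(
        ItemsetSupport(itemset=s, count=c, support=Fraction(c, n))
        for s, c in level.items())

    k = 2
    while level and (params.max_itemset_size is None
                     or k <= params.max_itemset_size):
        prev = set(level)
        prev_sorted = sorted(prev, key=lambda s: tuple(sorted(s)))
        candidates = set()
        for i, a in enumerate(prev_sorted):
            for b in prev_sorted[i + 1:]:
                union = a | b
                if len(union) != k:
                    continue
                if all(union - {x} in prev for x in union):
                    candidates.add(union)
        if len(candidates) > params.candidate_ceiling:
            raise ValidationError(
                f"candidate count {len(candidates)} exceeds ceiling "
                f"{params.candidate_ceiling} at level {k}")
        counts = _counts(db, sorted(candidates, key=lambda s: tuple(sorted(s))))
        level = {s: c for s, c in counts.items()
                 if Fraction(c, n) >= params.min_rule_support}
        frequent.extend(
            ItemsetSupport(itemset=s, count=c, support=Fraction(c, n))
            for s, c in level.items())
        k += 1

    frequent.sort(key=ItemsetSupport.sort_key)
    return frequent


def _proper_subsets(items: frozenset[str]):
    elems = sorted(items)
    return chain.from_iterable(
        combinations(elems, r) for r in range(1, len(elems)))


def association_rules(frequent: list[ItemsetSupport], db: TransactionDB,
                      min_rule_support: Fraction = DEFAULT_MIN_RULE_SUPPORT,
                      ) -> list[AssociationRule]:
    """All rules A -> (S - A) over frequent itemsets S of size >= 2.

    Rule support is support(S); rules below ``min_rule_support`` are
    dropped.  Confidence = support(S) / support(A) is reported but not
    thresholded, and is exact: confidence * support(A) == support(S) as
    rationals.
    """
    min_rule_support = Fraction(min_rule_support).limit_denominator(10**9)
    sup_cache: dict[frozenset[str], Fraction] = {
        f.itemset: f.support for f in frequent}

    def sup(s: frozenset[str]) -> Fraction:
        if s not in sup_cache:
            sup_cache[s] = support(s, db).support
        return sup_cache[s]

    rules = []
    for f in frequent:
        if len(f.itemset) < 2 or f.support < min_rule_support:
            continue
        for ante_items in _proper_subsets(f.itemset):
            antecedent = frozenset(ante_items)
            sa = sup(antecedent)
            if sa == 0:
                continue  # unreachable for itemsets with positive support
            rules.append(AssociationRule(
                antecedent=antecedent,
                consequent=f.itemset - antecedent,
                support=f.support,
                confidence=f.support / sa))
    rules.sort(key=AssociationRule.sort_key)
    return rules


def rank_pathways(db: TransactionDB) -> list[PathwayScore]:
    """Score each pathway by the mean support of its own genes.

    Gene supports are computed individually over the full database with no
    threshold; a pathway's score is the arithmetic mean over the genes it
    contains, so pathways dense in widely shared genes rank first.  Ranks
    are 1..m by descending score, ties broken lexicographically by id.
    The score is a mean of supports, not the support of the pathway's gene
    set as a whole.
    """
    if db.n_transactions == 0:
        raise ValidationError("transaction database is empty")
    n = db.n_transactions
    gene_counts: dict[str, int] = {}
    for _, genes in db.transactions:
        for g in genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    gene_support = {g: Fraction(c, n) for g, c in gene_counts.items()}

    scored = []
    for pid, genes in db.transactions:
        supports = tuple((g, gene_support[g]) for g in sorted(genes))
        score = sum((s for _, s in supports), Fraction(0)) / len(supports)
        scored.append((pid, score, supports))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        PathwayScore(pathway_id=pid, score=score, rank=i + 1,
                     gene_supports=supports)
        for i, (pid, score, supports) in enumerate(scored)
    ]
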