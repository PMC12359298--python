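"""Stage 5: shortlist approved drugs for the high-support genes.

The genes that dominate the frequent combinations are queried against a
drug-gene interaction table (DGIdb-style export).  A record survives the
shortlist only if the gene was queried, the drug is FDA-approved and its
interaction score strictly exceeds the threshold (default > 0.10 — a score
of exactly 0.10 is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .mining import ItemsetSupport

DEFAULT_MIN_SCORE = 0.10
DEFAULT_TOP_K = 4


@dataclass(frozen=True)
class DrugInteraction:
    gene: str
    drug: str
    interaction_score: float
    approved: bool
    sources: tuple[str, ...] = ()

    def __post_init__(self):
        if self.interaction_score < 0:
            raise ValidationError(
                f"interaction score must be >= 0: {self.interaction_score}")
        if not self.gene or not self.drug:
            raise ValidationError("drug interaction needs gene and drug names")


def select_query_genes(frequent: list[ItemsetSupport],
                       top_k: int = DEFAULT_TOP_K) -> set[str]:
    """Genes of the top-k single-gene itemsets by support (ties: name)."""
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    singles = sorted(
        (f for f in frequent if len(f.itemset) == 1),
        key=lambda f: (-f.support, next(iter(f.itemset))))
    return {next(iter(f.itemset)) for f in singles[:top_k]}


def filter_drugs(records: list[DrugInteraction], genes: set[str],
                 min_score: float = DEFAULT_MIN_SCORE,
                 approved_only: bool = True,
                 ) -> dict[str, list[DrugInteraction]]:
    """Per-gene shortlists of interactions passing all three predicates.

    Keeps records whose gene was queried, whose score is *strictly* above
    ``min_score``, and (with ``approved_only``) whose drug is approved.
    Each gene's list is sorted by descending score, ties by drug name.
    Idempotent: re-filtering a shortlist changes nothing.
    """
    if min_score < 0:
        raise ValidationError(f"min_score must be >= 0, got {min_score}")
    out: dict[str, list[DrugInteraction]] = {}
    for rec in records:
        if rec.gene not in genes:
            continue
        if rec.interaction_score <= min_score:
            continue
        if approved_only and not rec.approved:
            continue
        out.setdefault(rec.gene, []).append(rec)
    for gene in out:
        out[gene].sort(key=lambda r: (-r.interaction_score, r.drug))
    return out
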