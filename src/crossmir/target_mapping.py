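"""Stage 2: strong-evidence target genes of the shared miRNAs.

Curated miRNA-target interaction (MTI) databases tier their records by
experimental evidence; only records labelled "Functional MTI" (reporter
assay, Western blot, qPCR) count as strong here.  Shared miRNAs are mapped
to per-direction target-gene sets, and miRNAs with no qualifying record are
reported as missing rather than silently dropped.  The miRNA-gene pairs
also feed a plain edge list for downstream graph tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, ValidationError
from .overlap import Direction, SharedMirnaSet

STRONG_SUPPORT_TYPE = "functional mti"


@dataclass(frozen=True)
class MtiRecord:
    """One experimentally supported miRNA -> gene interaction."""

    mirna_id: str
    gene: str
    support_type: str
    experiments: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.gene:
            raise ValidationError("MTI record has empty gene symbol")
        if not self.support_type or not self.support_type.strip():
            raise ValidationError("MTI record has empty support type")

    @property
    def is_strong(self) -> bool:
        return self.support_type.strip().lower() == STRONG_SUPPORT_TYPE


@dataclass
class TargetSets:
    """Per-direction target-gene sets of the shared miRNAs."""

    up_targets: set[str] = field(default_factory=set)
    down_targets: set[str] = field(default_factory=set)
    per_mirna: dict[str, set[str]] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    direction_of: dict[str, Direction] = field(default_factory=dict)

    def targets(self, direction: Direction) -> set[str]:
        return self.up_targets if direction is Direction.UP else self.down_targets


def filter_strong_mti(records: list[MtiRecord]) -> list[MtiRecord]:
    """Keep exactly the records whose support type is "Functional MTI".

    The match is case-insensitive and ignores surrounding whitespace but is
    otherwise strict: qualified labels like "Functional MTI (Weak)" do not
    pass.  File order is preserved; idempotent.
    """
    return [r for r in records if r.is_strong]


def collect_targets(shared: SharedMirnaSet,
                    records: list[MtiRecord]) -> TargetSets:
    """Union the strong targets of each shared miRNA, per direction.

    ``records`` must already be strong-filtered; a weak record anywhere is a
    contract violation, because a miRNA whose only records are weak must be
    reported as ``missing`` (it contributes no targets) and silently mixing
    tiers would mask that.
    """
    weak = [r for r in records if not r.is_strong]
    if weak:
        raise ContractError(
            f"collect_targets requires strong-filtered records; found "
            f"{len(weak)} non-strong record(s), first: "
            f"{weak[0].mirna_id} -> {weak[0].gene} ({weak[0].support_type!r})")

    out = TargetSets()
    by_mirna: dict[str, set[str]] = {}
    for rec in records:
        by_mirna.setdefault(rec.mirna_id, set()).add(rec.gene)

    for mirna in sorted(shared.shared):
        direction = shared.direction_of(mirna)
        out.direction_of[mirna] = direction
        genes = by_mirna.get(mirna, set())
        if not genes:
            out.missing.add(mirna)
            continue
        out.per_mirna[mirna] = set(genes)
        if direction is Direction.UP:
            out.up_targets |= genes
        else:
            out.down_targets |= genes
    return out


def build_edge_list(target_sets: TargetSets) -> list[tuple[str, str, str]]:
    """Flatten per-miRNA targets into (miRNA, gene, direction) edges.

    One edge per pair, stably sorted by (direction, miRNA, gene) so output
    files are byte-stable across runs.
    """
    edges = [
        (mirna, gene, target_sets.direction_of[mirna].value)
        for mirna, genes in target_sets.per_mirna.items()
        for gene in genes
    ]
    edges.sort(key=lambda e: (e[2], e[0], e[1]))
    return edges
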