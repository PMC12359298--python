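"""Stage 1: miRNAs consistently dysregulated in both diseases.

Two systematic-review tables (one per disease) list study-level reports of
circulating miRNAs as up- or downregulated versus controls.  A miRNA is a
cross-disease candidate only if it is reported in *both* diseases and its
direction is consistent everywhere: one discordant report — in either
disease — excludes it.  This vote-counting rule is direction-only; fold
change magnitudes play no part.

The module also houses the risk-of-bias classifier for the JBI case-control
appraisal checklist (0-10 points).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from .errors import ValidationError

_ARM_SUFFIX = re.compile(r"-(3p|5p)$")
_SPECIES_PREFIX = re.compile(r"^hsa-", re.IGNORECASE)


def normalize_mirna_name(raw: str) -> str:
    """Canonicalize a miRNA name for exact-string matching.

    Strips the human species prefix (``hsa-``) and lower-cases the body so
    that ``hsa-miR-132-3p``, ``MIR-132-3P`` and ``mir-132-3p`` collide.
    Arm suffixes (``-3p``/``-5p``) are preserved: distinct arms are distinct
    mature miRNAs.  Idempotent on its own output.
    """
    if raw is None:
        raise ValidationError("miRNA name is missing")
    name = raw.strip()
    if not name:
        raise ValidationError("miRNA name is empty or whitespace-only")
    if any(ch.isspace() for ch in name):
        raise ValidationError(f"miRNA name contains internal whitespace: {raw!r}")
    name = _SPECIES_PREFIX.sub("", name)
    return name.lower()


def family_key(name: str) -> str:
    """Collapse a normalized name to its family by dropping the arm suffix."""
    return _ARM_SUFFIX.sub("", name)


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"


class ExclusionReason(str, enum.Enum):
    WITHIN_DISEASE = "within_disease_conflict"
    CROSS_DISEASE = "cross_disease_conflict"


class QualityClass(str, enum.Enum):
    HIGH_RISK = "high_risk"
    MODERATE_RISK = "moderate_risk"
    LOW_RISK = "low_risk"


@dataclass(frozen=True)
class MirnaObservation:
    """One study-level report of a miRNA's regulation direction."""

    mirna_id: str
    disease: str
    direction: Direction
    study_id: str
    fold_change: float | None = None
    p_value: float | None = None
    sample_type: str | None = None

    def __post_init__(self):
        if not self.mirna_id:
            raise ValidationError("observation has empty miRNA id")
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))
        if self.fold_change is not None and self.fold_change <= 0:
            raise ValidationError(
                f"fold_change must be positive, got {self.fold_change}")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValidationError(f"p_value must be in (0,1], got {self.p_value}")


@dataclass
class MirnaTable:
    """All differential-miRNA observations for one disease."""

    rows: list[MirnaObservation]
    disease_label: str

    def __len__(self) -> int:
        return len(self.rows)

    def mirnas(self) -> set[str]:
        return {r.mirna_id for r in self.rows}


@dataclass
class SharedMirnaSet:
    """Outcome of the cross-disease consistency screen."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    excluded: dict[str, ExclusionReason] = field(default_factory=dict)
    # miRNA -> supporting (disease, study_id) pairs; includes single-disease
    # miRNAs for audit even though they are not candidates.
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def shared(self) -> set[str]:
        return self.up | self.down

    def direction_of(self, mirna: str) -> Direction:
        if mirna in self.up:
            return Direction.UP
        if mirna in self.down:
            return Direction.DOWN
        raise KeyError(mirna)


def find_shared_mirnas(table_a: MirnaTable, table_b: MirnaTable,
                       collapse_families: bool = False) -> SharedMirnaSet:
    """Intersect two disease signatures under the consistency rules.

    A miRNA enters ``up`` iff it has at least one up observation in each
    disease and no down observation anywhere (symmetric for ``down``).
    A miRNA observed in both diseases but with mixed directions lands in
    ``excluded``; conflicts *within* one disease are diagnosed before
    conflicts *between* the diseases.  miRNAs seen in only one disease are
    recorded in provenance but are neither shared nor excluded.

    With ``collapse_families`` the match key drops the -3p/-5p arm suffix,
    grouping sibling arms into one family-level vote.
    """
    if not table_a.rows or not table_b.rows:
        raise ValidationError("both miRNA tables must be non-empty")

    key = family_key if collapse_families else (lambda n: n)

    # name -> disease -> set of directions; name -> provenance pairs
    directions: dict[str, dict[str, set[Direction]]] = {}
    result = SharedMirnaSet()
    for table in (table_a, table_b):
        for obs in table.rows:
            name = key(obs.mirna_id)
            directions.setdefault(name, {}).setdefault(
                obs.disease, set()).add(obs.direction)
            result.provenance.setdefault(name, []).append(
                (obs.disease, obs.study_id))

    for name, per_disease in sorted(directions.items()):
        if len(per_disease) < 2:
            continue  # single-disease: not a candidate, not a conflict
        if any(len(dirs) > 1 for dirs in per_disease.values()):
            result.excluded[name] = ExclusionReason.WITHIN_DISEASE
            continue
        all_dirs = {next(iter(dirs)) for dirs in per_disease.values()}
        if len(all_dirs) > 1:
            result.excluded[name] = ExclusionReason.CROSS_DISEASE
            continue
        (result.up if all_dirs == {Direction.UP} else result.down).add(name)
    return result


def jbi_quality_class(score: int) -> QualityClass:
    """Map a JBI case-control appraisal score (0-10) to a risk-of-bias class.

    <=4 is high risk, 5-7 moderate, >=8 low.
    """
    if not isinstance(score, int) or isinstance(score, bool):
        raise ValidationError(f"JBI score must be an integer, got {score!r}")
    if not 0 <= score <= 10:
        raise ValidationError(f"JBI score must be in 0..10, got {score}")
    if score <= 4:
        return QualityClass.HIGH_RISK
    if score <= 7:
        return QualityClass.MODERATE_RISK
    return QualityClass.LOW_RISK
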