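"""Seeded generators for all four pipeline inputs with planted truth.

Every downstream stage is testable without external data: the generators
plant recoverable structure — shared/conflicting miRNAs, strong/weak
interaction evidence, pathway gene sets with chosen joint-occurrence
counts, and drugs straddling the interaction-score boundary — and return
a machine-readable truth record alongside each artifact.

Defaults reproduce the study conditions this package models: two disease
signatures of 124 and 286 miRNAs sharing 21 consistent miRNAs (10 up,
11 down); four shared miRNAs absent from the interaction database; 265
(down) and 243 (up) pathway transactions in which the core signalling
genes (MAP2K1, MAPK1, AKT1, RAF1 for the down branch; MAP2K1, RAF1, HRAS,
PIK3R1 for the up branch) co-occur with exact planted counts, e.g.
support({MAP2K1, MAPK1}) = 78/265 = 0.2943; and a drug-gene catalog of
the known FDA-approved interactions for those six genes.

Joint counts are planted by a block construction: each planted itemset C
receives ``block(C) = count(C) - sum(block(D) for planted D ⊃ C)``
dedicated transactions containing exactly C among planted genes, so the
joint support of every planted itemset is met exactly however the blocks
overlap in genes.  Filler genes (drawn from the direction's target pool,
never from planted genes) pad transactions but are capped at a per-gene
support well below every planted value, so they cannot mask the planted
structure.  One filler-free "flagship" transaction holding the full
planted gene set tops the mean-gene-support pathway ranking by
construction.

One global seed drives four independent sub-streams, one per generator:
changing one generator's parameters does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .drug_filter import DrugInteraction
from .enrichment import GeneSetLibrary
from .errors import ValidationError
from .overlap import Direction, MirnaObservation, MirnaTable
from .target_mapping import MtiRecord

# ---------------------------------------------------------------------------
# default planted structure (the study conditions)
# ---------------------------------------------------------------------------

DOWN_GENES = ("AKT1", "MAP2K1", "MAPK1", "RAF1")
UP_GENES = ("HRAS", "MAP2K1", "PIK3R1", "RAF1")

# Joint transaction counts for the down branch (over 265 transactions).
# Pairs/triples carry the published 4-decimal supports; the count of
# transactions holding all four genes is not published and is fixed at 40,
# inside the feasibility band [34, 52] implied by inclusion-exclusion.
_DOWN_COMBO_COUNTS = {
    frozenset(DOWN_GENES): 40,
    frozenset({"MAP2K1", "MAPK1", "RAF1"}): 59,   # 0.2226
    frozenset({"AKT1", "MAP2K1", "MAPK1"}): 53,   # 0.2000
    frozenset({"MAP2K1", "MAPK1"}): 78,           # 0.2943
    frozenset({"AKT1", "MAPK1"}): 75,             # 0.2830
    frozenset({"MAP2K1", "RAF1"}): 67,            # 0.2528
    frozenset({"MAPK1", "RAF1"}): 65,             # 0.2453
}

# Up branch (over 243 transactions); unpublished triples with PIK3R1 and
# the four-gene count are all fixed at 40 (below the 0.2000 print floor).
_UP_COMBO_COUNTS = {
    frozenset(UP_GENES): 40,
    frozenset({"HRAS", "MAP2K1", "RAF1"}): 60,    # 0.2469
    frozenset({"HRAS", "MAP2K1", "PIK3R1"}): 40,
    frozenset({"HRAS", "PIK3R1", "RAF1"}): 40,
    frozenset({"MAP2K1", "PIK3R1", "RAF1"}): 40,
    frozenset({"MAP2K1", "RAF1"}): 69,            # 0.2840
    frozenset({"HRAS", "PIK3R1"}): 67,            # 0.2757
    frozenset({"HRAS", "RAF1"}): 66,              # 0.2716
    frozenset({"HRAS", "MAP2K1"}): 64,            # 0.2634
    frozenset({"MAP2K1", "PIK3R1"}): 61,          # 0.2510
    frozenset({"PIK3R1", "RAF1"}): 56,            # 0.2305
}


def _combos_as_supports(counts: dict, n: int):
    return tuple((tuple(sorted(genes)), Fraction(c, n))
                 for genes, c in sorted(counts.items(),
                                        key=lambda kv: (-len(kv[0]),
                                                        sorted(kv[0]))))


#: Known FDA-approved drug interactions for the six core genes
#: (interaction scores as published in DGIdb exports).
DRUG_CATALOG: dict[str, tuple[tuple[str, float], ...]] = {
    "AKT1": (("Capivasertib", 0.51), ("Nelfinavir", 0.12)),
    "MAPK1": (("Benzalkonium chloride", 0.14),),
    "MAP2K1": (
        ("Cobimetinib", 0.56), ("Trametinib dimethyl sulfoxide", 0.54),
        ("Selumetinib", 0.47), ("Binimetinib", 0.4), ("Dabrafenib", 0.34),
        ("Vemurafenib", 0.33), ("Cobimetinib fumarate", 0.31),
        ("Selumetinib sulfate", 0.31), ("Encorafenib", 0.27),
        ("Panitumumab", 0.18), ("Cetuximab", 0.16)),
    "RAF1": (("Tovorafenib", 0.66), ("Encorafenib", 0.22),
             ("Regorafenib", 0.18), ("Sorafenib", 0.15)),
    "PIK3R1": (("Leniolisib", 0.33), ("Copanlisib", 0.18),
               ("Alpelisib", 0.11)),
    "HRAS": (("Sotorasib", 0.41), ("Pralsetinib", 0.17), ("Lorlatinib", 0.14),
             ("Trametinib dimethyl sulfoxide", 0.14), ("Selumetinib", 0.11),
             ("Vitamin E", 0.11), ("Cabozantinib S-malate", 0.11)),
}

_ANCHOR_UP = ("let-7b", "mir-34c-5p", "mir-1260a", "mir-3176")
_ANCHOR_DOWN = ("mir-132-3p", "mir-671-3p", "mir-181c-3p")
DEFAULT_ABSENT = ("mir-1260a", "mir-3176", "mir-671-3p", "mir-181c-3p")

_EXPERIMENTS = ("Luciferase reporter assay", "Western blot", "qRT-PCR",
                "Microarray", "Next generation sequencing")
_DECOY_KEYWORD_NAMES = ("CANCER", "INFECTION", "CELL_CYCLE", "RHEUMATOID")


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 20240501
    disease_a: str = "AD"
    disease_b: str = "T2DM"
    n_shared_up: int = 10
    n_shared_down: int = 11
    n_conflicting: int = 4
    n_specific_a: int = 99
    n_specific_b: int = 261
    absent_mirnas: tuple[str, ...] = DEFAULT_ABSENT
    n_targets_up: int = 233
    n_targets_down: int = 337
    frac_weak_mti: float = 0.15
    n_pathways_up: int = 243
    n_pathways_down: int = 265
    planted_combos_up: tuple = _combos_as_supports(_UP_COMBO_COUNTS, 243)
    planted_combos_down: tuple = _combos_as_supports(_DOWN_COMBO_COUNTS, 265)
    gene_support_floor_up: float = 0.30
    gene_support_floor_down: float = 0.45
    filler_support_cap: float = 0.10
    min_tx_genes: int = 4
    n_decoy_pathways: int = 3
    n_nonsig_pathways: int = 10
    universe_size: int = 20000
    flagship_up: str = "BIOCARTA_ECM_PATHWAY"
    flagship_down: str = "PID_TCR_RAS_PATHWAY"
    n_drugs_per_gene: int = 3
    score_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        counts = (self.n_shared_up, self.n_shared_down, self.n_conflicting,
                  self.n_specific_a, self.n_specific_b, self.n_targets_up,
                  self.n_targets_down, self.n_pathways_up,
                  self.n_pathways_down, self.n_decoy_pathways,
                  self.n_nonsig_pathways, self.n_drugs_per_gene)
        if any(c < 0 for c in counts):
            raise ValidationError("all synthetic counts must be >= 0")
        if not 0 <= self.frac_weak_mti <= 1:
            raise ValidationError("frac_weak_mti must be in [0,1]")
        for combos in (self.planted_combos_up, self.planted_combos_down):
            for genes, s in combos:
                if not 0 <= Fraction(s) <= 1:
                    raise ValidationError(f"planted support outside [0,1]: {s}")
                if not genes:
                    raise ValidationError("planted combo has no genes")
        if not (0 <= self.score_range[0] <= self.score_range[1]):
            raise ValidationError(f"bad score_range {self.score_range}")
        if self.min_tx_genes < 1:
            raise ValidationError("min_tx_genes must be >= 1")

    def rngs(self) -> tuple[np.random.Generator, ...]:
        """Four independent sub-streams: study, mti, pathway, drug."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return tuple(np.random.default_rng(s) for s in children)

    # deterministic name catalogs -------------------------------------

    def shared_names(self, direction: Direction) -> tuple[str, ...]:
        anchors = _ANCHOR_UP if direction is Direction.UP else _ANCHOR_DOWN
        n = self.n_shared_up if direction is Direction.UP else self.n_shared_down
        tag = "u" if direction is Direction.UP else "d"
        pad = tuple(f"mir-9{tag}{i:02d}" for i in range(1, max(0, n - len(anchors)) + 1))
        return (anchors + pad)[:n]

    def target_pool(self, direction: Direction) -> tuple[str, ...]:
        """Direction's target genes: planted core genes first, then
        synthetic symbols up to the configured count."""
        planted = self.planted_genes(direction)
        n = self.n_targets_up if direction is Direction.UP else self.n_targets_down
        tag = "GU" if direction is Direction.UP else "GD"
        fillers = tuple(f"{tag}{i:04d}" for i in range(1, max(0, n - len(planted)) + 1))
        return (planted + fillers)[:n]

    def planted_genes(self, direction: Direction) -> tuple[str, ...]:
        combos = (self.planted_combos_up if direction is Direction.UP
                  else self.planted_combos_down)
        out: set[str] = set()
        for genes, _ in combos:
            out.update(genes)
        return tuple(sorted(out))


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class StudyTruth:
    shared_up: set[str]
    shared_down: set[str]
    conflicting: dict[str, str]  # name -> expected exclusion reason
    specific_a: set[str]
    specific_b: set[str]


@dataclass
class MtiTruth:
    targets_up: set[str]
    targets_down: set[str]
    per_mirna: dict[str, set[str]]
    absent: set[str]  # shared miRNAs with no strong record
    n_strong: int
    n_weak: int


@dataclass
class PathwayTruth:
    # direction value -> planted itemset (sorted tuple) -> exact count
    planted_counts: dict[str, dict[tuple[str, ...], int]]
    # direction value -> every non-empty subset of planted genes -> count
    subset_counts: dict[str, dict[tuple[str, ...], int]]
    n_transactions: dict[str, int]
    transaction_ids: dict[str, set[str]]
    gene_counts: dict[str, dict[str, int]]  # individual planted-gene counts
    flagship: dict[str, str]
    decoys: set[str]
    nonsig: set[str]
    filler_cap_count: dict[str, int]


@dataclass
class DrugTruth:
    # gene -> expected shortlist [(drug, score), ...] under the default
    # filter (approved, score strictly > 0.10)
    passing: dict[str, list[tuple[str, float]]]


@dataclass
class SyntheticBundle:
    table_a: MirnaTable
    table_b: MirnaTable
    mti: list[MtiRecord]
    library: GeneSetLibrary
    drugs: list[DrugInteraction]
    study_truth: StudyTruth
    mti_truth: MtiTruth
    pathway_truth: PathwayTruth
    drug_truth: DrugTruth


# ---------------------------------------------------------------------------
# stage generators
# ---------------------------------------------------------------------------

def _observation(rng, name, disease, direction, study):
    return MirnaObservation(
        mirna_id=name, disease=disease, direction=direction, study_id=study,
        fold_change=round(float(rng.uniform(1.2, 4.0)), 3),
        p_value=round(float(rng.uniform(1e-4, 0.049)), 6),
        sample_type=str(rng.choice(["serum", "plasma"])),
    )


def generate_study_tables(config: SyntheticConfig,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[MirnaTable, MirnaTable, StudyTruth]:
    """Two disease signatures with planted shared/conflicting structure.

    Shared miRNAs are reported with a consistent direction in 1-2 studies
    of each disease; conflicting miRNAs alternate between within-disease
    and cross-disease discordance (both subtypes occur whenever
    ``n_conflicting >= 2``); the remainder are disease-specific fillers.
    """
    if rng is None:
        rng = config.rngs()[0]
    a, b = config.disease_a, config.disease_b
    rows_a: list[MirnaObservation] = []
    rows_b: list[MirnaObservation] = []

    def study(disease, i):
        return f"{disease}-S{i:02d}"

    shared_up = config.shared_names(Direction.UP)
    shared_down = config.shared_names(Direction.DOWN)
    for names, direction in ((shared_up, Direction.UP),
                             (shared_down, Direction.DOWN)):
        for name in names:
            for disease, rows in ((a, rows_a), (b, rows_b)):
                for k in range(int(rng.integers(1, 3))):
                    rows.append(_observation(rng, name, disease, direction,
                                             study(disease, rng.integers(1, 30))))

    conflicting: dict[str, str] = {}
    for i in range(config.n_conflicting):
        name = f"mir-8c{i + 1:02d}"
        if i % 2 == 0:  # within-disease conflict (alternating disease)
            home, other = ((a, rows_a), (b, rows_b))[i % 4 // 2], None
            home_rows = rows_a if home[0] == a else rows_b
            other_rows = rows_b if home[0] == a else rows_a
            other_name = b if home[0] == a else a
            home_rows.append(_observation(rng, name, home[0], Direction.UP,
                                          study(home[0], 1)))
            home_rows.append(_observation(rng, name, home[0], Direction.DOWN,
                                          study(home[0], 2)))
            other_rows.append(_observation(rng, name, other_name, Direction.UP,
                                           study(other_name, 3)))
            conflicting[name] = "within_disease_conflict"
        else:  # cross-disease conflict
            d1, d2 = (Direction.UP, Direction.DOWN) if i % 4 == 1 else (
                Direction.DOWN, Direction.UP)
            rows_a.append(_observation(rng, name, a, d1, study(a, 4)))
            rows_b.append(_observation(rng, name, b, d2, study(b, 5)))
            conflicting[name] = "cross_disease_conflict"

    specific_a = {f"mir-7a{i:03d}" for i in range(1, config.n_specific_a + 1)}
    specific_b = {f"mir-7b{i:03d}" for i in range(1, config.n_specific_b + 1)}
    for name in sorted(specific_a):
        rows_a.append(_observation(rng, name, a,
                                   Direction.UP if rng.random() < 0.5 else Direction.DOWN,
                                   study(a, rng.integers(1, 30))))
    for name in sorted(specific_b):
        rows_b.append(_observation(rng, name, b,
                                   Direction.UP if rng.random() < 0.5 else Direction.DOWN,
                                   study(b, rng.integers(1, 30))))

    truth = StudyTruth(shared_up=set(shared_up), shared_down=set(shared_down),
                       conflicting=conflicting, specific_a=specific_a,
                       specific_b=specific_b)
    return (MirnaTable(rows=rows_a, disease_label=a),
            MirnaTable(rows=rows_b, disease_label=b), truth)


def generate_mti(config: SyntheticConfig,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[list[MtiRecord], MtiTruth]:
    """Strong-evidence targets for the shared miRNAs, plus planted gaps.

    Every shared miRNA outside ``absent_mirnas`` receives "Functional MTI"
    records covering the direction's whole target pool (round-robin, with
    a few genes assigned twice to exercise de-duplication).  Of the absent
    miRNAs, half get only weak records and half no record at all — both
    must surface as ``missing`` downstream.  ``frac_weak_mti`` adds weak
    records on top of the strong ones.
    """
    if rng is None:
        rng = config.rngs()[1]
    records: list[MtiRecord] = []
    per_mirna: dict[str, set[str]] = {}
    truth_targets = {Direction.UP: set(), Direction.DOWN: set()}

    shared_all = (config.shared_names(Direction.UP)
                  + config.shared_names(Direction.DOWN))
    absent = tuple(n for n in config.absent_mirnas if n in shared_all)
    weak_only = set(absent[: len(absent) // 2])
    n_strong = 0

    for direction in (Direction.UP, Direction.DOWN):
        names = [n for n in config.shared_names(direction) if n not in absent]
        pool = list(config.target_pool(direction))
        if not names:
            continue
        rng.shuffle(pool)
        for i, gene in enumerate(pool):
            mirna = names[i % len(names)]
            records.append(MtiRecord(
                mirna_id=mirna, gene=gene, support_type="Functional MTI",
                experiments=tuple(map(str, rng.choice(
                    _EXPERIMENTS, size=int(rng.integers(1, 3)),
                    replace=False)))))
            per_mirna.setdefault(mirna, set()).add(gene)
            truth_targets[direction].add(gene)
            n_strong += 1
        # duplicate assignments: same gene under a second miRNA
        for gene in pool[: min(5, len(pool))]:
            mirna = names[int(rng.integers(0, len(names)))]
            if gene not in per_mirna.get(mirna, set()):
                records.append(MtiRecord(
                    mirna_id=mirna, gene=gene, support_type="Functional MTI",
                    experiments=("Western blot",)))
                per_mirna.setdefault(mirna, set()).add(gene)
                n_strong += 1

    # weak-evidence noise over miRNAs that may carry records (the fully
    # absent half must stay absent from the table altogether)
    n_weak = int(round(config.frac_weak_mti * n_strong))
    all_genes = sorted(truth_targets[Direction.UP] | truth_targets[Direction.DOWN])
    fully_absent = set(absent) - weak_only
    weak_sources = sorted(set(shared_all) - fully_absent)
    for _ in range(n_weak):
        records.append(MtiRecord(
            mirna_id=str(rng.choice(weak_sources)),
            gene=str(rng.choice(all_genes)) if all_genes else "GX0001",
            support_type="Functional MTI (Weak)",
            experiments=("Microarray",)))
    for mirna in sorted(weak_only):  # guarantee at least one weak record
        records.append(MtiRecord(
            mirna_id=mirna, gene=all_genes[0] if all_genes else "GX0001",
            support_type="Functional MTI (Weak)", experiments=("Microarray",)))
        n_weak += 1

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = MtiTruth(targets_up=truth_targets[Direction.UP],
                     targets_down=truth_targets[Direction.DOWN],
                     per_mirna=per_mirna, absent=set(absent),
                     n_strong=n_strong, n_weak=n_weak)
    return records, truth


def _blocks_from_counts(combos: list[tuple[frozenset[str], int]],
                        n: int) -> dict[frozenset[str], int]:
    """Dedicated-transaction counts per planted itemset (Mobius over the
    planted containment poset): block(C) = count(C) - sum blocks of
    planted strict supersets.  Raises if the targets are inconsistent."""
    seen = set()
    for genes, _ in combos:
        if genes in seen:
            raise ValidationError(f"duplicate planted combo {sorted(genes)}")
        seen.add(genes)
    blocks: dict[frozenset[str], int] = {}
    for genes, count in sorted(combos, key=lambda kv: -len(kv[0])):
        over = sum(b for d, b in blocks.items() if d > genes)
        block = count - over
        if block < 0:
            raise ValidationError(
                f"planted supports are inconsistent: itemset {sorted(genes)} "
                f"needs count {count} but strict supersets already occupy {over}")
        blocks[genes] = block
    if sum(blocks.values()) > n:
        raise ValidationError(
            f"planted blocks need {sum(blocks.values())} transactions, "
            f"only {n} available")
    return blocks


class _FillerPool:
    """Round-robin filler sampler with a hard per-gene usage cap."""

    def __init__(self, genes: list[str], cap: int, rng):
        if not genes:
            raise ValidationError("filler pool is empty")
        self.genes = list(genes)
        rng.shuffle(self.genes)
        self.cap = cap
        self.usage = {g: 0 for g in self.genes}
        self._idx = 0

    def draw(self, k: int, exclude: frozenset[str]) -> list[str]:
        out: list[str] = []
        scanned = 0
        while len(out) < k:
            if scanned > 2 * len(self.genes):
                raise ValidationError(
                    "filler pool exhausted: raise the pool size or the "
                    "filler support cap")
            g = self.genes[self._idx % len(self.genes)]
            self._idx += 1
            scanned += 1
            if g in exclude or g in out or self.usage[g] >= self.cap:
                continue
            out.append(g)
        for g in out:
            self.usage[g] += 1
        return out


def _powerset_counts(blocks: dict[frozenset[str], int]) -> dict[tuple[str, ...], int]:
    from itertools import combinations
    planted: set[str] = set()
    for genes in blocks:
        planted |= genes
    out = {}
    for r in range(1, len(planted) + 1):
        for sub in combinations(sorted(planted), r):
            s = frozenset(sub)
            out[tuple(sub)] = sum(b for d, b in blocks.items() if s <= d)
    return out


def generate_pathway_library(config: SyntheticConfig,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[GeneSetLibrary, PathwayTruth]:
    """One GMT library holding both directions' planted transactions.

    Per direction: planted blocks, per-gene solo boosts lifting each
    planted gene to its support floor (so gene-level pruning keeps it),
    filler-padded transactions, one filler-free flagship with the full
    planted gene set, plus keyword decoys (significant but excluded) and
    non-significant background pathways.
    """
    if rng is None:
        rng = config.rngs()[2]
    pathways: dict[str, frozenset[str]] = {}
    truth = PathwayTruth(planted_counts={}, subset_counts={},
                         n_transactions={}, transaction_ids={},
                         gene_counts={}, flagship={}, decoys=set(),
                         nonsig=set(), filler_cap_count={})

    for direction in (Direction.UP, Direction.DOWN):
        d = direction.value
        n = config.n_pathways_up if direction is Direction.UP else config.n_pathways_down
        combos_cfg = (config.planted_combos_up if direction is Direction.UP
                      else config.planted_combos_down)
        floor = (config.gene_support_floor_up if direction is Direction.UP
                 else config.gene_support_floor_down)
        flagship_name = (config.flagship_up if direction is Direction.UP
                         else config.flagship_down)
        if n == 0:
            continue

        combos = [(frozenset(g), int(math.floor(Fraction(s) * n + Fraction(1, 2))))
                  for g, s in combos_cfg]
        blocks = _blocks_from_counts(combos, n)
        planted = sorted({g for genes in blocks for g in genes})

        gene_counts = {g: sum(b for d_, b in blocks.items() if g in d_)
                       for g in planted}
        floor_count = math.ceil(floor * n)
        solos = {g: max(0, floor_count - c) for g, c in gene_counts.items()}
        total = sum(blocks.values()) + sum(solos.values())
        if total > n:
            raise ValidationError(
                f"{d}: blocks+solo boosts need {total} transactions, have {n}")

        # transaction gene cores, flagship (largest planted set) first
        cores: list[frozenset[str]] = []
        for genes in sorted(blocks, key=lambda s: (-len(s), sorted(s))):
            cores.extend([genes] * blocks[genes])
        for g in planted:
            cores.extend([frozenset([g])] * solos[g])
        cores.extend([frozenset()] * (n - total))

        cap = int(math.floor(config.filler_support_cap * n))
        pool_genes = [g for g in config.target_pool(direction)
                      if g not in set(planted)]
        pool = _FillerPool(pool_genes, cap, rng)
        exclude = frozenset(planted)

        tx_sets: list[frozenset[str]] = []
        for i, core in enumerate(cores):
            if i == 0 and core == frozenset(planted):
                tx_sets.append(core)  # flagship: no fillers
                continue
            need = max(config.min_tx_genes - len(core), 1)
            extra = int(rng.integers(0, 3))
            fillers = pool.draw(need + extra, exclude)
            tx_sets.append(core | frozenset(fillers))

        # name the transactions; shuffle so ids do not encode structure
        order = list(rng.permutation(len(tx_sets)))
        tag = "UP" if direction is Direction.UP else "DN"
        ids = []
        counter = 1
        for j in order:
            if j == 0 and cores[0] == frozenset(planted):
                name = flagship_name
            else:
                name = f"SYNPATH_{tag}_{counter:04d}"
                counter += 1
            pathways[name] = tx_sets[j]
            ids.append(name)

        truth.planted_counts[d] = {
            tuple(sorted(genes)): count for genes, count in combos}
        subset = _powerset_counts(blocks)
        for g in planted:  # solo boosts raise single-gene counts only
            subset[(g,)] += solos[g]
        truth.subset_counts[d] = subset
        truth.n_transactions[d] = n
        truth.transaction_ids[d] = set(ids)
        truth.gene_counts[d] = {g: subset[(g,)] for g in planted}
        truth.flagship[d] = (flagship_name
                             if cores and cores[0] == frozenset(planted)
                             else "")
        truth.filler_cap_count[d] = cap

        # keyword decoys: all genes inside the query, name carries an
        # excluded disease category
        for i in range(config.n_decoy_pathways):
            kw = _DECOY_KEYWORD_NAMES[i % len(_DECOY_KEYWORD_NAMES)]
            name = f"KEGG_{kw}_SYN_{tag}_{i + 1:02d}"
            genes = frozenset(pool_genes[: config.min_tx_genes + 2])
            pathways[name] = genes
            truth.decoys.add(name)

    for i in range(config.n_nonsig_pathways):
        name = f"SYNPATH_BG_{i + 1:02d}"
        genes = frozenset(f"BGRND{i * 7 + j:05d}" for j in range(6))
        pathways[name] = genes
        truth.nonsig.add(name)

    library = GeneSetLibrary(name="synthetic_library", pathways=pathways,
                             universe_size=config.universe_size)
    return library, truth


def generate_drug_table(config: SyntheticConfig, genes: set[str],
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[DrugInteraction], DrugTruth]:
    """Drug-gene interactions straddling the 0.10 score boundary.

    Per gene: the catalog of known approved interactions (or random
    approved drugs above the boundary for uncataloged genes), one record
    at exactly 0.10, one below, and one high-scoring unapproved drug.
    The truth record is the shortlist the strict default filter keeps.
    """
    if rng is None:
        rng = config.rngs()[3]
    records: list[DrugInteraction] = []
    passing: dict[str, list[tuple[str, float]]] = {}
    lo, hi = config.score_range
    for gene in sorted(genes):
        entries = DRUG_CATALOG.get(gene)
        if entries is None:
            entries = tuple(
                (f"SYNDRUG-{gene}-{i + 1}",
                 round(float(rng.uniform(max(0.12, lo), max(0.2, hi))), 2))
                for i in range(config.n_drugs_per_gene))
        for drug, score in entries:
            records.append(DrugInteraction(gene=gene, drug=drug,
                                           interaction_score=score,
                                           approved=True, sources=("DGIdb",)))
        records.append(DrugInteraction(gene=gene, drug=f"BOUNDARY-{gene}",
                                       interaction_score=0.10, approved=True,
                                       sources=("synthetic",)))
        records.append(DrugInteraction(gene=gene, drug=f"LOWSCORE-{gene}",
                                       interaction_score=round(
                                           float(rng.uniform(lo, 0.09)), 3),
                                       approved=True, sources=("synthetic",)))
        records.append(DrugInteraction(gene=gene, drug=f"UNAPPROVED-{gene}",
                                       interaction_score=0.90, approved=False,
                                       sources=("synthetic",)))
        passing[gene] = sorted(((d, s) for d, s in entries),
                               key=lambda t: (-t[1], t[0]))
    order = rng.permutation(len(records))
    return [records[i] for i in order], DrugTruth(passing=passing)


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """All four inputs plus truth records from one seeded config."""
    config = config or SyntheticConfig()
    rng_study, rng_mti, rng_path, rng_drug = config.rngs()
    table_a, table_b, study_truth = generate_study_tables(config, rng_study)
    mti, mti_truth = generate_mti(config, rng_mti)
    library, pathway_truth = generate_pathway_library(config, rng_path)
    query = set(config.planted_genes(Direction.UP)) | set(
        config.planted_genes(Direction.DOWN))
    drugs, drug_truth = generate_drug_table(config, query, rng_drug)
    return SyntheticBundle(table_a=table_a, table_b=table_b, mti=mti,
                           library=library, drugs=drugs,
                           study_truth=study_truth, mti_truth=mti_truth,
                           pathway_truth=pathway_truth, drug_truth=drug_truth)
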