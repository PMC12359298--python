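# crossmir

Cross-disease mining of circulating-miRNA signatures: from two systematic
reviews' differential-miRNA tables to shared regulatory pathways and
candidate drugs.

Alzheimer's disease (AD) and type 2 diabetes mellitus (T2DM) share
pathophysiology — impaired insulin signalling, chronic inflammation — and
circulating microRNAs are candidate molecular links. `crossmir`
implements, as a tested and fully reproducible pipeline, the integrative
analysis that connects the two disease signatures:

1. **Overlap** — intersect the two diseases' differential-miRNA tables.
   A miRNA is shared only if it is reported in *both* diseases with a
   consistent direction everywhere; one discordant report (within a
   disease or between the diseases) excludes it.
2. **Targets** — map shared miRNAs to target genes with strong
   experimental evidence (miRTarBase-style "Functional MTI" records:
   reporter assay, Western blot, qPCR), per direction of regulation.
3. **Enrichment** — one-sided hypergeometric over-representation of each
   target set against GMT pathway libraries with Benjamini–Hochberg
   adjustment (default cut: adjusted p ≤ 1e-5), excluding pathway
   categories foreign to the question (infections, rheumatic disease,
   cancer, cell cycle) by keyword. Each retained pathway becomes a
   *transaction* carrying its overlap with the query.
4. **Mining** — Apriori frequent-itemset search over the transactions.
   The support of a gene set *X* is
   `support(X) = |{pathways containing every gene of X}| / |pathways|`,
   kept as an exact rational. Individual genes are pruned below a
   per-direction floor (0.40 for the down branch, 0.15 for the up
   branch); combinations of size ≥ 2 and association rules
   ("if X, then Y", confidence = support(X∪Y)/support(X)) are governed
   by a 0.01 floor. Pathways are then ranked by
   `score(P) = mean of support({g}) over genes g in P`.
5. **Drugs** — the genes dominating the frequent combinations are
   queried against a DGIdb-style drug–gene table; only FDA-approved
   drugs with interaction score strictly greater than 0.10 survive.

There is no network dependency: a seeded synthetic-data module generates
all four inputs with planted, exactly recoverable structure, and its
defaults encode the study conditions (124- and 286-miRNA signatures
sharing 21 miRNAs; 265/243 pathway transactions with exact planted joint
gene counts; the published drug catalog for the six core genes).

## Worked example

```sh
crossmir run --seed 1 --out demo_out
```

prints

```
bundle written to demo_out (19 files)
  n_shared = 21
  n_targets_up = 233
  n_targets_down = 337
  n_transactions_up = 243
  n_transactions_down = 265
```

Of 124 + 286 input miRNAs, 21 are consistently shared (10 up, 11 down);
their strong-evidence targets (233 up / 337 down) enrich 243 and 265
pathways, which become the mining transactions. `demo_out/` then holds
the full report bundle — shared/excluded miRNA tables, per-direction
target lists, a miRNA–gene edge list, enrichment and transaction tables,
frequent itemsets, association rules, ranked pathways, the drug
shortlist and a run manifest. For instance `itemsets_down.tsv` begins

```
items   count   support
AKT1    120     0.4528
MAP2K1  120     0.4528
MAPK1   120     0.4528
RAF1    120     0.4528
MAP2K1;MAPK1    78      0.2943
```

— the most frequent down-branch gene pair is MAP2K1/MAPK1, present in 78
of the 265 pathways (support 0.2943) — and `pathway_scores_down.tsv`
ranks `PID_TCR_RAS_PATHWAY` first (the up branch ranks
`BIOCARTA_ECM_PATHWAY` first). In `drug_shortlist.tsv` the top AKT1
interaction is Capivasertib (score 0.51); a drug at exactly 0.10 is
excluded by the strict threshold.

Every stage is also available as a subcommand (`simulate`, `overlap`,
`targets`, `enrich`, `mine`, `rank`, `drugs`, `summarize`) operating on
the previous stage's files, and as plain library functions
(`crossmir.find_shared_mirnas`, `crossmir.apriori`, ...).

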