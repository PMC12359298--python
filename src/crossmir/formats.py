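"""Readers and writers for every external table the pipeline touches.

All four upstream resources (systematic-review miRNA tables, a
miRTarBase-style interaction export, GMT pathway libraries, a DGIdb-style
drug-gene export) ship as tab-delimited text; each reader takes a
configurable :class:`TableDialect` but defaults to tabs.  Normalization
happens once, at read time — miRNA names are canonicalized and gene
symbols upper-cased — so every downstream join is an exact string match.
Decimal parsing is locale-independent (dot separator only).

Writers are exact inverses of the readers: read(write(x)) == x field by
field, and writing the same object twice is byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .drug_filter import DrugInteraction
from .enrichment import GeneSetLibrary
from .errors import FormatError, ValidationError
from .overlap import Direction, MirnaObservation, MirnaTable, normalize_mirna_name
from .target_mapping import MtiRecord

_DIRECTION_ALIASES = {
    "up": Direction.UP, "upregulated": Direction.UP,
    "down": Direction.DOWN, "downregulated": Direction.DOWN,
}
_BOOL_ALIASES = {
    "true": True, "yes": True, "1": True,
    "false": False, "no": False, "0": False,
}


@dataclass(frozen=True)
class TableDialect:
    delimiter: str = "\t"
    required_columns: tuple[str, ...] = ()
    comment_prefix: str = "#"

    def __post_init__(self):
        if len(self.required_columns) != len(set(self.required_columns)):
            raise ValidationError("required_columns must be unique")


MIRNA_DIALECT = TableDialect(required_columns=("mirna", "direction", "study_id"))
MTI_DIALECT = TableDialect(required_columns=("mirna", "gene", "support_type"))
DRUG_DIALECT = TableDialect(
    required_columns=("gene", "drug", "interaction_score", "approved"))


def _read_frame(path, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError("input file does not exist", path=str(path))
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                        comment=dialect.comment_prefix or None,
                        keep_default_na=False)
    for col in dialect.required_columns:
        if col not in frame.columns:
            raise FormatError("missing required column",
                              path=str(path), column=col)
    return frame


def _parse_float(value: str, what: str, path: str, row: int,
                 allow_negative: bool = False) -> float | None:
    if value == "":
        return None
    if "," in value:
        raise FormatError(f"{what}: comma decimal separator not accepted",
                          path=path, line=row)
    try:
        out = float(value)
    except ValueError:
        raise FormatError(f"{what}: unparseable number {value!r}",
                          path=path, line=row) from None
    if not allow_negative and out < 0:
        raise FormatError(f"{what}: negative value {out}", path=path, line=row)
    return out


def read_mirna_table(path, dialect: TableDialect = MIRNA_DIALECT,
                     disease_label: str | None = None) -> MirnaTable:
    """Load one disease's differential-miRNA observations.

    Required columns: mirna, direction, study_id; optional: fold_change,
    p_value, sample_type.  Directions map case-insensitively onto
    up/down; miRNA names are normalized.
    """
    frame = _read_frame(path, dialect)
    label = disease_label if disease_label is not None else Path(path).stem
    rows = []
    for i, rec in enumerate(frame.to_dict("records")):
        rownum = i + 2  # 1-based physical line, after the header
        raw_dir = str(rec["direction"]).strip().lower()
        if raw_dir not in _DIRECTION_ALIASES:
            raise FormatError(f"unparseable direction {rec['direction']!r}",
                              path=str(path), line=rownum, column="direction")
        try:
            mirna = normalize_mirna_name(str(rec["mirna"]))
        except ValidationError as exc:
            raise FormatError(str(exc), path=str(path), line=rownum,
                              column="mirna") from None
        sample = str(rec.get("sample_type", "")).strip() or None
        rows.append(MirnaObservation(
            mirna_id=mirna,
            disease=label,
            direction=_DIRECTION_ALIASES[raw_dir],
            study_id=str(rec["study_id"]).strip(),
            fold_change=_parse_float(str(rec.get("fold_change", "")).strip(),
                                     "fold_change", str(path), rownum),
            p_value=_parse_float(str(rec.get("p_value", "")).strip(),
                                 "p_value", str(path), rownum),
            sample_type=sample,
        ))
    return MirnaTable(rows=rows, disease_label=label)


def write_mirna_table(table: MirnaTable, path,
                      dialect: TableDialect = MIRNA_DIALECT) -> None:
    cols = ["mirna", "direction", "study_id", "fold_change", "p_value",
            "sample_type"]
    recs = [{
        "mirna": o.mirna_id,
        "direction": o.direction.value,
        "study_id": o.study_id,
        "fold_change": "" if o.fold_change is None else repr(o.fold_change),
        "p_value": "" if o.p_value is None else repr(o.p_value),
        "sample_type": o.sample_type or "",
    } for o in table.rows]
    pd.DataFrame(recs, columns=cols).to_csv(
        path, sep=dialect.delimiter, index=False)


def read_gmt(path, name: str | None = None,
             universe_size: int | None = None) -> GeneSetLibrary:
    """Parse a GMT gene-set library: name <tab> description <tab> genes...

    Genes are upper-cased and de-duplicated per set; duplicate pathway
    names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError("input file does not exist", path=str(path))
    pathways: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} field(s); need set name, "
                    "description and at least one gene",
                    path=str(path), line=lineno)
            set_name = fields[0].strip()
            if set_name in pathways:
                raise FormatError(f"duplicate pathway name {set_name!r}",
                                  path=str(path), line=lineno)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError("pathway has no genes",
                                  path=str(path), line=lineno)
            pathways[set_name] = genes
    return GeneSetLibrary(name=name or path.stem, pathways=pathways,
                          universe_size=universe_size)


def write_gmt(library: GeneSetLibrary, path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for pid in library.pathways:
            genes = sorted(library.pathways[pid])
            fh.write("\t".join([pid, descriptions.get(pid, "na"), *genes]) + "\n")


def read_mti_table(path, dialect: TableDialect = MTI_DIALECT) -> list[MtiRecord]:
    """Load a miRTarBase-style interaction table, preserving file order.

    Required columns: mirna, gene, support_type; optional: experiments
    (semicolon-joined).  Gene symbols are upper-cased, miRNA names
    normalized.
    """
    frame = _read_frame(path, dialect)
    records = []
    for i, rec in enumerate(frame.to_dict("records")):
        rownum = i + 2
        try:
            mirna = normalize_mirna_name(str(rec["mirna"]))
        except ValidationError as exc:
            raise FormatError(str(exc), path=str(path), line=rownum,
                              column="mirna") from None
        experiments = tuple(
            e.strip() for e in str(rec.get("experiments", "")).split(";")
            if e.strip())
        gene = str(rec["gene"]).strip().upper()
        if not gene:
            raise FormatError("empty gene symbol", path=str(path),
                              line=rownum, column="gene")
        records.append(MtiRecord(mirna_id=mirna, gene=gene,
                                 support_type=str(rec["support_type"]).strip(),
                                 experiments=experiments))
    return records


def write_mti_table(records: list[MtiRecord], path,
                    dialect: TableDialect = MTI_DIALECT) -> None:
    cols = ["mirna", "gene", "support_type", "experiments"]
    recs = [{
        "mirna": r.mirna_id,
        "gene": r.gene,
        "support_type": r.support_type,
        "experiments": ";".join(r.experiments),
    } for r in records]
    pd.DataFrame(recs, columns=cols).to_csv(
        path, sep=dialect.delimiter, index=False)


def read_drug_table(path,
                    dialect: TableDialect = DRUG_DIALECT) -> list[DrugInteraction]:
    """Load a DGIdb-style drug-gene interaction export.

    Scores must parse as non-negative decimals; the approved flag accepts
    true/false, yes/no and 1/0 (case-insensitive).
    """
    frame = _read_frame(path, dialect)
    records = []
    for i, rec in enumerate(frame.to_dict("records")):
        rownum = i + 2
        score = _parse_float(str(rec["interaction_score"]).strip(),
                             "interaction_score", str(path), rownum)
        if score is None:
            raise FormatError("missing interaction score", path=str(path),
                              line=rownum, column="interaction_score")
        raw_flag = str(rec["approved"]).strip().lower()
        if raw_flag not in _BOOL_ALIASES:
            raise FormatError(f"unparseable approved flag {rec['approved']!r}",
                              path=str(path), line=rownum, column="approved")
        sources = tuple(
            s.strip() for s in str(rec.get("sources", "")).split(";")
            if s.strip())
        records.append(DrugInteraction(
            gene=str(rec["gene"]).strip().upper(),
            drug=str(rec["drug"]).strip(),
            interaction_score=score,
            approved=_BOOL_ALIASES[raw_flag],
            sources=sources))
    return records


def write_drug_table(records: list[DrugInteraction], path,
                     dialect: TableDialect = DRUG_DIALECT) -> None:
    cols = ["gene", "drug", "interaction_score", "approved", "sources"]
    recs = [{
        "gene": r.gene,
        "drug": r.drug,
        "interaction_score": repr(r.interaction_score),
        "approved": "true" if r.approved else "false",
        "sources": ";".join(r.sources),
    } for r in records]
    pd.DataFrame(recs, columns=cols).to_csv(
        path, sep=dialect.delimiter, index=False)


def read_transactions(path, dialect: TableDialect | None = None) -> "TransactionDB":
    """Two-column transaction table: pathway id, semicolon-joined genes."""
    from .enrichment import TransactionDB
    dialect = dialect or TableDialect(required_columns=("pathway", "genes"))
    frame = _read_frame(path, dialect)
    transactions = []
    for i, rec in enumerate(frame.to_dict("records")):
        genes = frozenset(g.strip().upper()
                          for g in str(rec["genes"]).split(";") if g.strip())
        if not genes:
            raise FormatError("transaction has no genes", path=str(path),
                              line=i + 2)
        transactions.append((str(rec["pathway"]).strip(), genes))
    return TransactionDB(transactions=transactions)


def write_transactions(db, path, dialect: TableDialect | None = None) -> None:
    delimiter = (dialect or TableDialect()).delimiter
    recs = [{"pathway": pid, "genes": ";".join(sorted(genes))}
            for pid, genes in db.transactions]
    pd.DataFrame(recs, columns=["pathway", "genes"]).to_csv(
        path, sep=delimiter, index=False)


def write_report_bundle(tables: dict[str, pd.DataFrame], out_dir,
                        metadata: dict, delimiter: str = "\t") -> dict:
    """Emit the report bundle: one delimited table per result, plus
    run metadata and a manifest listing every file written.

    ``tables`` maps a table name (used as the file stem) to a DataFrame;
    ``metadata`` records inputs, parameters, seed and versions.  Returns
    the manifest, which is also written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"report directory not writable: {out_dir}") from exc

    files = []
    for name, frame in tables.items():
        fname = f"{name}.tsv"
        frame.to_csv(out_dir / fname, sep=delimiter, index=False)
        files.append({"file": fname, "table": name, "rows": int(len(frame))})

    meta = dict(metadata)
    meta.setdefault("versions", {})
    meta["versions"].setdefault("python", platform.python_version())
    meta["versions"].setdefault("pandas", pd.__version__)
    with open(out_dir / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    files.append({"file": "run_metadata.json", "table": "run_metadata",
                  "rows": None})

    manifest = {"out_dir": str(out_dir), "files": files}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
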