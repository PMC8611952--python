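"""Domain records and flat-file ingestion.

The pipeline consumes a ChEMBL-dump-like delimited table of bioactivity
records, a target-metadata table, a protein-class hierarchy and
term-membership annotation files.  Column names are decoupled from the
semantic fields through a user-supplied *dialect* map, so any flat export
with the right content can be ingested without renaming columns upstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SPECIES = ("human", "rat", "mouse", "other")
ASSAY_TYPES = ("A", "B", "F", "U")
MEASURES = ("Ki", "IC50", "EC50", "other")

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: semantic field -> default column name for the activity table
ACTIVITY_FIELDS = (
    "molecule_id",
    "smiles",
    "inchikey",
    "target_id",
    "species",
    "assay_type",
    "measure",
    "value_nM",
    "confidence",
)


class DataIntegrityError(ValueError):
    """Input data contradicts a structural invariant."""


class EmptyInputError(ValueError):
    """A required input file carried no usable rows."""


@dataclass(frozen=True)
class ActivityRecord:
    """One measured molecule-target bioactivity with its assay metadata."""

    molecule_id: str
    smiles: str
    inchikey: str | None
    target_id: str
    species: str
    assay_type: str
    measure: str
    value_nM: float
    confidence: int

    def __post_init__(self) -> None:
        if self.value_nM <= 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if not 0 <= self.confidence <= 9:
            raise ValueError(f"confidence must lie in 0..9, got {self.confidence}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.inchikey is not None and not INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey {self.inchikey!r}")


@dataclass(frozen=True)
class TargetEntity:
    """A species-specific protein target and its species-agnostic entry.

    ``ui_id`` names the protein entry shared by orthologs: the human and
    rat serotonin 1A receptors are distinct targets but one entry.
    """

    target_id: str
    name: str
    species: str
    ui_id: str
    protein_class_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProteinClassNode:
    """One node of the 7-level protein-family classification tree."""

    class_id: str
    name: str
    level: int
    parent_id: str | None = None


@dataclass
class AnnotationMap:
    """A functional term (GO / KEGG pathway / disease) and its member proteins."""

    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in {"GO", "KEGG", "DO"}:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


@dataclass
class RejectionReport:
    """Bookkeeping for rows dropped during ingestion, by reason."""

    n_rows: int = 0
    n_accepted: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.reasons.values())

    def to_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "accepted": self.n_accepted,
            "rejected": self.n_rejected,
            "reasons": dict(sorted(self.reasons.items())),
        }


def _resolve_dialect(columns: Iterable[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    dialect = dict(dialect or {})
    mapping = {}
    cols = set(columns)
    for semantic in ACTIVITY_FIELDS:
        col = dialect.get(semantic, semantic)
        if col in cols:
            mapping[semantic] = col
        elif semantic == "inchikey":
            continue  # structure key is optional
        else:
            raise ConfigColumnError(
                f"required column for field {semantic!r} "
                f"(expected name {col!r}) missing from table"
            )
    return mapping


class ConfigColumnError(ValueError):
    """A dialect map does not resolve a required semantic column."""


def read_activity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[ActivityRecord], RejectionReport]:
    """Read a delimited bioactivity table into validated records.

    Rows with a missing or unparseable value, missing SMILES, or an enum
    value outside the declared vocabulary are dropped and tallied in the
    returned :class:`RejectionReport` rather than raising.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    dialect:
        Optional map from semantic field names (see ``ACTIVITY_FIELDS``) to
        the column names actually present, e.g.
        ``{"value_nM": "standard_value"}``.
    sep:
        Field separator; inferred from the extension when omitted.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise EmptyInputError(f"activity table {path} has no data rows")
    colmap = _resolve_dialect(df.columns, dialect)

    report = RejectionReport(n_rows=len(df))
    records: list[ActivityRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda f: str(row[colmap[f]]).strip() if f in colmap else ""
        smiles = get("smiles")
        if not smiles:
            report.reject("missing_smiles")
            continue
        try:
            value = float(get("value_nM"))
        except ValueError:
            report.reject("unparseable_value")
            continue
        if value <= 0:
            report.reject("non_positive_value")
            continue
        species = get("species")
        if species not in SPECIES:
            report.reject("unknown_species")
            continue
        assay_type = get("assay_type")
        if assay_type not in ASSAY_TYPES:
            report.reject("unknown_assay_type")
            continue
        measure = get("measure")
        if measure not in MEASURES:
            report.reject("unknown_measure")
            continue
        try:
            confidence = int(get("confidence"))
            if not 0 <= confidence <= 9:
                raise ValueError
        except ValueError:
            report.reject("bad_confidence")
            continue
        inchikey = get("inchikey") or None
        if inchikey is not None and not INCHIKEY_RE.match(inchikey):
            report.reject("malformed_inchikey")
            continue
        records.append(
            ActivityRecord(
                molecule_id=get("molecule_id"),
                smiles=smiles,
                inchikey=inchikey,
                target_id=get("target_id"),
                species=species,
                assay_type=assay_type,
                measure=measure,
                value_nM=value,
                confidence=confidence,
            )
        )
    report.n_accepted = len(records)
    return records, report


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    """Write records back to the canonical-header CSV form (reader inverse)."""
    rows = [
        {
            "molecule_id": r.molecule_id,
            "smiles": r.smiles,
            "inchikey": r.inchikey or "",
            "target_id": r.target_id,
            "species": r.species,
            "assay_type": r.assay_type,
            "measure": r.measure,
            "value_nM": repr(r.value_nM),
            "confidence": r.confidence,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ACTIVITY_FIELDS)).to_csv(path, index=False)


def read_target_table(path: str | Path, sep: str | None = None) -> list[TargetEntity]:
    """Read target metadata: target_id, name, species, ui_id, protein_class_ids.

    ``protein_class_ids`` is an optional ``;``-separated list column.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    targets = []
    for row in df.itertuples(index=False):
        classes = tuple(c for c in str(getattr(row, "protein_class_ids", "")).split(";") if c)
        targets.append(
            TargetEntity(
                target_id=row.target_id,
                name=getattr(row, "name", row.target_id),
                species=row.species,
                ui_id=row.ui_id,
                protein_class_ids=classes,
            )
        )
    return targets


def read_protein_classes(path: str | Path, sep: str | None = None) -> list[ProteinClassNode]:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return [
        ProteinClassNode(
            class_id=row.class_id,
            name=getattr(row, "name", row.class_id),
            level=int(row.level),
            parent_id=(row.parent_id or None) if hasattr(row, "parent_id") else None,
        )
        for row in df.itertuples(index=False)
    ]


def read_annotations(
    members_path: str | Path,
    names_path: str | Path | None = None,
    namespace: str | None = None,
) -> list[AnnotationMap]:
    """Read term annotations from a 2-column ``term_id<TAB>ui_id`` file.

    The optional names file maps ``term_id<TAB>term_name``.  The namespace
    is taken from the term-id prefix (``GO:`` / ``KEGG:`` / ``DOID:``)
    unless given explicitly.
    """
    members: dict[str, set[str]] = {}
    with open(members_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term_id, ui_id = line.split("\t")[:2]
            members.setdefault(term_id, set()).add(ui_id)
    names: dict[str, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                term_id, name = line.split("\t")[:2]
                names[term_id] = name
    out = []
    for term_id in sorted(members):
        ns = namespace or _infer_namespace(term_id)
        out.append(
            AnnotationMap(
                term_id=term_id,
                term_name=names.get(term_id, term_id),
                namespace=ns,
                members=frozenset(members[term_id]),
            )
        )
    return out


def _infer_namespace(term_id: str) -> str:
    prefix = term_id.split(":", 1)[0].upper()
    if prefix == "GO":
        return "GO"
    if prefix == "DOID":
        return "DO"
    if prefix in {"KEGG", "HSA", "PATH"}:
        return "KEGG"
    raise ValueError(f"cannot infer namespace from term id {term_id!r}")


def map_targets_to_ui(targets: Iterable[TargetEntity]) -> dict[str, str]:
    """Collapse species-specific targets onto species-agnostic protein entries.

    Orthologous targets (same protein entry measured in human, rat or
    mouse) share one ``ui_id`` and are treated as a single protein in all
    downstream counting, so species replicates never inflate coverage.

    Raises
    ------
    DataIntegrityError
        If the same ``target_id`` appears with two different entries.
    """
    mapping: dict[str, str] = {}
    for t in targets:
        prev = mapping.get(t.target_id)
        if prev is not None and prev != t.ui_id:
            raise DataIntegrityError(
                f"target {t.target_id} maps to both {prev} and {t.ui_id}"
            )
        mapping[t.target_id] = t.ui_id
    return mapping
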