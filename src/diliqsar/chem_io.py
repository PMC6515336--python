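"""Reading and writing labeled compound tables.

Compounds arrive as SMILES in CSV/TSV tables or as SDF files with label and
source tags.  Every structure is tracked as a :class:`CompoundRecord` through
the whole curation pipeline; records are never silently dropped — a record
that fails some stage keeps its identity and gets a ``rejected_*`` status and
a reason.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unknown")
TIERS = ("tier1", "tier2")
STATUSES = (
    "active",
    "rejected_structure",
    "rejected_size",
    "rejected_conflict",
    "rejected_vote",
)

#: accepted spellings of the binary hepatotoxicity label, lower-cased
_LABEL_ALIASES = {
    "1": "positive",
    "1.0": "positive",
    "pos": "positive",
    "positive": "positive",
    "p": "positive",
    "true": "positive",
    "0": "negative",
    "0.0": "negative",
    "neg": "negative",
    "negative": "negative",
    "n": "negative",
    "false": "negative",
    "": "unknown",
    "nan": "unknown",
    "unknown": "unknown",
    "na": "unknown",
}

CSV_COLUMNS = [
    "compound_id",
    "smiles",
    "label",
    "source_name",
    "source_tier",
    "canonical_key",
    "status",
    "reject_reason",
]


class CompoundTableError(ValueError):
    """Raised for malformed compound tables (duplicate ids, bad labels...)."""


@dataclass
class CompoundRecord:
    """One structure with identity, label, provenance and curation status.

    ``canonical_key`` is a hash of the standardized (salt-stripped, neutral,
    stereo-free) structure and is only defined once standardization has run;
    salt forms and stereoisomers of one parent share a key.
    """

    compound_id: str
    smiles: str
    label: str = "unknown"
    source_name: str = ""
    source_tier: str = "tier2"
    canonical_key: str | None = None
    status: str = "active"
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise CompoundTableError(
                f"record {self.compound_id!r}: label must be one of {LABELS}, "
                f"got {self.label!r}"
            )
        if self.source_tier not in TIERS:
            raise CompoundTableError(
                f"record {self.compound_id!r}: source_tier must be one of "
                f"{TIERS}, got {self.source_tier!r}"
            )
        if self.status not in STATUSES:
            raise CompoundTableError(
                f"record {self.compound_id!r}: unknown status {self.status!r}"
            )

    @property
    def is_active(self) -> bool:
        return self.status == "active"

    def rejected(self, status: str, reason: str) -> "CompoundRecord":
        """Return a copy of this record marked rejected.

        A structure-level rejection also clears the canonical key (the key
        is only defined for records with a standardized structure).
        """
        key = None if status == "rejected_structure" else self.canonical_key
        return replace(self, status=status, reject_reason=reason, canonical_key=key)


def normalize_label(raw: object) -> str:
    """Map a raw label value (1/0, pos/neg, positive/negative...) onto the
    canonical {positive, negative, unknown} vocabulary."""
    key = str(raw).strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise CompoundTableError(f"unrecognized label value {raw!r}")


def structure_key(smiles: str) -> str:
    """Stable short hash of a (canonical) SMILES string."""
    return hashlib.sha1(smiles.encode()).hexdigest()[:16]


def _check_unique_ids(records: Sequence[CompoundRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.compound_id] = seen.get(rec.compound_id, 0) + 1
    dupes = sorted(cid for cid, n in seen.items() if n > 1)
    if dupes:
        raise CompoundTableError(
            f"duplicate compound_id values: {', '.join(dupes[:10])}"
        )


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    raise CompoundTableError(f"cannot infer compound-table format from {path}")


def read_compound_table(
    path: str | Path, format: str | None = None
) -> list[CompoundRecord]:
    """Read a compound table (CSV/TSV with a header, or SDF).

    CSV/TSV must carry at least ``compound_id, smiles, label, source_name``
    columns (``source_tier`` and curation columns are optional and round-trip
    if present).  SDF records carry the label/source as ``<LABEL>`` /
    ``<SOURCE>`` / ``<TIER>`` tags; an SDF molecule that RDKit cannot parse
    still produces a record, with status ``rejected_structure``.
    """
    path = Path(path)
    fmt = format or infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("csv", "tsv"):
        records = _read_delimited(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "sdf":
        records = _read_sdf(path)
    else:
        raise CompoundTableError(f"unsupported format {fmt!r}")
    _check_unique_ids(records)
    return records


def _read_delimited(path: Path, sep: str) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"compound_id", "smiles", "label"}
    missing = required - set(df.columns)
    if missing:
        raise CompoundTableError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CompoundRecord(
                compound_id=d["compound_id"],
                smiles=d["smiles"],
                label=normalize_label(d.get("label", "")),
                source_name=d.get("source_name", ""),
                source_tier=d.get("source_tier") or "tier2",
                canonical_key=d.get("canonical_key") or None,
                status=d.get("status") or "active",
                reject_reason=d.get("reject_reason") or None,
            )
        )
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            # RDKit could not sanitize this block; keep the record, flag it
            logger.warning("%s: molecule #%d unparsable", path, i)
            records.append(
                CompoundRecord(
                    compound_id=f"sdf_{i}",
                    smiles="",
                    status="rejected_structure",
                    reject_reason="unparsable SDF block",
                )
            )
            continue
        props = mol.GetPropsAsDict()
        cid = str(
            props.get("COMPOUND_ID", mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}")
        ) or f"sdf_{i}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=Chem.MolToSmiles(mol),
                label=normalize_label(props.get("LABEL", "")),
                source_name=str(props.get("SOURCE", "")),
                source_tier=str(props.get("TIER", "tier2")),
            )
        )
    return records


def write_dataset(records: Iterable[CompoundRecord], path: str | Path) -> Path:
    """Write records as CSV (all fields, including curation status).

    ``read_compound_table(write_dataset(x))`` reproduces ids, labels,
    statuses and keys exactly.
    """
    path = Path(path)
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "label": r.label,
            "source_name": r.source_name,
            "source_tier": r.source_tier,
            "canonical_key": r.canonical_key or "",
            "status": r.status,
            "reject_reason": r.reject_reason or "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
    return path


def write_sdf(records: Iterable[CompoundRecord], path: str | Path) -> Path:
    """Write parsable records to an SDF (V2000) with LABEL/SOURCE/TIER tags."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                logger.warning("skipping %s: unparsable SMILES", r.compound_id)
                continue
            mol.SetProp("_Name", r.compound_id)
            mol.SetProp("COMPOUND_ID", r.compound_id)
            mol.SetProp("LABEL", r.label)
            mol.SetProp("SOURCE", r.source_name)
            mol.SetProp("TIER", r.source_tier)
            writer.write(mol)
    finally:
        writer.close()
    return path
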