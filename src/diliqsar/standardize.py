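"""Structure normalization and admission rules.

The curation protocol admits only ordinary organic structures:

1. counterions, water and solvents are stripped, keeping the largest
   organic component (salts are thereby converted to the parent acid/base);
2. anything containing a metal or otherwise non-organic element, any
   inorganic species and any true multi-component mixture is rejected;
3. aromatic systems are written in Kekulé form, formal charges are
   neutralized where this is a pure (de)protonation, and all stereochemical
   annotations are cleared — the model treats enantiomers as one compound;
4. tiny fragments (fewer than 4 carbons) and very large structures
   (molecular weight above 900) are rejected.

The whole pass is idempotent: re-standardizing a standardized record is a
no-op.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

from .chem_io import CompoundRecord, structure_key

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

#: conventional organic/QSAR element whitelist ("metal and rare atoms" are
#: everything outside it)
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

MIN_CARBONS = 4          # fewer than 4 carbons -> rejected
MAX_MOLECULAR_WEIGHT = 900.0  # strictly greater than 900 -> rejected

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass
class StandardizationReport:
    """Bookkeeping for one standardization pass; counts are conserved."""

    input_count: int = 0
    rejected_unparsable: int = 0
    rejected_metal_or_rare: int = 0
    rejected_mixture_inorganic: int = 0
    rejected_size: int = 0
    passed: int = 0

    def check(self) -> None:
        total = (
            self.rejected_unparsable
            + self.rejected_metal_or_rare
            + self.rejected_mixture_inorganic
            + self.rejected_size
            + self.passed
        )
        if total != self.input_count:
            raise AssertionError(
                f"standardization counts not conserved: {total} != {self.input_count}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _carbon_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")


def _strip_to_parent(mol: Chem.Mol) -> tuple[Chem.Mol | None, str | None]:
    """Strip counterions/solvents; return (parent, rejection reason).

    The largest carbon-containing fragment (by heavy-atom count, ties broken
    by canonical SMILES for determinism) is the parent.  If two or more
    fragments each carry >= 4 carbons the input is a true mixture, not a
    salt form, and is rejected; if no fragment contains carbon the input is
    inorganic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _carbon_count(f) > 0]
    if not organic:
        return None, "inorganic (no carbon-containing component)"
    big = [f for f in organic if _carbon_count(f) >= MIN_CARBONS]
    if len(big) >= 2:
        return None, "mixture (multiple organic components)"
    parent = max(
        organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
    )
    return parent, None


def standardize_structure(record: CompoundRecord) -> CompoundRecord:
    """Normalize one record's structure and set its canonical key.

    Rejections (unparsable, metal/rare element, inorganic, mixture) set
    status ``rejected_structure`` with a reason; survivors get the
    standardized SMILES and a ``canonical_key``.
    """
    if record.status == "rejected_structure":
        return record
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return record.rejected("rejected_structure", "unparsable SMILES")

    parent, reason = _strip_to_parent(mol)
    if parent is None:
        return record.rejected("rejected_structure", reason or "no parent")

    bad = sorted(
        {a.GetSymbol() for a in parent.GetAtoms()} - ALLOWED_ELEMENTS
    )
    if bad:
        return record.rejected(
            "rejected_structure", f"metal or rare atom: {', '.join(bad)}"
        )

    try:
        Chem.SanitizeMol(parent)
        parent = _UNCHARGER.uncharge(parent)
        Chem.RemoveStereochemistry(parent)
        Chem.Kekulize(parent, clearAromaticFlags=True)
        Chem.SanitizeMol(parent)
        smiles = Chem.MolToSmiles(parent, isomericSmiles=False)
    except Exception as exc:  # pragma: no cover - rdkit sanitization corner
        return record.rejected("rejected_structure", f"sanitization failed: {exc}")

    return replace(
        record,
        smiles=smiles,
        canonical_key=structure_key(smiles),
        status="active",
        reject_reason=None,
    )


def apply_size_filters(record: CompoundRecord) -> CompoundRecord:
    """Reject standardized parents with < 4 carbons or MW > 900.

    Both boundaries are strict as stated: exactly 4 carbons or MW 900.00 is
    kept.  MW is the average molecular weight from standard atomic masses,
    hydrogens included.
    """
    if not record.is_active:
        return record
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # pragma: no cover - guarded by standardize_structure
        return record.rejected("rejected_structure", "unparsable SMILES")
    n_carbon = _carbon_count(mol)
    mw = Descriptors.MolWt(mol)
    if n_carbon < MIN_CARBONS:
        return record.rejected("rejected_size", f"{n_carbon} carbon atoms < {MIN_CARBONS}")
    if mw > MAX_MOLECULAR_WEIGHT:
        return record.rejected("rejected_size", f"MW {mw:.2f} > {MAX_MOLECULAR_WEIGHT:.0f}")
    return record


def standardize_dataset(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], StandardizationReport]:
    """Run the full standardization + size-filter pass over a dataset."""
    report = StandardizationReport(input_count=len(records))
    out: list[CompoundRecord] = []
    for rec in records:
        std = apply_size_filters(standardize_structure(rec))
        out.append(std)
        if std.status == "rejected_structure":
            reason = std.reject_reason or ""
            if "metal or rare" in reason:
                report.rejected_metal_or_rare += 1
            elif "inorganic" in reason or "mixture" in reason:
                report.rejected_mixture_inorganic += 1
            else:
                report.rejected_unparsable += 1
            logger.info("rejected %s: %s", std.compound_id, reason)
        elif std.status == "rejected_size":
            report.rejected_size += 1
        else:
            report.passed += 1
    report.check()
    return out, report
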