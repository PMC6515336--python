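"""Molecular descriptors, path fingerprints and diversity summaries.

The feature block is a named, versioned set of 85 descriptors — 30
physicochemical (mass, lipophilicity, polarizability, refractivity,
H-bonding, surface area, composition, charge) and 55 topological (ring
system, connectivity indices, kappa shape, VSA partitions) — computed with
RDKit.  The proprietary descriptor set the protocol was originally run with
is not reproducible bit-for-bit; this set covers the same property families
and keeps the four descriptors known to matter for hepatotoxicity models
(molecular weight, ClogP, polarizability, molar refractivity) mandatory.

Chemical diversity is summarized by pairwise Tanimoto similarity on hashed
linear-path fingerprints (paths up to 7 bonds folded to 1024 bits, the FP2
convention) and by the MW/ClogP chemical-space ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors

from .chem_io import CompoundRecord

logger = logging.getLogger(__name__)

DESCRIPTOR_SET_VERSION = "rdkit-85-v1"

#: element-additive atomic polarizabilities (Angstrom^3), used because no
#: molecular-polarizability descriptor ships with RDKit
_ATOMIC_POLARIZABILITY = {
    "H": 0.6668, "B": 3.03, "C": 1.76, "N": 1.10, "O": 0.802,
    "F": 0.557, "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18,
    "Se": 3.77, "Br": 3.05, "I": 5.35,
}


def molecular_polarizability(mol: Chem.Mol) -> float:
    """Element-additive estimate of molecular polarizability (Angstrom^3)."""
    total = 0.0
    for atom in mol.GetAtoms():
        total += _ATOMIC_POLARIZABILITY.get(atom.GetSymbol(), 0.0)
        total += atom.GetTotalNumHs() * _ATOMIC_POLARIZABILITY["H"]
    return total


def _atom_count(symbol: str) -> Callable[[Chem.Mol], float]:
    def count(mol: Chem.Mol) -> float:
        return float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol))
    return count


def _halogen_count(mol: Chem.Mol) -> float:
    return float(
        sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I"))
    )


def _hydrogen_count(mol: Chem.Mol) -> float:
    return float(sum(a.GetTotalNumHs() for a in mol.GetAtoms()))


def _build_descriptor_set() -> list[tuple[str, str, Callable[[Chem.Mol], float]]]:
    """The ordered (name, class, function) triples of descriptor set v1."""
    phys: list[tuple[str, Callable]] = [
        ("MolWt", Descriptors.MolWt),
        ("HeavyAtomMolWt", Descriptors.HeavyAtomMolWt),
        ("ExactMolWt", Descriptors.ExactMolWt),
        ("ClogP", Crippen.MolLogP),
        ("MolarRefractivity", Crippen.MolMR),
        ("Polarizability", molecular_polarizability),
        ("TPSA", Descriptors.TPSA),
        ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
        ("NumHDonors", Descriptors.NumHDonors),
        ("NumHAcceptors", Descriptors.NumHAcceptors),
        ("NumRotatableBonds", Descriptors.NumRotatableBonds),
        ("NumHeteroatoms", Descriptors.NumHeteroatoms),
        ("NOCount", Descriptors.NOCount),
        ("NHOHCount", Descriptors.NHOHCount),
        ("FractionCSP3", Descriptors.FractionCSP3),
        ("NumValenceElectrons", Descriptors.NumValenceElectrons),
        ("FormalCharge", lambda m: float(Chem.GetFormalCharge(m))),
        ("NumCarbonAtoms", _atom_count("C")),
        ("NumNitrogenAtoms", _atom_count("N")),
        ("NumOxygenAtoms", _atom_count("O")),
        ("NumSulfurAtoms", _atom_count("S")),
        ("NumHalogenAtoms", _halogen_count),
        ("HeavyAtomCount", Descriptors.HeavyAtomCount),
        ("NumHydrogenAtoms", _hydrogen_count),
        ("MaxEStateIndex", Descriptors.MaxEStateIndex),
        ("MinEStateIndex", Descriptors.MinEStateIndex),
        ("MaxAbsEStateIndex", Descriptors.MaxAbsEStateIndex),
        ("MinAbsEStateIndex", Descriptors.MinAbsEStateIndex),
        ("QED", Descriptors.qed),
        ("NumAmideBonds", rdMolDescriptors.CalcNumAmideBonds),
    ]
    topo: list[tuple[str, Callable]] = [
        ("RingCount", Descriptors.RingCount),
        ("NumAromaticRings", Descriptors.NumAromaticRings),
        ("NumSaturatedRings", Descriptors.NumSaturatedRings),
        ("NumAliphaticRings", Descriptors.NumAliphaticRings),
        ("NumAromaticHeterocycles", Descriptors.NumAromaticHeterocycles),
        ("NumAromaticCarbocycles", Descriptors.NumAromaticCarbocycles),
        ("NumSaturatedHeterocycles", Descriptors.NumSaturatedHeterocycles),
        ("NumSaturatedCarbocycles", Descriptors.NumSaturatedCarbocycles),
        ("NumAliphaticHeterocycles", Descriptors.NumAliphaticHeterocycles),
        ("NumAliphaticCarbocycles", Descriptors.NumAliphaticCarbocycles),
        ("NumSpiroAtoms", rdMolDescriptors.CalcNumSpiroAtoms),
        ("NumBridgeheadAtoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
        ("BondCount", lambda m: float(m.GetNumBonds())),
        ("BalabanJ", GraphDescriptors.BalabanJ),
        ("BertzCT", GraphDescriptors.BertzCT),
        ("AvgIpc", lambda m: GraphDescriptors.Ipc(m, avg=True)),
        ("HallKierAlpha", Descriptors.HallKierAlpha),
        ("Kappa1", Descriptors.Kappa1),
        ("Kappa2", Descriptors.Kappa2),
        ("Kappa3", Descriptors.Kappa3),
        ("Phi", rdMolDescriptors.CalcPhi),
        ("Chi0", Descriptors.Chi0),
        ("Chi1", Descriptors.Chi1),
        ("Chi0n", Descriptors.Chi0n),
        ("Chi1n", Descriptors.Chi1n),
        ("Chi2n", Descriptors.Chi2n),
        ("Chi3n", Descriptors.Chi3n),
        ("Chi4n", Descriptors.Chi4n),
        ("Chi0v", Descriptors.Chi0v),
        ("Chi1v", Descriptors.Chi1v),
        ("Chi2v", Descriptors.Chi2v),
        ("Chi3v", Descriptors.Chi3v),
        ("Chi4v", Descriptors.Chi4v),
    ]
    topo += [
        (f"SMR_VSA{i}", getattr(Descriptors, f"SMR_VSA{i}")) for i in range(1, 11)
    ]
    topo += [
        (f"SlogP_VSA{i}", getattr(Descriptors, f"SlogP_VSA{i}"))
        for i in range(1, 13)
    ]
    out = [(name, "physicochemical", fn) for name, fn in phys]
    out += [(name, "topological", fn) for name, fn in topo]
    return out


DESCRIPTOR_SET = _build_descriptor_set()
DESCRIPTOR_NAMES = [name for name, _, _ in DESCRIPTOR_SET]
DESCRIPTOR_CLASSES = {name: cls for name, cls, _ in DESCRIPTOR_SET}

assert len(DESCRIPTOR_NAMES) == 85
assert sum(1 for c in DESCRIPTOR_CLASSES.values() if c == "physicochemical") == 30
assert sum(1 for c in DESCRIPTOR_CLASSES.values() if c == "topological") == 55


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds x named numeric features with per-feature class metadata."""

    values: pd.DataFrame  # index = compound_id, columns = feature names
    feature_classes: dict[str, str] = field(default_factory=dict)
    version: str = DESCRIPTOR_SET_VERSION

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            self.values.loc[list(ids)], dict(self.feature_classes), self.version
        )

    def subset_features(self, names: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            self.values[list(names)],
            {n: self.feature_classes.get(n, "") for n in names},
            self.version,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path, index_label="compound_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="compound_id")
        df.index = df.index.astype(str)
        classes = {c: DESCRIPTOR_CLASSES.get(c, "") for c in df.columns}
        return cls(df, classes)


def compute_descriptors(record: CompoundRecord) -> dict[str, float]:
    """Compute the full named descriptor row for one standardized record.

    Raises :class:`DescriptorError` if the structure cannot be parsed or any
    descriptor comes back non-finite; callers flag the row and keep it out of
    modeling.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise DescriptorError(f"{record.compound_id}: unparsable SMILES")
    row: dict[str, float] = {}
    for name, _cls, fn in DESCRIPTOR_SET:
        try:
            value = float(fn(mol))
        except Exception as exc:
            raise DescriptorError(f"{record.compound_id}: {name} failed: {exc}")
        if not math.isfinite(value):
            raise DescriptorError(f"{record.compound_id}: {name} is non-finite")
        row[name] = value
    return row


def compute_descriptor_matrix(
    records: Sequence[CompoundRecord], active_only: bool = True
) -> tuple[DescriptorMatrix, list[str]]:
    """Descriptor rows for a dataset; returns (matrix, flagged compound ids).

    Flagged compounds (descriptor failure) are excluded from the matrix and
    logged, never silently imputed.
    """
    rows, ids, flagged = [], [], []
    for rec in records:
        if active_only and not rec.is_active:
            continue
        try:
            rows.append(compute_descriptors(rec))
            ids.append(rec.compound_id)
        except DescriptorError as exc:
            logger.warning("descriptor row flagged: %s", exc)
            flagged.append(rec.compound_id)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"), columns=DESCRIPTOR_NAMES)
    return DescriptorMatrix(df, dict(DESCRIPTOR_CLASSES)), flagged


# ---------------------------------------------------------------------------
# fingerprints & diversity


@dataclass
class BitFingerprint:
    """Fixed-length hashed path fingerprint for one molecule."""

    molecule_id: str
    bits: np.ndarray  # boolean vector

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_hex(self) -> str:
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()

    @classmethod
    def from_hex(cls, molecule_id: str, hex_string: str, n_bits: int = 1024):
        raw = np.frombuffer(bytes.fromhex(hex_string), dtype=np.uint8)
        bits = np.unpackbits(raw)[:n_bits].astype(bool)
        return cls(molecule_id, bits)


def compute_fingerprint(
    record: CompoundRecord, n_bits: int = 1024, max_path: int = 7
) -> BitFingerprint:
    """Hashed linear-path fingerprint (paths of 1..max_path bonds).

    Deterministic per structure.  A molecule with no bonds between heavy
    atoms (e.g. methane) has no paths and yields the all-zero fingerprint.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise DescriptorError(f"{record.compound_id}: unparsable SMILES")
    fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=max_path, fpSize=n_bits)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return BitFingerprint(record.compound_id, bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined as identical (similarity 1.0).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}"
        )
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a.bits & b.bits))
    return inter / union


@dataclass
class DiversitySummary:
    mean_tanimoto: float
    histogram_counts: np.ndarray   # 10 bins over [0, 1]
    histogram_edges: np.ndarray
    mw_range: tuple[float, float]
    clogp_range: tuple[float, float]
    n_compounds: int
    n_pairs: int


def diversity_summary(records: Sequence[CompoundRecord]) -> DiversitySummary:
    """Pairwise-Tanimoto distribution and MW/ClogP chemical-space ranges."""
    records = [r for r in records if r.is_active]
    if len(records) < 2:
        raise ValueError("diversity summary needs at least 2 compounds")
    fps = [compute_fingerprint(r) for r in records]
    sims = [
        tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    counts, edges = np.histogram(sims, bins=10, range=(0.0, 1.0))
    mols = [Chem.MolFromSmiles(r.smiles) for r in records]
    mws = [Descriptors.MolWt(m) for m in mols]
    logps = [Crippen.MolLogP(m) for m in mols]
    return DiversitySummary(
        mean_tanimoto=float(np.mean(sims)),
        histogram_counts=counts,
        histogram_edges=edges,
        mw_range=(min(mws), max(mws)),
        clogp_range=(min(logps), max(logps)),
        n_compounds=len(records),
        n_pairs=len(sims),
    )


def write_fingerprints(fps: Iterable[BitFingerprint], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"compound_id": f.molecule_id, "fingerprint_hex": f.to_hex(), "n_bits": f.n_bits} for f in fps]
    )
    df.to_csv(path, index=False)
    return path
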