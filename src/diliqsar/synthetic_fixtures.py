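"""Synthetic datasets for exercising every pipeline stage offline.

Two generators:

* :func:`generate_synthetic_dataset` — a two-class Gaussian descriptor
  table with controllable per-feature class separation (in SD units),
  injected redundant (|r| > 0.95) and near-constant columns, and optional
  label noise whose flipped rows are recorded.  The Gaussian
  class-conditional model is deliberate: its Bayes error is available in
  closed form, so empirical accuracies have an analytic cross-check.
* :func:`generate_smiles_dataset` — programmatically assembled valid SMILES
  (substituted rings and hetero-chains) with labels tied to a noisy
  molecular-weight rule, for end-to-end runs through the chemistry stages.

A third fixture, :func:`toy_smiles_fixture`, is a hand-picked truth table
of ~30 structures spanning every standardization branch (salts, mixtures,
metal atoms, tiny/huge molecules, stereo pairs, ordinary drugs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors

from .chem_io import CompoundRecord
from .descriptors import DescriptorMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the Gaussian two-class descriptor generator.

    ``signal`` is the between-class mean separation, in within-class SD
    units, applied to each of the first ``n_informative`` base features;
    the remaining base features are pure noise.  Redundant columns copy
    randomly chosen base columns with 5% added noise (r ~ 0.999);
    near-constant columns hold one value on > 95% of rows.
    """

    n: int = 600
    n_features: int = 55
    class_balance: float = 0.5
    signal: float = 1.0
    n_informative: int | None = None  # None -> min(5, base features)
    n_redundant: int = 0
    n_near_constant: int = 0
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"invalid SyntheticSpec.n: {self.n}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(
                f"invalid SyntheticSpec.class_balance: {self.class_balance}"
            )
        if self.signal < 0:
            raise ValueError(f"invalid SyntheticSpec.signal: {self.signal}")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError(f"invalid SyntheticSpec.label_noise: {self.label_noise}")
        n_base = self.n_features - self.n_redundant - self.n_near_constant
        if n_base < 1:
            raise ValueError(
                "invalid SyntheticSpec.n_features: no base features left after "
                "redundant/near-constant injection"
            )
        if self.n_informative is not None and not 0 <= self.n_informative <= n_base:
            raise ValueError(
                f"invalid SyntheticSpec.n_informative: {self.n_informative}"
            )

    def resolved_informative(self) -> int:
        n_base = self.n_features - self.n_redundant - self.n_near_constant
        return min(5, n_base) if self.n_informative is None else self.n_informative


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for verification in tests."""

    informative_features: list[str]
    redundant_pairs: list[tuple[str, str]]  # (injected, source)
    near_constant_features: list[str]
    flipped_ids: list[str]
    clean_labels: pd.Series = field(repr=False)


def generate_synthetic_dataset(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, pd.Series, SyntheticTruth]:
    """Generate (matrix, labels, truth) reproducibly from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_base = spec.n_features - spec.n_redundant - spec.n_near_constant
    n_pos = int(round(spec.n * spec.class_balance))
    y = np.array([1] * n_pos + [0] * (spec.n - n_pos))

    X = rng.standard_normal((spec.n, n_base))
    # symmetric mean shift: +signal/2 for positives, -signal/2 for negatives
    shift = np.where(y == 1, spec.signal / 2.0, -spec.signal / 2.0)
    n_informative = spec.resolved_informative()
    X[:, :n_informative] += shift[:, None]

    base_names = [f"feat_{i:02d}" for i in range(n_base)]
    columns = {name: X[:, i] for i, name in enumerate(base_names)}

    redundant_pairs = []
    for i in range(spec.n_redundant):
        src = base_names[int(rng.integers(n_base))]
        name = f"redundant_{i:02d}"
        columns[name] = columns[src] + 0.05 * rng.standard_normal(spec.n)
        redundant_pairs.append((name, src))

    near_constant = []
    for i in range(spec.n_near_constant):
        name = f"nearconst_{i:02d}"
        col = np.full(spec.n, 1.0)
        # strictly fewer than 5% of rows get a different value
        n_off = max(1, int(0.02 * spec.n))
        off = rng.choice(spec.n, size=n_off, replace=False)
        col[off] = rng.standard_normal(n_off) + 5.0
        columns[name] = col
        near_constant.append(name)

    ids = [f"cmpd_{i:04d}" for i in range(spec.n)]
    df = pd.DataFrame(columns, index=pd.Index(ids, name="compound_id"))
    labels = pd.Series(y, index=df.index, name="label")
    clean = labels.copy()

    flipped: list[str] = []
    if spec.label_noise > 0:
        n_flip = int(round(spec.label_noise * spec.n))
        flip_idx = rng.choice(spec.n, size=n_flip, replace=False)
        labels.iloc[flip_idx] = 1 - labels.iloc[flip_idx]
        flipped = [ids[i] for i in sorted(flip_idx)]

    truth = SyntheticTruth(
        informative_features=base_names[:n_informative],
        redundant_pairs=redundant_pairs,
        near_constant_features=near_constant,
        flipped_ids=flipped,
        clean_labels=clean,
    )
    matrix = DescriptorMatrix(df, {c: "synthetic" for c in df.columns}, "synthetic")
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# SMILES fixtures

# hand-picked truth table: (id, smiles, label, expected post-standardization
# status).  Statuses: active, rejected_structure (metal/rare atom, inorganic,
# mixture, unparsable) or rejected_size (<4 C or MW>900).
_TOY_SMILES: list[tuple[str, str, str, str]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", "positive", "active"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", "positive", "active"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", "positive", "active"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "negative", "active"),
    ("benzene", "c1ccccc1", "negative", "active"),
    ("naphthalene", "c1ccc2ccccc2c1", "negative", "active"),
    ("toluene", "Cc1ccccc1", "negative", "active"),
    ("nicotine", "CN1CCCC1c1cccnc1", "positive", "active"),
    ("valproate", "CCCC(CCC)C(=O)O", "positive", "active"),
    ("isoniazid", "NNC(=O)c1ccncc1", "positive", "active"),
    # salt forms: counterion stripped, parent kept
    ("ibuprofen_na", "CC(C)Cc1ccc(C(C)C(=O)[O-])cc1.[Na+]", "positive", "active"),
    ("diphenhydramine_hcl", "CN(C)CCOC(c1ccccc1)c1ccccc1.Cl", "negative", "active"),
    ("butyrate_k", "CCCC(=O)[O-].[K+]", "negative", "active"),
    ("amine_hbr", "NCCCCc1ccccc1.Br", "negative", "active"),
    # hydrate: water removed
    ("hydrate", "CCCCCC(=O)O.O", "negative", "active"),
    # charged parent: neutralized
    ("anilinium", "[NH3+]c1ccccc1", "negative", "active"),
    # stereoisomer pair: collapses to a single canonical key
    ("phe_L", "N[C@@H](Cc1ccccc1)C(=O)O", "negative", "active"),
    ("phe_D", "N[C@H](Cc1ccccc1)C(=O)O", "negative", "active"),
    # metal / rare atoms
    ("cisplatin_like", "N.N.Cl[Pt]Cl", "positive", "rejected_structure"),
    ("phenylmercury", "CC(=O)O[Hg]c1ccccc1", "positive", "rejected_structure"),
    ("tributyltin", "CCCC[Sn](CCCC)CCCC", "positive", "rejected_structure"),
    ("phenylarsonic", "O[As](=O)(O)c1ccccc1", "positive", "rejected_structure"),
    # inorganic / no carbon
    ("water", "O", "negative", "rejected_structure"),
    ("saline", "[Na+].[Cl-]", "negative", "rejected_structure"),
    ("silica", "O=[Si]=O", "negative", "rejected_structure"),
    # true mixtures (two organic components with >= 4 carbons each)
    ("mixture_two_drugs", "CCCCO.CCCCc1ccccc1", "negative", "rejected_structure"),
    ("mixture_acids", "CCCCC(=O)O.OC(=O)CCCCC", "negative", "rejected_structure"),
    # size filter
    ("propane", "CCC", "negative", "rejected_size"),
    ("methanol", "CO", "negative", "rejected_size"),
    ("acetate_na", "CC(=O)[O-].[Na+]", "negative", "rejected_size"),
    ("huge_alkane", "C" * 70, "negative", "rejected_size"),
    # unparsable
    ("garbage", "not_a_smiles", "unknown", "rejected_structure"),
]

#: expected post-standardization status per toy compound id
TOY_EXPECTED_STATUS = {cid: status for cid, _, _, status in _TOY_SMILES}


def toy_smiles_fixture() -> list[CompoundRecord]:
    """The hand-picked standardization truth-table fixture (~30 records)."""
    return [
        CompoundRecord(compound_id=cid, smiles=smi, label=label, source_name="toy")
        for cid, smi, label, _status in _TOY_SMILES
    ]


_SCAFFOLDS = [
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCCCC1",      # cyclohexane
    "c1ccsc1",       # thiophene
    "c1ccoc1",       # furan
]
_SUBSTITUENTS = ["C", "CC", "CCC", "O", "N", "F", "Cl", "Br", "C(=O)O", "C(=O)N", "OC", "S"]


def generate_smiles_dataset(
    n: int, seed: int = 0, label_noise: float = 0.15
) -> list[CompoundRecord]:
    """Programmatically assemble ``n`` distinct valid labeled structures.

    Structures are scaffold + random substituent chains; the label is
    positive when molecular weight exceeds the running median, then a
    ``label_noise`` fraction is flipped — a weak but real structure-label
    signal, enough for end-to-end pipeline runs.
    """
    from rdkit import RDLogger

    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    mols: list[tuple[str, str, float]] = []
    attempts = 0
    RDLogger.DisableLog("rdApp.error")  # invalid random assemblies are expected
    try:
        while len(mols) < n and attempts < 50 * n:
            attempts += 1
            scaffold = _SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))]
            n_subs = int(rng.integers(1, 4))
            chain = "".join(
                _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
                for _ in range(n_subs)
            )
            mol = Chem.MolFromSmiles(chain + scaffold)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            mols.append((f"syn_{len(mols):04d}", canonical, _RDDescriptors.MolWt(mol)))
    finally:
        RDLogger.EnableLog("rdApp.error")
    if len(mols) < n:
        raise RuntimeError(f"could only assemble {len(mols)} distinct structures")
    median_mw = float(np.median([mw for _, _, mw in mols]))
    records = []
    for cid, smiles, mw in mols:
        label = "positive" if mw > median_mw else "negative"
        if rng.random() < label_noise:
            label = "negative" if label == "positive" else "positive"
        records.append(
            CompoundRecord(
                compound_id=cid, smiles=smiles, label=label, source_name="synthetic"
            )
        )
    return records
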