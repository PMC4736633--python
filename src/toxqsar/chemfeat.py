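"""Molecule handling and featurization.

Parses and cleans SMILES records, computes 2-D (and optionally 3-D)
molecular descriptors through RDKit analogues of the classical MOE
names, evaluates SMARTS-dictionary substructure fingerprints (PubChem-
and SubFP-style, including element count-rule bits such as ``>=2 N``),
and extracts Murcko frameworks for scaffold analysis.

Descriptor values are toolkit analogues, not name-for-name reproductions
of any commercial package; the mapping is documented in the methods
note.  All featurization is deterministic: 3-D descriptors come from a
single ETKDG conformer embedded with a fixed seed.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, GraphDescriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "MoleculeSet",
    "Rejection",
    "FeatureTable",
    "FingerprintBit",
    "FingerprintDictionary",
    "parse_and_clean",
    "compute_descriptors",
    "descriptor_table",
    "compute_fingerprint",
    "fingerprint_table",
    "murcko_framework",
    "load_dictionary",
    "bundled_dictionary",
    "read_molecule_csv",
    "DESCRIPTOR_REGISTRY",
    "DEFAULT_2D_DESCRIPTORS",
]

# 3-D embedding seed; fixed so conformer-dependent descriptors are
# reproducible across runs (no trajectory/ensemble averaging).
_EMBED_SEED = 20160201


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: identifier, SMILES and optional activity.

    ``activity`` is a continuous endpoint, conventionally pLD50 in
    log[1/(mol/kg)] — higher means more toxic.
    """

    id: str
    smiles: str
    activity: float | None = None


@dataclass(frozen=True)
class Rejection:
    """A record removed during cleaning, with a machine-readable reason."""

    id: str
    smiles: str
    reason: str  # parse_fail | duplicate | activity_range | descriptor_fail
    detail: str = ""


class MoleculeSet:
    """An ordered collection of cleaned molecules with cached RDKit mols."""

    def __init__(self, records: Sequence[MoleculeRecord], mols: Sequence[Chem.Mol]):
        if len(records) != len(mols):
            raise ValueError("records and mols must align")
        self.records = list(records)
        self.mols = list(mols)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def activities(self) -> np.ndarray:
        return np.array(
            [np.nan if r.activity is None else r.activity for r in self.records],
            dtype=float,
        )

    def subset(self, ids: Iterable[str]) -> "MoleculeSet":
        keep = set(ids)
        pairs = [(r, m) for r, m in zip(self.records, self.mols) if r.id in keep]
        return MoleculeSet([p[0] for p in pairs], [p[1] for p in pairs])


@dataclass
class FeatureTable:
    """Molecules x named features, with per-column provenance.

    ``data`` is a pandas DataFrame indexed by molecule id;
    ``provenance`` maps each column to ``"descriptor"`` or
    ``"fingerprint"``.  Fingerprint columns are {0, 1} valued.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for col in self.data.columns:
            self.provenance.setdefault(col, "descriptor")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, columns: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            self.data[list(columns)].copy(),
            {c: self.provenance[c] for c in columns},
        )

    def join(self, other: "FeatureTable") -> "FeatureTable":
        if set(self.data.columns) & set(other.data.columns):
            raise ValueError("overlapping feature names")
        data = pd.concat([self.data, other.data.loc[self.data.index]], axis=1)
        prov = dict(self.provenance)
        prov.update(other.provenance)
        return FeatureTable(data, prov)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict[str, str] | None = None) -> "FeatureTable":
        data = pd.read_csv(path, index_col="id", float_precision="round_trip")
        return cls(data, dict(provenance or {}))


# ---------------------------------------------------------------------------
# Parsing and cleaning


def parse_and_clean(
    records: Sequence[MoleculeRecord],
    activity_min: float = 0.0,
    activity_max: float = 7.0,
    require_activity: bool = True,
) -> tuple[MoleculeSet, list[Rejection]]:
    """Parse SMILES, drop invalid/duplicate/out-of-range records.

    Molecules whose activity lies outside ``[activity_min, activity_max]``
    are removed (extreme values are sparse and distort the regression
    target).  Duplicates are detected on canonical SMILES; the first
    occurrence wins.  Every removal is logged with a reason code.
    """
    if len(records) == 0:
        raise ValueError("empty input: no molecule records")
    kept_records: list[MoleculeRecord] = []
    kept_mols: list[Chem.Mol] = []
    rejections: list[Rejection] = []
    seen_smiles: set[str] = set()
    seen_ids: set[str] = set()
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rejections.append(Rejection(rec.id, rec.smiles, "parse_fail"))
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen_smiles or rec.id in seen_ids:
            rejections.append(Rejection(rec.id, rec.smiles, "duplicate", canon))
            continue
        if rec.activity is None:
            if require_activity:
                rejections.append(Rejection(rec.id, rec.smiles, "activity_range", "missing"))
                continue
        elif not (activity_min <= rec.activity <= activity_max):
            rejections.append(
                Rejection(rec.id, rec.smiles, "activity_range", f"{rec.activity!r}")
            )
            continue
        seen_smiles.add(canon)
        seen_ids.add(rec.id)
        kept_records.append(MoleculeRecord(rec.id, canon, rec.activity))
        kept_mols.append(mol)
    if not kept_records:
        raise ValueError("all records rejected during cleaning")
    return MoleculeSet(kept_records, kept_mols), rejections


def read_molecule_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read (id, smiles, pLD50) records from a headered CSV file."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("id", "smiles"):
        if needed not in cols:
            raise ValueError(f"CSV must have an '{needed}' column")
    act_col = cols.get("pld50") or cols.get("activity")
    out = []
    for _, row in df.iterrows():
        act = float(row[act_col]) if act_col is not None and pd.notna(row[act_col]) else None
        out.append(MoleculeRecord(str(row[cols["id"]]), str(row[cols["smiles"]]), act))
    return out


# ---------------------------------------------------------------------------
# Descriptors


def _kier_flex(mol: Chem.Mol) -> float:
    # Kier molecular flexibility: kappa1*kappa2 / heavy-atom count.
    n = mol.GetNumHeavyAtoms()
    if n == 0:
        return 0.0
    return Descriptors.Kappa1(mol) * Descriptors.Kappa2(mol) / n


def _esol_logs(mol: Chem.Mol) -> float:
    # Delaney ESOL estimate of intrinsic aqueous solubility (log mol/L).
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = arom / heavy if heavy else 0.0
    return (
        0.16
        - 0.63 * Crippen.MolLogP(mol)
        - 0.0062 * Descriptors.MolWt(mol)
        + 0.066 * rdMolDescriptors.CalcNumRotatableBonds(mol)
        - 0.74 * ap
    )


_ZHAO_INCREMENTS = {
    1: 7.24, 5: 40.48, 6: 20.58, 7: 15.60, 8: 14.71, 9: 13.31, 14: 38.79,
    15: 24.43, 16: 24.43, 17: 22.45, 33: 26.52, 34: 28.73, 35: 26.52,
    52: 36.62, 53: 32.52,
}


def _zhao_vdw_volume(mol: Chem.Mol) -> float:
    # Zhao/Abraham/Zissimos fast van-der-Waals volume (A^3):
    # atomic increments minus bond and ring corrections.
    molh = Chem.AddHs(mol)
    vol = 0.0
    for atom in molh.GetAtoms():
        try:
            vol += _ZHAO_INCREMENTS[atom.GetAtomicNum()]
        except KeyError:
            raise ValueError(f"no vdW increment for element Z={atom.GetAtomicNum()}")
    n_bonds = molh.GetNumBonds()
    ri = mol.GetRingInfo()
    n_arom = sum(
        1
        for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    n_nonarom = ri.NumRings() - n_arom
    return vol - 5.92 * n_bonds - 14.7 * n_arom - 3.8 * n_nonarom


def _count_element(symbol: str) -> Callable[[Chem.Mol], float]:
    def counter(mol: Chem.Mol) -> float:
        return float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol))

    return counter


def _embed_3d(mol: Chem.Mol) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise ValueError("conformer embedding failed")
    return molh


def _pmi(index: int) -> Callable[[Chem.Mol], float]:
    fns = {1: rdMolDescriptors.CalcPMI1, 2: rdMolDescriptors.CalcPMI2, 3: rdMolDescriptors.CalcPMI3}

    def calc(mol: Chem.Mol) -> float:
        return fns[index](_embed_3d(mol))

    return calc


#: name -> callable(mol) -> float.  Names follow the classical MOE-style
#: vocabulary (MW, a_acc, b_rotN, SlogP, logS, TPSA, vdw_vol, KierFlex, ...)
#: but values are RDKit analogues; see the methods note for the mapping.
DESCRIPTOR_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {
    "MW": Descriptors.MolWt,
    "SlogP": Crippen.MolLogP,
    "SMR": Crippen.MolMR,
    "logS": _esol_logs,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "a_acc": lambda m: float(rdMolDescriptors.CalcNumHBA(m)),
    "a_don": lambda m: float(rdMolDescriptors.CalcNumHBD(m)),
    "b_rotN": lambda m: float(rdMolDescriptors.CalcNumRotatableBonds(m)),
    "rings": lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    "a_aro": lambda m: float(sum(1 for a in m.GetAtoms() if a.GetIsAromatic())),
    "a_heavy": lambda m: float(m.GetNumHeavyAtoms()),
    "a_nF": _count_element("F"),
    "a_nN": _count_element("N"),
    "a_nO": _count_element("O"),
    "a_nCl": _count_element("Cl"),
    "a_nS": _count_element("S"),
    "KierFlex": _kier_flex,
    "Kier1": Descriptors.Kappa1,
    "Kier2": Descriptors.Kappa2,
    "Kier3": Descriptors.Kappa3,
    "HallKierAlpha": Descriptors.HallKierAlpha,
    "chi0v": Descriptors.Chi0v,
    "chi1v": Descriptors.Chi1v,
    "balabanJ": GraphDescriptors.BalabanJ,
    "bertzCT": GraphDescriptors.BertzCT,
    "fCsp3": rdMolDescriptors.CalcFractionCSP3,
    "vdw_vol": _zhao_vdw_volume,
    "labuteASA": rdMolDescriptors.CalcLabuteASA,
    # 3-D (single fixed-seed ETKDG conformer; may raise descriptor_fail)
    "pmi1": _pmi(1),
    "pmi2": _pmi(2),
    "pmi3": _pmi(3),
}

#: the default descriptor block used by the workflow: every 2-D name.
DEFAULT_2D_DESCRIPTORS: tuple[str, ...] = tuple(
    n for n in DESCRIPTOR_REGISTRY if not n.startswith("pmi")
)


def compute_descriptors(
    mol: MoleculeRecord | Chem.Mol | str,
    descriptor_set: Sequence[str] = DEFAULT_2D_DESCRIPTORS,
) -> dict[str, float]:
    """Compute named descriptors for one molecule.

    Raises ``KeyError`` for an unknown descriptor name and ``ValueError``
    when the molecule does not parse or a descriptor cannot be evaluated
    (callers flag the molecule ``descriptor_fail``).
    """
    rdmol = _as_mol(mol)
    unknown = [n for n in descriptor_set if n not in DESCRIPTOR_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown descriptors {unknown}; registry: {sorted(DESCRIPTOR_REGISTRY)}"
        )
    out: dict[str, float] = {}
    for name in descriptor_set:
        try:
            val = float(DESCRIPTOR_REGISTRY[name](rdmol))
        except Exception as exc:  # noqa: BLE001 - mapped to descriptor_fail
            raise ValueError(f"descriptor {name} failed: {exc}") from exc
        if not math.isfinite(val):
            raise ValueError(f"descriptor {name} is non-finite")
        out[name] = val
    return out


def descriptor_table(
    molset: MoleculeSet,
    descriptor_set: Sequence[str] = DEFAULT_2D_DESCRIPTORS,
) -> tuple[FeatureTable, list[Rejection]]:
    """Descriptor FeatureTable over a molecule set.

    Molecules failing any descriptor are dropped and logged with reason
    ``descriptor_fail`` (mirroring standard practice of removing
    molecules a descriptor engine cannot handle).
    """
    rows, ok_ids, rejections = [], [], []
    for rec, mol in zip(molset.records, molset.mols):
        try:
            rows.append(compute_descriptors(mol, descriptor_set))
            ok_ids.append(rec.id)
        except ValueError as exc:
            rejections.append(Rejection(rec.id, rec.smiles, "descriptor_fail", str(exc)))
    if not rows:
        raise ValueError("no molecule survived descriptor computation")
    data = pd.DataFrame(rows, index=ok_ids)
    return FeatureTable(data, {c: "descriptor" for c in data.columns}), rejections


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    smiles = mol.smiles if isinstance(mol, MoleculeRecord) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return rdmol


# ---------------------------------------------------------------------------
# Fingerprints

_COUNT_RULE_RE = re.compile(r"^>=\s*(\d+)\s+([A-Z][a-z]?)$")


@dataclass(frozen=True)
class FingerprintBit:
    index: int
    pattern: str  # SMARTS, or a count rule ">=<n> <El>"
    description: str
    _query: Chem.Mol | None = field(default=None, compare=False, repr=False)
    _count_rule: tuple[str, int] | None = field(default=None, compare=False, repr=False)

    def matches(self, mol: Chem.Mol) -> bool:
        if self._count_rule is not None:
            el, n = self._count_rule
            return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == el) >= n
        return mol.HasSubstructMatch(self._query)


class FingerprintDictionary:
    """Ordered list of substructure bits (SMARTS or element count rules).

    Bit indices are contiguous from 0.  Each bit carries a free-text
    description; feature columns are named ``<name>:<description-slug>``
    so alert reports stay human readable.
    """

    def __init__(self, name: str, entries: Sequence[tuple[int, str, str]]):
        self.name = name
        bits: list[FingerprintBit] = []
        for i, (idx, pattern, desc) in enumerate(entries):
            if idx != i:
                raise ValueError(f"bit indices must be contiguous from 0, got {idx} at {i}")
            m = _COUNT_RULE_RE.match(pattern.strip())
            if m:
                bits.append(
                    FingerprintBit(idx, pattern.strip(), desc,
                                   _count_rule=(m.group(2), int(m.group(1))))
                )
            else:
                query = Chem.MolFromSmarts(pattern)
                if query is None:
                    raise ValueError(f"SMARTS does not compile: {pattern!r}")
                bits.append(FingerprintBit(idx, pattern, desc, _query=query))
        self.bits = bits

    def __len__(self) -> int:
        return len(self.bits)

    def column_names(self) -> list[str]:
        return [f"{self.name}:{_slug(b.description)}" for b in self.bits]


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text.strip()).strip("_").lower()


def load_dictionary(path: str | Path, name: str | None = None) -> FingerprintDictionary:
    """Load a fingerprint dictionary from a tab-separated text file.

    Format: ``index<TAB>SMARTS-or-countrule<TAB>description`` with ``#``
    comment lines.
    """
    path = Path(path)
    entries = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx, pattern, desc = line.split("\t", 2)
        entries.append((int(idx), pattern, desc))
    return FingerprintDictionary(name or path.stem, entries)


_BUNDLED = {"subfp": "subfp_mini.tsv", "pubchem": "pubchem_mini.tsv"}
_DICT_CACHE: dict[str, FingerprintDictionary] = {}


def bundled_dictionary(name: str) -> FingerprintDictionary:
    """A bundled curated dictionary: ``"subfp"`` or ``"pubchem"``.

    These are in-house SMARTS subsets covering the classical alert bits
    (trifluoromethyl, alkylfluoride, hetero-N basic H, heterocyclic,
    N-counts, C=N, ...) plus generic substructure bits — not the full
    official 881/307-bit dictionaries, which can be supplied as files.
    """
    key = name.lower()
    if key not in _BUNDLED:
        raise KeyError(f"no bundled dictionary {name!r}; choose from {sorted(_BUNDLED)}")
    if key not in _DICT_CACHE:
        ref = resources.files("toxqsar.data").joinpath(_BUNDLED[key])
        with resources.as_file(ref) as p:
            _DICT_CACHE[key] = load_dictionary(p, name="SubFP" if key == "subfp" else "PubchemFP")
    return _DICT_CACHE[key]


def compute_fingerprint(
    mol: MoleculeRecord | Chem.Mol | str, dictionary: FingerprintDictionary
) -> np.ndarray:
    """Binary fingerprint vector: bit i is 1 iff pattern i matches."""
    rdmol = _as_mol(mol)
    return np.array([1 if b.matches(rdmol) else 0 for b in dictionary.bits], dtype=np.int8)


def fingerprint_table(molset: MoleculeSet, dictionary: FingerprintDictionary) -> FeatureTable:
    rows = np.vstack([compute_fingerprint(m, dictionary) for m in molset.mols])
    data = pd.DataFrame(rows, index=molset.ids(), columns=dictionary.column_names())
    return FeatureTable(data, {c: "fingerprint" for c in data.columns})


# ---------------------------------------------------------------------------
# Scaffolds


def murcko_framework(mol: MoleculeRecord | Chem.Mol | str) -> str:
    """Canonical Murcko framework SMILES ('' for acyclic molecules).

    The framework is the molecule's ring systems plus the linkers
    connecting them, with all side chains removed.
    """
    rdmol = _as_mol(mol)
    if rdmol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(rdmol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)
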