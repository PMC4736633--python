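"""Seeded synthetic-data generators.

Every statistical structure the workflow assumes can be generated here
without external data: a sinc regression benchmark for the sparse
kernel machinery, a planted-signal feature table for the filter
selection and validation statistics, and a toy molecule set assembled
from a small fragment grammar whose activity follows a recorded
structure-based rule (a trifluoromethyl boost, a smaller alkyl-fluoride
boost, an imine penalty and a ring-count term), emulating the alert
structure of acute-toxicity data.

All generators are pure functions of their arguments; the same seed
always reproduces the same data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from rdkit import Chem

from toxqsar.chemfeat import MoleculeRecord

__all__ = [
    "gen_sinc",
    "gen_feature_table",
    "gen_toy_molecules",
    "TOY_ACTIVITY_RULE",
    "SyntheticSpec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Record of a generator call; fully determines its output."""

    generator: str
    n: int
    seed: int
    params: tuple

    def to_dict(self) -> dict:
        return asdict(self)


def gen_sinc(n: int, noise_sd: float = 0.05, seed: int = 0):
    """The classic sinc benchmark: x ~ U[-10, 10], t = sin(x)/x + noise."""
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-10.0, 10.0, size=n)
    t = np.sinc(x / np.pi) + rng.normal(0.0, noise_sd, size=n)
    return x[:, None], t


def gen_feature_table(
    n: int,
    p: int,
    k_informative: int,
    coef_magnitude: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    binarize_fraction: float = 0.0,
):
    """Planted-signal regression data for feature-selection benchmarks.

    Features are iid standard normal; a ``binarize_fraction`` of them is
    thresholded at 0 into {0,1} (fingerprint-like columns).  The
    activity is a +/-``coef_magnitude`` linear combination of the first
    ``k_informative`` features plus Gaussian noise.  Returns
    (FeatureTable, activity, truth mask).
    """
    from toxqsar.chemfeat import FeatureTable
    import pandas as pd

    if not 0 <= k_informative <= p:
        raise ValueError("need 0 <= k_informative <= p")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    n_binary = int(round(binarize_fraction * p))
    # binarize from the tail so informative (leading) columns stay continuous
    if n_binary:
        X[:, p - n_binary:] = (X[:, p - n_binary:] > 0).astype(float)
    signs = rng.choice([-1.0, 1.0], size=k_informative)
    activity = X[:, :k_informative] @ (signs * coef_magnitude)
    activity = activity + rng.normal(0.0, noise_sd, size=n)
    names = [f"f{j:04d}" for j in range(p)]
    prov = {
        name: ("fingerprint" if j >= p - n_binary else "descriptor")
        for j, name in enumerate(names)
    }
    table = FeatureTable(
        pd.DataFrame(X, columns=names, index=[f"m{i:05d}" for i in range(n)]), prov
    )
    truth = np.zeros(p, dtype=bool)
    truth[:k_informative] = True
    return table, activity, truth


# ---------------------------------------------------------------------------
# Toy molecules

_CORES = (
    "c1cc{a}cc{b}c1{c}",      # benzene
    "c1cc{a}nc{b}c1{c}",      # pyridine
    "C1CC{a}CC{b}C1{c}",      # cyclohexane
)
_BIPHENYL = "c1ccc(-c2ccc{a}cc2)cc1"
_SUBSTITUENTS = (
    "",            # unsubstituted position
    "C(F)(F)F",    # trifluoromethyl
    "F",           # fluoride (alkyl-F on the cyclohexane core only)
    "C=NC",        # imine side chain
    "N",           # amine
    "C",           # methyl
    "CC",          # ethyl
    "O",           # hydroxyl
    "Cl",          # chloride
)

#: the generative activity rule, recorded for downstream tests:
#: pLD50 = 2.5 + 1.5*[CF3] + 0.6*[alkyl-F] - 0.8*[C=N] + 0.3*rings + N(0, 0.3)
TOY_ACTIVITY_RULE = {
    "intercept": 2.5,
    "cf3": 1.5,
    "alkyl_f": 0.6,
    "imine": -0.8,
    "per_ring": 0.3,
    "noise_sd": 0.3,
}

_CF3_QUERY = Chem.MolFromSmarts("[CX4](F)(F)F")
_ALKF_QUERY = Chem.MolFromSmarts("[CX4;!$(C(F)(F)F)][FX1]")
_IMINE_QUERY = Chem.MolFromSmarts("[CX3]=[NX2]")


def _toy_activity(mol: Chem.Mol, rng: np.random.Generator) -> float:
    rule = TOY_ACTIVITY_RULE
    act = rule["intercept"]
    if mol.HasSubstructMatch(_CF3_QUERY):
        act += rule["cf3"]
    if mol.HasSubstructMatch(_ALKF_QUERY):
        act += rule["alkyl_f"]
    if mol.HasSubstructMatch(_IMINE_QUERY):
        act += rule["imine"]
    act += rule["per_ring"] * mol.GetRingInfo().NumRings()
    return float(act + rng.normal(0.0, rule["noise_sd"]))


def _branch(sub: str) -> str:
    return f"({sub})" if sub else ""


def gen_toy_molecules(n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Assemble n valid toy molecules with rule-based activities.

    Cores (benzene, pyridine, cyclohexane, biphenyl) carry up to three
    random substituents from a small grammar; the activity follows
    ``TOY_ACTIVITY_RULE`` so planted alerts (trifluoromethyl positive,
    imine negative) are recoverable but not noise-free.  Duplicate
    structures may occur and are left to downstream cleaning.
    """
    if n < 40:
        raise ValueError("n must be >= 40")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    i = 0
    while len(records) < n:
        if rng.random() < 0.1:
            smiles = _BIPHENYL.format(a=_branch(rng.choice(_SUBSTITUENTS)))
        else:
            core = _CORES[rng.integers(len(_CORES))]
            subs = rng.choice(_SUBSTITUENTS, size=3)
            smiles = core.format(a=_branch(subs[0]), b=_branch(subs[1]), c=subs[2])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees validity; guard anyway
            continue
        canon = Chem.MolToSmiles(mol)
        records.append(MoleculeRecord(f"toy{i:05d}", canon, _toy_activity(mol, rng)))
        i += 1
    return records
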