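"""Symmetric pair-type feature vectors.

Each complex is summarised by accumulating its per-contact energies into
bins indexed by the *unordered* pair of atom classes (18 classes, so
C(18,2)+18 = 171 features, kind ``"AT"``) or of residue classes (20
classes, C(20,2)+20 = 210 features, kind ``"AA"``).  A feature is thus the
cumulative energy of every interface contact whose two atoms carry that
pair of types; pair order is irrelevant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .energy import EnergyModel, make_model
from .interface import InterfaceContact, find_contacts
from .structure import (Complex, TypingTable, UNTYPED, N_ATOM_TYPES,
                        N_RESIDUE_TYPES, default_table)

AT, AA = "AT", "AA"
_KIND_K = {AT: N_ATOM_TYPES, AA: N_RESIDUE_TYPES}


def n_pair_features(K: int) -> int:
    """Number of unordered type pairs with repetition: K(K+1)/2."""
    return K * (K + 1) // 2


def pair_index(a: int, b: int, K: int) -> int:
    """Canonical index of the unordered pair {a, b} in [0, K(K+1)/2).

    With s = min(a,b), t = max(a,b): index = s·K − s(s−1)/2 + (t−s).
    Symmetric in (a, b) and bijective over unordered pairs.
    """
    if not (0 <= a < K and 0 <= b < K):
        raise ValueError(f"type indices ({a},{b}) out of range for K={K}")
    s, t = (a, b) if a <= b else (b, a)
    return s * K - s * (s - 1) // 2 + (t - s)


def feature_names(kind: str, table: TypingTable | None = None) -> list[str]:
    """Canonical pair labels 'TYPEa-TYPEb' with a <= b, in index order."""
    table = table or default_table()
    if kind == AA:
        names = table.residue_type_names()
    elif kind == AT:
        names = table.atom_type_names or [f"T{i}" for i in range(N_ATOM_TYPES)]
    else:
        raise ValueError(f"unknown feature kind: {kind!r}")
    K = len(names)
    out = [""] * n_pair_features(K)
    for s in range(K):
        for t in range(s, K):
            out[pair_index(s, t, K)] = f"{names[s]}-{names[t]}"
    return out


@dataclass
class FeatureVector:
    """Accumulated pair energies for one complex."""

    values: np.ndarray
    feature_kind: str
    energy_kind: str
    cutoff: float
    complex_id: str
    label: str | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = n_pair_features(_KIND_K[self.feature_kind])
        if self.values.shape != (expect,):
            raise ValueError(
                f"{self.feature_kind} vector must have {expect} entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def build_features(cplx: Complex, contacts: list[InterfaceContact],
                   model: EnergyModel, kind: str,
                   cutoff: float) -> FeatureVector:
    """Accumulate each contact's pair energy into its unordered-pair bin.

    AT bins by the two atoms' atom classes, AA by their parent residues'
    classes.  Contacts with an untyped atom (or, for electrostatics, a
    missing charge) are skipped and counted in ``n_skipped``.  The vector
    sum equals the total interface energy of the retained contacts.
    """
    K = _KIND_K[kind]
    values = np.zeros(n_pair_features(K))
    skipped = 0
    for c in contacts:
        e = model.pair_energy(c, cutoff)
        if e is None:
            skipped += 1
            continue
        if kind == AT:
            ta, tb = c.ligand_atom.atom_type, c.receptor_atom.atom_type
        else:
            ta, tb = c.ligand_atom.residue_type, c.receptor_atom.residue_type
        if ta == UNTYPED or tb == UNTYPED:
            skipped += 1
            continue
        values[pair_index(ta, tb, K)] += e
    return FeatureVector(values, kind, model.kind, cutoff, cplx.id,
                         cplx.label, skipped)


@dataclass
class FeatureMatrix:
    """One feature vector per complex, plus names, labels and ids."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)
    feature_kind: str = AA
    energy_kind: str = "electrostatic"
    cutoff: float = 9.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("matrix/feature-name shape mismatch")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("label count must match row count")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "complex", self.ids or [str(i) for i in range(len(df))])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("complex", "label")]
        return cls(df[names].to_numpy(float), names,
                   df["label"].to_numpy(), list(df.get("complex", [])), **meta)

    def subset(self, columns: list[int]) -> "FeatureMatrix":
        return FeatureMatrix(self.X[:, columns],
                             [self.feature_names[i] for i in columns],
                             self.labels, self.ids, self.feature_kind,
                             self.energy_kind, self.cutoff)


class InterfaceEnergyFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from complexes to pair-type energy features.

    Stateless (``fit`` is a no-op); ``transform`` runs interface detection
    and energy accumulation per complex.  Parameters
    ----------
    feature_kind : 'AT' (171 atom-class pairs) or 'AA' (210 residue-class
        pairs).
    energy_kind : 'desolvation' or 'electrostatic'.
    cutoff : interface distance cutoff in Å (strict).
    dielectric : constant or '4r', electrostatic model only.
    heavy_only : drop hydrogens before contact detection.
    """

    def __init__(self, feature_kind: str = AA,
                 energy_kind: str = "electrostatic", cutoff: float = 9.0,
                 dielectric: str | float = 1.0, heavy_only: bool = False,
                 table: TypingTable | None = None):
        self.feature_kind = feature_kind
        self.energy_kind = energy_kind
        self.cutoff = cutoff
        self.dielectric = dielectric
        self.heavy_only = heavy_only
        self.table = table

    def fit(self, X=None, y=None):
        self.feature_names_ = feature_names(self.feature_kind,
                                            self.table or default_table())
        return self

    def transform(self, complexes: list[Complex]) -> np.ndarray:
        model = make_model(self.energy_kind,
                           table=self.table or default_table(),
                           dielectric=self.dielectric)
        rows = []
        for cplx in complexes:
            contacts = find_contacts(cplx, self.cutoff,
                                     heavy_only=self.heavy_only)
            rows.append(build_features(cplx, contacts, model,
                                       self.feature_kind, self.cutoff).values)
        return np.stack(rows) if rows else np.empty(
            (0, n_pair_features(_KIND_K[self.feature_kind])))


def build_matrix(complexes: list[Complex], *, feature_kind: str = AA,
                 energy_kind: str = "electrostatic", cutoff: float = 9.0,
                 dielectric: str | float = 1.0, heavy_only: bool = False,
                 table: TypingTable | None = None) -> FeatureMatrix:
    """Assemble the dataset matrix, one row per complex in input order."""
    feat = InterfaceEnergyFeaturizer(feature_kind, energy_kind, cutoff,
                                     dielectric, heavy_only, table).fit()
    X = feat.transform(complexes)
    labels = np.array([c.label if c.label is not None else "UNLABELED"
                       for c in complexes])
    return FeatureMatrix(X, feat.feature_names_, labels,
                         [c.id for c in complexes], feature_kind,
                         energy_kind, cutoff)
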