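"""Domain types and rigid-body geometry for complex assembly.

A complex is modelled at reduced resolution: each residue contributes a CA
and a CB coordinate (CA standing in for CB in glycine) plus a per-residue
confidence (plDDT, normalised to [0, 1]).  Chains are compared by *entity*
label — the identifier of a unique sequence — never by the chain id used in
a particular file, since many placed chains share one entity.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "ResidueRecord",
    "ChainModel",
    "SubComponentModel",
    "RigidTransform",
    "kabsch_superpose",
    "read_subcomponent",
    "write_assembly",
    "ParseError",
    "ConfigurationError",
]

# one- <-> three-letter amino-acid codes (used when writing synthetic PDBs)
_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
_AA1 = {v: k for k, v in _AA3.items()}


class ParseError(ValueError):
    """A structure file violates the expected conventions."""


class ConfigurationError(ValueError):
    """User-supplied configuration (entity map, spec) is inconsistent."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: 1-based index, one-letter code, CA/CB coordinates (Å),
    plDDT in [0, 1]."""

    seq_index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray
    plddt: float


class ChainModel:
    """One polypeptide chain with CA/CB traces and per-residue confidence.

    Coordinates are stored as (n, 3) float arrays for speed; ``residues``
    materialises :class:`ResidueRecord` views on demand.
    """

    __slots__ = ("chain_id", "entity", "seq", "seq_index", "ca", "cb", "plddt")

    def __init__(self, chain_id, entity, seq, ca, cb, plddt, seq_index=None):
        ca = np.asarray(ca, dtype=float)
        cb = np.asarray(cb, dtype=float)
        plddt = np.asarray(plddt, dtype=float)
        n = len(seq)
        if n == 0:
            raise ValueError("chain must contain at least one residue")
        if ca.shape != (n, 3) or cb.shape != (n, 3) or plddt.shape != (n,):
            raise ValueError("inconsistent residue array shapes")
        if not (np.isfinite(ca).all() and np.isfinite(cb).all()):
            raise ValueError("non-finite coordinates")
        if plddt.min() < 0.0 or plddt.max() > 1.0:
            raise ValueError("plddt must lie in [0, 1] after normalisation")
        if seq_index is None:
            seq_index = np.arange(1, n + 1)
        seq_index = np.asarray(seq_index, dtype=int)
        if np.any(np.diff(seq_index) <= 0):
            raise ValueError("seq_index must be strictly increasing")
        self.chain_id = chain_id
        self.entity = entity
        self.seq = seq
        self.seq_index = seq_index
        self.ca = ca
        self.cb = cb
        self.plddt = plddt

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def residues(self) -> list[ResidueRecord]:
        return [
            ResidueRecord(int(i), a, c, b, float(p))
            for i, a, c, b, p in zip(
                self.seq_index, self.seq, self.ca, self.cb, self.plddt
            )
        ]

    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)

    def _moved(self, ca: np.ndarray, cb: np.ndarray) -> "ChainModel":
        """Fast copy with replaced coordinates; validation skipped because
        rigid motion preserves it."""
        new = object.__new__(ChainModel)
        new.chain_id = self.chain_id
        new.entity = self.entity
        new.seq = self.seq
        new.seq_index = self.seq_index
        new.ca = ca
        new.cb = cb
        new.plddt = self.plddt
        return new

    def transformed(self, transform: "RigidTransform", chain_id=None) -> "ChainModel":
        """Return a copy with coordinates moved by ``transform``."""
        new = self._moved(transform.apply(self.ca), transform.apply(self.cb))
        if chain_id is not None:
            new.chain_id = chain_id
        return new

    def with_noise(self, rng: np.random.Generator, sigma: float) -> "ChainModel":
        """Per-residue Gaussian displacement applied to CA and CB jointly;
        ``sigma`` is the RMS displacement in Å (std sigma/sqrt(3) per
        axis)."""
        if sigma <= 0:
            return self
        d = rng.normal(0.0, sigma / np.sqrt(3.0), size=self.ca.shape)
        return ChainModel(
            self.chain_id, self.entity, self.seq,
            self.ca + d, self.cb + d, self.plddt, self.seq_index,
        )


@dataclass
class SubComponentModel:
    """A predicted small multimer (dimer–tetramer) used as an assembly
    building block.

    ``composition`` is the multiset of entity labels, ``model_index`` the
    1–5 index of the upstream predictor model that produced it.
    """

    chains: list[ChainModel]
    model_index: int = 1
    source_path: str = ""

    def __post_init__(self):
        if not 2 <= len(self.chains) <= 4:
            raise ValueError("sub-component must contain 2-4 chains, got %d"
                             % len(self.chains))
        if not 1 <= self.model_index <= 5:
            raise ValueError("model_index must be in 1..5")

    @property
    def composition(self) -> tuple[str, ...]:
        return tuple(sorted(c.entity for c in self.chains))

    @property
    def composition_string(self) -> str:
        from .combinatorics import composition_string
        return composition_string(self.composition)

    def mean_plddt(self) -> float:
        return float(np.concatenate([c.plddt for c in self.chains]).mean())


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation Å-preserving, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        # direct checks (cheaper than np.allclose in the assembly hot path)
        if abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation must be orthonormal")
        det = (
            R[0, 0] * (R[1, 1] * R[2, 2] - R[1, 2] * R[2, 1])
            - R[0, 1] * (R[1, 0] * R[2, 2] - R[1, 2] * R[2, 0])
            + R[0, 2] * (R[1, 0] * R[2, 1] - R[1, 1] * R[2, 0])
        )
        if abs(det - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimising the RMSD of the moved
    mobile points to the target points, and that minimal RMSD (Å).
    Reflections are excluded by sign-correcting the smallest singular
    vector (the Kabsch convention).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be equal-shape (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 points")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("non-finite coordinates")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _normalise_plddt(values: np.ndarray) -> np.ndarray:
    """Per-file plDDT scale detection: any value > 1 means a 0–100 file."""
    if values.size and values.max() > 1.0:
        values = values / 100.0
    return np.clip(values, 0.0, 1.0)


def read_chains(path, entity_map: Mapping[str, str]) -> list[ChainModel]:
    """Read all chains of a PDB file into :class:`ChainModel` objects.

    ``entity_map`` maps every chain id in the file to its entity label.
    plDDT is taken from the B-factor column (0–100 files auto-scaled to
    [0, 1]); CB falls back to CA for glycine or when CB is absent.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    model = st[0]
    chains: list[ChainModel] = []
    for ch in model:
        seq, ca, cb, plddt, idx = [], [], [], [], []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if res.name not in _AA1 and not (info and info.is_amino_acid()):
                continue
            ca_atom = res.find_atom("CA", "*")
            if ca_atom is None:
                raise ParseError(
                    f"{path}: missing CA atom in chain {ch.name} residue "
                    f"{res.seqid.num} {res.name}"
                )
            cb_atom = res.find_atom("CB", "*")
            if cb_atom is None or res.name == "GLY":
                cb_atom = ca_atom
            seq.append(_AA1.get(res.name, "X"))
            ca.append([ca_atom.pos.x, ca_atom.pos.y, ca_atom.pos.z])
            cb.append([cb_atom.pos.x, cb_atom.pos.y, cb_atom.pos.z])
            plddt.append(ca_atom.b_iso)
            idx.append(res.seqid.num)
        if not seq:
            continue
        if ch.name not in entity_map:
            raise ConfigurationError(
                f"chain id {ch.name!r} absent from entity map ({path})"
            )
        chains.append(
            ChainModel(
                ch.name,
                entity_map[ch.name],
                "".join(seq),
                np.array(ca),
                np.array(cb),
                _normalise_plddt(np.array(plddt)),
                np.array(idx),
            )
        )
    if not chains:
        raise ParseError(f"{path}: no protein chains with CA atoms")
    return chains


def read_subcomponent(
    path, entity_map: Mapping[str, str], model_index: int = 1
) -> SubComponentModel:
    """Read one 2-4-chain sub-component from a PDB file (see
    :func:`read_chains` for the parsing conventions)."""
    chains = read_chains(path, entity_map)
    if len(chains) < 2:
        raise ParseError(f"{path}: sub-component must contain >=2 chains")
    if len(chains) > 4:
        raise ParseError(f"{path}: sub-component must contain <=4 chains")
    return SubComponentModel(chains, model_index=model_index,
                             source_path=str(path))


def chain_id_sequence() -> Iterable[str]:
    """A, B, ..., Z, a..z, 0..9, then two-letter ids — never exhausted."""
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    yield from alphabet
    for a in alphabet:
        for b in alphabet:
            yield a + b


def _chains_of(assembly) -> list[ChainModel]:
    chains = getattr(assembly, "chains", assembly)
    return list(chains)


def write_assembly(state, path) -> None:
    """Write an assembly (any object with ``.chains`` or a chain list) as a
    PDB file: chains renamed A, B, ...; plDDT written back as B-factor × 100;
    a REMARK line carries the stoichiometry string."""
    from .combinatorics import stoichiometry_of

    chains = _chains_of(state)
    if not chains:
        raise ValueError("cannot write an empty assembly")
    st = gemmi.Structure()
    st.name = "assembly"
    model = gemmi.Model("1")
    for new_id, chain in zip(chain_id_sequence(), chains):
        gch = gemmi.Chain(new_id)
        for i, (aa, ca, cb, pl, num) in enumerate(
            zip(chain.seq, chain.ca, chain.cb, chain.plddt, chain.seq_index)
        ):
            res = gemmi.Residue()
            res.name = _AA3.get(aa, "UNK")
            res.seqid = gemmi.SeqId(int(num), " ")
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(*ca)
            a.b_iso = float(pl) * 100.0
            a.occ = 1.0
            res.add_atom(a)
            if aa != "G":
                b = gemmi.Atom()
                b.name = "CB"
                b.element = gemmi.Element("C")
                b.pos = gemmi.Position(*cb)
                b.b_iso = float(pl) * 100.0
                b.occ = 1.0
                res.add_atom(b)
            gch.add_residue(res)
        model.add_chain(gch)
    st.add_model(model)
    st.raw_remarks = [
        "REMARK 300 STOICHIOMETRY " + str(stoichiometry_of(chains))
    ]
    st.setup_entities()
    st.write_pdb(str(path))
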