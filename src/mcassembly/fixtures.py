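"""Synthetic ground-truth complexes and predicted-sub-component emulation.

The upstream structure predictor is never run here; instead this module
builds reference complexes with known point-group / helical symmetry and
stoichiometry from a compact synthetic chain template, then slices them
into overlapping dimer–tetramer sub-components with controllable
coordinate noise and simulated per-residue confidence, emulating what the
predictor would emit (five pseudo-model variants per sub-component).
Every pipeline stage downstream is therefore testable offline, with the
true structure and stoichiometry known exactly.

The chain template is a 20-residue CA/CB trace wound on a small sphere —
a compact blob, not a real protein fold.  Real predicted sub-components
differ in ways the generator does not emulate (flexible loops, partially
disordered chains, systematically wrong interfaces with high confidence),
so passing here demonstrates the assembly machinery, not predictor-level
accuracy.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .combinatorics import Stoichiometry, stoichiometry_of
from .interfaces import (
    DEFAULT_CLASH_CUTOFF,
    DEFAULT_CONTACT_CUTOFF,
    clash_fraction,
    interface_contacts,
)
from .processing import DEFAULT_MIN_PAIR_CONTACTS
from .structures import ChainModel, SubComponentModel, chain_id_sequence

SYMMETRIES = ("cyclic", "dihedral", "tetrahedral", "helical", "asymmetric")

_TEMPLATE_SEQ = "ACDEFHIKLMNPQRSTVWYG"  # 20 residues, glycine included


class GenerationError(RuntimeError):
    """The requested geometry yields no valid complex."""


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def chain_template(
    n_res: int = 20, radius: float = 4.5, cb_offset: float = 1.2
) -> tuple[np.ndarray, np.ndarray]:
    """Compact synthetic CA/CB trace: CA wound on a sphere of ``radius`` Å
    (1.5 turns, ~3.5-4 Å consecutive spacing), CB pushed radially outward
    by ``cb_offset``.  Deterministic."""
    t = np.linspace(0.0, 1.0, n_res)
    theta = np.arccos(1.0 - 2.0 * t * (1 - 1e-9) - 1e-9)
    phi = 3.0 * np.pi * t
    ca = radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
         np.cos(theta)], axis=1,
    )
    cb = ca * (1.0 + cb_offset / radius)
    return ca, cb


def _glycine_cb(seq: str, ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """CB convention: glycine carries no CB, CA stands in."""
    mask = np.array([c == "G" for c in seq])
    out = cb.copy()
    out[mask] = ca[mask]
    return out


def _entity_sequence(entity_index: int, n_res: int) -> str:
    s = _TEMPLATE_SEQ[: n_res] if n_res <= len(_TEMPLATE_SEQ) else (
        _TEMPLATE_SEQ * (n_res // len(_TEMPLATE_SEQ) + 1))[:n_res]
    k = entity_index % len(s)
    return s[k:] + s[:k]


@dataclass
class ComplexSpec:
    """Recipe for one synthetic reference complex.

    ``n_units`` is the rotational order for cyclic/dihedral/helical
    symmetry (a dihedral Dn complex has 2n asymmetric units) and ignored
    for tetrahedral (12 units).  ``entities`` lists the entity labels of
    one asymmetric unit; for ``asymmetric`` symmetry they are the chains
    themselves.  ``contact_distance`` is the centre-centre distance (Å) at
    which two template blobs form an interface; radii/rises derive from it
    unless given explicitly.
    """

    symmetry: str = "cyclic"
    n_units: int = 6
    entities: Sequence[str] = ("A",)
    contact_distance: float = 14.0
    ring_radius: Optional[float] = None
    rise: Optional[float] = None        # helical only, Å per unit
    twist: float = 40.0                 # helical only, degrees per unit
    n_res: int = 20
    noise_sigma: float = 0.0
    plddt_mean: float = 0.9
    plddt_noise_penalty: float = 0.3    # plDDT drawdown per Å of noise sigma
    seed: int = 0

    def __post_init__(self):
        if self.symmetry not in SYMMETRIES:
            raise GenerationError(
                f"unknown symmetry {self.symmetry!r}; valid: {SYMMETRIES}"
            )


@dataclass
class ReferenceComplex:
    """Ground truth: placed chains, stoichiometry, contact adjacency."""

    chains: list[ChainModel]
    stoichiometry: Stoichiometry
    adjacency: list[tuple[int, int]]
    spec: ComplexSpec

    def manifest(self) -> dict:
        return {
            "symmetry": self.spec.symmetry,
            "n_units": self.spec.n_units,
            "entities": list(self.spec.entities),
            "n_chains": len(self.chains),
            "stoichiometry": str(self.stoichiometry),
            "adjacency": [list(e) for e in self.adjacency],
            "noise_sigma": self.spec.noise_sigma,
            "seed": self.spec.seed,
        }


def _unit_chains(spec: ComplexSpec) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """One asymmetric unit: entity chains stacked along z, centred."""
    ca0, cb0 = chain_template(spec.n_res)
    m = len(spec.entities)
    out = []
    for e_idx, ent in enumerate(spec.entities):
        z = (e_idx - (m - 1) / 2.0) * spec.contact_distance
        off = np.array([0.0, 0.0, z])
        out.append((ent, ca0 + off, cb0 + off))
    return out


def _tetrahedral_rotations() -> list[np.ndarray]:
    """The 12 proper rotations of the tetrahedral group T, deterministic
    order: identity, face axes (±120°), edge axes (180°)."""
    rots = [np.eye(3)]
    for axis in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
        v = np.array(axis, dtype=float) / math.sqrt(3.0)
        for ang in (2 * np.pi / 3, -2 * np.pi / 3):
            rots.append(Rotation.from_rotvec(ang * v).as_matrix())
    for axis in np.eye(3):
        rots.append(Rotation.from_rotvec(np.pi * axis).as_matrix())
    return rots


def _unit_placements(spec: ComplexSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """(rotation, translation) applied to the centred asymmetric unit for
    every unit of the complex."""
    d = spec.contact_distance
    m = len(spec.entities)
    sym = spec.symmetry
    if sym == "cyclic":
        n = spec.n_units
        if n < 2:
            raise GenerationError("cyclic symmetry needs n_units >= 2")
        R = spec.ring_radius or (
            d / (2.0 * math.sin(math.pi / n)) if n > 1 else d
        )
        return [
            (_rz(2 * math.pi * k / n), _rz(2 * math.pi * k / n) @ np.array([R, 0.0, 0.0]))
            for k in range(n)
        ]
    if sym == "dihedral":
        n = spec.n_units
        if n < 2:
            raise GenerationError("dihedral symmetry needs n_units >= 2")
        R = spec.ring_radius or d / (2.0 * math.sin(math.pi / n))
        h = m * d / 2.0
        p0 = np.array([R, 0.0, h])
        placements = []
        for k in range(n):
            g = _rz(2 * math.pi * k / n)
            placements.append((g, g @ p0))
        flip = _rx(math.pi)
        for k in range(n):
            g = flip @ _rz(2 * math.pi * k / n)
            placements.append((g, g @ p0))
        return placements
    if sym == "tetrahedral":
        p0 = d * np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)
        return [(g, g @ p0) for g in _tetrahedral_rotations()]
    if sym == "helical":
        n = spec.n_units
        r_h = spec.ring_radius or 8.0
        twist = math.radians(spec.twist)
        chord = 2.0 * r_h * math.sin(twist / 2.0)
        if spec.rise is not None:
            rise = spec.rise
        else:
            if chord >= d:
                raise GenerationError(
                    "helical chord exceeds contact distance; reduce radius"
                )
            rise = math.sqrt(d * d - chord * chord)
        return [
            (_rz(k * twist),
             _rz(k * twist) @ np.array([r_h, 0.0, 0.0])
             + np.array([0.0, 0.0, k * rise]))
            for k in range(n)
        ]
    if sym == "asymmetric":
        # a bent, non-symmetric chain of units with consecutive contacts
        n = len(spec.entities) if m > 1 else spec.n_units
        headings = [0.0, 75.0, 150.0, 205.0, 280.0, 340.0]
        centre = np.zeros(3)
        placements = [(_rz(0.35), centre.copy())]
        for k in range(1, n):
            a = math.radians(headings[(k - 1) % len(headings)])
            step = d * np.array([math.cos(a), math.sin(a), 0.12 * (k % 3)])
            step *= d / np.linalg.norm(step)
            centre = centre + step
            placements.append((_rz(0.35 + 0.9 * k), centre.copy()))
        return placements
    raise GenerationError(f"unknown symmetry {sym!r}")


def make_complex(spec: ComplexSpec) -> ReferenceComplex:
    """Build the ground-truth complex for ``spec``.

    Deterministic for a fixed spec/seed.  Verifies its own contract: every
    chain must share an interface (>= the default pair-contact floor) with
    at least one other chain, the contact graph must be connected, and no
    chain pair may clash.
    """
    sym = spec.symmetry
    if sym == "asymmetric" and len(spec.entities) < 2:
        raise GenerationError("asymmetric spec needs >= 2 entities")

    entity_order = sorted(set(spec.entities))
    ent_index = {e: i for i, e in enumerate(entity_order)}
    placements = _unit_placements(spec)
    chains: list[ChainModel] = []
    ids = chain_id_sequence()
    if sym == "asymmetric":
        ca0, cb0 = chain_template(spec.n_res)
        for (rot, tr), ent in zip(placements, spec.entities):
            seq = _entity_sequence(ent_index[ent], spec.n_res)
            ca = ca0 @ rot.T + tr
            chains.append(ChainModel(
                next(ids), ent, seq, ca,
                _glycine_cb(seq, ca, cb0 @ rot.T + tr),
                np.full(spec.n_res, spec.plddt_mean),
            ))
    else:
        unit = _unit_chains(spec)
        for rot, tr in placements:
            for ent, ca, cb in unit:
                seq = _entity_sequence(ent_index[ent], spec.n_res)
                ca_g = ca @ rot.T + tr
                chains.append(ChainModel(
                    next(ids), ent, seq, ca_g,
                    _glycine_cb(seq, ca_g, cb @ rot.T + tr),
                    np.full(spec.n_res, spec.plddt_mean),
                ))
    n = len(chains)
    if not 3 <= n <= 30:
        raise GenerationError(f"complex size {n} outside the supported 3-30")

    adjacency = []
    neighbours = [0] * n
    for i, j in itertools.combinations(range(n), 2):
        if clash_fraction(chains[i], chains[j], DEFAULT_CLASH_CUTOFF) > 0:
            raise GenerationError(
                f"chains {i} and {j} clash; increase contact_distance"
            )
        st = interface_contacts(chains[i], chains[j], DEFAULT_CONTACT_CUTOFF)
        if st.n_contacts >= DEFAULT_MIN_PAIR_CONTACTS:
            adjacency.append((i, j))
            neighbours[i] += 1
            neighbours[j] += 1
    if any(v == 0 for v in neighbours) or not _connected(n, adjacency):
        raise GenerationError(
            "generated geometry leaves isolated chains; reduce the ring "
            "radius or contact_distance"
        )
    return ReferenceComplex(chains, stoichiometry_of(chains), adjacency, spec)


def _connected(n: int, edges: Sequence[tuple[int, int]]) -> bool:
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def _connected_windows(
    n: int, edges: Sequence[tuple[int, int]], k: int, max_windows: int = 60
) -> list[tuple[int, ...]]:
    """All connected induced k-subsets of the contact graph, sorted; evenly
    subsampled to ``max_windows`` if the enumeration is larger."""
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    found: set[frozenset[int]] = set()

    def grow(subset: frozenset[int], frontier: set[int]):
        if len(subset) == k:
            found.add(subset)
            return
        for v in sorted(frontier):
            if v > min(subset):  # enumerate each subset from its min vertex
                grow(subset | {v},
                     (frontier | adj[v]) - subset - {v})

    for v in range(n):
        grow(frozenset([v]), set(adj[v]))
    windows = sorted(tuple(sorted(s)) for s in found)
    if len(windows) > max_windows:
        idx = np.linspace(0, len(windows) - 1, max_windows).round().astype(int)
        windows = [windows[i] for i in sorted(set(idx.tolist()))]
    return windows


def slice_subcomponents(
    reference: ReferenceComplex,
    k: int = 2,
    noise_sigma: float | None = None,
    seed: int = 0,
    n_models: int = 5,
    max_windows: int = 60,
) -> list[SubComponentModel]:
    """Cut the reference into overlapping sub-components of ``k`` spatially
    adjacent chains, emulating independent predictor outputs.

    Each window is re-centred, given a random orientation, perturbed with
    per-residue Gaussian noise of ``noise_sigma`` Å (default: the spec's),
    and assigned simulated confidence: base plDDT for core residues,
    interface residues drawn down in proportion to the noise level, all
    clipped to [0.3, 0.98].  ``n_models`` seeded pseudo-model variants are
    produced per window.
    """
    chains = reference.chains
    if k > len(chains):
        raise ValueError(f"window size {k} exceeds chain count {len(chains)}")
    if not 2 <= k <= 4:
        raise ValueError("sub-components hold 2-4 chains")
    spec = reference.spec
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    windows = _connected_windows(len(chains), reference.adjacency, k,
                                 max_windows)
    out: list[SubComponentModel] = []
    for w_idx, window in enumerate(windows):
        members = [chains[i] for i in window]
        centroid = np.mean([c.centroid() for c in members], axis=0)
        # interface membership within the noise-free window
        iface: list[np.ndarray] = [np.zeros(len(c), dtype=bool) for c in members]
        for a, b in itertools.combinations(range(len(members)), 2):
            st = interface_contacts(members[a], members[b],
                                    DEFAULT_CONTACT_CUTOFF)
            pos_a = {int(x) for x in st.residues_a}
            pos_b = {int(x) for x in st.residues_b}
            iface[a] |= np.isin(members[a].seq_index, list(pos_a))
            iface[b] |= np.isin(members[b].seq_index, list(pos_b))
        for m in range(1, n_models + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(w_idx, m))
            )
            rot = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31)))).as_matrix()
            moved = []
            for c, mask in zip(members, iface):
                ca = (c.ca - centroid) @ rot.T
                cb = (c.cb - centroid) @ rot.T
                # noise_sigma is the RMS per-atom displacement (Å): each
                # coordinate axis gets std sigma/sqrt(3)
                disp = rng.normal(0.0, sigma / math.sqrt(3.0), size=ca.shape)
                local = np.linalg.norm(disp, axis=1)
                jitter = np.abs(rng.normal(0.0, 0.02, size=len(c)))
                plddt = np.full(len(c), spec.plddt_mean) - jitter
                # interface confidence tracks the realised local error, so
                # pooling several pseudo-models lets the scorer prefer the
                # least-distorted geometry (as real predictors' confidence
                # estimates do)
                plddt[mask] -= spec.plddt_noise_penalty * local[mask]
                plddt = np.clip(plddt, 0.3, 0.98)
                moved.append(ChainModel(
                    c.chain_id, c.entity, c.seq, ca + disp, cb + disp,
                    plddt, c.seq_index,
                ))
            out.append(SubComponentModel(
                moved, model_index=m,
                source_path=f"synthetic:w{'-'.join(map(str, window))}:m{m}",
            ))
    return out


def make_decoy_pair(
    reference: ReferenceComplex,
    wrong_orientation_angle: float,
    seed: int = 0,
) -> SubComponentModel:
    """A dimer whose partner chain is rotated about its own centroid by
    ``wrong_orientation_angle`` degrees — a wrong-orientation decoy.

    The decoy's interface confidence is reduced (x0.65), emulating the
    lower confidence predictors assign to incorrect interfaces; at angle 0
    the geometry is identical to a true pair (only confidence differs when
    the angle is nonzero).
    """
    i, j = reference.adjacency[0]
    a, b = reference.chains[i], reference.chains[j]
    centroid = (a.centroid() + b.centroid()) / 2.0
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(math.radians(wrong_orientation_angle) * axis)
    b_centre = b.centroid()
    ca = (b.ca - b_centre) @ rot.as_matrix().T + b_centre
    cb = (b.cb - b_centre) @ rot.as_matrix().T + b_centre
    plddt_a = a.plddt.copy()
    plddt_b = b.plddt.copy()
    if wrong_orientation_angle != 0.0:
        st = interface_contacts(a, b, DEFAULT_CONTACT_CUTOFF)
        mask_a = np.isin(a.seq_index, [int(x) for x in st.residues_a])
        mask_b = np.isin(b.seq_index, [int(x) for x in st.residues_b])
        plddt_a[mask_a] *= 0.65
        plddt_b[mask_b] *= 0.65
    a2 = ChainModel(a.chain_id, a.entity, a.seq, a.ca - centroid,
                    a.cb - centroid, plddt_a, a.seq_index)
    b2 = ChainModel(b.chain_id, b.entity, b.seq, ca - centroid,
                    cb - centroid, plddt_b, b.seq_index)
    return SubComponentModel(
        [a2, b2], model_index=1,
        source_path=f"synthetic:decoy{wrong_orientation_angle:g}",
    )


def default_test_matrix() -> list[ComplexSpec]:
    """The symmetry classes exercised by the test suite: cyclic, dihedral,
    tetrahedral and helical complexes at the 3-12-chain scale, plus one
    asymmetric four-entity complex."""
    return [
        ComplexSpec(symmetry="cyclic", n_units=3),
        ComplexSpec(symmetry="cyclic", n_units=6),
        ComplexSpec(symmetry="cyclic", n_units=12),
        ComplexSpec(symmetry="dihedral", n_units=2),
        ComplexSpec(symmetry="dihedral", n_units=3),
        ComplexSpec(symmetry="tetrahedral"),
        ComplexSpec(symmetry="helical", n_units=10),
        ComplexSpec(symmetry="asymmetric", entities=("A", "B", "C", "D")),
    ]


def write_fixture_bundle(reference: ReferenceComplex, out_dir, k: int = 2,
                         n_models: int = 5) -> dict:
    """Write reference PDB, sub-component PDBs and a ground-truth manifest
    (JSON) to ``out_dir``; returns the manifest dict."""
    from pathlib import Path

    from .structures import write_assembly

    out_dir = Path(out_dir)
    sub_dir = out_dir / "subcomponents"
    sub_dir.mkdir(parents=True, exist_ok=True)
    write_assembly(reference.chains, out_dir / "reference.pdb")
    subs = slice_subcomponents(reference, k=k, seed=reference.spec.seed,
                               n_models=n_models)
    sub_files = []
    for idx, sub in enumerate(subs):
        fname = f"sub_{idx:03d}_m{sub.model_index}.pdb"
        write_assembly(sub.chains, sub_dir / fname)
        sub_files.append({
            "filename": f"subcomponents/{fname}",
            "source": sub.source_path,
            "model_index": sub.model_index,
            "entities": [c.entity for c in sub.chains],
        })
    manifest = dict(reference.manifest())
    manifest["subcomponents"] = sub_files
    manifest["window_size"] = k
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
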