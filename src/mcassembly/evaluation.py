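"""Comparison of an assembled complex against a reference structure.

Chains are matched one-to-one within entity labels, a single global rigid
superposition is computed over the mapped CA atoms, and similarity is the
standard length-normalised TM-style score

    score = (1/L) * sum_i 1 / (1 + (d_i/d0)^2),   d0 = 1.24 (L-15)^(1/3) - 1.8

(d0 floored at 0.5 Å), with L = max(total predicted residues, total
reference residues) so that both missing and surplus chains lower the
score.  This single-superposition scorer is an internal stand-in for the
external structural alignment tool used in the field (an optional wrapper
is provided); it is an approximation adequate for fixture-scale
comparisons, not a re-implementation of the tool's alignment search.
A complex is conventionally counted as correctly predicted at score >= 0.8.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import warnings
from dataclasses import dataclass

import numpy as np

from .combinatorics import stoichiometry_of
from .structures import ChainModel, kabsch_superpose

DEFAULT_SUCCESS_THRESHOLD = 0.8
EXHAUSTIVE_MAPPING_MAX_CHAINS = 8


class ExternalToolError(RuntimeError):
    """The external alignment binary is unavailable or produced
    unparseable output."""


@dataclass
class EvaluationReport:
    mapped_pairs: list[tuple[int, int]]
    complex_score: float
    per_chain_rmsd: list[float]
    stoichiometry_correct: bool
    n_pred_chains: int
    n_ref_chains: int
    success: bool

    def as_dict(self) -> dict:
        return {
            "mapped_pairs": [list(p) for p in self.mapped_pairs],
            "complex_score": self.complex_score,
            "per_chain_rmsd": self.per_chain_rmsd,
            "stoichiometry_correct": self.stoichiometry_correct,
            "n_pred_chains": self.n_pred_chains,
            "n_ref_chains": self.n_ref_chains,
            "success": self.success,
        }


def _chains_of(assembly) -> list[ChainModel]:
    return list(getattr(assembly, "chains", assembly))


def _tm_d0(length: int) -> float:
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _norm_length(pred: list[ChainModel], ref: list[ChainModel]) -> int:
    return max(sum(len(c) for c in pred), sum(len(c) for c in ref))


def _mapping_score(
    pred: list[ChainModel], ref: list[ChainModel],
    mapping: list[tuple[int, int]],
) -> float:
    """TM-style score of a candidate mapping under its best global
    superposition over all mapped CA atoms."""
    if not mapping:
        return 0.0
    P = np.concatenate([pred[i].ca for i, _ in mapping])
    Q = np.concatenate([ref[j].ca for _, j in mapping])
    tr, _ = kabsch_superpose(P, Q)
    d = np.linalg.norm(tr.apply(P) - Q, axis=1)
    L = _norm_length(pred, ref)
    return float(np.sum(1.0 / (1.0 + (d / _tm_d0(L)) ** 2)) / L)


def _greedy_mapping(
    pred: list[ChainModel], ref: list[ChainModel]
) -> list[tuple[int, int]]:
    """Entity-consistent greedy mapping seeded by the best single-chain
    superposition: each candidate seed pair defines a global frame; the
    remaining chains are matched nearest-centroid within entity; the seed
    whose mapping scores best wins."""
    cands = [
        (i, j)
        for i, p in enumerate(pred)
        for j, r in enumerate(ref)
        if p.entity == r.entity and len(p) == len(r)
    ]
    best_map: list[tuple[int, int]] = []
    best_score = -1.0
    for si, sj in cands:
        tr, _ = kabsch_superpose(pred[si].ca, ref[sj].ca)
        pc = np.array([tr.apply(p.ca).mean(axis=0) for p in pred])
        rc = np.array([r.ca.mean(axis=0) for r in ref])
        pairs = sorted(
            ((np.linalg.norm(pc[i] - rc[j]), i, j)
             for i, p in enumerate(pred) for j, r in enumerate(ref)
             if p.entity == r.entity and len(p) == len(r)),
        )
        used_p: set[int] = set()
        used_r: set[int] = set()
        mapping = []
        for _, i, j in pairs:
            if i in used_p or j in used_r:
                continue
            mapping.append((i, j))
            used_p.add(i)
            used_r.add(j)
        score = _mapping_score(pred, ref, mapping)
        if score > best_score:
            best_score, best_map = score, mapping
    return sorted(best_map)


def _exhaustive_mapping(
    pred: list[ChainModel], ref: list[ChainModel]
) -> list[tuple[int, int]]:
    """Best entity-wise bijection by direct enumeration (small complexes)."""
    ents = sorted({c.entity for c in pred} & {c.entity for c in ref})
    pred_by = {e: [i for i, c in enumerate(pred) if c.entity == e] for e in ents}
    ref_by = {e: [j for j, c in enumerate(ref) if c.entity == e] for e in ents}
    best_map, best_score = [], -1.0
    per_entity = []
    for e in ents:
        ps, rs = pred_by[e], ref_by[e]
        k = min(len(ps), len(rs))
        opts = [
            list(zip(pc, rp))
            for pc in itertools.combinations(ps, k)
            for rp in itertools.permutations(rs, k)
        ]
        per_entity.append(opts)
    for combo in itertools.product(*per_entity):
        mapping = sorted(itertools.chain.from_iterable(combo))
        score = _mapping_score(pred, ref, mapping)
        if score > best_score:
            best_score, best_map = score, mapping
    return best_map


def map_chains(pred, ref, exhaustive: bool = False) -> list[tuple[int, int]]:
    """One-to-one, entity-consistent chain mapping between two assemblies,
    as (pred index, ref index) pairs.  Surplus chains stay unmapped."""
    pred_c, ref_c = _chains_of(pred), _chains_of(ref)
    if not pred_c or not ref_c:
        raise ValueError("both assemblies must be nonempty")
    if not ({c.entity for c in pred_c} & {c.entity for c in ref_c}):
        warnings.warn("no entity overlap between assemblies; empty mapping")
        return []
    if exhaustive and max(len(pred_c), len(ref_c)) <= EXHAUSTIVE_MAPPING_MAX_CHAINS:
        return _exhaustive_mapping(pred_c, ref_c)
    return _greedy_mapping(pred_c, ref_c)


def complex_tm_score(pred, ref, mapping) -> float:
    """Length-normalised similarity in [0, 1] under ``mapping``; 1 only for
    coordinate-identical structures (up to a rigid motion)."""
    if not mapping:
        warnings.warn("empty chain mapping; complex score is 0")
        return 0.0
    return _mapping_score(_chains_of(pred), _chains_of(ref), list(mapping))


def evaluate(
    pred, ref,
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
    exhaustive: bool = False,
) -> EvaluationReport:
    """Full comparison: chain mapping, complex score, per-chain RMSD and
    stoichiometry check."""
    pred_c, ref_c = _chains_of(pred), _chains_of(ref)
    mapping = map_chains(pred_c, ref_c, exhaustive=exhaustive)
    score = complex_tm_score(pred_c, ref_c, mapping)
    per_chain = []
    if mapping:
        P = np.concatenate([pred_c[i].ca for i, _ in mapping])
        Q = np.concatenate([ref_c[j].ca for _, j in mapping])
        tr, _ = kabsch_superpose(P, Q)
        for i, j in mapping:
            d = tr.apply(pred_c[i].ca) - ref_c[j].ca
            per_chain.append(float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    stoich_ok = stoichiometry_of(pred_c) == stoichiometry_of(ref_c)
    return EvaluationReport(
        mapped_pairs=list(mapping),
        complex_score=score,
        per_chain_rmsd=per_chain,
        stoichiometry_correct=stoich_ok,
        n_pred_chains=len(pred_c),
        n_ref_chains=len(ref_c),
        success=score >= success_threshold,
    )


def run_mmalign(pred_path, ref_path, binary_path: str = "MMalign") -> float:
    """Score two PDB files with the external alignment binary; raises
    :class:`ExternalToolError` when the binary is absent — the internal
    scorer is never substituted silently."""
    exe = shutil.which(binary_path)
    if exe is None:
        raise ExternalToolError(
            f"external alignment tool {binary_path!r} not found on PATH"
        )
    proc = subprocess.run(
        [exe, str(pred_path), str(ref_path)],
        capture_output=True, text=True, check=False,
    )
    out = proc.stdout
    scores = []
    for line in out.splitlines():
        if line.startswith("TM-score=") or line.lstrip().startswith("TM-score="):
            try:
                scores.append(float(line.split("=")[1].split()[0]))
            except (IndexError, ValueError):
                pass
    if not scores:
        raise ExternalToolError(
            f"could not parse a score from alignment output:\n{out[:2000]}"
        )
    return max(scores)
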