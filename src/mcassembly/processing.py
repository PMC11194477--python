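"""Sub-component deduplication and interaction-pair harvesting.

Predicted sub-components are redundant in two ways: the same composition is
predicted by five upstream predictor models, and overlapping compositions
contain the same chain-chain arrangement.  This module (a) collapses
structurally equivalent sub-components, keeping the most confident copy,
(b) extracts every contacting chain pair as an :class:`InteractionPair` —
two chains frozen in their predicted relative orientation, the atomic unit
reused (possibly many times) during assembly — and (c) removes pairs whose
relative orientations are near-duplicates, keeping the highest-scoring
member of each cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interfaces import (
    DEFAULT_CONTACT_CUTOFF,
    InterfaceStats,
    interface_contacts,
    pdockq_score,
)
from .structures import (
    ChainModel,
    SubComponentModel,
    kabsch_superpose,
    read_subcomponent,
    write_assembly,
)

DEFAULT_MIN_PAIR_CONTACTS = 10
DEFAULT_DEDUP_THRESHOLD = 0.9
DEFAULT_PAIR_RMSD_TOLERANCE = 2.0  # Å


@dataclass(frozen=True)
class InteractionPair:
    """Two chains in a fixed relative orientation plus interface summary."""

    anchor: ChainModel
    partner: ChainModel
    stats: InterfaceStats
    source: tuple[str, int]  # (composition string, model_index)
    pair_id: str

    @property
    def pdockq(self) -> float:
        return pdockq_score(self.stats)

    @property
    def entity_key(self) -> tuple[str, str]:
        return tuple(sorted((self.anchor.entity, self.partner.entity)))

    def oriented(self, flipped: bool) -> tuple[ChainModel, ChainModel]:
        """(chain to superpose onto a placed chain, chain to add)."""
        return (self.partner, self.anchor) if flipped else (self.anchor, self.partner)

    def mean_plddt(self) -> float:
        return float(
            np.concatenate([self.anchor.plddt, self.partner.plddt]).mean()
        )


def _tm_d0(length: int) -> float:
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _entity_consistent_mappings(
    a: Sequence[ChainModel], b: Sequence[ChainModel]
) -> Iterable[tuple[int, ...]]:
    """All bijections a[i] -> b[perm[i]] preserving entity labels."""
    by_ent: dict[str, list[int]] = {}
    for j, ch in enumerate(b):
        by_ent.setdefault(ch.entity, []).append(j)
    ents = sorted(by_ent)
    slots = {e: [i for i, ch in enumerate(a) if ch.entity == e] for e in ents}
    if any(len(slots[e]) != len(by_ent[e]) for e in ents):
        return
    for perms in itertools.product(
        *(itertools.permutations(by_ent[e]) for e in ents)
    ):
        mapping = [0] * len(a)
        for e, perm in zip(ents, perms):
            for i, j in zip(slots[e], perm):
                mapping[i] = j
        yield tuple(mapping)


def subcomponent_similarity(
    a: SubComponentModel, b: SubComponentModel
) -> float:
    """Best chain-mapped, length-normalised structural similarity in [0, 1].

    Over every entity-consistent chain bijection, the models are rigidly
    superposed on all mapped CA atoms and scored with the standard
    per-residue similarity kernel 1/(1+(d/d0)^2); the best mapping wins.
    Models of different composition score 0.
    """
    if a.composition != b.composition:
        return 0.0
    best = 0.0
    ca_a = np.concatenate([ch.ca for ch in a.chains])
    L = len(ca_a)
    d0 = _tm_d0(L)
    for mapping in _entity_consistent_mappings(a.chains, b.chains):
        if any(len(a.chains[i]) != len(b.chains[j]) for i, j in enumerate(mapping)):
            continue
        ca_b = np.concatenate([b.chains[j].ca for j in mapping])
        tr, _rmsd = kabsch_superpose(ca_a, ca_b)
        d = np.linalg.norm(tr.apply(ca_a) - ca_b, axis=1)
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        best = max(best, score)
    return best


def _model_sort_key(m: SubComponentModel):
    # higher mean plddt first; ties by lexicographic provenance
    return (-m.mean_plddt(), m.source_path, m.model_index)


def deduplicate_subcomponents(
    models: Sequence[SubComponentModel],
    similarity_threshold: float = DEFAULT_DEDUP_THRESHOLD,
) -> list[SubComponentModel]:
    """Drop structurally redundant sub-components.

    Models sharing a composition whose best chain-mapped superposition
    reaches ``similarity_threshold`` are merged; the copy with the highest
    mean plDDT survives.  Models of different composition are never
    compared.  Idempotent, deterministic output order.
    """
    if not 0.0 < similarity_threshold <= 1.0:
        raise ValueError("similarity_threshold must be in (0, 1]")
    survivors: list[SubComponentModel] = []
    for m in sorted(models, key=_model_sort_key):
        dup = any(
            s.composition == m.composition
            and subcomponent_similarity(s, m) >= similarity_threshold
            for s in survivors
        )
        if not dup:
            survivors.append(m)
    return survivors


def extract_pairs(
    model: SubComponentModel,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_pair_contacts: int = DEFAULT_MIN_PAIR_CONTACTS,
) -> list[InteractionPair]:
    """One pair per unordered chain pair with at least ``min_pair_contacts``
    contacts, coordinates kept in the sub-component's frame."""
    out: list[InteractionPair] = []
    comp = model.composition_string
    for i, j in itertools.combinations(range(len(model.chains)), 2):
        a, b = model.chains[i], model.chains[j]
        if a.entity > b.entity:
            a, b = b, a
        stats = interface_contacts(a, b, contact_cutoff)
        if stats.n_contacts >= min_pair_contacts:
            src = model.source_path or f"{comp}:m{model.model_index}"
            pid = f"{src}:{i}-{j}"
            out.append(
                InteractionPair(a, b, stats, (comp, model.model_index), pid)
            )
    return out


def pair_orientation_rmsd(p: InteractionPair, q: InteractionPair) -> float:
    """Relative-orientation difference: RMSD of q's partner after
    superposing the anchors.  For homotypic pairs the swapped chain
    assignment is also tried and the minimum returned."""
    if p.entity_key != q.entity_key:
        return float("inf")

    def _rmsd(pa, pp, qa, qp):
        if len(pa) != len(qa) or len(pp) != len(qp):
            return float("inf")
        tr, _ = kabsch_superpose(pa.ca, qa.ca)
        moved = tr.apply(pp.ca)
        return float(np.sqrt(np.mean(np.sum((moved - qp.ca) ** 2, axis=1))))

    candidates = []
    if p.anchor.entity == q.anchor.entity:
        candidates.append(_rmsd(p.anchor, p.partner, q.anchor, q.partner))
    if p.anchor.entity == q.partner.entity:
        candidates.append(_rmsd(p.anchor, p.partner, q.partner, q.anchor))
    return min(candidates) if candidates else float("inf")


def _pair_sort_key(p: InteractionPair):
    # highest score first; ties by mean plddt then lexicographic id
    return (-p.pdockq, -p.mean_plddt(), p.pair_id)


def filter_pairs(
    pairs: Sequence[InteractionPair],
    rmsd_tolerance: float = DEFAULT_PAIR_RMSD_TOLERANCE,
) -> list[InteractionPair]:
    """Remove near-duplicate relative orientations.

    Pairs with the same (entity, entity) key whose partner-chain RMSD after
    anchor superposition is within ``rmsd_tolerance`` are merged; the
    higher-scoring pair survives.  Output sorted by score descending.
    """
    survivors: list[InteractionPair] = []
    for p in sorted(pairs, key=_pair_sort_key):
        dup = any(
            pair_orientation_rmsd(s, p) <= rmsd_tolerance for s in survivors
        )
        if not dup:
            survivors.append(p)
    return survivors


def pool_models(
    per_model_pairs: Mapping[int, Sequence[InteractionPair]],
    use_all_models: bool = True,
    rmsd_tolerance: float = DEFAULT_PAIR_RMSD_TOLERANCE,
) -> list[InteractionPair]:
    """Pool interaction pairs across upstream predictor models.

    With ``use_all_models`` the union of all models' pairs is deduplicated
    with :func:`filter_pairs`; otherwise only the top-ranked (lowest index)
    model's pairs pass through.  Provenance is preserved on every survivor.
    """
    if not per_model_pairs:
        raise ValueError("no model pair lists supplied")
    if use_all_models:
        pooled = [p for k in sorted(per_model_pairs) for p in per_model_pairs[k]]
        return filter_pairs(pooled, rmsd_tolerance)
    top = min(per_model_pairs)
    return filter_pairs(list(per_model_pairs[top]), rmsd_tolerance)


# ---------------------------------------------------------------------------
# pair-library serialisation: one two-chain PDB per pair plus an index TSV
# (the assembler's on-disk input contract)

INDEX_COLUMNS = [
    "pair_id", "entity_a", "entity_b", "n_contacts", "avg_plddt",
    "pdockq", "composition", "model_index", "filename",
]


def write_pair_library(pairs: Sequence[InteractionPair], out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(pairs):
        fname = f"pair_{i:04d}.pdb"
        write_assembly([p.anchor, p.partner], out_dir / fname)
        rows.append({
            "pair_id": p.pair_id,
            "entity_a": p.anchor.entity,
            "entity_b": p.partner.entity,
            "n_contacts": p.stats.n_contacts,
            "avg_plddt": round(p.stats.avg_plddt, 6),
            "pdockq": round(p.pdockq, 6),
            "composition": p.source[0],
            "model_index": p.source[1],
            "filename": fname,
        })
    index = out_dir / "index.tsv"
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(index, sep="\t", index=False)
    return index


def read_pair_library(
    lib_dir, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[InteractionPair]:
    lib_dir = Path(lib_dir)
    index = lib_dir / "index.tsv"
    if not index.exists():
        raise FileNotFoundError(f"pair library index not found: {index}")
    df = pd.read_csv(index, sep="\t")
    pairs: list[InteractionPair] = []
    for row in df.itertuples(index=False):
        sub = read_subcomponent(
            lib_dir / row.filename,
            {"A": row.entity_a, "B": row.entity_b},
            model_index=int(row.model_index),
        )
        a, b = sub.chains
        stats = interface_contacts(a, b, contact_cutoff)
        pairs.append(
            InteractionPair(
                a, b, stats,
                (str(row.composition), int(row.model_index)),
                str(row.pair_id),
            )
        )
    return pairs
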