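"""Interface geometry and scoring.

Two residues on different chains are *in contact* when their CB atoms (CA
for glycine) lie within a cutoff, 8 Å by default — the standard pDockQ
contact convention.  An interface is scored by the product form

    score = log10(number of interface contacts) x average interface plDDT,

where the average runs over the union of interface residues from both
chains and plDDT is on the [0, 1] scale.  Zero or one contact scores 0.
The assembly-level reward used by the tree search is the mean interface
score over all contacting chain pairs, weighted by completeness (chains
placed / chain budget) so that partial assemblies never outrank fuller ones
with equally good interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structures import ChainModel

DEFAULT_CONTACT_CUTOFF = 8.0   # Å, CB-CB
DEFAULT_CLASH_CUTOFF = 3.0     # Å, CA-CA
DEFAULT_CLASH_TOLERANCE = 0.2  # max tolerated clash_fraction


@dataclass(frozen=True)
class InterfaceStats:
    """Contact count and confidence summary of one chain-chain interface."""

    n_contacts: int
    avg_plddt: float
    residues_a: frozenset[int]
    residues_b: frozenset[int]

    def __post_init__(self):
        if (self.n_contacts == 0) != (not self.residues_a and not self.residues_b):
            raise ValueError("zero contacts iff both residue sets empty")
        if self.n_contacts > 0 and not 0.0 <= self.avg_plddt <= 1.0:
            raise ValueError("avg_plddt must lie in [0, 1]")


def interface_contacts(
    a: ChainModel, b: ChainModel, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> InterfaceStats:
    """Count residue-residue contacts (CB-CB distance <= cutoff, inclusive)
    between two chains and average plDDT over the participating residues."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = cdist(a.cb, b.cb)
    mask = d <= cutoff
    n = int(mask.sum())
    if n == 0:
        return InterfaceStats(0, 0.0, frozenset(), frozenset())
    ia = np.flatnonzero(mask.any(axis=1))
    ib = np.flatnonzero(mask.any(axis=0))
    plddts = np.concatenate([a.plddt[ia], b.plddt[ib]])
    return InterfaceStats(
        n,
        float(plddts.mean()),
        frozenset(int(a.seq_index[i]) for i in ia),
        frozenset(int(b.seq_index[j]) for j in ib),
    )


def pdockq_score(stats: InterfaceStats) -> float:
    """log10(n_contacts) x avg interface plDDT; 0 for n_contacts <= 1."""
    if stats.n_contacts <= 1:
        return 0.0
    return math.log10(stats.n_contacts) * stats.avg_plddt


def clash_fraction(
    a: ChainModel, b: ChainModel, clash_cutoff: float = DEFAULT_CLASH_CUTOFF
) -> float:
    """Fraction of CA atoms of the smaller chain within ``clash_cutoff`` of
    any CA atom of the other chain."""
    if clash_cutoff <= 0:
        raise ValueError("clash_cutoff must be positive")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    d = cdist(small.ca, large.ca)
    return float((d.min(axis=1) <= clash_cutoff).mean())


def assembly_reward(
    state, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> float:
    """Mean interface score over contacting chain pairs, scaled by
    completeness (placed chains / max_chains).

    ``state`` is an assembly state (``.chains``, ``.max_chains``; a cached
    per-pair score table is used when present) or a plain chain list, in
    which case completeness is 1.
    """
    chains = list(getattr(state, "chains", state))
    if len(chains) < 2:
        return 0.0
    max_chains = getattr(state, "max_chains", len(chains))
    cached = getattr(state, "pair_scores", None)
    if cached is not None:
        scores = list(cached.values())
    else:
        scores = []
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                st = interface_contacts(chains[i], chains[j], contact_cutoff)
                if st.n_contacts > 0:
                    scores.append(pdockq_score(st))
    if not scores:
        return 0.0
    return float(np.mean(scores)) * len(chains) / max_chains
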