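"""Thin composition of the pipeline stages for in-memory use.

Covers the common benchmark loop: slice a reference complex into
pseudo-predicted sub-components, deduplicate, harvest/pool interaction
pairs, assemble by tree search, and score against the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .evaluation import EvaluationReport, evaluate
from .fixtures import ReferenceComplex, slice_subcomponents
from .mcts import AssemblyState, assemble
from .processing import (
    deduplicate_subcomponents,
    extract_pairs,
    pool_models,
)

__all__ = ["ReassemblyResult", "pairs_from_reference", "reassemble"]


@dataclass
class ReassemblyResult:
    state: AssemblyState
    report: EvaluationReport
    n_pairs: int

    @property
    def stoichiometry(self) -> str:
        from .combinatorics import stoichiometry_of

        return str(stoichiometry_of(self.state))


def pairs_from_reference(
    reference: ReferenceComplex,
    k: int = 2,
    seed: int = 0,
    n_models: int = 5,
    config: RunConfig | None = None,
):
    """Slice, deduplicate and pool: the pair library a predictor + the
    processing stages would deliver for this complex."""
    config = config or RunConfig()
    subs = slice_subcomponents(reference, k=k, seed=seed, n_models=n_models)
    subs = deduplicate_subcomponents(subs, config.dedup_threshold)
    per_model: dict[int, list] = {}
    for sub in subs:
        per_model.setdefault(sub.model_index, []).extend(
            extract_pairs(sub, config.contact_cutoff, config.min_pair_contacts)
        )
    return pool_models(per_model, config.use_all_models,
                       config.pair_rmsd_tolerance)


def reassemble(
    reference: ReferenceComplex,
    k: int = 2,
    seed: int = 0,
    n_models: int = 5,
    config: RunConfig | None = None,
) -> ReassemblyResult:
    """Full loop: reference -> sub-components -> pairs -> search -> score."""
    config = config or RunConfig()
    pairs = pairs_from_reference(reference, k=k, seed=seed,
                                 n_models=n_models, config=config)
    state = assemble(pairs, config.mcts(), seed=seed)
    report = evaluate(state, reference.chains, config.success_threshold)
    return ReassemblyResult(state, report, len(pairs))
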