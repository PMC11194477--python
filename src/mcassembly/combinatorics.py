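"""Sub-component composition enumeration and stoichiometry bookkeeping.

The first assembly step enumerates every multiset of the complex's unique
chains (entities) up to the sub-component size limit; each composition is a
candidate multimer prediction job for the upstream structure predictor.
Stoichiometry — the copy number of each entity in a complex — is written in
the conventional compact form, e.g. ``A6B2``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

MAX_SUBCOMPONENT_SIZE = 4


def composition_string(composition: Sequence[str]) -> str:
    """Canonical composition string: entities sorted, repeats kept, e.g.
    ('A','A','B') -> 'AAB'."""
    return "".join(sorted(composition))


@dataclass(frozen=True)
class Stoichiometry:
    """Copy number of each entity in a complex."""

    counts: Mapping[str, int]

    def __post_init__(self):
        if not self.counts or any(v < 1 for v in self.counts.values()):
            raise ValueError("stoichiometry counts must be >= 1")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return "".join(f"{e}{n}" for e, n in sorted(self.counts.items()))

    def __eq__(self, other) -> bool:
        if isinstance(other, Stoichiometry):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))


def stoichiometry_of(state) -> Stoichiometry:
    """Stoichiometry of an assembly (anything with ``.chains`` or a chain
    list)."""
    chains = getattr(state, "chains", state)
    chains = list(chains)
    if not chains:
        raise ValueError("empty assembly has no stoichiometry")
    return Stoichiometry(Counter(c.entity for c in chains))


def enumerate_compositions(
    entities: Iterable[str], min_size: int = 2, max_size: int = 4
) -> list[tuple[str, ...]]:
    """Every multiset of entities with size in [min_size, max_size], in
    lexicographic order."""
    ents = sorted(set(entities))
    if not ents:
        raise ValueError("need at least one entity")
    if not 1 <= min_size <= max_size:
        raise ValueError("require 1 <= min_size <= max_size")
    if max_size > MAX_SUBCOMPONENT_SIZE:
        raise ValueError(
            f"sub-components are at most {MAX_SUBCOMPONENT_SIZE}mers "
            f"(got max_size={max_size})"
        )
    out: list[tuple[str, ...]] = []
    for k in range(min_size, max_size + 1):
        out.extend(combinations_with_replacement(ents, k))
    return out


def compositions_to_fasta(
    compositions: Sequence[Sequence[str]],
    sequences: Mapping[str, str],
    out_dir,
) -> list[Path]:
    """Write one multi-record FASTA per composition (records in canonical
    composition order) plus a ``manifest.tsv`` mapping composition string to
    filename.  Returns the FASTA paths."""
    out_dir = Path(out_dir)
    paths: list[Path] = []
    rows: list[tuple[str, str]] = []
    if compositions:
        out_dir.mkdir(parents=True, exist_ok=True)
    for comp in compositions:
        comp = tuple(sorted(comp))
        for ent in comp:
            if ent not in sequences:
                raise KeyError(f"no sequence supplied for entity {ent!r}")
        name = composition_string(comp)
        path = out_dir / f"{name}.fasta"
        with open(path, "w") as fh:
            for i, ent in enumerate(comp, start=1):
                fh.write(f">{name}_{i} entity={ent}\n{sequences[ent]}\n")
        paths.append(path)
        rows.append((name, path.name))
    if compositions:
        with open(out_dir / "manifest.tsv", "w") as fh:
            fh.write("composition\tfilename\n")
            for comp_str, fname in rows:
                fh.write(f"{comp_str}\t{fname}\n")
    return paths
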