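"""Sub-component deduplication, pair harvesting, filtering and pooling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcassembly.fixtures import (
    ComplexSpec,
    make_complex,
    make_decoy_pair,
    slice_subcomponents,
)
from mcassembly.processing import (
    deduplicate_subcomponents,
    extract_pairs,
    filter_pairs,
    pair_orientation_rmsd,
    pool_models,
    read_pair_library,
    subcomponent_similarity,
    write_pair_library,
)
from mcassembly.structures import RigidTransform, SubComponentModel

from conftest import make_chain


@pytest.fixture(scope="module")
def c6_pairs(c6_reference):
    subs = slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)
    return [p for s in subs for p in extract_pairs(s)]


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    return RigidTransform(
        Rotation.random(random_state=np.random.RandomState(seed)).as_matrix(),
        rng.normal(scale=15, size=3),
    )


class TestDeduplication:
    def test_identical_models_merge(self, c6_reference):
        sub = slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)[0]
        kept = deduplicate_subcomponents([sub, sub], 0.9)
        assert len(kept) == 1

    def test_rigidly_moved_copy_merges(self, c6_reference):
        sub = slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)[0]
        tr = random_rigid(3)
        moved = SubComponentModel(
            [c.transformed(tr) for c in sub.chains],
            model_index=2, source_path="synthetic:moved",
        )
        assert subcomponent_similarity(sub, moved) > 0.999
        kept = deduplicate_subcomponents([sub, moved], 0.9)
        assert len(kept) == 1

    def test_different_compositions_never_compared(self, d3_hetero_reference):
        subs = slice_subcomponents(d3_hetero_reference, k=2, seed=0,
                                   n_models=1)
        aa = next(s for s in subs if s.composition == ("A", "A"))
        ab = next(s for s in subs if s.composition == ("A", "B"))
        assert subcomponent_similarity(aa, ab) == 0.0
        assert len(deduplicate_subcomponents([aa, ab], 0.9)) == 2

    def test_idempotent(self, c6_reference):
        subs = slice_subcomponents(c6_reference, k=2, noise_sigma=0.5,
                                   seed=1, n_models=3)
        once = deduplicate_subcomponents(subs, 0.9)
        twice = deduplicate_subcomponents(once, 0.9)
        assert [s.source_path for s in twice] == [s.source_path for s in once]

    def test_keeps_highest_confidence_copy(self, c6_reference):
        subs = slice_subcomponents(c6_reference, k=2, noise_sigma=0.3,
                                   seed=1, n_models=2)
        same_window = [s for s in subs if s.source_path.startswith("synthetic:w0")]
        kept = deduplicate_subcomponents(same_window, 0.5)
        assert len(kept) == 1
        assert kept[0].mean_plddt() == max(s.mean_plddt() for s in same_window)


class TestExtractPairs:
    def test_linear_trimer_contact_gating(self):
        # A-B-C in a line: A and C never touch
        ca = np.array([[0.1 * i, 0.0, 0.0] for i in range(10)])
        a = make_chain(ca, entity="A", chain_id="A")
        b = make_chain(ca + [7.0, 0, 0], entity="B", chain_id="B")
        c = make_chain(ca + [14.0, 0, 0], entity="C", chain_id="C")
        sub = SubComponentModel([a, b, c], source_path="synthetic:lin")
        keys = {p.entity_key for p in extract_pairs(sub, 8.0, 3)}
        assert keys == {("A", "B"), ("B", "C")}

    def test_ring_slice_matches_brute_force(self, c6_reference):
        subs = slice_subcomponents(c6_reference, k=4, seed=0, n_models=1)
        from mcassembly.interfaces import interface_contacts

        for sub in subs[:3]:
            pairs = extract_pairs(sub, 8.0, 10)
            expected = 0
            for i in range(4):
                for j in range(i + 1, 4):
                    st = interface_contacts(sub.chains[i], sub.chains[j], 8.0)
                    expected += st.n_contacts >= 10
            assert len(pairs) == expected == 3  # consecutive ring windows

    def test_no_contacts_empty(self):
        a = make_chain([[0, 0, 0]] * 3, entity="A")
        b = make_chain([[99, 0, 0]] * 3, entity="B", chain_id="B")
        assert extract_pairs(SubComponentModel([a, b]), 8.0, 1) == []


class TestFilterPairs:
    def test_duplicates_collapse(self, c6_pairs):
        p = c6_pairs[0]
        assert len(filter_pairs([p, p], 2.0)) == 1

    def test_distinct_orientations_survive(self, c6_reference):
        true_pair = extract_pairs(
            slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)[0]
        )[0]
        decoy = extract_pairs(make_decoy_pair(c6_reference, 180.0, seed=1))[0]
        assert pair_orientation_rmsd(true_pair, decoy) > 2.0
        kept = filter_pairs([true_pair, decoy], 2.0)
        assert len(kept) == 2
        # sorted by score descending
        assert kept[0].pdockq >= kept[1].pdockq

    def test_empty_input(self):
        assert filter_pairs([], 2.0) == []

    def test_idempotent_and_keeps_top_scorer(self, c6_reference):
        pairs = []
        for seed in range(4):
            subs = slice_subcomponents(c6_reference, k=2, noise_sigma=0.6,
                                       seed=seed, n_models=2)
            pairs.extend(p for s in subs for p in extract_pairs(s))
        kept = filter_pairs(pairs, 2.0)
        again = filter_pairs(kept, 2.0)
        assert [p.pair_id for p in again] == [p.pair_id for p in kept]
        best = max(pairs, key=lambda p: p.pdockq)
        assert best.pair_id in {p.pair_id for p in kept}


class TestPoolModels:
    def test_identical_pairs_merge_across_models(self, c6_pairs):
        p = c6_pairs[0]
        pooled = pool_models({1: [p], 3: [p]}, use_all_models=True)
        assert len(pooled) == 1
        assert pooled[0].source[1] in (1, 3)

    def test_top_model_gating(self, c6_reference):
        subs = slice_subcomponents(c6_reference, k=2, noise_sigma=0.4,
                                   seed=2, n_models=5)
        per = {}
        for s in subs:
            per.setdefault(s.model_index, []).extend(extract_pairs(s))
        only_top = pool_models(per, use_all_models=False)
        assert all(p.source[1] == 1 for p in only_top)
        pooled = pool_models(per, use_all_models=True)
        assert len(pooled) >= len(only_top)

    def test_pair_only_in_one_model_is_rescued(self, c6_reference):
        # the ring-closing pair exists only in model 4's list
        subs = slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)
        pairs = [p for s in subs for p in extract_pairs(s)]
        closing = pairs[0]
        decoy = extract_pairs(make_decoy_pair(c6_reference, 120.0, seed=2))[0]
        per = {1: [decoy], 4: [closing]}
        pooled_ids = {p.pair_id for p in pool_models(per, use_all_models=True)}
        single_ids = {p.pair_id for p in pool_models(per, use_all_models=False)}
        assert closing.pair_id in pooled_ids
        assert closing.pair_id not in single_ids

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_models({}, True)


class TestPairLibraryIO:
    def test_round_trip(self, tmp_path, c6_pairs, d3_hetero_reference):
        hetero = [
            p for s in slice_subcomponents(d3_hetero_reference, k=2, seed=0,
                                           n_models=1)
            for p in extract_pairs(s)
        ]
        pairs = filter_pairs(c6_pairs + hetero, 2.0)
        write_pair_library(pairs, tmp_path)
        back = read_pair_library(tmp_path)
        assert [p.pair_id for p in back] == [p.pair_id for p in pairs]
        for got, want in zip(back, pairs):
            assert got.entity_key == want.entity_key
            assert got.stats.n_contacts == want.stats.n_contacts
            assert got.pdockq == pytest.approx(want.pdockq, abs=1e-3)

    def test_missing_index_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pair_library(tmp_path / "nowhere")
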