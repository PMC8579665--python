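"""Loss-free compression steps and exact mode decompression."""

from fractions import Fraction

import pytest

from efmx import (
    CompressionRecord,
    MetabolicModel,
    compress,
    decompress_modes,
    enumerate_efms,
    rational_kernel,
)
from efmx.compress import (
    merge_enzyme_subsets,
    remove_blocked_by_kernel,
    remove_deadend_metabolites,
    remove_dependent_rows,
)
from efmx.ddm import brute_force_efms
from efmx.fixtures import random_flux_cone
from efmx.postprocess import FluxMode, ModeSet

F = Fraction


class TestRationalKernel:
    def test_single_balance(self):
        K = rational_kernel(((F(1), F(-1)),))
        assert len(K) == 1
        v = K[0]
        assert v[0] == v[1] != 0

    def test_zero_matrix_full_kernel(self):
        K = rational_kernel(((F(0),) * 3, (F(0),) * 3), n=3)
        assert len(K) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_random_matrices_annihilate_and_span(self, seed):
        cone = random_flux_cone(4, 8, 0.5, seed)
        K = rational_kernel(cone.N)
        from efmx._linalg import rank

        assert len(K) == 8 - rank(list(cone.N), 8)
        for v in K:
            for row in cone.N:
                assert sum(a * b for a, b in zip(row, v)) == 0


class TestDeadendRemoval:
    def test_unconsumed_product(self):
        m = MetabolicModel(
            ("A", "D"), ("R1", "R2", "R6"),
            ((F(1), F(-1), F(-1)), (F(0), F(0), F(1))),
            (False, False, False),
        )
        out, step = remove_deadend_metabolites(m)
        assert step.payload["removed_reactions"] == ["R6"]
        assert step.payload["removed_metabolites"] == ["D"]
        assert out.reaction_ids == ("R1", "R2")

    def test_toy_branch_untouched(self, toy):
        out, step = remove_deadend_metabolites(toy)
        assert out == toy
        assert not step.payload["removed_reactions"]

    def test_cascade_to_fixpoint(self):
        """Removing R6 orphans E, whose reactions fall in a second pass."""
        m = MetabolicModel(
            ("A", "D", "E"), ("R1", "R2", "R6", "R7"),
            (
                (F(1), F(-1), F(-1), F(0)),
                (F(0), F(0), F(1), F(-1)),   # D: made by R6, eaten by R7
                (F(0), F(0), F(0), F(1)),    # E: made by R7, never eaten
            ),
            (False,) * 4,
        )
        out, step = remove_deadend_metabolites(m)
        assert set(step.payload["removed_reactions"]) == {"R6", "R7"}
        assert set(step.payload["removed_metabolites"]) == {"D", "E"}
        assert out.reaction_ids == ("R1", "R2")


class TestKernelBlocked:
    def test_kernel_zero_reaction_removed(self):
        # R3 consumes B and makes C, but C is recycled to B only through
        # itself: flux forced to zero by mass balance without being a
        # structural dead end after the A loop
        m = MetabolicModel(
            ("A", "B"), ("Rin", "Rout", "Rblocked"),
            ((F(1), F(-1), F(-2)), (F(0), F(0), F(1))),
            (False, False, False),
        )
        out, step = remove_blocked_by_kernel(m)
        assert step.payload["removed_reactions"] == ["Rblocked"]
        assert out.reaction_ids == ("Rin", "Rout")

    def test_fully_coupled_toy_unchanged(self, toy):
        out, step = remove_blocked_by_kernel(toy)
        assert not step.payload["removed_reactions"]

    def test_trivial_kernel_empties_model(self):
        m = MetabolicModel(
            ("A", "B"), ("R1", "R2"),
            ((F(1), F(0)), (F(0), F(1))), (False, False),
        )
        with pytest.warns(UserWarning, match="emptiness"):
            out, step = remove_blocked_by_kernel(m)
        assert out.n_reactions == 0


class TestEnzymeSubsets:
    def test_linear_chain_merges_to_one(self):
        m = MetabolicModel(
            ("A", "B"), ("R1", "R2", "R3"),
            ((F(1), F(-1), F(0)), (F(0), F(1), F(-1))),
            (False,) * 3,
        )
        out, step = merge_enzyme_subsets(m)
        assert out.n_reactions == 1
        (merge,) = step.payload["merges"]
        assert merge["representative"] == "R1"
        assert [c for _, c in merge["members"]] == [F(1), F(1), F(1)]

    def test_toy_branch_two_subsets(self, toy):
        out, step = merge_enzyme_subsets(toy)
        groups = {
            frozenset(rid for rid, _ in m["members"])
            for m in step.payload["merges"]
        }
        assert groups == {frozenset({"R2", "R4"}), frozenset({"R3", "R5"})}
        efms = brute_force_efms(out.S, out.n_reactions)
        assert len(efms) == 2

    def test_antiparallel_irreversible_pair_blocked(self):
        """v1 = -v2 with both fluxes nonnegative forces both to zero."""
        m = MetabolicModel(
            ("A",), ("R1", "R2"),
            ((F(1), F(1)),), (False, False),
        )
        out, step = merge_enzyme_subsets(m)
        assert set(step.payload["removed_reactions"]) == {"R1", "R2"}
        assert out.n_reactions == 0


class TestDependentRows:
    def test_duplicate_row(self):
        m = MetabolicModel(
            ("A", "A2"), ("R1", "R2"),
            ((F(1), F(-1)), (F(1), F(-1))), (False, False),
        )
        out, step = remove_dependent_rows(m)
        assert step.payload["removed_metabolites"] == ["A2"]

    def test_sum_relation(self):
        m = MetabolicModel(
            ("A", "B", "AB"), ("R1", "R2"),
            (
                (F(1), F(0)),
                (F(0), F(1)),
                (F(1), F(1)),  # conserved moiety: row3 = row1 + row2
            ),
            (False, False),
        )
        out, step = remove_dependent_rows(m)
        assert step.payload["removed_metabolites"] == ["AB"]

    @pytest.mark.parametrize("seed", range(6))
    def test_kernel_preserved(self, seed):
        cone = random_flux_cone(5, 9, 0.5, seed)
        m = MetabolicModel(
            tuple(f"M{i}" for i in range(5)), cone.reaction_ids,
            cone.N, (False,) * 9,
        )
        out, _ = remove_dependent_rows(m)
        assert rational_kernel(m.S, 9) == rational_kernel(out.S, 9)


class TestCompressPipeline:
    def test_toy_branch_compression(self, toy):
        cm, record = compress(toy)
        assert cm.n_reactions <= 3
        merges = [
            g
            for s in record.steps
            if s.kind == "enzyme_subset_merge"
            for g in s.payload["merges"]
        ]
        assert len(merges) >= 2

    def test_idempotent(self, toy):
        cm, _ = compress(toy)
        cm2, record2 = compress(cm)
        assert len(record2) == 0
        assert cm2 == cm

    def test_steps_shrink_the_model(self, toy):
        cm, record = compress(toy)
        assert cm.n_reactions + cm.n_metabolites < (
            toy.n_reactions + toy.n_metabolites
        )
        assert record.steps  # at least one recorded step

    def test_record_json_round_trip(self, toy, tmp_path):
        _, record = compress(toy)
        p = tmp_path / "rec.json"
        record.to_json(p)
        back = CompressionRecord.from_json(p)
        assert [s.kind for s in back.steps] == [s.kind for s in record.steps]
        assert [s.payload for s in back.steps] == [
            s.payload for s in record.steps
        ]


class TestDecompression:
    def test_empty_record_is_identity(self, toy):
        ms = ModeSet(toy.reaction_ids,
                     (FluxMode((F(1), F(1), F(0), F(1), F(0)), "efm"),))
        assert decompress_modes(ms, CompressionRecord()) == ms

    def test_chain_merge_distributes(self):
        m = MetabolicModel(
            ("A", "B"), ("R1", "R2", "R3"),
            ((F(1), F(-1), F(0)), (F(0), F(1), F(-1))),
            (False,) * 3,
        )
        cm, record = compress(m)
        ms = ModeSet(cm.reaction_ids, (FluxMode((F(2),), "efm"),))
        out = decompress_modes(ms, record)
        assert out.reaction_ids == ("R1", "R2", "R3")
        assert out.modes[0].values == (F(1), F(1), F(1))  # gcd-normalized

    def test_unknown_compressed_id_rejected(self, toy):
        _, record = compress(toy)
        ms = ModeSet(("bogus",), (FluxMode((F(1),), "efm"),))
        with pytest.raises(KeyError):
            decompress_modes(ms, record)


@pytest.mark.parametrize("seed", range(10))
def test_losslessness_on_random_networks(seed):
    """Defining claim: compression never changes the EFM set."""
    cone = random_flux_cone(4, 9, 0.5, seed)
    rev = tuple(j % 3 == 0 for j in range(9))
    m = MetabolicModel(
        tuple(f"M{i}" for i in range(4)), cone.reaction_ids, cone.N, rev
    )
    direct = enumerate_efms(m, compress=False)
    via_compression = enumerate_efms(m, compress=True)
    assert direct.value_set() == via_compression.value_set()
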