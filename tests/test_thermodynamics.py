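import math

import numpy as np
import pytest

from coaxstack import (
    GeneratorConfig,
    Stem,
    coaxial_stack_energy,
    decompose_junction,
    generate_junction,
    helix_free_energy,
    load_turner_params,
)
from coaxstack.secondary_structure import PseudoTwoWayJunction
from coaxstack.thermodynamics import CANONICAL_PAIRS


def make_stem(b5: str, b3: str, start: int = 0, end: int = 100) -> Stem:
    """Stem from aligned strand strings (b3 given 3'->5', aligned under b5)."""
    pairs = tuple((start + k, end - k) for k in range(len(b5)))
    return Stem(pairs=pairs, bases=tuple(zip(b5, b3)))


def make_pair(loop0: str, top: str = "GG", bottom: str = "CC", order: int = 2,
              loop1: str = "A", loop2: str = "A") -> PseudoTwoWayJunction:
    return PseudoTwoWayJunction(
        pair_id="t:H1-H2",
        h1=make_stem("G", "C"),
        h2=make_stem("G", "C", start=40, end=60),
        loop0_seq=loop0,
        loop1_seq=loop1,
        loop2_seq=loop2,
        intervening_stem_count=order - 2,
        parent_order=order,
        interface_top=top,
        interface_bottom=bottom,
    )


@pytest.fixture(scope="module")
def p():
    return load_turner_params()


class TestParameterSet:
    def test_tables_complete(self, p):
        assert p.version == "turner2004"
        assert len(p.stack_table) == 36
        assert len(p.flush_coax_table) == 36
        assert len(p.mismatch_coax_table) == 36

    def test_wc_stacks_are_stabilizing(self, p):
        wc = {"AU", "UA", "CG", "GC"}
        for step, dg in p.stack_table.items():
            x, y, w, z = step[0], step[1], step[3], step[4]
            if x + w in wc and y + z in wc:
                assert dg < 0

    def test_printed_empirical_constants(self, p):
        assert (p.a, p.b, p.c) == (9.3, 0.0, -0.6)
        assert p.mismatch_penalty == 2.1


class TestHelixFreeEnergy:
    def test_one_bp_stem_has_no_stacking_term(self, p):
        e = helix_free_energy(make_stem("A", "U"), p)
        assert e.components["stacking"] == 0.0
        # both helix ends fall on the single AU pair
        assert e.components["au_end"] == pytest.approx(2 * p.au_end_penalty)
        assert e.total == pytest.approx(p.init_energy + 2 * p.au_end_penalty)

    def test_ggac_helix_hand_sum(self, p):
        # 5'GGAC3'/3'CCUG5': steps GG/CC, GA/CU, AC/UG from the embedded table
        e = helix_free_energy(make_stem("GGAC", "CCUG"), p)
        assert e.components["stacking"] == pytest.approx(-3.26 - 2.35 - 2.24)
        assert e.components["au_end"] == 0.0
        assert e.components["sym"] == 0.0
        assert e.total == pytest.approx(4.09 - 7.85)

    def test_self_complementary_correction_applied_once(self, p):
        # 5'GGCC3'/3'CCGG5': both strands read GGCC 5'->3'
        e = helix_free_energy(make_stem("GGCC", "CCGG"), p)
        assert e.components["sym"] == pytest.approx(p.sym_correction)
        near = helix_free_energy(make_stem("GGCA", "CCGU"), p)
        assert near.components["sym"] == 0.0

    def test_non_canonical_pair_rejected(self, p):
        with pytest.raises(ValueError, match="non-canonical"):
            helix_free_energy(make_stem("GA", "CC"), p)

    def test_additivity_over_random_stems(self, p):
        rng = np.random.default_rng(4)
        pairs = sorted(CANONICAL_PAIRS)
        for _ in range(30):
            L = int(rng.integers(2, 9))
            chosen = [pairs[i] for i in rng.integers(0, len(pairs), L)]
            b5 = "".join(c[0] for c in chosen)
            b3 = "".join(c[1] for c in chosen)
            full = helix_free_energy(make_stem(b5, b3), p)
            prefix = helix_free_energy(make_stem(b5[:-1], b3[:-1]), p)
            step = p.stack_table[f"{b5[-2]}{b5[-1]}/{b3[-2]}{b3[-1]}"]
            assert full.components["stacking"] == pytest.approx(
                prefix.components["stacking"] + step
            )

    def test_strand_role_reversal_invariance(self, p):
        rng = np.random.default_rng(9)
        pairs = sorted(CANONICAL_PAIRS)
        for _ in range(20):
            L = int(rng.integers(1, 8))
            chosen = [pairs[i] for i in rng.integers(0, len(pairs), L)]
            stem = make_stem("".join(c[0] for c in chosen), "".join(c[1] for c in chosen))
            assert helix_free_energy(stem.reversed(), p).total == pytest.approx(
                helix_free_energy(stem, p).total
            )


class TestCoaxialStackEnergy:
    def test_flush_uses_interface_lookup(self, p):
        pair = make_pair("", top="GG", bottom="CC")
        assert coaxial_stack_energy(pair, p) == p.flush_coax_table["GG/CC"]

    def test_mismatch_mediated_adds_printed_penalty(self, p):
        pair = make_pair("A", top="GC", bottom="CG")
        expected = p.mismatch_coax_table["GC/CG"] + 2.1
        assert coaxial_stack_energy(pair, p) == pytest.approx(expected)

    def test_mid_range_loop_arithmetic(self, p):
        assert coaxial_stack_energy(make_pair("AAAA"), p) == pytest.approx(
            9.3 + 0 * 4 + 2 * (-0.6)
        )

    def test_continuity_at_six(self, p):
        at6 = coaxial_stack_energy(make_pair("A" * 6), p)
        limit = p.a + 6 * p.b + 1.1 * math.log(6 / 6) + 2 * p.c
        assert at6 == pytest.approx(limit)

    def test_monotone_beyond_six(self, p):
        vals = [coaxial_stack_energy(make_pair("A" * L), p) for L in range(6, 30)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_unknown_interface_step_rejected(self, p):
        with pytest.raises(KeyError):
            coaxial_stack_energy(make_pair("", top="GA", bottom="CC"), p)

    def test_generated_flush_pairs_hit_the_table(self, p):
        # records with 0-nt connecting loops must resolve real interface steps
        cfg = GeneratorConfig(seed=5, loop_length_range=(0, 2), loop_geometric_p=0.9)
        rng = np.random.default_rng(12)
        seen_flush = 0
        for _ in range(30):
            _, junction, _ = generate_junction(3, cfg, rng=rng)
            for pair in decompose_junction(junction):
                dg = coaxial_stack_energy(pair, p)
                if len(pair.loop0_seq) == 0:
                    seen_flush += 1
                    assert dg == p.flush_coax_table[
                        f"{pair.interface_top}/{pair.interface_bottom}"
                    ]
        assert seen_flush > 5
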