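"""Shared helpers for constructing small synthetic objects in tests."""

from coaxstack import Stem
from coaxstack.secondary_structure import PseudoTwoWayJunction


def make_stem(b5: str, b3: str, start: int = 0, end: int = 100) -> Stem:
    """Stem from aligned strands (b3 given 3'->5', aligned under b5)."""
    pairs = tuple((start + k, end - k) for k in range(len(b5)))
    return Stem(pairs=pairs, bases=tuple(zip(b5, b3)))


def make_interface_pair(
    loop0: str, top: str = "GG", bottom: str = "CC", order: int = 2
) -> PseudoTwoWayJunction:
    """Minimal pseudo two-way pair with a chosen connecting loop and interface."""
    return PseudoTwoWayJunction(
        pair_id="t:H1-H2",
        h1=make_stem("G", "C"),
        h2=make_stem("G", "C", start=40, end=60),
        loop0_seq=loop0,
        loop1_seq="A",
        loop2_seq="A",
        intervening_stem_count=order - 2,
        parent_order=order,
        interface_top=top,
        interface_bottom=bottom,
    )
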