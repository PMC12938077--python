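"""Nearest-neighbor free energies: helix stability and coaxial stacking.

Implements the two thermodynamic quantities used as classifier features,
both at 37 C in kcal/mol under the Turner 2004 rule set:

* helix free energy -- the Watson-Crick-Franklin duplex model: initiation
  energy, AU/GU helix-end penalties, a self-complementarity correction, and
  the sum of nearest-neighbor stack terms;

* coaxial stacking free energy between two adjacent stems, a piecewise
  empirical function of the connecting loop length L0: a sequence-dependent
  flush stack at L0 = 0, a mismatch-mediated stack plus a fixed terminal
  mismatch penalty at L0 = 1, and a loop-length penalty
  a + b*L0 + 2c for 2 <= L0 <= 6 that grows logarithmically
  (a + 6b + 1.1*ln(L0/6) + 2c) beyond L0 = 6.

Parameters ship as a versioned plain-text table (``data/turner2004_dg37.txt``)
so results are reproducible offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from .secondary_structure import PseudoTwoWayJunction, Stem

__all__ = [
    "TurnerParameterSet",
    "EnergyBreakdown",
    "load_turner_params",
    "helix_free_energy",
    "coaxial_stack_energy",
    "CANONICAL_PAIRS",
]

CANONICAL_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})
_AU_GU_ENDS = frozenset({"AU", "UA", "GU", "UG"})
_WC_PAIRS = ("AU", "UA", "CG", "GC")


def _all_steps() -> set[str]:
    steps = set()
    for xw in CANONICAL_PAIRS:
        for yz in CANONICAL_PAIRS:
            steps.add(f"{xw[0]}{yz[0]}/{xw[1]}{yz[1]}")
    return steps


@dataclass(frozen=True)
class TurnerParameterSet:
    """Versioned ΔG°37 parameter tables (kcal/mol)."""

    version: str
    init_energy: float
    au_end_penalty: float
    sym_correction: float
    mismatch_penalty: float
    a: float
    b: float
    c: float
    stack_table: dict[str, float]
    flush_coax_table: dict[str, float]
    mismatch_coax_table: dict[str, float]

    def __post_init__(self) -> None:
        required = _all_steps()
        for name, table in (
            ("stack", self.stack_table),
            ("flush_coax", self.flush_coax_table),
            ("mismatch_coax", self.mismatch_coax_table),
        ):
            missing = required - table.keys()
            if missing:
                raise ValueError(f"{name} table missing steps: {sorted(missing)[:4]}...")
        # Watson-Crick x Watson-Crick stacks are stabilizing by construction.
        for xw in _WC_PAIRS:
            for yz in _WC_PAIRS:
                step = f"{xw[0]}{yz[0]}/{xw[1]}{yz[1]}"
                if self.stack_table[step] > 0:
                    raise ValueError(f"positive WC stack entry {step}")
        if self.mismatch_penalty <= 0 or self.a <= 0:
            raise ValueError("mismatch_penalty and a must be positive")


def load_turner_params(path=None) -> TurnerParameterSet:
    """Load a parameter file (defaults to the embedded turner2004 table)."""
    if path is None:
        text = resources.files("coaxstack.data").joinpath("turner2004_dg37.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    scalars: dict[str, object] = {}
    tables: dict[str, dict[str, float]] = {"STACK": {}, "FLUSH_COAX": {}, "MISMATCH_COAX": {}}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] in tables:
            tables[parts[0]][parts[1]] = float(parts[2])
        elif parts[0] == "VERSION":
            scalars["VERSION"] = parts[1]
        else:
            scalars[parts[0]] = float(parts[1])
    return TurnerParameterSet(
        version=str(scalars["VERSION"]),
        init_energy=scalars["INIT"],
        au_end_penalty=scalars["AU_END"],
        sym_correction=scalars["SYM"],
        mismatch_penalty=scalars["MISMATCH_PENALTY"],
        a=scalars["COAX_A"],
        b=scalars["COAX_B"],
        c=scalars["COAX_C"],
        stack_table=tables["STACK"],
        flush_coax_table=tables["FLUSH_COAX"],
        mismatch_coax_table=tables["MISMATCH_COAX"],
    )


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total helix free energy with its named components (kcal/mol)."""

    total: float
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.components.values())) > 1e-9:
            raise ValueError("total does not equal the sum of components")


def _check_canonical(stem: Stem) -> None:
    for b5, b3 in stem.bases:
        if b5 + b3 not in CANONICAL_PAIRS:
            raise ValueError(f"non-canonical base pair {b5}-{b3} in stem")


def helix_free_energy(stem: Stem, params: TurnerParameterSet) -> EnergyBreakdown:
    """ΔG°37 of a helix under the WCF nearest-neighbor model.

    total = init + au_end * (#AU/GU terminal pairs) + sym (self-complementary
    duplexes only) + sum of stack terms over the length_bp - 1 steps.  A 1-bp
    stem has no stack term; both of its helix ends fall on the same pair, so
    an AU/GU pair there is penalized twice.
    """
    _check_canonical(stem)
    b5 = "".join(b for b, _ in stem.bases)
    b3 = "".join(b for _, b in stem.bases)
    stacking = 0.0
    for k in range(stem.length_bp - 1):
        stacking += params.stack_table[f"{b5[k]}{b5[k + 1]}/{b3[k]}{b3[k + 1]}"]
    ends = [stem.bases[0], stem.bases[-1]]
    au_end = params.au_end_penalty * sum(1 for p in ends if "".join(p) in _AU_GU_ENDS)
    sym = params.sym_correction if b5 == b3[::-1] else 0.0
    components = {
        "init": params.init_energy,
        "au_end": au_end,
        "sym": sym,
        "stacking": stacking,
    }
    return EnergyBreakdown(total=sum(components.values()), components=components)


def coaxial_stack_energy(pair: PseudoTwoWayJunction, params: TurnerParameterSet) -> float:
    """Empirical coaxial stacking ΔG°37 between the two stems of a pair.

    Piecewise in the connecting-loop length L0 = len(loop0_seq):
    flush-stack table at 0; mismatch-stack table plus the terminal mismatch
    penalty at 1; a + b*L0 + 2c for 2 <= L0 <= 6; and
    a + 6b + 1.1*ln(L0/6) + 2c beyond 6 (continuous at L0 = 6).
    """
    l0 = len(pair.loop0_seq)
    if l0 < 0:  # defensive; len() cannot go negative
        raise ValueError("negative L0")
    if l0 <= 1:
        step = f"{pair.interface_top}/{pair.interface_bottom}"
        table = params.flush_coax_table if l0 == 0 else params.mismatch_coax_table
        if step not in table:
            raise KeyError(f"unknown interface step {step} (non-canonical closing pairs?)")
        return table[step] + (0.0 if l0 == 0 else params.mismatch_penalty)
    if l0 <= 6:
        return params.a + params.b * l0 + 2.0 * params.c
    return params.a + 6.0 * params.b + 1.1 * math.log(l0 / 6.0) + 2.0 * params.c
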