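"""Edit-cost schemes: substitution costs and the affine gap-cost function.

A :class:`CostScheme` defines the edit distance used throughout the toolkit:
per-event substitution costs split into transitions (A<->G, C<->T) and
transversions, plus a gap-cost function ``f(l) = gap_open + gap_extend * l``
for a gap of ``l`` nucleotides (``f(0) = 0``).  ``gap_open = 0`` gives a
"simple" (linear) gap cost; ``gap_open > 0`` gives an "affine" one; and
``gap_open = +inf`` forbids indels entirely, in which limit treelength
optimization reduces to maximum parsimony.

Costs are held as exact rationals (:class:`fractions.Fraction`) so that
treelength comparisons and tie-breaks are deterministic; for dynamic
programming the scheme is re-scaled to integers (:meth:`CostScheme.integerized`).

The three named criteria shipped as presets follow the prior studies this
line of work builds on: ``simple1`` charges every event 1; ``simple2``
charges indels and transversions 2 and transitions 1; ``affine`` uses
gap_open 2, gap_extend 1/2, transition 1, transversion 2.  Every constant is
overridable — the criteria's structure, not the constants, is what the
toolkit fixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from functools import reduce
from typing import Union

Cost = Union[Fraction, float]  # Fraction, or math.inf for forbidden events

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: Large integer standing in for +inf in integerized DP tables.
INT_INF = 1 << 60


def _frac(x) -> Fraction:
    if isinstance(x, float):
        if math.isinf(x):
            raise ValueError("only gap_open may be infinite")
        return Fraction(x).limit_denominator(10**6)
    return Fraction(x)


@dataclass(frozen=True)
class CostScheme:
    """Substitution + affine gap cost parameters defining an edit distance."""

    name: str
    transition_cost: Fraction
    transversion_cost: Fraction
    gap_open: Cost
    gap_extend: Fraction
    match_cost: Fraction = Fraction(0)

    def __post_init__(self):
        object.__setattr__(self, "transition_cost", _frac(self.transition_cost))
        object.__setattr__(self, "transversion_cost", _frac(self.transversion_cost))
        object.__setattr__(self, "gap_extend", _frac(self.gap_extend))
        object.__setattr__(self, "match_cost", _frac(self.match_cost))
        go = self.gap_open
        if not (isinstance(go, float) and math.isinf(go)):
            object.__setattr__(self, "gap_open", _frac(go))
        for val in (self.transition_cost, self.transversion_cost, self.gap_extend, self.match_cost):
            if val < 0:
                raise ValueError("costs must be nonnegative")
        if not self.gap_forbidden and self.gap_open < 0:
            raise ValueError("costs must be nonnegative")

    # -- structure ----------------------------------------------------------

    @property
    def gap_forbidden(self) -> bool:
        return isinstance(self.gap_open, float) and math.isinf(self.gap_open)

    @property
    def is_simple(self) -> bool:
        """Linear gap cost (no opening charge)."""
        return not self.gap_forbidden and self.gap_open == 0

    @property
    def is_affine(self) -> bool:
        return not self.gap_forbidden and self.gap_open > 0

    # -- evaluation ---------------------------------------------------------

    def gap_cost(self, l: int) -> Cost:
        """Cost of one maximal gap of ``l`` nucleotides: 0 if l=0, else open + extend*l."""
        if l < 0:
            raise ValueError("gap length must be nonnegative")
        if l == 0:
            return Fraction(0)
        if self.gap_forbidden:
            return math.inf
        return self.gap_open + self.gap_extend * l

    def substitution_cost(self, x: str, y: str) -> Fraction:
        """Symmetric per-site substitution cost; N matches anything at cost 0."""
        if x == "N" or y == "N":
            return Fraction(0)
        if x not in "ACGT" or y not in "ACGT":
            raise ValueError(f"illegal base pair ({x!r}, {y!r})")
        if x == y:
            return self.match_cost
        if (x, y) in _TRANSITIONS:
            return self.transition_cost
        return self.transversion_cost

    def with_overrides(self, **kwargs) -> "CostScheme":
        return replace(self, **kwargs)

    # -- integer rescaling for DP -------------------------------------------

    def integerized(self) -> tuple[dict, int]:
        """Rescale all costs to integers; returns (cost table, scale).

        ``table`` maps: ``("sub", x, y) -> int``, ``"gap_open" -> int | INT_INF``
        (already including the first extension: the cost of opening a length-1
        run), ``"gap_extend" -> int``.  Divide by ``scale`` to recover exact
        Fractions.
        """
        fracs = [self.transition_cost, self.transversion_cost, self.gap_extend, self.match_cost]
        if not self.gap_forbidden:
            fracs.append(self.gap_open)
        scale = reduce(math.lcm, (f.denominator for f in fracs), 1)
        table: dict = {}
        alphabet = "ACGTN"
        for x in alphabet:
            for y in alphabet:
                if x in "ACGT" and y in "ACGT":
                    table[("sub", x, y)] = int(self.substitution_cost(x, y) * scale)
                else:
                    table[("sub", x, y)] = 0
        if self.gap_forbidden:
            table["open1"] = INT_INF
        else:
            table["open1"] = int((self.gap_open + self.gap_extend) * scale)
        table["extend"] = int(self.gap_extend * scale)
        return table, scale


_PRESETS = {
    # All events cost 1 (simple gap: no opening charge).
    "simple1": dict(transition_cost=1, transversion_cost=1, gap_open=0, gap_extend=1),
    # Indels and transversions cost 2, transitions 1.
    "simple2": dict(transition_cost=1, transversion_cost=2, gap_open=0, gap_extend=2),
    # Affine gap: opening charge 2, extension 1/2.
    "affine": dict(
        transition_cost=1, transversion_cost=2, gap_open=2, gap_extend=Fraction(1, 2)
    ),
    # Maximum-parsimony limit: indels forbidden, unit substitution costs.
    "mp": dict(transition_cost=1, transversion_cost=1, gap_open=math.inf, gap_extend=0),
}


def preset(name: str, **overrides) -> CostScheme:
    """Return a named treelength criterion; numeric fields are overridable."""
    try:
        params = dict(_PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown cost scheme preset: {name!r}") from None
    params.update(overrides)
    return CostScheme(name=name, **params)


def scheme_from_config(block: dict) -> CostScheme:
    """Build a scheme from a config mapping {name, transition, transversion, match, gap_open, gap_extend}."""
    name = block.get("name", "custom")
    base = dict(_PRESETS.get(name, _PRESETS["simple1"]))
    mapping = {
        "transition": "transition_cost",
        "transversion": "transversion_cost",
        "match": "match_cost",
        "gap_open": "gap_open",
        "gap_extend": "gap_extend",
    }
    for key, attr in mapping.items():
        if key in block and block[key] is not None:
            val = block[key]
            if attr == "gap_open" and (val in ("inf", "+inf") or val == math.inf):
                val = math.inf
            base[attr] = val
    return CostScheme(name=name, **base)
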