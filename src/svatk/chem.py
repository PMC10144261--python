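"""Monoisotopic mass bookkeeping for residues, modifications and substitutions.

Sequence-variant triage lives and dies on delta-mass arithmetic: a single
amino-acid substitution shifts a peptide's mass by the difference of two
residue masses, and several chemically distinct events can produce the same
shift within instrument tolerance (the classic case being Ala→Glu, Gly→Asp
and cysteine carboxymethylation, all at +58.0055 Da).  This module owns the
residue-mass table, modification definitions (including heavy-isotope
variants used to break such degeneracies), and exhaustive isobaric-conflict
lookup.

Masses are monoisotopic residue masses (free amino acid minus water), fixed
to six decimals so results do not drift with external tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

#: Monoisotopic mass of water, added once per peptide chain.
WATER_MONO = 18.010565

#: Monoisotopic proton mass, for m/z arithmetic.
PROTON = 1.00727646677

#: Mass difference between carbon-13 and carbon-12.
C13_MINUS_C12 = 1.0033548

# Standard monoisotopic residue masses for the 20 canonical amino acids.
_CANONICAL: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Non-canonical substitution targets shipped by default.  Methylnorleucine
#: (Mnl) is an Ile-position misincorporation product observed in recombinant
#: antibodies; it is modeled as Ile/Leu plus one CH2 (+14.01565 Da).
DEFAULT_NONCANONICAL: dict[str, float] = {
    "Mnl": _CANONICAL["I"] + 14.01565,
}


class UnknownResidueError(KeyError):
    """Raised when a residue symbol is not in the configured mass table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown residue symbol {self.symbol!r}"


class ResidueMassTable:
    """Total lookup table of residue symbol -> monoisotopic mass in Da.

    Always contains the 20 canonical residues; extra (possibly multi-letter)
    symbols such as ``Mnl`` may be configured.  Lookups of unconfigured
    symbols raise :class:`UnknownResidueError` rather than guessing.
    """

    def __init__(
        self,
        extra: Mapping[str, float] | None = None,
        include_default_noncanonical: bool = True,
    ):
        entries = dict(_CANONICAL)
        if include_default_noncanonical:
            entries.update(DEFAULT_NONCANONICAL)
        if extra:
            entries.update(extra)
        for sym, mass in entries.items():
            if mass <= 0:
                raise ValueError(f"residue mass for {sym!r} must be positive")
        self._entries = entries

    def mass(self, symbol: str) -> float:
        try:
            return self._entries[symbol]
        except KeyError:
            raise UnknownResidueError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(sorted(self._entries))

    @property
    def canonical_symbols(self) -> tuple[str, ...]:
        return tuple(sorted(_CANONICAL))


#: Shared default table (canonical residues + Mnl).
DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ModificationDef:
    """A named mass modification with residue/terminus targets.

    ``n_13c`` counts carbon-13 substitutions in the reagent: a heavy-labeled
    modification's delta is the light delta plus ``n_13c`` times the
    13C−12C mass difference.  This is how heavy iodoacetic acid moves
    cysteine carboxymethylation (+58.0055 Da, isobaric with Ala→Glu and
    Gly→Asp) off the substitution delta.
    """

    name: str
    delta: float
    targets: frozenset[str]
    n_13c: int = 0

    def as_heavy(self, n_13c: int) -> "ModificationDef":
        """Return the heavy-isotope version of a light modification."""
        if self.n_13c != 0:
            raise ValueError("as_heavy must start from a light modification")
        return replace(
            self,
            name=f"{self.name}(heavy)",
            delta=self.delta + n_13c * C13_MINUS_C12,
            n_13c=n_13c,
        )


#: Cysteine carboxymethylation by iodoacetic acid (CH2COOH replacing H).
CARBOXYMETHYL_LIGHT = ModificationDef(
    "carboxymethyl", 58.005479, frozenset({"C"}))

#: Default heavy reagent: two 13C atoms, +60.0122 Da, clear of the
#: +58.0055 substitution isobar.
CARBOXYMETHYL_HEAVY = CARBOXYMETHYL_LIGHT.as_heavy(2)

DEFAULT_MODIFICATIONS: tuple[ModificationDef, ...] = (CARBOXYMETHYL_HEAVY,)


def residue_mass(symbol: str, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Monoisotopic residue (chain) mass of one configured symbol."""
    return table.mass(symbol)


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, ModificationDef]] = (),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Neutral monoisotopic peptide mass: residues + water + modification deltas.

    ``mods`` are ``(position, ModificationDef)`` pairs with 1-based positions;
    each modification must target the residue actually present there.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    mass = WATER_MONO + sum(table.mass(sym) for sym in sequence)
    for pos, mod in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        residue = sequence[pos - 1]
        if residue not in mod.targets and not {"N-term", "C-term"} & mod.targets:
            raise ValueError(
                f"modification {mod.name!r} does not target residue "
                f"{residue!r} at position {pos}")
        mass += mod.delta
    return mass


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a peptide at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def substitution_delta(
    wildtype: str, observed: str, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Signed mass shift of a single substitution: mass(observed) − mass(wildtype)."""
    return table.mass(observed) - table.mass(wildtype)


@dataclass(frozen=True, order=True)
class IsobaricExplanation:
    """One chemical explanation for a delta mass."""

    label: str
    delta: float
    kind: str  # "substitution" | "modification"


def isobaric_partners(
    delta: float,
    tolerance: float,
    table: ResidueMassTable = DEFAULT_TABLE,
    modifications: Iterable[ModificationDef] = DEFAULT_MODIFICATIONS,
) -> list[IsobaricExplanation]:
    """All substitutions and registered modifications isobaric with ``delta``.

    Scans every ordered pair of distinct configured residues plus every
    registered modification and keeps those whose delta lies within
    ±``tolerance`` of the query.  Order is deterministic: ascending absolute
    deviation from the query, then alphabetical label.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    hits: list[tuple[float, str, IsobaricExplanation]] = []
    for wt in table.symbols:
        for obs in table.symbols:
            if wt == obs:
                continue
            d = substitution_delta(wt, obs, table)
            if abs(d - delta) <= tolerance:
                exp = IsobaricExplanation(f"{wt}->{obs}", d, "substitution")
                hits.append((abs(d - delta), exp.label, exp))
    for mod in modifications:
        if abs(mod.delta - delta) <= tolerance:
            exp = IsobaricExplanation(mod.name, mod.delta, "modification")
            hits.append((abs(mod.delta - delta), exp.label, exp))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [exp for _, _, exp in hits]
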