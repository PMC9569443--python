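"""Monoisotopic mass and m/z calculus for modified peptides.

This module is the numeric foundation of the package: neutral masses and
ion m/z values for tryptic peptides carrying the modifications that matter
for lamin A proteoform work — carbamidomethyl cysteine, the C-terminal
farnesyl + O-methyl pair of prenylated C-termini, and 13C/15N heavy labels
used for isotope-dilution standards.  It covers precursor ions, the b/y
fragment series, neutral losses (farnesyl, water) and heavy-label shifts.

All arithmetic is done at full double precision from standard monoisotopic
residue masses (taken from :mod:`pyteomics.mass`); values intended for
comparison against printed transition tables are rounded half-even to four
decimals with :func:`table_mz`.

Conventions
-----------
* Residue positions are 1-based.
* ``y_n`` is the C-terminal fragment of *n* residues, ``b_n`` the N-terminal
  one; both include the modifications sitting on their residues.
* A farnesylated peptide can be evaluated "defarnesylated": the farnesyl
  delta is dropped while the O-methyl ester is retained.  This is the
  species observed after the characteristic farnesyl neutral loss, whose
  fragments are what multistage (MS3) acquisitions monitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from pyteomics import mass as _ptmass

__all__ = [
    "PROTON",
    "WATER",
    "DELTA_13C",
    "DELTA_15N",
    "RESIDUE_MASS",
    "Modification",
    "ModificationRegistry",
    "DEFAULT_REGISTRY",
    "HeavyLabelSpec",
    "ModifiedPeptide",
    "Ion",
    "peptide_neutral_mass",
    "precursor_mz",
    "fragment_mz",
    "neutral_loss_mz",
    "apply_heavy_label",
    "table_mz",
]

# Physical constants (Da).  Residue masses come from the standard
# monoisotopic table shipped with pyteomics.
PROTON: float = 1.00727646677
WATER: float = 18.0105646863
DELTA_13C: float = 1.0033548  # 13C - 12C
DELTA_15N: float = 0.9970349  # 15N - 14N

RESIDUE_MASS: dict[str, float] = dict(_ptmass.std_aa_mass)


@dataclass(frozen=True)
class Modification:
    """A named mass modification attached to a residue or terminus.

    ``target`` is the one-letter residue code the modification may sit on,
    or ``"*"`` for any residue (used for abstract neutral-loss species such
    as water).
    """

    name: str
    target: str
    delta_mass: float

    def __post_init__(self) -> None:
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) != float("inf")):
            raise ValueError(f"delta_mass for {self.name!r} must be finite")


class ModificationRegistry:
    """Registry of known modifications, keyed by unique name.

    Ships with the built-ins needed for the lamin A / progerin panel and can
    be extended or loaded from a YAML mapping ``name -> {target, delta}``.
    """

    def __init__(self) -> None:
        self._mods: dict[str, Modification] = {}

    def register(self, mod: Modification) -> Modification:
        if mod.name in self._mods and self._mods[mod.name] != mod:
            raise ValueError(f"modification name {mod.name!r} already registered")
        self._mods[mod.name] = mod
        return mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(
                f"unknown modification {name!r}; known: {sorted(self._mods)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def names(self) -> list[str]:
        return sorted(self._mods)

    @classmethod
    def builtin(cls) -> "ModificationRegistry":
        reg = cls()
        reg.register(Modification("carbamidomethyl", "C", 57.021464))
        reg.register(Modification("farnesyl", "C", 204.187801))
        reg.register(Modification("o_methyl", "C", 14.015650))
        reg.register(Modification("water", "*", WATER))
        return reg

    def to_dict(self) -> dict:
        return {
            m.name: {"target": m.target, "delta": m.delta_mass}
            for m in self._mods.values()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModificationRegistry":
        reg = cls.builtin()
        for name, spec in d.items():
            mod = Modification(name, spec["target"], float(spec["delta"]))
            if name in reg and reg[name] != mod:
                raise ValueError(f"conflicting redefinition of builtin {name!r}")
            if name not in reg:
                reg.register(mod)
        return reg


def load_registry(path: str | None = None) -> "ModificationRegistry":
    """Load a modification registry from YAML (``name -> {target, delta}``);
    without a path, the packaged built-in registry file is used."""
    import yaml
    from importlib import resources
    from pathlib import Path

    if path is None:
        path = str(resources.files("laminprm.data") / "modifications.yaml")
    return ModificationRegistry.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_REGISTRY = ModificationRegistry.builtin()
CARBAMIDOMETHYL = DEFAULT_REGISTRY["carbamidomethyl"]
FARNESYL = DEFAULT_REGISTRY["farnesyl"]
O_METHYL = DEFAULT_REGISTRY["o_methyl"]


@dataclass(frozen=True)
class HeavyLabelSpec:
    """Stable-isotope label on a single residue: ``n_13c`` carbons and
    ``n_15n`` nitrogens replaced by their heavy isotopes.

    ``residue_position`` is a 1-based index, or the strings ``"N-term"`` /
    ``"C-term"`` for the first/last residue.
    """

    residue_position: int | str
    n_13c: int = 0
    n_15n: int = 0

    def __post_init__(self) -> None:
        if self.n_13c < 0 or self.n_15n < 0:
            raise ValueError("isotope counts must be non-negative")

    @property
    def delta(self) -> float:
        return self.n_13c * DELTA_13C + self.n_15n * DELTA_15N

    def resolve_position(self, length: int) -> int:
        """Return the 1-based residue index for a peptide of ``length``."""
        if self.residue_position == "N-term":
            return 1
        if self.residue_position == "C-term":
            return length
        pos = int(self.residue_position)
        if not 1 <= pos <= length:
            raise ValueError(
                f"label position {pos} outside peptide of length {length}"
            )
        return pos


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with per-residue modifications and an optional
    heavy-isotope label — the unit all mass calculus operates on.

    ``mods`` is a tuple of ``(position, Modification)`` with 1-based
    positions.  A farnesyl + O-methyl pair is only admitted on the
    C-terminal cysteine (the biology of prenylated C-termini).
    """

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()
    label: HeavyLabelSpec | None = None
    symbol: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, res in enumerate(self.sequence, start=1):
            if res not in RESIDUE_MASS:
                raise ValueError(
                    f"unknown residue {res!r} at position {i} in {self.sequence!r}"
                )
        object.__setattr__(self, "mods", tuple(self.mods))
        n = len(self.sequence)
        for pos, mod in self.mods:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"modification {mod.name!r} at position {pos} outside 1..{n}"
                )
            res = self.sequence[pos - 1]
            if mod.target not in ("*", res):
                raise ValueError(
                    f"modification {mod.name!r} targets {mod.target!r}, "
                    f"not {res!r} at position {pos}"
                )
            if mod.name in ("farnesyl", "o_methyl") and not (
                pos == n and res == "C"
            ):
                raise ValueError(
                    f"{mod.name} is only admitted on a C-terminal Cys "
                    f"(got position {pos} of {n})"
                )
        for name in ("farnesyl", "o_methyl"):
            if sum(1 for _, m in self.mods if m.name == name) > 1:
                raise ValueError(f"at most one {name} per peptide")
        if self.label is not None:
            self.label.resolve_position(n)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_farnesylated(self) -> bool:
        return any(m.name == "farnesyl" for _, m in self.mods)

    def mod_delta(self, start: int, end: int, *, skip_farnesyl: bool = False) -> float:
        """Summed modification deltas for residues ``start..end`` (1-based,
        inclusive), optionally omitting farnesyl (neutral-loss species)."""
        total = 0.0
        for pos, mod in self.mods:
            if start <= pos <= end:
                if skip_farnesyl and mod.name == "farnesyl":
                    continue
                total += mod.delta_mass
        return total

    def label_delta(self, start: int | None = None, end: int | None = None) -> float:
        """Heavy-label delta if the labeled residue lies in ``start..end``
        (whole peptide when omitted)."""
        if self.label is None:
            return 0.0
        pos = self.label.resolve_position(len(self.sequence))
        if start is None:
            start = 1
        if end is None:
            end = len(self.sequence)
        return self.label.delta if start <= pos <= end else 0.0


@dataclass(frozen=True)
class Ion:
    """A charged species derived from a peptide."""

    series: str  # precursor | b | y | precursor-NL | fragment-of-NL
    charge: int
    mz: float
    index: int | None = None  # residue count for b/y
    losses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


def table_mz(mz: float) -> float:
    """Round an m/z half-even to 4 decimals for transition-table display."""
    return round(mz, 4)


def peptide_neutral_mass(p: ModifiedPeptide, *, defarnesylated: bool = False) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas +
    heavy-label delta.  With ``defarnesylated`` the farnesyl delta is
    dropped (O-methyl retained)."""
    mass = WATER
    for res in p.sequence:
        mass += RESIDUE_MASS[res]
    mass += p.mod_delta(1, len(p.sequence), skip_farnesyl=defarnesylated)
    mass += p.label_delta()
    return mass


def precursor_mz(p: ModifiedPeptide, z: int, *, defarnesylated: bool = False) -> float:
    """(M + z·H+)/z for the intact (or farnesyl-stripped) peptide."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (peptide_neutral_mass(p, defarnesylated=defarnesylated) + z * PROTON) / z


def fragment_mz(
    p: ModifiedPeptide,
    series: str,
    index: int,
    z: int = 1,
    *,
    defarnesylated: bool = False,
) -> float:
    """m/z of a b- or y-series fragment.

    ``y_n`` covers the *n* C-terminal residues (plus water), ``b_n`` the
    *n* N-terminal ones.  Modifications and the heavy label shift a
    fragment only when their residue lies inside it.  ``defarnesylated``
    omits the farnesyl delta (fragments of the neutral-loss species).
    """
    n = len(p.sequence)
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} out of range 1..{n - 1}")
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if series == "y":
        start, end = n - index + 1, n
        residues = p.sequence[start - 1 :]
        base = WATER
    elif series == "b":
        start, end = 1, index
        residues = p.sequence[:index]
        base = 0.0
    else:
        raise ValueError(f"unknown fragment series {series!r} (use 'b' or 'y')")
    mass = base + sum(RESIDUE_MASS[r] for r in residues)
    mass += p.mod_delta(start, end, skip_farnesyl=defarnesylated)
    mass += p.label_delta(start, end)
    return (mass + z * PROTON) / z


def neutral_loss_mz(
    ion_mz: float,
    z: int,
    loss: Modification | str,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> float:
    """m/z after loss of a neutral species: ``ion_mz - delta/z``."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if isinstance(loss, str):
        loss = registry[loss]
    return ion_mz - loss.delta_mass / z


def apply_heavy_label(p: ModifiedPeptide, spec: HeavyLabelSpec) -> ModifiedPeptide:
    """Return the heavy isotopologue of ``p`` (same sequence and mods)."""
    spec.resolve_position(len(p.sequence))  # position check
    if p.label is not None and (p.label.n_13c or p.label.n_15n):
        warnings.warn(
            f"replacing existing heavy label on {p.symbol or p.sequence}",
            stacklevel=2,
        )
    symbol = p.symbol + "*" if p.symbol else p.symbol
    return replace(p, label=spec, symbol=symbol)
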