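"""Monoisotopic mass calculus for modified and crosslinked peptides.

Benzophenone photo-crosslinking (either the genetically encoded amino acid
Bpa, written ``B``, or a 4-(N-maleimido)benzophenone adduct on cysteine,
written ``X``) inserts into a C-H bond of a nearby residue with **zero mass
change**: the neutral mass of a crosslinked species is exactly the sum of
the two peptide masses.  Everything in this module follows from that and
from the standard monoisotopic residue masses.

Peptide sequences use one-letter codes plus the inline special letters
``B``/``X`` and the positional modification syntax ``M[ox]`` / ``C[cam]``.
The residue and modification tables are loaded from a versioned YAML config
(:data:`DEFAULT_CHEMISTRY`) and validated on load: each stated residue mass
must agree with the mass computed from its elemental composition.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml
from pyteomics.mass import nist_mass

__all__ = [
    "ResidueTable",
    "Peptide",
    "CrosslinkSpecies",
    "DEFAULT_CHEMISTRY",
    "PROTON_MASS",
    "WATER_MASS",
    "parse_peptide",
    "peptide_mass",
    "crosslink_mass",
    "ppm_error",
    "mz",
    "neutral_mass",
    "isotope_pattern",
]

PROTON_MASS = 1.007276466
WATER_MASS = 18.010565

#: Average spacing between adjacent isotopologue peaks of a peptide (Da).
ISOTOPE_SPACING = 1.0033548


def _element_mass(element: str) -> float:
    """Monoisotopic mass of an element from the NIST table."""
    return nist_mass[element][0][0]


def composition_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition such as ``{"C": 2, ...}``."""
    return sum(n * _element_mass(el) for el, n in composition.items())


class ChemistryError(ValueError):
    """Raised for unknown residues, illegal modification placements, etc."""


@dataclass(frozen=True)
class ResidueTable:
    """Residue and modification chemistry loaded from a versioned config.

    Parameters
    ----------
    residues
        One-letter residue code -> elemental composition (residue = amino
        acid minus water).
    residue_masses
        Stated monoisotopic residue masses; validated against the
        compositions on construction (tolerance 1e-5 Da).
    modifications
        Modification name -> (allowed target residues, delta composition).
    fixed_modifications
        Names applied automatically to every matching residue that does not
        already carry a modification (e.g. carbamidomethyl on cysteine).
    """

    version: int
    residues: Mapping[str, Counter]
    residue_masses: Mapping[str, float]
    modifications: Mapping[str, tuple[frozenset, Counter]]
    fixed_modifications: tuple[str, ...] = ()
    photo_residues: frozenset = frozenset({"B", "X"})

    def __post_init__(self):
        for letter, comp in self.residues.items():
            stated = self.residue_masses[letter]
            computed = composition_mass(comp)
            if abs(stated - computed) > 1e-5:
                raise ChemistryError(
                    f"residue {letter}: stated mass {stated} deviates from "
                    f"composition mass {computed:.6f} by more than 1e-5 Da"
                )

    @classmethod
    def from_yaml(cls, path=None) -> "ResidueTable":
        """Load the bundled default chemistry, or a user-supplied YAML file."""
        if path is None:
            text = (
                resources.files("xlmap").joinpath("data/chemistry.yaml").read_text()
            )
        else:
            with open(path) as fh:
                text = fh.read()
        cfg = yaml.safe_load(text)

        residues: dict[str, Counter] = {}
        masses: dict[str, float] = {}
        for letter, entry in cfg["residues"].items():
            residues[letter] = Counter(entry["composition"])
            masses[letter] = float(entry["mass"])
        for letter, entry in cfg.get("special_residues", {}).items():
            comp = residues[entry["base"]] + Counter(entry["delta_composition"])
            residues[letter] = comp
            masses[letter] = composition_mass(comp)
        mods = {}
        for name, entry in cfg.get("modifications", {}).items():
            mods[name] = (
                frozenset(entry["targets"]),
                Counter(entry["delta_composition"]),
            )
        return cls(
            version=int(cfg.get("version", 1)),
            residues=residues,
            residue_masses=masses,
            modifications=mods,
            fixed_modifications=tuple(cfg.get("fixed_modifications", ())),
        )

    def modification_delta(self, name: str) -> float:
        return composition_mass(self.modifications[name][1])


def _default_table() -> ResidueTable:
    return ResidueTable.from_yaml()


DEFAULT_CHEMISTRY: ResidueTable = _default_table()


@dataclass(frozen=True)
class Peptide:
    """A protein subsequence with positioned modifications.

    ``sequence`` uses plain letters plus ``B``/``X``; ``modifications`` maps
    1-based position within the peptide to a modification name.  ``parent``
    and ``start`` (1-based, inclusive) tie the peptide to its protein of
    origin when known.
    """

    sequence: str
    modifications: Mapping[int, str] = field(default_factory=dict)
    parent: str | None = None
    start: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ChemistryError("empty peptide sequence")
        object.__setattr__(self, "modifications", dict(self.modifications))

    @property
    def end(self) -> int | None:
        """1-based inclusive end position in the parent protein."""
        if self.start is None:
            return None
        return self.start + len(self.sequence) - 1

    def photo_sites(self, table: ResidueTable = None) -> list[int]:
        """1-based positions of photo-reactive residues (B or X)."""
        table = table or DEFAULT_CHEMISTRY
        return [
            i + 1 for i, c in enumerate(self.sequence) if c in table.photo_residues
        ]

    def to_parent_coord(self, position: int) -> int:
        """Map a 1-based peptide position to the parent protein coordinate."""
        if self.start is None:
            raise ValueError(f"peptide {self.sequence} has no parent coordinates")
        return self.start + position - 1


_MOD_RE = re.compile(r"([A-Z])(?:\[([a-z0-9]+)\])?")


def parse_peptide(
    notation: str,
    table: ResidueTable = None,
    parent: str | None = None,
    start: int | None = None,
    apply_fixed: bool = True,
) -> Peptide:
    """Parse inline notation like ``"QTEIFTHFM[ox]TNSAK"`` into a :class:`Peptide`.

    Fixed modifications from the chemistry config (carbamidomethyl on
    unlabeled Cys by default) are filled in unless ``apply_fixed`` is False.
    """
    table = table or DEFAULT_CHEMISTRY
    consumed = sum(len(m.group(0)) for m in _MOD_RE.finditer(notation))
    if consumed != len(notation):
        raise ChemistryError(f"unparseable peptide notation: {notation!r}")
    sequence = []
    mods: dict[int, str] = {}
    for m in _MOD_RE.finditer(notation):
        sequence.append(m.group(1))
        if m.group(2):
            mods[len(sequence)] = m.group(2)
    seq = "".join(sequence)
    if apply_fixed:
        for name in table.fixed_modifications:
            targets, _ = table.modifications[name]
            for i, c in enumerate(seq, start=1):
                if c in targets and i not in mods:
                    mods[i] = name
    pep = Peptide(seq, mods, parent=parent, start=start)
    validate_peptide(pep, table)
    return pep


def validate_peptide(p: Peptide, table: ResidueTable = None) -> None:
    """Check residue letters and modification placements; raise on violation."""
    table = table or DEFAULT_CHEMISTRY
    for i, c in enumerate(p.sequence, start=1):
        if c not in table.residues:
            raise ChemistryError(f"unknown residue {c!r} at position {i}")
    for pos, name in p.modifications.items():
        if not 1 <= pos <= len(p.sequence):
            raise ChemistryError(f"modification position {pos} outside peptide")
        if name not in table.modifications:
            raise ChemistryError(f"unknown modification {name!r} at position {pos}")
        targets, _ = table.modifications[name]
        if p.sequence[pos - 1] not in targets:
            raise ChemistryError(
                f"modification {name!r} at position {pos} targets "
                f"{sorted(targets)} but residue is {p.sequence[pos - 1]!r}"
            )


def peptide_composition(p: Peptide, table: ResidueTable = None) -> Counter:
    """Full elemental composition of the neutral peptide (including water)."""
    table = table or DEFAULT_CHEMISTRY
    validate_peptide(p, table)
    comp: Counter = Counter({"H": 2, "O": 1})
    for c in p.sequence:
        comp += table.residues[c]
    for name in p.modifications.values():
        comp += table.modifications[name][1]
    return comp


def peptide_mass(p: Peptide, table: ResidueTable = None) -> float:
    """Neutral monoisotopic mass (Da): residue masses + mod deltas + water."""
    table = table or DEFAULT_CHEMISTRY
    validate_peptide(p, table)
    m = WATER_MASS
    for c in p.sequence:
        m += table.residue_masses[c]
    for name in p.modifications.values():
        m += table.modification_delta(name)
    return m


@dataclass(frozen=True)
class CrosslinkSpecies:
    """A photo-crosslinked peptide pair; alpha carries the reactive group.

    The benzophenone insertion adds no mass, so ``mass`` is exactly
    ``peptide_mass(alpha) + peptide_mass(beta)``.
    """

    alpha: Peptide
    beta: Peptide
    mass: float

    def __str__(self):
        return f"{self.alpha.sequence}--{self.beta.sequence} ({self.mass:.4f} Da)"


def crosslink_mass(
    alpha: Peptide, beta: Peptide, table: ResidueTable = None
) -> CrosslinkSpecies:
    """Pair two peptides into a zero-linker-mass crosslinked species.

    ``alpha`` must contain exactly one photo-reactive residue (B or X).
    """
    table = table or DEFAULT_CHEMISTRY
    sites = alpha.photo_sites(table)
    if len(sites) != 1:
        raise ChemistryError(
            f"alpha peptide {alpha.sequence!r} must carry exactly one "
            f"photo-reactive residue (B/X); found {len(sites)}"
        )
    return CrosslinkSpecies(
        alpha=alpha,
        beta=beta,
        mass=peptide_mass(alpha, table) + peptide_mass(beta, table),
    )


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million: (obs - theo)/theo * 1e6."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return (observed - theoretical) / theoretical * 1e6


def mz(neutral_mass: float, z: int) -> float:
    """m/z of an [M + zH]^z+ ion."""
    if not isinstance(z, (int, np.integer)) or z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z!r}")
    return (neutral_mass + z * PROTON_MASS) / z


def neutral_mass(mz_value: float, z: int) -> float:
    """Neutral mass recovered from an observed m/z and charge."""
    if z <= 0:
        raise ValueError("charge must be a positive integer")
    return mz_value * z - z * PROTON_MASS


# Isotope patterns ----------------------------------------------------------

def _isotope_vector(element: str, max_shift: int) -> np.ndarray:
    """Abundance vector over nominal mass shifts 0..max_shift for one atom."""
    base = min(
        k for k, (_, abundance) in nist_mass[element].items() if k != 0 and abundance
    )
    vec = np.zeros(max_shift + 1)
    for k, (_, abundance) in nist_mass[element].items():
        if k == 0 or abundance == 0:
            continue
        shift = k - base
        if shift <= max_shift:
            vec[shift] += abundance
    return vec


def _power_convolve(vec: np.ndarray, n: int, keep: int) -> np.ndarray:
    """vec convolved with itself n times, truncated to ``keep`` entries."""
    result = np.zeros(keep)
    result[0] = 1.0
    base = vec[:keep].copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:keep]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:keep]
    return result


def isotope_pattern(
    species: Peptide | CrosslinkSpecies,
    n_peaks: int = 8,
    table: ResidueTable = None,
) -> list[tuple[float, float]]:
    """Isotopologue pattern by exact convolution of elemental isotope vectors.

    Returns ``n_peaks`` pairs of (mass, relative abundance).  The first peak
    is the monoisotopic mass; successive peaks are spaced by the average
    isotope spacing (~1.00336 Da).  Abundances are renormalized to sum to 1
    over the returned peaks.  Truncation is monotone: requesting more peaks
    never changes the relative proportions of earlier ones.
    """
    table = table or DEFAULT_CHEMISTRY
    if isinstance(species, CrosslinkSpecies):
        comp = peptide_composition(species.alpha, table) + peptide_composition(
            species.beta, table
        )
        mono = species.mass
    else:
        comp = peptide_composition(species, table)
        mono = peptide_mass(species, table)

    pattern = np.ones(1)
    for element, count in comp.items():
        vec = _isotope_vector(element, n_peaks - 1)
        vec = vec / vec.sum()
        pattern = np.convolve(pattern, _power_convolve(vec, count, n_peaks))[
            :n_peaks
        ]
    pattern = pattern / pattern.sum()
    return [
        (mono + k * ISOTOPE_SPACING, float(a)) for k, a in enumerate(pattern)
    ]


def iter_oxidation_variants(
    p: Peptide, max_ox: int = 1, table: ResidueTable = None
) -> Iterator[Peptide]:
    """Yield the peptide and its Met-oxidation variants (at most ``max_ox``).

    Used during candidate enumeration: the search considers each peptide
    with 0..max_ox oxidized methionines, one variant per distinct choice of
    oxidized positions.
    """
    table = table or DEFAULT_CHEMISTRY
    yield p
    if max_ox < 1:
        return
    met_positions = [
        i
        for i, c in enumerate(p.sequence, start=1)
        if c == "M" and i not in p.modifications
    ]
    for pos in met_positions:
        mods = dict(p.modifications)
        mods[pos] = "ox"
        yield Peptide(p.sequence, mods, parent=p.parent, start=p.start)
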