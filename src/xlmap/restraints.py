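"""Crosslink-derived distance restraints, ensemble filtering, contact maps.

A mapped photo-crosslink between residue *a* of the peptide and residue *b*
of the receptor implies the two residues were within the reach of the
benzophenone at the moment of insertion.  Each crosslink therefore becomes
an upper-bound distance restraint (default 20 A between C-alpha atoms).
When MS2 evidence localizes the attachment only to a residue interval the
restraint is ambiguous and counts as satisfied if ANY residue in the
interval satisfies the bound.

Docked structure ensembles (multi-model PDB, or a directory of single-model
files) are filtered down to the models that satisfy every restraint, and a
contact-probability surface is computed across the surviving family: the
fraction of models in which each (peptide residue, receptor residue) pair
is in contact (minimum heavy-atom distance <= cutoff, default 5 A), plus
the per-receptor-residue marginal (contact with any peptide residue).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .fixtures import parse_site_range
from .search import CrosslinkMatch

__all__ = [
    "DistanceRestraint",
    "ModelEnsemble",
    "ContactSurface",
    "restraints_from_crosslinks",
    "filter_ensemble",
    "contact_surface",
    "write_surface_pdb",
]


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper-bound distance restraint between two (possibly ambiguous) sites.

    ``residues_a``/``residues_b`` are tuples of (chain id, residue seqid);
    the restraint is satisfied when any a-b residue pair is within
    ``bound`` angstrom, measured between the atoms named by ``atom``
    ("CA" by default; any heavy atom of the residue when atom is None).
    """

    residues_a: tuple[tuple[str, int], ...]
    residues_b: tuple[tuple[str, int], ...]
    bound: float = 20.0
    atom: str | None = "CA"

    def __post_init__(self):
        if self.bound < 0:
            raise ValueError("restraint bound must be non-negative")
        if not self.residues_a or not self.residues_b:
            raise ValueError("restraint needs residues on both ends")

    @property
    def linkage(self) -> tuple:
        """Canonical identity used for deduplication of redundant crosslinks."""
        return (tuple(sorted(set(self.residues_a))), tuple(sorted(set(self.residues_b))))


def restraints_from_crosslinks(
    matches: list[CrosslinkMatch] | "object",
    bound: float = 20.0,
    chain_of_protein: dict[str, str] | None = None,
    atom: str | None = "CA",
) -> list[DistanceRestraint]:
    """Turn localized crosslink matches into deduplicated distance restraints.

    Accepts either a list of :class:`~xlmap.search.CrosslinkMatch` or a
    DataFrame with columns ``alpha_protein``, ``alpha_site``,
    ``beta_protein``, ``beta_site`` (sites as ``"n"`` or ``"lo-hi"``).
    ``chain_of_protein`` maps protein ids to structure chain ids (defaults:
    alpha proteins -> "P", beta proteins -> "R").  Redundant matches that
    collapse onto the same residue linkage yield a single restraint — the
    published five high-confidence H4 crosslinks reduce to three unique
    amino-acid linkages this way.
    """
    chain_of_protein = chain_of_protein or {}

    def chain_for(protein: str, default: str) -> str:
        return chain_of_protein.get(protein, default)

    specs: list[tuple] = []
    if hasattr(matches, "iterrows"):
        for _, row in matches.iterrows():
            a_lo, a_hi = parse_site_range(row["alpha_site"])
            b_lo, b_hi = parse_site_range(row["beta_site"])
            specs.append(
                (
                    chain_for(row["alpha_protein"], "P"),
                    (a_lo, a_hi),
                    chain_for(row["beta_protein"], "R"),
                    (b_lo, b_hi),
                )
            )
    else:
        for m in matches:
            if m.alpha_sites is None or m.beta_sites is None:
                raise ValueError(
                    f"match {m.xl} has no localized sites; run localization first"
                )
            specs.append(
                (
                    chain_for(m.xl.alpha.parent or "alpha", "P"),
                    m.alpha_sites,
                    chain_for(m.xl.beta.parent or "beta", "R"),
                    m.beta_sites,
                )
            )

    out: list[DistanceRestraint] = []
    seen: set = set()
    for chain_a, (a_lo, a_hi), chain_b, (b_lo, b_hi) in specs:
        r = DistanceRestraint(
            residues_a=tuple((chain_a, i) for i in range(a_lo, a_hi + 1)),
            residues_b=tuple((chain_b, i) for i in range(b_lo, b_hi + 1)),
            bound=bound,
            atom=atom,
        )
        if r.linkage not in seen:
            seen.add(r.linkage)
            out.append(r)
    return out


# Ensembles -----------------------------------------------------------------

@dataclass
class ModelEnsemble:
    """A family of coordinate models sharing one chain/residue topology."""

    structure: gemmi.Structure
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [str(m.num) for m in self.structure]
        topologies = {
            tuple(
                (chain.name, res.seqid.num, res.name)
                for chain in model
                for res in chain
            )
            for model in self.structure
        }
        if len(topologies) > 1:
            raise ValueError("models in an ensemble must share topology")

    def __len__(self) -> int:
        return len(self.structure)

    @classmethod
    def from_path(cls, path: str | Path) -> "ModelEnsemble":
        """Read a multi-model PDB file, or a directory of single-model files."""
        path = Path(path)
        if path.is_dir():
            files = sorted(path.glob("*.pdb"))
            if not files:
                raise FileNotFoundError(f"no .pdb files under {path}")
            combined = gemmi.Structure()
            combined.name = path.name
            labels = []
            for f in files:
                st = gemmi.read_structure(str(f))
                st.setup_entities()
                for model in st:
                    model.num = len(labels) + 1
                    combined.add_model(model)
                    labels.append(f.stem)
            return cls(combined, labels)
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls(st)

    def subset(self, indices: list[int]) -> "ModelEnsemble":
        """New ensemble containing the selected models, order preserved."""
        st = gemmi.Structure()
        st.name = self.structure.name
        for i in indices:
            st.add_model(self.structure[i])
        return ModelEnsemble(st, [self.labels[i] for i in indices])


def _residue_atoms(model: gemmi.Model, chain: str, seqid: int, atom: str | None):
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num == seqid:
                if atom is None:
                    return [a.pos for a in res if a.element.name != "H"]
                return [a.pos for a in res if a.name == atom]
    return []


def _restraint_satisfied(
    model: gemmi.Model, restraint: DistanceRestraint
) -> bool:
    found_any = False
    for (ca, ia), (cb, ib) in itertools.product(
        restraint.residues_a, restraint.residues_b
    ):
        pa = _residue_atoms(model, ca, ia, restraint.atom)
        pb = _residue_atoms(model, cb, ib, restraint.atom)
        if pa and pb:
            found_any = True
        for a, b in itertools.product(pa, pb):
            if a.dist(b) <= restraint.bound:
                return True
    if not found_any:
        raise KeyError(
            f"restraint references residues absent from model: "
            f"{restraint.residues_a[0]}..{restraint.residues_b[0]}"
        )
    return False


def filter_ensemble(
    ensemble: ModelEnsemble, restraints: list[DistanceRestraint]
) -> ModelEnsemble:
    """Keep exactly the models satisfying every restraint (any-of semantics
    for ambiguous ends).  Subset of the input; order preserved; idempotent."""
    keep = [
        i
        for i, model in enumerate(ensemble.structure)
        if all(_restraint_satisfied(model, r) for r in restraints)
    ]
    return ensemble.subset(keep)


# Contact surfaces ----------------------------------------------------------

@dataclass
class ContactSurface:
    """Per-residue contact probabilities across a model family.

    ``pairwise[(i, j)]`` is the fraction of models in which peptide residue
    i and receptor residue j are in contact; ``marginal[j]`` the fraction in
    which receptor residue j contacts ANY peptide residue.
    """

    pairwise: dict[tuple[int, int], float]
    marginal: dict[int, float]
    n_models: int
    peptide_chain: str
    receptor_chain: str
    cutoff: float


def contact_surface(
    ensemble: ModelEnsemble,
    peptide_chain: str,
    receptor_chain: str,
    cutoff: float = 5.0,
) -> ContactSurface:
    """Contact probabilities: min heavy-atom distance(i, j) <= cutoff, counted
    over models and divided by the family size."""
    n = len(ensemble)
    if n == 0:
        raise ValueError("empty ensemble")
    chains = {ch.name for model in ensemble.structure for ch in model}
    for name in (peptide_chain, receptor_chain):
        if name not in chains:
            raise KeyError(f"chain {name!r} not present (have {sorted(chains)})")

    pair_counts: dict[tuple[int, int], int] = {}
    marg_counts: dict[int, int] = {}
    for model in ensemble.structure:
        pep: dict[int, np.ndarray] = {}
        rec: dict[int, np.ndarray] = {}
        for ch in model:
            store = pep if ch.name == peptide_chain else (
                rec if ch.name == receptor_chain else None
            )
            if store is None:
                continue
            for res in ch:
                coords = np.array(
                    [[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"]
                )
                if len(coords):
                    store[res.seqid.num] = coords
        touched: set[int] = set()
        for j, rc in rec.items():
            marg_counts.setdefault(j, 0)
            for i, pc in pep.items():
                d2 = ((pc[:, None, :] - rc[None, :, :]) ** 2).sum(-1)
                if d2.min() <= cutoff**2:
                    pair_counts[(i, j)] = pair_counts.get((i, j), 0) + 1
                    touched.add(j)
        for j in touched:
            marg_counts[j] += 1
        for i in pep:
            for j in rec:
                pair_counts.setdefault((i, j), pair_counts.get((i, j), 0))
    return ContactSurface(
        pairwise={k: v / n for k, v in pair_counts.items()},
        marginal={k: v / n for k, v in marg_counts.items()},
        n_models=n,
        peptide_chain=peptide_chain,
        receptor_chain=receptor_chain,
        cutoff=cutoff,
    )


def write_surface_pdb(
    ensemble: ModelEnsemble,
    surface: ContactSurface,
    path: str | Path,
    model_index: int = 0,
) -> None:
    """Write one representative model with marginal contact probabilities in
    the B-factor column, scaled 0-100 (probability 1.0 -> B = 100.00)."""
    st = gemmi.Structure()
    st.name = ensemble.structure.name
    st.add_model(ensemble.structure[model_index])
    model = st[0]
    receptor_residues = {
        res.seqid.num
        for ch in model
        if ch.name == surface.receptor_chain
        for res in ch
    }
    missing = set(surface.marginal) - receptor_residues
    if missing:
        raise ValueError(
            f"surface references residues absent from the model: {sorted(missing)[:5]}"
        )
    for ch in model:
        for res in ch:
            if ch.name == surface.receptor_chain:
                b = 100.0 * surface.marginal.get(res.seqid.num, 0.0)
            else:
                b = 0.0
            for atom in res:
                atom.b_iso = b
    st.setup_entities()
    st.write_pdb(str(path))


def read_surface_pdb(path: str | Path, receptor_chain: str) -> dict[int, float]:
    """Read back per-residue probabilities from the B-factor column."""
    st = gemmi.read_structure(str(path))
    out: dict[int, float] = {}
    for ch in st[0]:
        if ch.name != receptor_chain:
            continue
        for res in ch:
            out[res.seqid.num] = res[0].b_iso / 100.0
    return out
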