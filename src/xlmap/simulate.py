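"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of one experimental data
type and emits the planted ground truth alongside, so every downstream
stage can be scored without reference to generator internals:

* :func:`simulate_xl_ms` — MS1 feature lists (+UV / -UV) and MS2 spectra
  containing planted crosslinked pairs with Gaussian ppm-scale mass error,
  UV enrichment, partial b/y ladders and random decoy peaks;
* :func:`simulate_ensemble` — a docked-peptide model family built on a toy
  helical receptor, with the peptide placed in a designated pocket in a
  stated fraction of models, so restraint satisfaction and contact
  probabilities are known by construction;
* :func:`simulate_kinetics` — single-exponential remodeling traces and
  linear NADH-depletion traces with Gaussian noise.

All outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .chemistry import crosslink_mass, mz as to_mz
from .kinetics import NADH_EXTINCTION, KineticTrace
from .restraints import DistanceRestraint, ModelEnsemble
from .search import DigestSpec, Ms1Feature, Ms2Spectrum, digest, fragment_ions

__all__ = [
    "XlMsRecipe",
    "EnsembleRecipe",
    "KineticsRecipe",
    "simulate_xl_ms",
    "simulate_ensemble",
    "simulate_kinetics",
    "shuffle_sequence",
    "write_xl_ms",
    "write_kinetics_csv",
]

# Default bait: the 24 N-terminal residues of histone H4 with the
# photo-reactive Bpa substitution at position 1 (the T1B peptide); trypsin
# releases the B-containing peptide BGR.
DEFAULT_BAIT = "BGRGKGGKGLGKGGAKRHRKVLRD"

# Default prey: a synthetic 72-residue receptor whose tryptic map mimics a
# remodeler ATPase-lobe fragment (peptides of 4-14 residues, one Met, one
# Cys, internal K.P sites left uncut).
DEFAULT_PREY = (
    "MSTEALKQIDGFNAESRLVTPEGWKHLDNQTPYEDRNVIEMGGRSPTKPAKGFECLIDWKTQAVNHEFGSR"
)


@dataclass(frozen=True)
class XlMsRecipe:
    """Conditions for the crosslinking-MS simulation.

    ``planted_sites`` pairs a bait-protein site (the photo residue) with a
    prey-protein site; the generator plants the crosslink between the
    shortest fully tryptic peptides covering those sites.  Mass errors are
    Gaussian with ``sigma_ppm``; planted species are ``uv_enrichment``-fold
    stronger after irradiation; decoy MS1 features appear at
    ``decoy_density`` per Da over the observed mass range; MS2 ladders keep
    each fragment with probability ``ms2_completeness`` and gain
    Poisson(``ms2_noise_peaks``) random noise peaks.
    """

    seed: int = 0
    bait_sequence: str = DEFAULT_BAIT
    prey_sequence: str = DEFAULT_PREY
    planted_sites: tuple[tuple[int, int], ...] = ((1, 33), (1, 41), (1, 47))
    sigma_ppm: float = 3.0
    uv_enrichment: float = 20.0
    decoy_density: float = 0.2
    ms2_completeness: float = 0.9
    ms2_noise_peaks: float = 20.0
    base_intensity: float = 1e6
    digest_spec: DigestSpec = field(default_factory=DigestSpec)


@dataclass
class XlMsData:
    """Simulated MS inputs plus the planted truth."""

    bait_id: str
    prey_id: str
    bait_sequence: str
    prey_sequence: str
    features: list[Ms1Feature]
    spectra: list[Ms2Spectrum]
    truth: pd.DataFrame


def _covering_peptide(peptides, site):
    hits = [p for p in peptides if p.start <= site <= p.end]
    if not hits:
        raise ValueError(f"no tryptic peptide covers site {site}")
    return min(hits, key=lambda p: len(p.sequence))


def simulate_xl_ms(recipe: XlMsRecipe) -> XlMsData:
    """Generate MS1 features (+UV/-UV), MS2 spectra and the truth table."""
    rng = np.random.default_rng(recipe.seed)
    bait_peps = digest(recipe.bait_sequence, recipe.digest_spec, parent="bait")
    prey_peps = digest(recipe.prey_sequence, recipe.digest_spec, parent="prey")

    features: list[Ms1Feature] = []
    spectra: list[Ms2Spectrum] = []
    truth_rows = []
    for n, (bait_site, prey_site) in enumerate(recipe.planted_sites):
        bait_pep = _covering_peptide(
            [p for p in bait_peps if p.photo_sites()], bait_site
        )
        prey_pep = _covering_peptide(prey_peps, prey_site)
        xl = crosslink_mass(bait_pep, prey_pep)
        ppm_shift = rng.normal(0.0, recipe.sigma_ppm)
        observed = xl.mass * (1.0 + ppm_shift * 1e-6)
        intensity = recipe.base_intensity * rng.lognormal(0.0, 0.3)
        features.append(
            Ms1Feature(
                mass=observed,
                intensity=intensity,
                condition="+UV",
                feature_id=f"planted{n}",
            )
        )
        features.append(
            Ms1Feature(
                mass=observed,
                intensity=intensity / recipe.uv_enrichment,
                condition="-UV",
                feature_id=f"planted{n}_ctrl",
            )
        )
        spectra.append(
            _planted_spectrum(xl, prey_site - prey_pep.start + 1, recipe, rng, n)
        )
        truth_rows.append(
            {
                "crosslink": n,
                "alpha_seq": bait_pep.sequence,
                "beta_seq": prey_pep.sequence,
                "alpha_site": bait_site,
                "beta_site": prey_site,
                "true_mass": xl.mass,
                "emitted_mass": observed,
                "emitted_ppm": ppm_shift,
                "intensity_plus_uv": intensity,
            }
        )
    truth = pd.DataFrame(truth_rows)

    lo = truth["true_mass"].min() - 50.0
    hi = truth["true_mass"].max() + 50.0
    n_decoys = rng.poisson(recipe.decoy_density * (hi - lo))
    for i in range(n_decoys):
        m = rng.uniform(lo, hi)
        inten = recipe.base_intensity * rng.lognormal(-1.0, 0.5)
        cond = "+UV" if rng.random() < 0.5 else "-UV"
        features.append(
            Ms1Feature(mass=m, intensity=inten, condition=cond, feature_id=f"decoy{i}")
        )
    return XlMsData(
        bait_id="bait",
        prey_id="prey",
        bait_sequence=recipe.bait_sequence,
        prey_sequence=recipe.prey_sequence,
        features=features,
        spectra=spectra,
        truth=truth,
    )


def _planted_spectrum(xl, beta_link_site, recipe, rng, index) -> Ms2Spectrum:
    charge = int(rng.integers(3, 6))
    alpha_site = xl.alpha.photo_sites()[0]
    frags = fragment_ions(xl, "alpha", alpha_site) + fragment_ions(
        xl, "beta", beta_link_site
    )
    mzs, intens = [], []
    for frag in frags:
        if rng.random() > recipe.ms2_completeness:
            continue
        z = int(rng.integers(1, charge))
        m = to_mz(frag.neutral, z)
        mzs.append(m * (1.0 + rng.normal(0.0, 3.0) * 1e-6))
        intens.append(rng.lognormal(10.0, 0.5))
    n_noise = rng.poisson(recipe.ms2_noise_peaks)
    top = to_mz(xl.mass, 1)
    for _ in range(n_noise):
        mzs.append(rng.uniform(100.0, top))
        intens.append(rng.lognormal(8.0, 0.5))
    order = np.argsort(mzs)
    return Ms2Spectrum(
        precursor_mz=to_mz(xl.mass, charge) * (1.0 + rng.normal(0, recipe.sigma_ppm) * 1e-6),
        precursor_charge=charge,
        peaks_mz=np.array(mzs)[order],
        peaks_intensity=np.array(intens)[order],
        title=f"planted{index}",
    )


def shuffle_sequence(sequence: str, seed: int) -> str:
    """Fisher-Yates shuffle of a protein sequence (decoy construction)."""
    rng = np.random.default_rng(seed)
    letters = list(sequence)
    rng.shuffle(letters)
    return "".join(letters)


# Structure ensembles -------------------------------------------------------

@dataclass(frozen=True)
class EnsembleRecipe:
    """Conditions for the docked-ensemble simulation.

    The receptor (chain R) is an idealized alpha helix of
    ``receptor_length`` residues; the docked peptide (chain P,
    ``peptide_length`` residues) is laid alongside the helix at the
    ``pocket_residues`` in a fraction ``fraction_in_pocket`` of the
    ``n_models`` models and displaced far from the receptor in the rest.
    """

    seed: int = 0
    n_models: int = 20
    fraction_in_pocket: float = 0.7
    receptor_length: int = 60
    peptide_length: int = 8
    # default pocket spans residues 36-43: consistent with the default
    # planted crosslink sites of the MS simulation (receptor residues 33,
    # 41 and 47 are all within the 20 A restraint reach of the docked
    # peptide), so the two generators describe one coherent system
    pocket_start: int = 36
    jitter: float = 0.4

    @property
    def pocket_residues(self) -> tuple[int, ...]:
        return tuple(range(self.pocket_start, self.pocket_start + self.peptide_length))


@dataclass
class EnsembleData:
    ensemble: ModelEnsemble
    in_pocket: list[bool]
    restraints: list[DistanceRestraint]
    pocket_residues: tuple[int, ...]


def _helix_ca(n: int) -> np.ndarray:
    """C-alpha positions of an ideal alpha helix (rise 1.5 A, radius 2.3 A,
    100 degrees per residue)."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def simulate_ensemble(recipe: EnsembleRecipe) -> EnsembleData:
    """Build a multi-model ensemble with a planted binding pocket.

    By construction the restraint-satisfying models are exactly the
    pocket-placed ones, and the contact-probability marginal of each pocket
    residue equals the in-pocket fraction.
    """
    if not 0.0 <= recipe.fraction_in_pocket <= 1.0:
        raise ValueError("fraction_in_pocket must lie in [0, 1]")
    rng = np.random.default_rng(recipe.seed)
    n_in = int(round(recipe.fraction_in_pocket * recipe.n_models))
    in_pocket = [i < n_in for i in range(recipe.n_models)]

    receptor = _helix_ca(recipe.receptor_length)
    pocket_idx = np.array(recipe.pocket_residues) - 1
    pocket_xyz = receptor[pocket_idx]
    # outward normals: radial direction of the helix at the pocket residues
    normals = pocket_xyz.copy()
    normals[:, 2] = 0.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    st = gemmi.Structure()
    st.name = "synthetic-docked-ensemble"
    for m_idx in range(recipe.n_models):
        model = gemmi.Model(m_idx + 1)
        chain_r = gemmi.Chain("R")
        for i, pos in enumerate(receptor, start=1):
            chain_r.add_residue(_ca_residue(i, pos))
        model.add_chain(chain_r)

        if in_pocket[m_idx]:
            pep = pocket_xyz + 4.0 * normals
            pep = pep + rng.normal(0.0, recipe.jitter, pep.shape)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = receptor.mean(0) + direction * rng.uniform(60.0, 90.0)
            pep = _helix_ca(recipe.peptide_length) + offset
        chain_p = gemmi.Chain("P")
        for i, pos in enumerate(pep, start=1):
            chain_p.add_residue(_ca_residue(i, pos))
        model.add_chain(chain_p)
        st.add_model(model)

    restraints = [
        DistanceRestraint(
            residues_a=(("P", 1),),
            residues_b=(("R", recipe.pocket_residues[0]),),
            bound=20.0,
        ),
        DistanceRestraint(
            residues_a=(("P", recipe.peptide_length),),
            residues_b=(("R", recipe.pocket_residues[-1]),),
            bound=20.0,
        ),
    ]
    return EnsembleData(
        ensemble=ModelEnsemble(st),
        in_pocket=in_pocket,
        restraints=restraints,
        pocket_residues=recipe.pocket_residues,
    )


def _ca_residue(seqid: int, pos: np.ndarray) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = "ALA"
    res.seqid = gemmi.SeqId(seqid, " ")
    atom = gemmi.Atom()
    atom.name = "CA"
    atom.element = gemmi.Element("C")
    atom.pos = gemmi.Position(*pos)
    atom.occ = 1.0
    res.add_atom(atom)
    return res


# Kinetic traces ------------------------------------------------------------

@dataclass(frozen=True)
class KineticsRecipe:
    """Conditions for the kinetics simulation.

    ``kind`` selects the trace shape: "exponential" for remodeling time
    courses (fraction-cut vs time) or "nadh" for linear NADH-depletion
    absorbance traces.  ``noise_sigma`` is the Gaussian s.d. expressed as a
    fraction of the trace amplitude.
    """

    seed: int = 0
    kind: str = "exponential"
    k_obs: float = 0.05            # s^-1 (exponential traces)
    y0: float = 1.0
    y_inf: float = 0.0
    turnover: float = 2.5          # s^-1 per enzyme (nadh traces)
    enzyme_conc: float = 1e-6      # M
    a340_start: float = 0.8        # AU
    noise_sigma: float = 0.05
    n_points: int = 60
    t_max: float | None = None
    replicates: int = 1


@dataclass
class KineticsData:
    traces: list[KineticTrace]
    truth: dict


def simulate_kinetics(recipe: KineticsRecipe) -> KineticsData:
    """Generate noisy kinetic traces plus the generating parameters."""
    rng = np.random.default_rng(recipe.seed)
    traces = []
    if recipe.kind == "exponential":
        if recipe.k_obs <= 0:
            raise ValueError("k_obs must be positive")
        t_max = recipe.t_max or 5.0 / recipe.k_obs
        t = np.linspace(0.0, t_max, recipe.n_points)
        clean = recipe.y_inf + (recipe.y0 - recipe.y_inf) * np.exp(-recipe.k_obs * t)
        amplitude = abs(recipe.y0 - recipe.y_inf)
        truth = {"k_obs": recipe.k_obs, "y0": recipe.y0, "y_inf": recipe.y_inf}
    elif recipe.kind == "nadh":
        if recipe.turnover < 0 or recipe.enzyme_conc <= 0:
            raise ValueError("turnover must be >= 0 and [E] > 0")
        slope = -recipe.turnover * NADH_EXTINCTION * recipe.enzyme_conc
        t_max = recipe.t_max or min(
            0.8 * recipe.a340_start / max(-slope, 1e-12), 600.0
        )
        t = np.linspace(0.0, t_max, recipe.n_points)
        clean = recipe.a340_start + slope * t
        amplitude = abs(slope * t_max) or recipe.a340_start
        truth = {
            "turnover": recipe.turnover,
            "slope": slope,
            "enzyme_conc": recipe.enzyme_conc,
        }
    else:
        raise ValueError(f"unknown trace kind {recipe.kind!r}")
    for r in range(recipe.replicates):
        noisy = clean + rng.normal(0.0, recipe.noise_sigma * amplitude, len(t))
        traces.append(
            KineticTrace(t, noisy, condition={"replicate": r, **truth})
        )
    return KineticsData(traces=traces, truth=truth)


# File writers --------------------------------------------------------------

def write_xl_ms(data: XlMsData, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + MS1 TSV + MGF + truth TSV; returns the paths."""
    from . import io as xio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "ms1": outdir / "ms1_features.tsv",
        "mgf": outdir / "spectra.mgf",
        "truth": outdir / "truth.tsv",
    }
    xio.write_fasta(
        {data.bait_id: data.bait_sequence, data.prey_id: data.prey_sequence},
        paths["fasta"],
    )
    xio.write_ms1_tsv(data.features, paths["ms1"])
    xio.write_mgf(data.spectra, paths["mgf"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_kinetics_csv(data: KineticsData, path: str | Path) -> Path:
    """Write traces as CSV columns time,signal[,replicate]."""
    path = Path(path)
    frames = []
    for trace in data.traces:
        df = pd.DataFrame({"time": trace.time, "signal": trace.signal})
        if len(data.traces) > 1:
            df["replicate"] = trace.condition.get("replicate", 0)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)
    return path
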