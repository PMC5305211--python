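"""Orchestration of the crosslink-mapping pipeline.

``run_mapping`` ties the stages together: crosslink search on MS data ->
site-localized, tiered matches -> distance restraints -> ensemble filtering
-> contact-probability surface -> summary report.  Every stage parameter
(the published settings are the defaults: +/-10 ppm MS1, +/-15 ppm MS2,
fragment charges up to precursor-1, 20 A restraint bound, 5 A contact
cutoff) lives in :class:`RunConfig`, which is serialized into the output
directory so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as xio
from .restraints import (
    ModelEnsemble,
    contact_surface,
    filter_ensemble,
    restraints_from_crosslinks,
    write_surface_pdb,
)
from .search import DigestSpec, TierRubric, search_crosslinks

logger = logging.getLogger("xlmap")

__all__ = ["RunConfig", "run_mapping", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class RunConfig:
    """Complete parameterization of a mapping run."""

    fasta: str = ""
    ms1: str = ""
    mgf: str = ""
    ensemble: str = ""                  # multi-model PDB or directory; optional
    bait_id: str = "bait"
    prey_id: str = "prey"
    output_dir: str = "xlmap_run"
    seed: int = 0

    ms1_window_ppm: float = 10.0
    ms2_window_ppm: float = 15.0
    max_missed_cleavages: int = 2
    min_peptide_length: int = 2
    max_peptide_length: int = 30
    max_oxidations: int = 1
    uv_threshold: float = 5.0
    tier_min_fragments: int = 3
    tier_high_ppm: float = 5.0

    restraint_bound_angstrom: float = 20.0
    restraint_atom: str = "CA"
    contact_cutoff_angstrom: float = 5.0
    peptide_chain: str = "P"
    receptor_chain: str = "R"
    chain_of_protein: dict = field(default_factory=dict)
    top_k_surface: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_mapping(config: RunConfig) -> dict:
    """Run the full mapping analysis; returns the summary report dict.

    Writes into ``config.output_dir``: the resolved config, the crosslink
    table, the restraint list, the filtered ensemble and contact surface
    (when an ensemble is supplied), and ``report.json``.
    """
    for name in ("fasta", "ms1", "mgf"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise PipelineError(f"inputs: missing {name} file {path!r}")
    if config.ensemble and not Path(config.ensemble).exists():
        raise PipelineError(f"inputs: ensemble path {config.ensemble!r} does not exist")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    logger.info("stage search: digesting and matching")
    try:
        proteins = xio.read_fasta(config.fasta)
        features = xio.read_ms1_tsv(config.ms1)
        spectra = xio.read_mgf(config.mgf)
        matches = search_crosslinks(
            proteins[config.bait_id],
            proteins[config.prey_id],
            features,
            spectra,
            bait_id=config.bait_id,
            prey_id=config.prey_id,
            digest_spec=DigestSpec(
                config.max_missed_cleavages,
                config.min_peptide_length,
                config.max_peptide_length,
            ),
            ms1_window_ppm=config.ms1_window_ppm,
            ms2_window_ppm=config.ms2_window_ppm,
            max_ox=config.max_oxidations,
            rubric=TierRubric(config.tier_min_fragments, config.tier_high_ppm),
            uv_threshold=config.uv_threshold,
        )
    except KeyError as exc:
        raise PipelineError(f"search: protein id {exc} not in FASTA") from exc
    except Exception as exc:
        raise PipelineError(f"search: {exc}") from exc
    xio.write_match_table(matches, outdir / "crosslinks.tsv")

    logger.info("stage restraints: %d matches", len(matches))
    try:
        chain_map = dict(config.chain_of_protein) or {
            config.bait_id: config.peptide_chain,
            config.prey_id: config.receptor_chain,
        }
        localized = [m for m in matches if m.alpha_sites and m.beta_sites]
        restraints = restraints_from_crosslinks(
            localized,
            bound=config.restraint_bound_angstrom,
            chain_of_protein=chain_map,
            atom=config.restraint_atom,
        )
    except Exception as exc:
        raise PipelineError(f"restraints: {exc}") from exc
    with open(outdir / "restraints.json", "w") as fh:
        json.dump(
            [
                {
                    "residues_a": list(map(list, r.residues_a)),
                    "residues_b": list(map(list, r.residues_b)),
                    "bound": r.bound,
                    "atom": r.atom,
                }
                for r in restraints
            ],
            fh,
            indent=1,
        )

    report = {
        "n_matches": len(matches),
        "tiers": {
            t: sum(1 for m in matches if m.tier == t) for t in ("high", "medium", "low")
        },
        "n_unique_linkages": len(restraints),
    }

    if config.ensemble:
        logger.info("stage ensemble: filtering against %d restraints", len(restraints))
        try:
            ensemble = ModelEnsemble.from_path(config.ensemble)
            retained = filter_ensemble(ensemble, restraints)
            surface = contact_surface(
                retained,
                config.peptide_chain,
                config.receptor_chain,
                config.contact_cutoff_angstrom,
            )
        except Exception as exc:
            raise PipelineError(f"ensemble: {exc}") from exc
        write_surface_pdb(retained, surface, outdir / "contact_surface.pdb")
        top = sorted(surface.marginal.items(), key=lambda kv: (-kv[1], kv[0]))
        report.update(
            n_models_input=len(ensemble),
            n_models_retained=len(retained),
            top_contact_residues=[
                {"residue": int(r), "probability": round(p, 4)}
                for r, p in top[: config.top_k_surface]
            ],
        )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("run complete: %s", report)
    return report
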