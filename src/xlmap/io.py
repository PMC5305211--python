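"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython, MGF through pyteomics; MS1 feature lists and
crosslink tables are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf

from .search import CrosslinkMatch, Ms1Feature, Ms2Spectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ms1_tsv",
    "write_ms1_tsv",
    "read_mgf",
    "write_mgf",
    "matches_to_table",
    "write_match_table",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> sequence (uppercased; inline B/X letters preserved)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_ms1_tsv(path: str | Path) -> list[Ms1Feature]:
    """Read a feature list: columns mass|mz [+ charge], intensity, condition."""
    df = pd.read_csv(path, sep="\t")
    features = []
    for _, row in df.iterrows():
        features.append(
            Ms1Feature(
                mass=float(row["mass"]) if "mass" in df and pd.notna(row.get("mass")) else None,
                mz=float(row["mz"]) if "mz" in df and pd.notna(row.get("mz")) else None,
                charge=int(row["charge"]) if "charge" in df and pd.notna(row.get("charge")) else None,
                intensity=float(row.get("intensity", 0.0)),
                condition=str(row.get("condition", "+UV")),
                feature_id=str(row["feature_id"]) if "feature_id" in df else None,
            )
        )
    return features


def write_ms1_tsv(features: list[Ms1Feature], path: str | Path) -> None:
    pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mass": [f.mass for f in features],
            "mz": [f.mz for f in features],
            "charge": [f.charge for f in features],
            "intensity": [f.intensity for f in features],
            "condition": [f.condition for f in features],
        }
    ).to_csv(path, sep="\t", index=False)


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0])
            order = np.argsort(entry["m/z array"])
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks_mz=entry["m/z array"][order],
                    peaks_intensity=entry["intensity array"][order],
                    title=params.get("title", ""),
                )
            )
    return spectra


def write_mgf(spectra: list[Ms2Spectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.peaks_mz,
            "intensity array": s.peaks_intensity,
            "params": {
                "title": s.title,
                "pepmass": (s.precursor_mz,),
                "charge": [s.precursor_charge],
            },
        }
        for s in spectra
    ]
    mgf.write(entries, str(path), file_mode="w")


def _fmt_site(interval: tuple[int, int] | None) -> str:
    if interval is None:
        return ""
    lo, hi = interval
    return str(lo) if lo == hi else f"{lo}-{hi}"


def matches_to_table(matches: list[CrosslinkMatch]) -> pd.DataFrame:
    """Crosslink matches as a table mirroring the published overview columns."""
    rows = []
    for i, m in enumerate(matches, start=1):
        rows.append(
            {
                "id": f"XL{i}",
                "mass_da": round(m.xl.mass, 4),
                "ms1_error_ppm": round(m.ms1_ppm, 2),
                "alpha_seq": m.xl.alpha.sequence,
                "alpha_site": _fmt_site(m.alpha_sites),
                "beta_seq": m.xl.beta.sequence,
                "beta_site": _fmt_site(m.beta_sites),
                "alpha_fragments": m.report.alpha_matched if m.report else 0,
                "beta_fragments": m.report.beta_matched if m.report else 0,
                "uv_ratio": round(m.uv_ratio, 2) if m.uv_ratio is not None else np.nan,
                "reliability": m.tier,
            }
        )
    return pd.DataFrame(rows)


def write_match_table(matches: list[CrosslinkMatch], path: str | Path) -> None:
    matches_to_table(matches).to_csv(path, sep="\t", index=False)
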