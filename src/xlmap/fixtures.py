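"""Bundled machine-readable crosslink table.

The package ships the published overview of benzophenone photo-crosslinks
between the ISWI remodeler, its N-terminal region, and the histone H4 tail
as a TSV: identifier, reliability tier, the two peptide sequences (inline
``B`` = Bpa, ``X`` = benzophenone-labeled Cys, ``M[ox]`` = oxidized Met),
the crosslink sites in parent-protein coordinates, the observed neutral
monoisotopic mass, and the reported ppm error.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_crosslink_table"]


def load_crosslink_table() -> pd.DataFrame:
    """Return the bundled crosslink overview table as a DataFrame.

    Columns include ``alpha_seq``/``beta_seq`` (peptide notation),
    ``alpha_site``/``beta_site`` (site or ``lo-hi`` range, parent protein
    coordinates), ``observed_mass_da`` and ``error_ppm``.
    """
    with resources.files("xlmap").joinpath("data/crosslink_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"alpha_site": str, "beta_site": str})
    df["reliability"] = df["reliability"].fillna("")
    return df


def parse_site_range(site: str) -> tuple[int, int]:
    """Parse a site annotation like ``"483"`` or ``"69-72"`` into (lo, hi)."""
    parts = str(site).split("-")
    lo = int(parts[0])
    hi = int(parts[-1]) if len(parts) > 1 else lo
    return lo, hi
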