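"""Identification of photo-crosslinked peptide pairs from MS data.

The search follows the workflow used for benzophenone photo-crosslinks: the
proteins are digested in silico with trypsin, candidate crosslinked species
are enumerated as (bait peptide carrying the photo-reactive residue) x
(prey peptide) pairs expanded over variable Met oxidation, MS1 features are
matched to candidate neutral masses inside a ppm window (default +/-10 ppm),
MS2 spectra are scored by b/y fragment matching (default +/-15 ppm), the
attachment site on the prey chain is localized to the smallest residue
interval consistent with the matched site-discriminating fragments, UV
dependence is quantified from +UV/-UV precursor intensities, and each match
is assigned a high/medium/low reliability tier by a configurable rubric.

Because the photo-insertion adds no mass, every residue of the prey peptide
is a potential attachment site; localization relies entirely on the mass
shift (the full mass of the partner peptide) carried by fragments that span
the crosslinked residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemistry import (
    DEFAULT_CHEMISTRY,
    ChemistryError,
    CrosslinkSpecies,
    Peptide,
    ResidueTable,
    WATER_MASS,
    crosslink_mass,
    iter_oxidation_variants,
    mz as to_mz,
    neutral_mass,
    peptide_mass,
    ppm_error,
)

__all__ = [
    "DigestSpec",
    "Ms1Feature",
    "Ms2Spectrum",
    "Fragment",
    "FragmentReport",
    "CrosslinkMatch",
    "TierRubric",
    "digest",
    "enumerate_candidates",
    "match_ms1",
    "fragment_ions",
    "score_ms2",
    "localize_sites",
    "uv_dependence",
    "tier_matches",
    "search_crosslinks",
]


# Digestion -----------------------------------------------------------------

@dataclass(frozen=True)
class DigestSpec:
    """Tryptic digestion parameters.

    Cleavage C-terminal of K/R, suppressed when the next residue is P;
    peptides with up to ``max_missed_cleavages`` internal uncut sites and
    length within ``(min_length, max_length)`` are emitted.
    """

    max_missed_cleavages: int = 2
    min_length: int = 2
    max_length: int = 30


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    sequence: str,
    spec: DigestSpec = DigestSpec(),
    parent: str | None = None,
    table: ResidueTable = None,
) -> list[Peptide]:
    """In-silico tryptic digest; deterministic order (by start, then length)."""
    table = table or DEFAULT_CHEMISTRY
    for i, c in enumerate(sequence):
        if c not in table.residues:
            raise ChemistryError(f"illegal residue {c!r} at position {i + 1}")
    if not sequence:
        return []
    sites = cleavage_sites(sequence)
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(sequence)]  # exclusive
    peptides = []
    for si, start in enumerate(starts):
        for sj in range(si, min(si + spec.max_missed_cleavages + 1, len(ends))):
            end = ends[sj]
            if not spec.min_length <= end - start <= spec.max_length:
                continue
            peptides.append(
                Peptide(sequence[start:end], parent=parent, start=start + 1)
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


# Candidate enumeration -----------------------------------------------------

def enumerate_candidates(
    bait_peptides: list[Peptide],
    prey_peptides: list[Peptide],
    max_ox: int = 1,
    table: ResidueTable = None,
) -> list[CrosslinkSpecies]:
    """All bait x prey crosslink candidates, expanded over Met oxidation.

    Bait peptides without exactly one photo-reactive residue are skipped.
    Duplicates (same mass to 1e-6 Da, same sequences) are collapsed.
    """
    table = table or DEFAULT_CHEMISTRY
    if not bait_peptides:
        raise ValueError("bait peptide set is empty")
    seen: set = set()
    out: list[CrosslinkSpecies] = []
    for bait in bait_peptides:
        if len(bait.photo_sites(table)) != 1:
            continue
        for bait_var in iter_oxidation_variants(bait, max_ox, table):
            for prey in prey_peptides:
                for prey_var in iter_oxidation_variants(prey, max_ox, table):
                    xl = crosslink_mass(bait_var, prey_var, table)
                    key = (
                        bait_var.sequence,
                        prey_var.sequence,
                        round(xl.mass, 6),
                    )
                    if key not in seen:
                        seen.add(key)
                        out.append(xl)
    return out


# MS1 matching --------------------------------------------------------------

@dataclass(frozen=True)
class Ms1Feature:
    """A deisotoped MS1 feature: neutral mass or (m/z, charge), an intensity,
    and the irradiation condition it was observed in."""

    mass: float | None = None
    mz: float | None = None
    charge: int | None = None
    intensity: float = 0.0
    condition: str = "+UV"
    feature_id: str | None = None

    def __post_init__(self):
        if self.mass is None and (self.mz is None or self.charge is None):
            raise ValueError("feature needs a neutral mass or (m/z, charge)")
        if self.charge is not None and not 1 <= self.charge <= 8:
            raise ValueError(f"charge {self.charge} outside 1..8")
        if self.intensity < 0:
            raise ValueError("negative intensity")

    @property
    def neutral(self) -> float:
        if self.mass is not None:
            return self.mass
        return neutral_mass(self.mz, self.charge)


def match_ms1(
    features: list[Ms1Feature],
    candidates: list[CrosslinkSpecies],
    window_ppm: float = 10.0,
) -> list[tuple[Ms1Feature, CrosslinkSpecies, float]]:
    """All (feature, candidate) pairs with |ppm error| <= window.

    Sorted candidate masses + binary search keep this near O((F+C) log C);
    the result is identical to the brute-force all-pairs comparison.
    """
    if window_ppm <= 0:
        raise ValueError("window must be positive")
    if not candidates:
        return []
    masses = np.array([c.mass for c in candidates])
    order = np.argsort(masses)
    sorted_masses = masses[order]
    out = []
    for f in features:
        m = f.neutral
        delta = m * window_ppm * 1e-6
        lo = np.searchsorted(sorted_masses, m - delta, side="left")
        hi = np.searchsorted(sorted_masses, m + delta, side="right")
        for idx in order[lo:hi]:
            c = candidates[idx]
            ppm = ppm_error(m, c.mass)
            if abs(ppm) <= window_ppm:
                out.append((f, c, ppm))
    return out


# Fragment ions and MS2 scoring --------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A theoretical backbone fragment (neutral mass, singly described)."""

    chain: str          # "alpha" | "beta"
    kind: str           # "b" | "y"
    index: int          # ladder index, 1..n-1
    neutral: float
    crosslinked: bool   # carries the partner peptide as an added rigid mass


def _residue_masses(p: Peptide, table: ResidueTable) -> np.ndarray:
    masses = np.array([table.residue_masses[c] for c in p.sequence])
    for pos, name in p.modifications.items():
        masses[pos - 1] += table.modification_delta(name)
    return masses


def fragment_ions(
    xl: CrosslinkSpecies,
    chain: str,
    link_site: int,
    table: ResidueTable = None,
) -> list[Fragment]:
    """Theoretical b/y fragments of one chain with the link at ``link_site``.

    For a chain of length n there are 2(n-1) fragments.  A fragment whose
    span includes the crosslinked residue carries the full neutral mass of
    the partner peptide as an added rigid mass.
    """
    table = table or DEFAULT_CHEMISTRY
    if chain == "alpha":
        pep, partner = xl.alpha, xl.beta
    elif chain == "beta":
        pep, partner = xl.beta, xl.alpha
    else:
        raise ValueError(f"chain must be 'alpha' or 'beta', got {chain!r}")
    if not 1 <= link_site <= len(pep.sequence):
        raise ValueError(f"link site {link_site} outside chain of length {len(pep.sequence)}")
    res = _residue_masses(pep, table)
    partner_mass = peptide_mass(partner, table)
    n = len(res)
    prefix = np.cumsum(res)
    frags = []
    for i in range(1, n):
        b_has_link = link_site <= i
        y_has_link = link_site > i
        frags.append(
            Fragment(
                chain, "b", i,
                float(prefix[i - 1]) + (partner_mass if b_has_link else 0.0),
                b_has_link,
            )
        )
        frags.append(
            Fragment(
                chain, "y", n - i,
                float(prefix[n - 1] - prefix[i - 1]) + WATER_MASS
                + (partner_mass if y_has_link else 0.0),
                y_has_link,
            )
        )
    return frags


@dataclass(frozen=True)
class Ms2Spectrum:
    """A centroided fragment spectrum with its precursor."""

    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    title: str = ""

    def __post_init__(self):
        object.__setattr__(self, "peaks_mz", np.asarray(self.peaks_mz, float))
        object.__setattr__(
            self, "peaks_intensity", np.asarray(self.peaks_intensity, float)
        )
        if len(self.peaks_mz) != len(self.peaks_intensity):
            raise ValueError("peak arrays differ in length")
        if np.any(np.diff(self.peaks_mz) < 0):
            raise ValueError("peaks must be sorted by m/z")

    @property
    def precursor_neutral(self) -> float:
        return neutral_mass(self.precursor_mz, self.precursor_charge)


@dataclass
class FragmentReport:
    """Outcome of scoring one spectrum against one crosslink candidate."""

    xl: CrosslinkSpecies
    alpha_link_site: int
    beta_site_scores: dict[int, int]          # hypothesis site -> matched count
    best_beta_sites: tuple[int, ...]          # argmax set (ties)
    alpha_matched: int
    alpha_total: int
    beta_matched: int
    beta_total: int
    intensity_explained: float                # fraction of total ion current
    window_ppm: float

    @property
    def total_matched(self) -> int:
        return self.alpha_matched + self.beta_matched


def _match_count(
    frags: list[Fragment],
    spectrum: Ms2Spectrum,
    charges: range,
    window_ppm: float,
) -> tuple[int, np.ndarray]:
    """Matched-fragment count and boolean mask of explained peaks."""
    explained = np.zeros(len(spectrum.peaks_mz), bool)
    matched = 0
    peaks = spectrum.peaks_mz
    for frag in frags:
        hit = False
        for z in charges:
            target = to_mz(frag.neutral, z)
            tol = target * window_ppm * 1e-6
            lo = np.searchsorted(peaks, target - tol, side="left")
            hi = np.searchsorted(peaks, target + tol, side="right")
            if hi > lo:
                hit = True
                explained[lo:hi] = True
        if hit:
            matched += 1
    return matched, explained


def score_ms2(
    spectrum: Ms2Spectrum,
    xl: CrosslinkSpecies,
    window_ppm: float = 15.0,
    table: ResidueTable = None,
) -> FragmentReport:
    """Score a spectrum against a crosslink candidate.

    The attachment site on the bait chain is fixed by chemistry (the B/X
    residue).  The prey-chain site is unknown, so every residue is tried as
    a hypothesis; the report records the matched-fragment count per
    hypothesis and the argmax set, which downstream localization turns into
    a site interval.  Fragment charges 1..(precursor charge - 1) are
    considered.
    """
    table = table or DEFAULT_CHEMISTRY
    if len(spectrum.peaks_mz) == 0:
        raise ValueError("empty spectrum")
    charges = range(1, max(spectrum.precursor_charge, 2))
    alpha_site = xl.alpha.photo_sites(table)[0]

    alpha_frags = fragment_ions(xl, "alpha", alpha_site, table)
    alpha_matched, alpha_explained = _match_count(
        alpha_frags, spectrum, charges, window_ppm
    )

    beta_len = len(xl.beta.sequence)
    site_scores: dict[int, int] = {}
    best_explained = np.zeros(len(spectrum.peaks_mz), bool)
    best = -1
    for site in range(1, beta_len + 1):
        frags = fragment_ions(xl, "beta", site, table)
        count, explained = _match_count(frags, spectrum, charges, window_ppm)
        site_scores[site] = count
        if count > best:
            best = count
            best_explained = explained
    best_sites = tuple(s for s, c in site_scores.items() if c == best)

    total_intensity = float(spectrum.peaks_intensity.sum())
    explained_mask = alpha_explained | best_explained
    frac = (
        float(spectrum.peaks_intensity[explained_mask].sum()) / total_intensity
        if total_intensity > 0
        else 0.0
    )
    return FragmentReport(
        xl=xl,
        alpha_link_site=alpha_site,
        beta_site_scores=site_scores,
        best_beta_sites=best_sites,
        alpha_matched=alpha_matched,
        alpha_total=len(alpha_frags),
        beta_matched=best,
        beta_total=2 * (beta_len - 1) if beta_len > 1 else 0,
        intensity_explained=frac,
        window_ppm=window_ppm,
    )


def localize_sites(report: FragmentReport) -> tuple[tuple[int, int], tuple[int, int]]:
    """Smallest contiguous site interval on each chain, peptide coordinates.

    The bait chain is pinned to its photo-reactive residue.  On the prey
    chain the interval spans the hypothesis sites that tie for the maximal
    matched-fragment count; with no discriminating ions that is the whole
    peptide, with a complete ladder a single residue.
    """
    alpha = (report.alpha_link_site, report.alpha_link_site)
    sites = report.best_beta_sites
    if not sites or report.beta_matched <= 0:
        beta = (1, len(report.xl.beta.sequence))
    else:
        beta = (min(sites), max(sites))
    return alpha, beta


# UV dependence -------------------------------------------------------------

def uv_dependence(
    plus_uv: list[Ms1Feature],
    minus_uv: list[Ms1Feature],
    species: CrosslinkSpecies,
    window_ppm: float = 10.0,
    floor_fraction: float = 0.01,
    threshold: float = 5.0,
) -> tuple[float, bool]:
    """Enrichment ratio of a species in irradiated vs. control runs.

    Sums feature intensities matching the species mass in each condition and
    returns ``(ratio, flagged)`` where ratio = I(+UV) / max(I(-UV), floor)
    and floor = ``floor_fraction`` of the +UV signal (guards the
    divide-by-zero of a species wholly absent without UV).
    """

    def signal(features: list[Ms1Feature]) -> float:
        return sum(
            f.intensity
            for f in features
            if abs(ppm_error(f.neutral, species.mass)) <= window_ppm
        )

    plus = signal(plus_uv)
    minus = signal(minus_uv)
    if plus == 0 and minus == 0:
        raise ValueError(f"species {species} absent from both conditions")
    floor = max(floor_fraction * plus, np.finfo(float).tiny)
    ratio = plus / max(minus, floor)
    return ratio, ratio >= threshold


# Reliability tiers ---------------------------------------------------------

@dataclass(frozen=True)
class TierRubric:
    """Codified reliability rubric.

    high   : >= ``min_fragments`` matched fragments on *both* chains, the
             species is UV-dependent, and |MS1 error| <= ``high_ppm``;
    medium : >= ``min_fragments`` matched fragments on at least one chain;
    low    : everything else.
    """

    min_fragments: int = 3
    high_ppm: float = 5.0


@dataclass
class CrosslinkMatch:
    """A scored, localized, tiered crosslink identification."""

    xl: CrosslinkSpecies
    ms1_ppm: float
    report: FragmentReport | None = None
    alpha_sites: tuple[int, int] | None = None   # parent coordinates
    beta_sites: tuple[int, int] | None = None
    uv_ratio: float | None = None
    uv_dependent: bool = False
    tier: str = "low"
    feature: Ms1Feature | None = None


def tier_matches(
    matches: list[CrosslinkMatch], rubric: TierRubric = TierRubric()
) -> list[CrosslinkMatch]:
    """Assign high/medium/low reliability to each match (returns new list)."""
    out = []
    for m in matches:
        alpha_n = m.report.alpha_matched if m.report else 0
        beta_n = m.report.beta_matched if m.report else 0
        if (
            alpha_n >= rubric.min_fragments
            and beta_n >= rubric.min_fragments
            and m.uv_dependent
            and abs(m.ms1_ppm) <= rubric.high_ppm
        ):
            tier = "high"
        elif alpha_n >= rubric.min_fragments or beta_n >= rubric.min_fragments:
            tier = "medium"
        else:
            tier = "low"
        out.append(replace(m, tier=tier))
    return out


# End-to-end search ---------------------------------------------------------

def _to_parent_interval(pep: Peptide, interval: tuple[int, int]) -> tuple[int, int]:
    if pep.start is None:
        return interval
    return (pep.to_parent_coord(interval[0]), pep.to_parent_coord(interval[1]))


def search_crosslinks(
    bait_sequence: str,
    prey_sequence: str,
    features: list[Ms1Feature],
    spectra: list[Ms2Spectrum],
    bait_id: str = "bait",
    prey_id: str = "prey",
    digest_spec: DigestSpec = DigestSpec(),
    ms1_window_ppm: float = 10.0,
    ms2_window_ppm: float = 15.0,
    max_ox: int = 1,
    rubric: TierRubric = TierRubric(),
    uv_threshold: float = 5.0,
    require_ms2: bool = True,
    table: ResidueTable = None,
) -> list[CrosslinkMatch]:
    """Full crosslink search on one bait/prey protein pair.

    Digests both proteins, enumerates candidates, matches +UV MS1 features,
    scores MS2 spectra (a spectrum is paired with a candidate when its
    precursor neutral mass falls inside the MS1 window), localizes sites,
    quantifies UV dependence and tiers the matches.  Matches are
    deduplicated per (candidate species), keeping the best-scoring spectrum.
    With ``require_ms2`` (the default) a candidate supported only by an MS1
    mass coincidence — no matched fragments — is not reported.
    """
    table = table or DEFAULT_CHEMISTRY
    bait_peps = [
        p for p in digest(bait_sequence, digest_spec, parent=bait_id, table=table)
        if len(p.photo_sites(table)) == 1
    ]
    prey_peps = digest(prey_sequence, digest_spec, parent=prey_id, table=table)
    candidates = enumerate_candidates(bait_peps, prey_peps, max_ox, table)

    plus = [f for f in features if f.condition == "+UV"]
    minus = [f for f in features if f.condition == "-UV"]
    ms1_hits = match_ms1(plus, candidates, ms1_window_ppm)

    best: dict[int, CrosslinkMatch] = {}
    for feature, candidate, ppm in ms1_hits:
        report = None
        for spectrum in spectra:
            if abs(ppm_error(spectrum.precursor_neutral, candidate.mass)) > ms1_window_ppm:
                continue
            r = score_ms2(spectrum, candidate, ms2_window_ppm, table)
            if report is None or r.total_matched > report.total_matched:
                report = r
        try:
            ratio, flagged = uv_dependence(
                plus, minus, candidate, ms1_window_ppm, threshold=uv_threshold
            )
        except ValueError:
            ratio, flagged = None, False
        if report is not None:
            a_int, b_int = localize_sites(report)
            alpha_sites = _to_parent_interval(candidate.alpha, a_int)
            beta_sites = _to_parent_interval(candidate.beta, b_int)
        else:
            alpha_sites = beta_sites = None
        match = CrosslinkMatch(
            xl=candidate,
            ms1_ppm=ppm,
            report=report,
            alpha_sites=alpha_sites,
            beta_sites=beta_sites,
            uv_ratio=ratio,
            uv_dependent=flagged,
            feature=feature,
        )
        key = id(candidate)
        prev = best.get(key)
        if (
            prev is None
            or (match.report.total_matched if match.report else -1)
            > (prev.report.total_matched if prev.report else -1)
        ):
            best[key] = match
    kept = [
        m
        for m in best.values()
        if not require_ms2 or (m.report is not None and m.report.total_matched > 0)
    ]
    return tier_matches(kept, rubric)
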