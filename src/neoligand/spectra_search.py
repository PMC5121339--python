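"""Simplified spectrum-to-peptide matching for HLA ligandomics.

Candidate peptides are retrieved from a mass-sorted index within a +/-6 ppm
precursor window (inclusive), fragmented in silico into b/y ions, and scored
with a binomial-tail survival score: the probability of matching at least k
of n theoretical fragments by chance at the per-peak match probability
implied by the 20 ppm fragment tolerance and the scanned m/z range, expressed
as -10*log10(p) so that higher is better.  The score is a deterministic,
closed-form stand-in for a full probabilistic search engine.

Variable modifications carry the exact monoisotopic deltas used throughout:
N-terminal acetylation (+42.010565 Da), methionine oxidation (+15.994915 Da)
and phosphorylation (+79.9663304 Da on S/T/Y).  At most one phosphorylation
and one oxidation plus an optional N-terminal acetylation are considered per
peptide.  Site localization probabilities come from rescoring all single-site
phospho isomers and normalizing 10**(score/10) over them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pymass
from pyteomics import mgf as _pymgf
from scipy import stats as _stats

from .peptide_space import PeptideForm, is_variant_sequence

__all__ = [
    "ModificationSpec",
    "MODIFICATIONS",
    "ObservedSpectrum",
    "SearchTolerances",
    "SpectrumMatch",
    "PeptideIndex",
    "peptide_mass",
    "generate_by_ions",
    "enumerate_placements",
    "candidate_lookup",
    "match_probability",
    "binomial_tail_score",
    "score_match",
    "delta_score",
    "localize_sites",
    "search_spectra",
    "read_mgf",
    "write_mgf",
]

PROTON = 1.007276  # Da
WATER = _pymass.calculate_mass(formula="H2O")
_AA_MASS = dict(_pymass.std_aa_mass)


@dataclass(frozen=True)
class ModificationSpec:
    name: str
    delta_mass: float  # monoisotopic, Da
    residues: frozenset[str]  # empty set = N-terminus


MODIFICATIONS: dict[str, ModificationSpec] = {
    "ac": ModificationSpec("ac", 42.010565, frozenset()),
    "ox": ModificationSpec("ox", 15.994915, frozenset("M")),
    "ph": ModificationSpec("ph", 79.9663304, frozenset("STY")),
}

# a placement is a tuple of (mod name, 0-based residue index; -1 = N-terminus)
Placement = tuple[str, int]
Placements = tuple[Placement, ...]


@dataclass(frozen=True)
class SearchTolerances:
    precursor_ppm: float = 6.0
    fragment_ppm: float = 20.0

    def __post_init__(self) -> None:
        if self.precursor_ppm <= 0 or self.fragment_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ObservedSpectrum:
    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.charge not in (1, 2, 3):
            raise ValueError(f"charge must be 1-3, got {self.charge}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=float)[order]
        self.intensity = np.asarray(self.intensity, dtype=float)[order]

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON


@dataclass
class SpectrumMatch:
    spectrum_id: str
    sequence: str
    placements: Placements
    score: float
    delta_score: float
    precursor_error_ppm: float
    is_variant: bool
    is_decoy: bool
    n_matched: int
    n_theoretical: int
    site_localizations: dict[int, float] = field(default_factory=dict)  # 1-based
    precursor_intensity: float = float("nan")
    peptide_class: str | None = None
    pep: float = float("nan")

    @property
    def is_phospho(self) -> bool:
        return any(name == "ph" for name, _ in self.placements)

    @property
    def modified_sequence(self) -> str:
        if not self.placements:
            return self.sequence
        tags = ",".join(f"{n}@{p}" for n, p in sorted(self.placements, key=lambda x: x[1]))
        return f"{self.sequence}[{tags}]"

    @property
    def max_localization(self) -> float:
        return max(self.site_localizations.values()) if self.site_localizations else float("nan")


def _placement_deltas(sequence: str, placements: Placements) -> tuple[np.ndarray, float]:
    """Per-residue modification deltas and the N-terminal delta."""
    per_res = np.zeros(len(sequence))
    nterm = 0.0
    for name, pos in placements:
        spec = MODIFICATIONS[name]
        if not spec.residues:
            if pos != -1:
                raise ValueError(f"{name} is N-terminal; position must be -1")
            nterm += spec.delta_mass
        else:
            if not 0 <= pos < len(sequence):
                raise ValueError(f"{name} position {pos} outside peptide")
            if sequence[pos] not in spec.residues:
                raise ValueError(
                    f"{name} not allowed on residue {sequence[pos]!r} at {pos}"
                )
            per_res[pos] += spec.delta_mass
    return per_res, nterm


def peptide_mass(sequence: str, placements: Placements = ()) -> float:
    """Neutral monoisotopic mass of a (modified) peptide."""
    per_res, nterm = _placement_deltas(sequence, placements)
    return _pymass.fast_mass(sequence) + float(per_res.sum()) + nterm


def generate_by_ions(
    sequence: str, placements: Placements = (), charge: int = 1
) -> np.ndarray:
    """m/z of b1..b(n-1) and y1..y(n-1) at fragment charges 1..min(charge, 2).

    A modification's mass is carried only by fragments containing its site;
    N-terminal acetylation rides on the b series.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    per_res, nterm = _placement_deltas(sequence, placements)
    res = np.array([_AA_MASS[a] for a in sequence]) + per_res
    b_neutral = np.cumsum(res)[:-1] + nterm
    y_neutral = np.cumsum(res[::-1])[:-1] + WATER
    mz = []
    for z in range(1, min(charge, 2) + 1):
        mz.append((b_neutral + z * PROTON) / z)
        mz.append((y_neutral + z * PROTON) / z)
    return np.sort(np.concatenate(mz))


def enumerate_placements(
    sequence: str, enabled: Sequence[str] = ("ac", "ox", "ph")
) -> list[Placements]:
    """All legal variable-modification placements for a peptide, bounded to
    <=1 phospho, <=1 oxidation and an optional N-terminal acetylation."""
    ph_opts: list[Placement | None] = [None]
    if "ph" in enabled:
        ph_opts += [("ph", i) for i, a in enumerate(sequence) if a in "STY"]
    ox_opts: list[Placement | None] = [None]
    if "ox" in enabled:
        ox_opts += [("ox", i) for i, a in enumerate(sequence) if a == "M"]
    ac_opts: list[Placement | None] = [None]
    if "ac" in enabled:
        ac_opts.append(("ac", -1))
    out: list[Placements] = []
    for ph in ph_opts:
        for ox in ox_opts:
            for ac in ac_opts:
                out.append(tuple(p for p in (ac, ph, ox) if p is not None))
    return out


class PeptideIndex:
    """Mass-sorted index over all (peptide form, modification placement)
    pairs of a target plus decoy search space."""

    def __init__(
        self,
        target_space: Mapping[str, list[PeptideForm]],
        decoy_space: Mapping[str, list[PeptideForm]] | None = None,
        enabled_mods: Sequence[str] = ("ac", "ox", "ph"),
    ) -> None:
        masses: list[float] = []
        entries: list[tuple[str, Placements, bool, bool]] = []
        for space, decoy in ((target_space, False), (decoy_space or {}, True)):
            for seq, forms in space.items():
                variant = is_variant_sequence(forms)
                base = _pymass.fast_mass(seq)
                for placements in enumerate_placements(seq, enabled_mods):
                    m = base
                    for name, _pos in placements:
                        m += MODIFICATIONS[name].delta_mass
                    masses.append(m)
                    entries.append((seq, placements, variant, decoy))
        order = np.argsort(np.asarray(masses, dtype=float), kind="stable")
        self.masses = np.asarray(masses, dtype=float)[order]
        self.entries = [entries[i] for i in order]

    def __len__(self) -> int:
        return len(self.entries)


def candidate_lookup(
    spectrum: ObservedSpectrum,
    index: PeptideIndex,
    tolerances: SearchTolerances | None = None,
) -> list[tuple[str, Placements, bool, bool]]:
    """All indexed forms within the precursor tolerance (inclusive) of the
    observed neutral mass."""
    tolerances = tolerances or SearchTolerances()
    obs = spectrum.neutral_mass
    # inclusive boundary with a 1e-9 relative guard against fp rounding
    tol = tolerances.precursor_ppm * 1e-6 * (1.0 + 1e-9)
    lo = obs / (1.0 + tol)
    hi = obs * (1.0 + tol)
    i = int(np.searchsorted(index.masses, lo, side="left"))
    j = int(np.searchsorted(index.masses, hi, side="right"))
    return [
        index.entries[k]
        for k in range(i, j)
        if abs(obs - index.masses[k]) <= index.masses[k] * tol
    ]


def match_probability(
    n_observed_peaks: int,
    tolerances: SearchTolerances,
    mz_range: tuple[float, float],
) -> float:
    """Chance that a random observed peak set hits one theoretical fragment:
    1 - (1 - w/span)**n for a tolerance window of width w in a scan span."""
    lo, hi = mz_range
    width = 2.0 * tolerances.fragment_ppm * 1e-6 * 0.5 * (lo + hi)
    frac = min(width / max(hi - lo, 1e-9), 1.0)
    p = 1.0 - (1.0 - frac) ** max(n_observed_peaks, 0)
    return float(min(max(p, 1e-12), 0.5))


def binomial_tail_score(k: int, n: int, p: float) -> float:
    """-10*log10 P(X >= k), X ~ Binomial(n, p); 0 when no fragment matches."""
    if k <= 0:
        return 0.0
    tail = float(_stats.binom.sf(k - 1, n, p))
    return float(-10.0 * np.log10(max(tail, 1e-300)))


def _count_matched(theoretical: np.ndarray, observed: np.ndarray, frag_tol: float) -> int:
    if observed.size == 0 or theoretical.size == 0:
        return 0
    idx = np.searchsorted(observed, theoretical)
    left = np.clip(idx - 1, 0, observed.size - 1)
    right = np.clip(idx, 0, observed.size - 1)
    d = np.minimum(
        np.abs(theoretical - observed[left]), np.abs(theoretical - observed[right])
    )
    return int(np.count_nonzero(d <= theoretical * frag_tol * 1e-6))


def score_match(
    spectrum: ObservedSpectrum,
    sequence: str,
    placements: Placements = (),
    tolerances: SearchTolerances | None = None,
    mz_range: tuple[float, float] = (100.0, 1700.0),
) -> tuple[float, int, int]:
    """Score one candidate assignment; returns (score, n_matched, n_theoretical)."""
    tolerances = tolerances or SearchTolerances()
    theo = generate_by_ions(sequence, placements, spectrum.charge)
    k = _count_matched(theo, spectrum.mz, tolerances.fragment_ppm)
    n = theo.size
    p = match_probability(spectrum.mz.size, tolerances, mz_range)
    return binomial_tail_score(k, n, p), k, n


def delta_score(
    ranked: Sequence[tuple[float, str, Placements]]
) -> float:
    """Score gap from the best assignment to the best DISTINCT alternative
    (different sequence or different placement); the best score itself when
    no alternative exists."""
    if not ranked:
        raise ValueError("at least one candidate required")
    best_score, best_seq, best_pl = ranked[0]
    for score, seq, pl in ranked[1:]:
        if seq != best_seq or pl != best_pl:
            return best_score - score
    return best_score


def localize_sites(
    spectrum: ObservedSpectrum,
    sequence: str,
    placements: Placements,
    tolerances: SearchTolerances | None = None,
    mz_range: tuple[float, float] = (100.0, 1700.0),
    mod_name: str = "ph",
) -> dict[int, float]:
    """Site probabilities for a positionable modification.

    Every single-site isomer is rescored; isomer weights are 10**(score/10),
    normalized; a site's probability is the weight mass of isomers placing
    the modification there.  Keys are 1-based residue positions.
    """
    spec = MODIFICATIONS[mod_name]
    sites = [i for i, a in enumerate(sequence) if a in spec.residues]
    if not sites:
        raise ValueError(f"no legal site for {mod_name} in {sequence}")
    others = tuple(p for p in placements if p[0] != mod_name)
    weights: dict[int, float] = {}
    scores = []
    for site in sites:
        isomer = tuple(sorted(others + ((mod_name, site),), key=lambda x: x[1]))
        s, _k, _n = score_match(spectrum, sequence, isomer, tolerances, mz_range)
        scores.append((site, s))
    smax = max(s for _i, s in scores)
    for site, s in scores:
        weights[site + 1] = 10.0 ** ((s - smax) / 10.0)
    total = sum(weights.values())
    return {pos: w / total for pos, w in weights.items()}


def search_spectra(
    spectra: Iterable[ObservedSpectrum],
    index: PeptideIndex,
    tolerances: SearchTolerances | None = None,
    mz_range: tuple[float, float] = (100.0, 1700.0),
) -> list[SpectrumMatch]:
    """Best assignment per spectrum with delta score and, for phosphopeptides,
    site localization probabilities.  Spectra without candidates are dropped."""
    tolerances = tolerances or SearchTolerances()
    matches: list[SpectrumMatch] = []
    for spectrum in spectra:
        candidates = candidate_lookup(spectrum, index, tolerances)
        if not candidates:
            continue
        scored = []
        for seq, placements, variant, decoy in candidates:
            s, k, n = score_match(spectrum, seq, placements, tolerances, mz_range)
            scored.append((s, seq, placements, variant, decoy, k, n))
        # deterministic: by score desc, then sequence/placement lexicographic
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        s, seq, placements, variant, decoy, k, n = scored[0]
        delta = delta_score([(t[0], t[1], t[2]) for t in scored])
        theo_mass = peptide_mass(seq, placements)
        ppm = (spectrum.neutral_mass - theo_mass) / theo_mass * 1e6
        match = SpectrumMatch(
            spectrum_id=spectrum.spectrum_id,
            sequence=seq,
            placements=placements,
            score=s,
            delta_score=delta,
            precursor_error_ppm=ppm,
            is_variant=variant,
            is_decoy=decoy,
            n_matched=k,
            n_theoretical=n,
            precursor_intensity=spectrum.precursor_intensity,
        )
        if match.is_phospho:
            match.site_localizations = localize_sites(
                spectrum, seq, placements, tolerances, mz_range
            )
        matches.append(match)
    return matches


# --- MGF I/O ------------------------------------------------------------


def write_mgf(spectra: Sequence[ObservedSpectrum], path) -> None:
    records = []
    for s in spectra:
        pepmass = (
            (s.precursor_mz,)
            if np.isnan(s.precursor_intensity)
            else (s.precursor_mz, s.precursor_intensity)
        )
        records.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": pepmass,
                    "charge": [s.charge],
                },
            }
        )
    _pymgf.write(records, str(path), file_mode="w")


def read_mgf(path) -> list[ObservedSpectrum]:
    spectra: list[ObservedSpectrum] = []
    with _pymgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            pepmass = params["pepmass"]
            intensity = float("nan")
            if isinstance(pepmass, tuple):
                mz0 = float(pepmass[0])
                if len(pepmass) > 1 and pepmass[1] is not None:
                    intensity = float(pepmass[1])
            else:
                mz0 = float(pepmass)
            spectra.append(
                ObservedSpectrum(
                    spectrum_id=str(params.get("title", f"scan{len(spectra)}")),
                    precursor_mz=mz0,
                    charge=int(params["charge"][0]),
                    mz=np.asarray(rec["m/z array"], dtype=float),
                    intensity=np.asarray(rec["intensity array"], dtype=float),
                    precursor_intensity=intensity,
                )
            )
    return spectra
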