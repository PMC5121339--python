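"""Synthetic cohort generator with planted ground truth.

Emulates the inputs of a variant-aware immunopeptidomics experiment without
any external data: coding transcripts with planted missense SNVs, pileup
columns whose variant-supporting read counts follow Binomial(depth, VAF),
a motif-biased peptidome with a configurable length distribution peaking at
9-mers (typical for eluted HLA-I ligands), and MS/MS spectra containing the
true peptide's b/y fragments plus Poisson-distributed uniform noise peaks.
Everything is deterministic under a fixed seed, and the planted truth is
returned alongside the data so every downstream stage can be benchmarked.

Base qualities are drawn from a truncated normal around ``quality_mean`` so
tests can place observations on both sides of the Q13 cutoff; pure-noise
spectra give the FDR stage its true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .personal_db import ProteinVariant, TranscriptRecord, apply_variant, translate
from .spectra_search import (
    PROTON,
    ObservedSpectrum,
    Placements,
    generate_by_ions,
    peptide_mass,
)
from .variant_calling import PileupColumn

__all__ = [
    "CohortConfig",
    "PlantedVariant",
    "TruePeptide",
    "PlantedTruth",
    "make_reference",
    "plant_truth",
    "simulate_pileups",
    "simulate_peptidome_and_spectra",
    "write_truth_tsv",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
_QUAL_LO, _QUAL_HI = 2, 41


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_transcripts: int = 12
    cds_length: int = 360  # nucleotides, multiple of 3 (-> 119-residue proteins)
    n_variants: int = 5
    vaf_range: tuple[float, float] = (0.2, 0.5)
    depth_range: tuple[int, int] = (80, 160)
    base_error_rate: float = 0.001
    quality_mean: float = 30.0
    quality_sd: float = 4.0
    motif_anchor_spec: Mapping[int, str] = field(default_factory=dict)  # 1-based
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.10, 9: 0.40, 10: 0.20, 11: 0.12,
                                 12: 0.08, 13: 0.05, 14: 0.05}
    )
    n_peptides: int = 300
    n_patients: int = 4
    variant_peptide_fraction: float = 0.2
    phospho_fraction: float = 0.0
    charge_weights: tuple[float, float, float] = (0.15, 0.60, 0.25)
    noise_peak_rate: float = 5.0  # Poisson mean noise peaks per spectrum
    n_noise_spectra: int = 0
    noise_spectrum_peaks: int = 40
    mz_range: tuple[float, float] = (100.0, 1700.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(f"cds_length {self.cds_length} not divisible by 3")
        total = sum(self.length_weights.values())
        if self.length_weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"length weights sum to {total}, not 1")
        shortest = min(self.length_weights) if self.length_weights else 0
        for pos in self.motif_anchor_spec:
            if pos > shortest:
                raise ValueError(
                    f"motif anchor position {pos} exceeds shortest sampled "
                    f"length {shortest}"
                )


@dataclass(frozen=True)
class PlantedVariant:
    transcript_id: str
    protein_id: str
    cds_pos: int  # 1-based within the CDS
    ref_base: str
    alt_base: str
    vaf: float  # true allele fraction in [0, 1]
    aa_pos: int  # 1-based
    ref_aa: str
    alt_aa: str

    def as_protein_variant(self) -> ProteinVariant:
        return ProteinVariant(self.protein_id, self.aa_pos, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class TruePeptide:
    sequence: str
    placements: Placements
    source_protein: str
    is_variant: bool
    patient: str


@dataclass
class PlantedTruth:
    variants: list[PlantedVariant]
    true_peptides: list[TruePeptide] = field(default_factory=list)
    spectrum_assignments: dict[str, TruePeptide | str] = field(default_factory=dict)


def _rng(config: CohortConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def make_reference(
    config: CohortConfig,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Deterministic CDS set (ATG + non-stop codons + stop) and its
    standard-table translation."""
    rng = _rng(config, 1)
    transcripts: list[TranscriptRecord] = []
    proteome: dict[str, str] = {}
    n_codons = config.cds_length // 3
    for i in range(config.n_transcripts):
        body = "".join(rng.choice(_CODONS, size=max(n_codons - 2, 0)))
        stop = rng.choice(sorted(_STOPS)) if n_codons >= 2 else ""
        cds = ("ATG" + body + stop)[: config.cds_length]
        tid, pid = f"ENST{i:04d}", f"PROT{i:04d}"
        transcripts.append(TranscriptRecord(tid, pid, cds))
        proteome[pid] = translate(cds)
    return transcripts, proteome


def plant_truth(
    transcripts: Sequence[TranscriptRecord], config: CohortConfig
) -> PlantedTruth:
    """Plant missense SNVs at distinct codons with VAFs from ``vaf_range``."""
    rng = _rng(config, 2)
    variants: list[PlantedVariant] = []
    used: set[tuple[str, int]] = set()
    n_codons = config.cds_length // 3
    if config.n_variants and (config.n_transcripts == 0 or n_codons < 3):
        raise ValueError("reference too small to plant variants")
    attempts = 0
    while len(variants) < config.n_variants:
        attempts += 1
        if attempts > 10000 * max(config.n_variants, 1):
            raise RuntimeError("could not plant requested variants")
        t = transcripts[int(rng.integers(len(transcripts)))]
        codon_idx = int(rng.integers(1, n_codons - 1))  # skip start and stop
        if (t.transcript_id, codon_idx) in used:
            continue
        within = int(rng.integers(3))
        pos = codon_idx * 3 + within  # 0-based in CDS
        ref_base = t.cds[pos]
        alt_base = str(rng.choice([b for b in _BASES if b != ref_base]))
        codon = t.cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        if alt_codon in _STOPS:
            continue
        ref_aa, alt_aa = translate(codon), translate(alt_codon)
        if ref_aa == alt_aa:
            continue
        used.add((t.transcript_id, codon_idx))
        variants.append(
            PlantedVariant(
                transcript_id=t.transcript_id,
                protein_id=t.protein_id,
                cds_pos=pos + 1,
                ref_base=ref_base,
                alt_base=alt_base,
                vaf=float(rng.uniform(*config.vaf_range)),
                aa_pos=codon_idx + 1,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    variants.sort(key=lambda v: (v.transcript_id, v.cds_pos))
    return PlantedTruth(variants=variants)


def _qualities(rng: np.random.Generator, n: int, config: CohortConfig) -> np.ndarray:
    a = (_QUAL_LO - config.quality_mean) / config.quality_sd
    b = (_QUAL_HI - config.quality_mean) / config.quality_sd
    q = truncnorm.rvs(
        a, b, loc=config.quality_mean, scale=config.quality_sd,
        size=n, random_state=np.random.RandomState(int(rng.integers(2**31 - 1))),
    )
    return np.rint(q).astype(int)


def simulate_pileups(
    transcripts: Sequence[TranscriptRecord],
    truth: PlantedTruth,
    config: CohortConfig,
) -> list[PileupColumn]:
    """One pileup column per CDS position.

    Variant positions carry Binomial(depth, VAF) variant-supporting reads;
    every other read substitutes at ``base_error_rate`` to a random other base.
    """
    rng = _rng(config, 3)
    by_site = {(v.transcript_id, v.cds_pos): v for v in truth.variants}
    columns: list[PileupColumn] = []
    for t in transcripts:
        for pos1 in range(1, len(t.cds) + 1):
            ref = t.cds[pos1 - 1]
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            v = by_site.get((t.transcript_id, pos1))
            bases = np.full(depth, ref, dtype="<U1")
            if v is not None:
                n_alt = int(rng.binomial(depth, v.vaf))
                bases[:n_alt] = v.alt_base
                start_err = n_alt
            else:
                start_err = 0
            if config.base_error_rate > 0:
                err = np.nonzero(
                    rng.random(depth - start_err) < config.base_error_rate
                )[0]
                for i in err:
                    others = [b for b in _BASES if b != bases[start_err + i]]
                    bases[start_err + i] = others[int(rng.integers(3))]
            perm = rng.permutation(depth)
            quals = _qualities(rng, depth, config)
            obs = tuple(
                (str(bases[perm[i]]), int(quals[i])) for i in range(depth)
            )
            columns.append(PileupColumn(t.transcript_id, pos1, ref, obs))
    return columns


def _sample_length(rng: np.random.Generator, config: CohortConfig) -> int:
    lengths = sorted(config.length_weights)
    weights = np.array([config.length_weights[l] for l in lengths])
    return int(rng.choice(lengths, p=weights / weights.sum()))


def _matches_motif(peptide: str, config: CohortConfig) -> bool:
    return all(
        peptide[pos - 1] in allowed
        for pos, allowed in config.motif_anchor_spec.items()
    )


def simulate_peptidome_and_spectra(
    proteome: Mapping[str, str],
    truth: PlantedTruth,
    config: CohortConfig,
) -> tuple[list[ObservedSpectrum], pd.DataFrame, PlantedTruth]:
    """Sample the peptidome, build one spectrum per planted peptide plus the
    configured pure-noise spectra, and return the eluted-ligand table.

    Sampled peptides are exact substrings of the personalized proteome
    (reference proteins, or single-variant isoforms for variant peptides).
    """
    rng = _rng(config, 4)
    isoforms = {
        v: apply_variant(proteome[v.protein_id], v.as_protein_variant())
        for v in truth.variants
    }
    n_variant = round(config.n_peptides * config.variant_peptide_fraction)
    n_variant = min(n_variant, config.n_peptides) if truth.variants else 0
    peptides: list[TruePeptide] = []

    for j in range(n_variant):
        v = truth.variants[j % len(truth.variants)]
        iso = isoforms[v]
        for _ in range(200):
            length = _sample_length(rng, config)
            lo = max(0, v.aa_pos - length)
            hi = min(v.aa_pos - 1, len(iso) - length)
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            seq = iso[start : start + length]
            peptides.append(
                TruePeptide(seq, (), v.protein_id, True,
                            f"Mel{int(rng.integers(config.n_patients)) + 1}")
            )
            break

    pids = sorted(proteome)
    plens = np.array([len(proteome[p]) for p in pids], dtype=float)
    while len(peptides) < config.n_peptides:
        chosen = None
        for _ in range(200):
            pid = pids[int(rng.choice(len(pids), p=plens / plens.sum()))]
            seq_full = proteome[pid]
            length = _sample_length(rng, config)
            if len(seq_full) < length:
                continue
            start = int(rng.integers(0, len(seq_full) - length + 1))
            pep = seq_full[start : start + length]
            chosen = (pep, pid)
            if _matches_motif(pep, config):
                break
        if chosen is None:
            raise RuntimeError("could not sample a peptide; proteome too short")
        pep, pid = chosen
        peptides.append(
            TruePeptide(pep, (), pid, False,
                        f"Mel{int(rng.integers(config.n_patients)) + 1}")
        )

    # plant phosphorylations on S/T/Y carriers
    final: list[TruePeptide] = []
    for tp in peptides:
        placements: Placements = ()
        if config.phospho_fraction > 0 and rng.random() < config.phospho_fraction:
            sites = [i for i, a in enumerate(tp.sequence) if a in "STY"]
            if sites:
                placements = (("ph", int(rng.choice(sites))),)
        final.append(replace(tp, placements=placements))
    truth.true_peptides = final

    spectra: list[ObservedSpectrum] = []
    rows = []
    lo, hi = config.mz_range
    cw = np.array(config.charge_weights, dtype=float)
    for i, tp in enumerate(final):
        sid = f"spec{i:05d}"
        charge = int(rng.choice([1, 2, 3], p=cw / cw.sum()))
        theo = generate_by_ions(tp.sequence, tp.placements, charge)
        theo = theo[(theo >= lo) & (theo <= hi)]
        n_noise = int(rng.poisson(config.noise_peak_rate))
        noise_mz = rng.uniform(lo, hi, size=n_noise)
        mz = np.concatenate([theo, noise_mz])
        inten = np.concatenate(
            [rng.uniform(0.2, 1.0, size=theo.size),
             rng.uniform(0.01, 0.3, size=n_noise)]
        )
        prec_int = float(rng.lognormal(10.0, 1.0))
        spectrum = ObservedSpectrum(
            spectrum_id=sid,
            precursor_mz=(peptide_mass(tp.sequence, tp.placements) + charge * PROTON)
            / charge,
            charge=charge,
            mz=mz,
            intensity=inten,
            precursor_intensity=prec_int,
        )
        spectra.append(spectrum)
        truth.spectrum_assignments[sid] = tp
        mods = ";".join(f"{n}@{p + 1}" for n, p in tp.placements)
        rows.append(
            {
                "sequence": tp.sequence,
                "patient": tp.patient,
                "hla_class": "I",
                "intensity": prec_int,
                "modifications": mods,
                "source_protein": tp.source_protein,
                "is_variant": tp.is_variant,
                "spectrum_id": sid,
            }
        )

    for j in range(config.n_noise_spectra):
        sid = f"noise{j:05d}"
        charge = int(rng.choice([1, 2, 3], p=cw / cw.sum()))
        length = _sample_length(rng, config)
        fake = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        n_peaks = max(int(rng.poisson(config.noise_spectrum_peaks)), 1)
        spectrum = ObservedSpectrum(
            spectrum_id=sid,
            precursor_mz=(peptide_mass(fake) + charge * PROTON) / charge,
            charge=charge,
            mz=rng.uniform(lo, hi, size=n_peaks),
            intensity=rng.uniform(0.01, 1.0, size=n_peaks),
        )
        spectra.append(spectrum)
        truth.spectrum_assignments[sid] = "noise"

    table = pd.DataFrame(rows)
    return spectra, table, truth


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tfields\n")
        for v in truth.variants:
            fh.write(
                f"variant\t{v.transcript_id}:{v.cds_pos}{v.ref_base}>{v.alt_base}"
                f"|{v.protein_id}:{v.ref_aa}{v.aa_pos}{v.alt_aa}|vaf={v.vaf:.4f}\n"
            )
        for sid, assignment in truth.spectrum_assignments.items():
            if isinstance(assignment, str):
                fh.write(f"spectrum\t{sid}|noise\n")
            else:
                mods = ";".join(f"{n}@{p + 1}" for n, p in assignment.placements)
                fh.write(
                    f"spectrum\t{sid}|{assignment.sequence}|{mods}|"
                    f"{assignment.patient}\n"
                )
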