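"""Descriptive analytics over an eluted-ligand table.

Covers the ligandome summaries used to characterize a cohort: peptide length
distributions, per-protein coverage profiles with cross-patient "hot spots",
normalized tumour-associated-antigen counts correlated (after square-root
transform) with external covariates under Holm correction, intensity-rank
quartile placement of a peptide subset, and positional summaries of
phosphopeptides (shared fractions, S/T/Y usage, site-by-length matrix,
position-1 residue usage and per-position logo frequencies).

The input table carries one row per (sequence, patient, HLA class) with a
precursor intensity and a modification string ("ph@4;ox@2", 1-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageProfile",
    "AntigenSummary",
    "PhosphoSummary",
    "length_distribution",
    "map_peptides_to_proteome",
    "coverage_profile",
    "antigen_correlation",
    "intensity_rank_projection",
    "phospho_summaries",
]


@dataclass
class CoverageProfile:
    protein_id: str
    ligand_count: np.ndarray  # per residue: overlapping ligand rows
    patient_count: np.ndarray  # per residue: distinct patients
    hot_spots: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open


@dataclass(frozen=True)
class AntigenSummary:
    antigen_id: str
    normalized_counts: Mapping[str, float]  # patient -> ligands / patient total
    sqrt_counts: Mapping[str, float]
    pearson_r: float
    p_value: float
    corrected_p: float


@dataclass
class PhosphoSummary:
    shared_fraction: float
    residue_fractions: dict[str, float]  # S/T/Y
    site_position_matrix: pd.DataFrame  # rows: peptide length, cols: position
    p1_residue_freqs: pd.Series
    logo_matrices: dict[int, pd.DataFrame]  # length -> position x residue counts


def length_distribution(table: pd.DataFrame, hla_class: str | None = None) -> pd.Series:
    """Exact histogram of peptide lengths, optionally per HLA class."""
    if hla_class is not None:
        table = table[table["hla_class"] == hla_class]
    if table.empty:
        return pd.Series(dtype=int)
    return table["sequence"].str.len().value_counts().sort_index()


def map_peptides_to_proteome(
    sequences: Sequence[str], proteome: Mapping[str, str]
) -> dict[str, list[tuple[str, int]]]:
    """Exact-substring mapping sequence -> [(protein, 0-based start), ...].

    Peptides hitting several proteins are mapped to each occurrence (and
    flagged by the caller); all occurrences within one protein count."""
    hits: dict[str, list[tuple[str, int]]] = {seq: [] for seq in set(sequences)}
    for pid, pseq in proteome.items():
        for seq in hits:
            start = pseq.find(seq)
            while start != -1:
                hits[seq].append((pid, start))
                start = pseq.find(seq, start + 1)
    return hits


def coverage_profile(
    table: pd.DataFrame,
    proteome: Mapping[str, str],
    hotspot_min_patients: int = 3,
) -> dict[str, CoverageProfile]:
    """Per-residue ligand and patient coverage, with hot spots called as
    maximal runs of residues covered by >= ``hotspot_min_patients`` distinct
    patients."""
    hits = map_peptides_to_proteome(table["sequence"], proteome)
    multimapped = [s for s, h in hits.items() if len({p for p, _ in h}) > 1]
    if multimapped:
        logger.warning(
            "%d peptide(s) map to multiple proteins; counted for each",
            len(multimapped),
        )
    profiles: dict[str, CoverageProfile] = {}
    per_protein_patients: dict[str, list[set[str]]] = {
        pid: [set() for _ in seq] for pid, seq in proteome.items()
    }
    counts = {pid: np.zeros(len(seq), dtype=int) for pid, seq in proteome.items()}
    for _, row in table.iterrows():
        for pid, start in hits.get(row["sequence"], []):
            end = start + len(row["sequence"])
            counts[pid][start:end] += 1
            for i in range(start, end):
                per_protein_patients[pid][i].add(row["patient"])
    for pid in proteome:
        pat = np.array([len(s) for s in per_protein_patients[pid]], dtype=int)
        hot: list[tuple[int, int]] = []
        in_run, run_start = False, 0
        for i, n in enumerate(pat):
            if n >= hotspot_min_patients and not in_run:
                in_run, run_start = True, i
            elif n < hotspot_min_patients and in_run:
                in_run = False
                hot.append((run_start, i))
        if in_run:
            hot.append((run_start, len(pat)))
        profiles[pid] = CoverageProfile(pid, counts[pid], pat, hot)
    return profiles


def antigen_correlation(
    table: pd.DataFrame,
    antigen_map: Mapping[str, str],  # antigen id -> protein id
    covariates: pd.DataFrame,  # index: patient, columns: antigen ids
    proteome: Mapping[str, str],
    hla_class: str = "I",
) -> list[AntigenSummary]:
    """Normalized antigen ligand counts vs an external covariate.

    Per patient: (ligands mapping to the antigen) / (total ligands of the
    class-matched table), square-root transformed, Pearson-correlated with
    the covariate, Holm-corrected across the tested antigens.
    """
    sub = table[table["hla_class"] == hla_class]
    hits = map_peptides_to_proteome(sub["sequence"], proteome)
    patients = list(covariates.index)
    if len(patients) < 3:
        raise ValueError("need >= 3 patients with covariate values")
    totals = sub.groupby("patient").size()
    summaries: list[tuple[str, dict, dict, float, float]] = []
    for antigen, pid in antigen_map.items():
        norm: dict[str, float] = {}
        for patient in patients:
            rows = sub[sub["patient"] == patient]
            n = sum(
                any(h[0] == pid for h in hits.get(seq, []))
                for seq in rows["sequence"]
            )
            total = int(totals.get(patient, 0))
            norm[patient] = n / total if total else 0.0
        sqrt_counts = {p: float(np.sqrt(v)) for p, v in norm.items()}
        x = np.array([sqrt_counts[p] for p in patients])
        y = covariates[antigen].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = _stats.pearsonr(x, y)
        summaries.append((antigen, norm, sqrt_counts, float(r), float(p)))
    pvals = [s[4] for s in summaries]
    finite = [i for i, p in enumerate(pvals) if np.isfinite(p)]
    corrected = dict.fromkeys(range(len(pvals)), float("nan"))
    if finite:
        adj = multipletests([pvals[i] for i in finite], method="holm")[1]
        corrected.update(dict(zip(finite, adj)))
    return [
        AntigenSummary(a, n, s, r, p, float(corrected[i]))
        for i, (a, n, s, r, p) in enumerate(summaries)
    ]


def intensity_rank_projection(
    table: pd.DataFrame, subset: Sequence[str]
) -> pd.DataFrame:
    """Rank all rows by descending intensity and place each subset peptide in
    its quartile of the full distribution.

    Quartile 1 holds the most intense peptides.  Ties are broken by sequence
    lexicographic order; quartile sizes differ by at most one.  Rows without
    an intensity are excluded with a warning.
    """
    missing = table["intensity"].isna()
    if missing.any():
        logger.warning(
            "%d row(s) without intensity excluded from ranking "
            "(MS/MS-level identification only)", int(missing.sum())
        )
    ranked = (
        table[~missing]
        .sort_values(["intensity", "sequence"], ascending=[False, True])
        .reset_index(drop=True)
    )
    n = len(ranked)
    ranked["rank"] = np.arange(1, n + 1)
    ranked["quartile"] = (np.arange(n) * 4) // max(n, 1) + 1
    ranked["in_subset"] = ranked["sequence"].isin(set(subset))
    return ranked


def _parse_sites(mods: str) -> list[int]:
    """1-based phospho positions from a 'ph@4;ox@2' style string."""
    sites = []
    for item in str(mods).split(";"):
        if item.startswith("ph@"):
            sites.append(int(item[3:]))
    return sites


def phospho_summaries(table: pd.DataFrame) -> PhosphoSummary:
    """Exact positional summaries of a phosphopeptide table."""
    rows = table[table["modifications"].fillna("").str.contains("ph@")]
    seq_patients = rows.groupby("sequence")["patient"].nunique()
    shared = float((seq_patients >= 2).sum() / len(seq_patients)) if len(seq_patients) else 0.0

    unique_rows = rows.drop_duplicates("sequence")
    residue_counts = {"S": 0, "T": 0, "Y": 0}
    site_records: list[tuple[int, int]] = []  # (peptide length, site position)
    p1: dict[str, int] = {}
    logo: dict[int, pd.DataFrame] = {}
    for _, row in unique_rows.iterrows():
        seq = row["sequence"]
        for pos in _parse_sites(row["modifications"]):
            residue_counts[seq[pos - 1]] = residue_counts.get(seq[pos - 1], 0) + 1
            site_records.append((len(seq), pos))
        p1[seq[0]] = p1.get(seq[0], 0) + 1
        n = len(seq)
        if n not in logo:
            logo[n] = pd.DataFrame(
                0, index=range(1, n + 1), columns=sorted("ACDEFGHIKLMNPQRSTVWY")
            )
        for i, aa in enumerate(seq, start=1):
            logo[n].loc[i, aa] += 1

    total_sites = sum(residue_counts.values())
    fractions = {
        aa: (residue_counts.get(aa, 0) / total_sites if total_sites else 0.0)
        for aa in "STY"
    }
    if site_records:
        lengths = sorted({l for l, _ in site_records})
        max_pos = max(p for _, p in site_records)
        matrix = pd.DataFrame(0, index=lengths, columns=range(1, max_pos + 1))
        for l, p in site_records:
            matrix.loc[l, p] += 1
    else:
        matrix = pd.DataFrame(dtype=int)
    return PhosphoSummary(
        shared_fraction=shared,
        residue_fractions=fractions,
        site_position_matrix=matrix,
        p1_residue_freqs=pd.Series(p1, dtype=int).sort_index(),
        logo_matrices=logo,
    )
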