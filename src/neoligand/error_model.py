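"""Peptide-class-dependent error estimation and FDR control.

HLA searches mix peptide populations with very different prior probabilities
of being correct: unmodified reference peptides, variant (mutated) peptides,
phosphopeptides, and variant phosphopeptides.  Pooling them under one score
threshold lets the large plain class set the bar for the rare classes, so the
posterior error probability (PEP) is estimated separately per class from the
target/decoy score distributions, and a single common PSM-FDR threshold is
then applied on the pooled, PEP-sorted list.

Peptide-level reporting uses 1% FDR globally and a less stringent 5% for the
variant (mutated-ligand) classes.  Reported phosphopeptides are additionally
required to have delta score > 15 and a best site-localization probability
> 0.75 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.isotonic import IsotonicRegression

from .spectra_search import SpectrumMatch

__all__ = [
    "PEPTIDE_CLASSES",
    "FDRConfig",
    "PEPModel",
    "assign_class",
    "fit_pep",
    "assign_peps",
    "apply_common_fdr",
    "qvalues_from_pep",
    "peptide_rollup",
    "global_report",
    "variant_report",
    "filter_phospho",
    "decoy_fdr_crosscheck",
]

PEPTIDE_CLASSES = ("plain", "variant", "phospho", "variant_phospho")
_VARIANT_CLASSES = ("variant", "variant_phospho")


@dataclass(frozen=True)
class FDRConfig:
    global_fdr: float = 0.01
    variant_fdr: float = 0.05
    phospho_delta_min_exclusive: float = 15.0
    phospho_locprob_min_exclusive: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.global_fdr < 1 and 0 < self.variant_fdr < 1):
            raise ValueError("FDR thresholds must lie in (0, 1)")
        if self.phospho_delta_min_exclusive < 0:
            raise ValueError("delta-score cutoff must be positive")


def assign_class(psm: SpectrumMatch) -> str:
    """Variant x phospho truth table; oxidation/acetylation do not define a
    class of their own."""
    if psm.is_variant and psm.is_phospho:
        return "variant_phospho"
    if psm.is_variant:
        return "variant"
    if psm.is_phospho:
        return "phospho"
    return "plain"


def _empirical_tail_pep(targets: np.ndarray, decoys: np.ndarray) -> Callable:
    """Fallback estimator when KDE is unusable: decoy/target tail-count ratio."""

    def pep(scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        nd = np.array([(decoys >= s).sum() for s in scores], dtype=float)
        nt = np.array([(targets >= s).sum() for s in scores], dtype=float)
        return np.clip(nd / np.maximum(nt, 1.0), 0.0, 1.0)

    return pep


def _fit_single(targets: np.ndarray, decoys: np.ndarray) -> Callable:
    """Monotone score -> PEP map for one class.

    Kernel-smoothed decoy/target density ratio scaled by the class decoy and
    target counts, capped above the highest decoy score at 1/(n_decoys + 1)
    (no decoy mass there), then monotonized with isotonic regression.
    """
    targets = np.asarray(targets, dtype=float)
    decoys = np.asarray(decoys, dtype=float)
    if targets.size == 0:
        return lambda s: np.ones_like(np.atleast_1d(np.asarray(s, dtype=float)))
    if decoys.size == 0:
        c = 1.0 / (targets.size + 1.0)
        return lambda s: np.full_like(np.atleast_1d(np.asarray(s, dtype=float)), c)
    grid = np.unique(np.concatenate([targets, decoys]))
    try:
        if np.std(targets) == 0 or np.std(decoys) == 0:
            raise np.linalg.LinAlgError("degenerate score distribution")
        f_t = gaussian_kde(targets)(grid)
        f_d = gaussian_kde(decoys)(grid)
        raw = np.clip(
            (decoys.size * f_d) / np.maximum(targets.size * f_t, 1e-300), 0.0, 1.0
        )
    except np.linalg.LinAlgError:
        raw = _empirical_tail_pep(targets, decoys)(grid)
    cap = 1.0 / (decoys.size + 1.0)
    raw = np.where(grid > decoys.max(), np.minimum(raw, cap), raw)
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(grid, raw)

    def pep(scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        return np.interp(scores, grid, fitted)

    return pep


@dataclass
class PEPModel:
    """Per-class monotone score -> PEP maps with a pooled fallback."""

    class_models: dict[str, Callable]
    pooled: Callable

    def predict(self, peptide_class: str, score: float) -> float:
        fn = self.class_models.get(peptide_class, self.pooled)
        return float(np.clip(fn(score)[0], 0.0, 1.0))


def fit_pep(
    psms: Sequence[SpectrumMatch], min_decoys_per_class: int = 50
) -> PEPModel:
    """Fit the class-dependent PEP model from target/decoy score distributions.

    Classes with fewer than ``min_decoys_per_class`` decoys fall back to the
    pooled (all-class) model; classes with no PSMs at all are skipped.
    """
    all_t = np.array([p.score for p in psms if not p.is_decoy])
    all_d = np.array([p.score for p in psms if p.is_decoy])
    pooled = _fit_single(all_t, all_d)
    class_models: dict[str, Callable] = {}
    for cls in PEPTIDE_CLASSES:
        group = [p for p in psms if assign_class(p) == cls]
        if not group:
            continue
        d = np.array([p.score for p in group if p.is_decoy])
        t = np.array([p.score for p in group if not p.is_decoy])
        if d.size >= min_decoys_per_class and t.size > 0:
            class_models[cls] = _fit_single(t, d)
        else:
            class_models[cls] = pooled
    return PEPModel(class_models, pooled)


def assign_peps(psms: Sequence[SpectrumMatch], model: PEPModel) -> None:
    """Annotate each PSM in place with its class and class-dependent PEP."""
    for p in psms:
        p.peptide_class = assign_class(p)
        p.pep = model.predict(p.peptide_class, p.score)


def _sort_key(p: SpectrumMatch):
    return (p.pep, -p.score, p.spectrum_id)


def qvalues_from_pep(peps: np.ndarray) -> np.ndarray:
    """q-values as the right-cumulative minimum of the running mean PEP of a
    PEP-ascending list."""
    peps = np.asarray(peps, dtype=float)
    running_mean = np.cumsum(peps) / np.arange(1, peps.size + 1)
    return np.minimum.accumulate(running_mean[::-1])[::-1]


def apply_common_fdr(
    psms: Sequence[SpectrumMatch], threshold: float = 0.01
) -> list[SpectrumMatch]:
    """Common PSM-FDR threshold on the pooled, PEP-sorted list.

    Accept the largest prefix whose running mean PEP stays at or below the
    threshold; ties broken by (PEP, score descending, spectrum id).
    """
    ordered = sorted(psms, key=_sort_key)
    if not ordered:
        return []
    running_mean = np.cumsum([p.pep for p in ordered]) / np.arange(1, len(ordered) + 1)
    passing = np.nonzero(running_mean <= threshold)[0]
    if passing.size == 0:
        return []
    return ordered[: passing[-1] + 1]


def peptide_rollup(psms: Sequence[SpectrumMatch]) -> pd.DataFrame:
    """Best (lowest-PEP) PSM per distinct modified sequence, with peptide-level
    q-values recomputed on the rolled-up list."""
    best: dict[tuple[str, bool], SpectrumMatch] = {}
    for p in psms:
        key = (p.modified_sequence, p.is_decoy)
        cur = best.get(key)
        if cur is None or _sort_key(p) < _sort_key(cur):
            best[key] = p
    rows = sorted(best.values(), key=_sort_key)
    df = pd.DataFrame(
        {
            "sequence": [p.sequence for p in rows],
            "modified_sequence": [p.modified_sequence for p in rows],
            "peptide_class": [p.peptide_class or assign_class(p) for p in rows],
            "is_variant": [p.is_variant for p in rows],
            "is_phospho": [p.is_phospho for p in rows],
            "is_decoy": [p.is_decoy for p in rows],
            "score": [p.score for p in rows],
            "delta_score": [p.delta_score for p in rows],
            "pep": [p.pep for p in rows],
            "qvalue": qvalues_from_pep([p.pep for p in rows]) if rows else [],
            "max_localization": [p.max_localization for p in rows],
            "precursor_intensity": [p.precursor_intensity for p in rows],
            "spectrum_id": [p.spectrum_id for p in rows],
        }
    )
    return df


def global_report(peptides: pd.DataFrame, config: FDRConfig | None = None) -> pd.DataFrame:
    """Peptides passing the global FDR; decoy rows are dropped from reports."""
    config = config or FDRConfig()
    mask = (~peptides["is_decoy"]) & (peptides["qvalue"] <= config.global_fdr)
    return peptides[mask].reset_index(drop=True)


def variant_report(peptides: pd.DataFrame, config: FDRConfig | None = None) -> pd.DataFrame:
    """Mutated-ligand report at the less stringent variant-class FDR."""
    config = config or FDRConfig()
    mask = (
        (~peptides["is_decoy"])
        & peptides["peptide_class"].isin(_VARIANT_CLASSES)
        & (peptides["qvalue"] <= config.variant_fdr)
    )
    return peptides[mask].reset_index(drop=True)


def filter_phospho(
    peptides: pd.DataFrame, config: FDRConfig | None = None
) -> pd.DataFrame:
    """Reported phosphopeptides: delta score > 15 and best localization
    probability > 0.75, both strict."""
    config = config or FDRConfig()
    mask = (
        peptides["is_phospho"]
        & (~peptides["is_decoy"])
        & (peptides["delta_score"] > config.phospho_delta_min_exclusive)
        & (peptides["max_localization"] > config.phospho_locprob_min_exclusive)
    )
    return peptides[mask].reset_index(drop=True)


def decoy_fdr_crosscheck(psms: Sequence[SpectrumMatch]) -> pd.DataFrame:
    """Classic decoy-counting FDR estimate (#decoys / #targets above each
    score), reported alongside the PEP-based control as a cross-check."""
    ordered = sorted(psms, key=lambda p: -p.score)
    n_decoy = np.cumsum([p.is_decoy for p in ordered])
    n_target = np.cumsum([not p.is_decoy for p in ordered])
    fdr = n_decoy / np.maximum(n_target, 1)
    return pd.DataFrame(
        {
            "score": [p.score for p in ordered],
            "n_target": n_target,
            "n_decoy": n_decoy,
            "decoy_fdr": np.minimum.accumulate(fdr[::-1])[::-1],
        }
    )
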