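"""Unspecific 8-25-mer search space with variant absence/presence combinatorics.

HLA ligands have no protease-defined termini, so the base search space is
every substring of every protein with length 8..25.  Each variant overlapping
a base peptide may be present or absent; all 2^k combinations are enumerated,
capped at 100 forms per base peptide (fewest-present-variants first, so the
low-order combinations — a priori the most plausible — survive the cap).
Decoys are built by per-protein sequence reversal followed by the identical
enumeration; decoy sequences colliding with targets are removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .personal_db import ProteinVariant

__all__ = [
    "BasePeptide",
    "VariantPattern",
    "PeptideForm",
    "ExpansionConfig",
    "enumerate_unspecific",
    "expand_patterns",
    "build_search_space",
    "build_decoys",
    "reverse_proteome",
]


@dataclass(frozen=True)
class ExpansionConfig:
    min_len: int = 8
    max_len: int = 25
    combination_cap: int = 100
    il_equivalent: bool = False  # merge I/L in sequence identity (off by default)

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.combination_cap < 1:
            raise ValueError("combination cap must be >= 1")


@dataclass(frozen=True)
class BasePeptide:
    """A substring of a protein; coordinates are 0-based half-open."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length disagrees with coordinates")


@dataclass(frozen=True)
class VariantPattern:
    """Absence/presence flags over the variants overlapping a base peptide."""

    variants: tuple[ProteinVariant, ...]  # ordered by position
    present: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.present):
            raise ValueError("one flag per variant required")

    @property
    def any_present(self) -> bool:
        return any(self.present)


@dataclass(frozen=True)
class PeptideForm:
    sequence: str
    pattern: VariantPattern
    is_variant: bool
    is_decoy: bool
    provenance: BasePeptide


def enumerate_unspecific(
    protein_id: str, sequence: str, config: ExpansionConfig | None = None
) -> Iterator[BasePeptide]:
    """All substrings with min_len <= length <= max_len, in (start, length)
    order.  Streamed: never materializes the whole space."""
    config = config or ExpansionConfig()
    n = len(sequence)
    for start in range(n):
        for length in range(config.min_len, config.max_len + 1):
            end = start + length
            if end > n:
                break
            yield BasePeptide(protein_id, start, end, sequence[start:end])


def count_unspecific(length: int, config: ExpansionConfig | None = None) -> int:
    """Closed form: sum over l of max(0, L - l + 1)."""
    config = config or ExpansionConfig()
    return sum(
        max(0, length - l + 1) for l in range(config.min_len, config.max_len + 1)
    )


def _apply_pattern(base: BasePeptide, pattern: VariantPattern) -> str:
    seq = list(base.sequence)
    for variant, flag in zip(pattern.variants, pattern.present):
        if not flag:
            continue
        i = variant.aa_pos - 1 - base.start
        if not 0 <= i < len(seq):
            raise ValueError(
                f"variant {variant.label} does not overlap "
                f"{base.protein_id}[{base.start}:{base.end})"
            )
        seq[i] = variant.alt_aa
    return "".join(seq)


def expand_patterns(
    base: BasePeptide,
    overlapping: Sequence[ProteinVariant],
    config: ExpansionConfig | None = None,
    is_decoy: bool = False,
) -> Iterator[PeptideForm]:
    """Enumerate absence/presence combinations of the overlapping variants.

    Order: ascending number of present variants, then positional
    lexicographic; the all-absent form comes first.  With k variants,
    min(2**k, cap) forms are emitted.
    """
    config = config or ExpansionConfig()
    variants = tuple(sorted(overlapping, key=lambda v: (v.aa_pos, v.alt_aa)))
    k = len(variants)
    emitted = 0
    for n_present in range(k + 1):
        for chosen in itertools.combinations(range(k), n_present):
            if emitted >= config.combination_cap:
                return
            present = tuple(i in chosen for i in range(k))
            pattern = VariantPattern(variants, present)
            yield PeptideForm(
                sequence=_apply_pattern(base, pattern),
                pattern=pattern,
                is_variant=pattern.any_present,
                is_decoy=is_decoy,
                provenance=base,
            )
            emitted += 1


def _canonical(sequence: str, config: ExpansionConfig) -> str:
    return sequence.replace("I", "L") if config.il_equivalent else sequence


def build_search_space(
    proteome: Mapping[str, str],
    variants: Sequence[ProteinVariant] = (),
    config: ExpansionConfig | None = None,
    is_decoy: bool = False,
) -> dict[str, list[PeptideForm]]:
    """Union of expanded forms over all proteins, deduplicated by sequence.

    Returns a mapping sequence -> all generating forms (multi-provenance).
    A sequence counts as variant only if EVERY generating form requires a
    variant; a variant peptide whose sequence also arises from the plain
    reference is therefore not a variant peptide.
    """
    config = config or ExpansionConfig()
    by_protein: dict[str, list[ProteinVariant]] = {}
    for v in variants:
        if v.alt_aa == "*":  # truncations live at the isoform level, not here
            continue
        by_protein.setdefault(v.protein_id, []).append(v)
    space: dict[str, list[PeptideForm]] = {}
    for pid, seq in proteome.items():
        pvars = by_protein.get(pid, [])
        for base in enumerate_unspecific(pid, seq, config):
            overlapping = [
                v for v in pvars if base.start < v.aa_pos <= base.end
            ]
            for form in expand_patterns(base, overlapping, config, is_decoy):
                space.setdefault(_canonical(form.sequence, config), []).append(form)
    return space


def is_variant_sequence(forms: Sequence[PeptideForm]) -> bool:
    return all(f.is_variant for f in forms)


def reverse_proteome(
    proteome: Mapping[str, str], variants: Sequence[ProteinVariant] = ()
) -> tuple[dict[str, str], list[ProteinVariant]]:
    """Reverse every protein and re-map variant positions accordingly."""
    rev = {f"REV__{pid}": seq[::-1] for pid, seq in proteome.items()}
    rev_variants = [
        ProteinVariant(
            protein_id=f"REV__{v.protein_id}",
            aa_pos=len(proteome[v.protein_id]) - v.aa_pos + 1,
            ref_aa=v.ref_aa,
            alt_aa=v.alt_aa,
            origin=v.origin,
        )
        for v in variants
        if v.alt_aa != "*"
    ]
    return rev, rev_variants


def build_decoys(
    proteome: Mapping[str, str],
    variants: Sequence[ProteinVariant] = (),
    config: ExpansionConfig | None = None,
    target_space: Mapping[str, list[PeptideForm]] | None = None,
) -> dict[str, list[PeptideForm]]:
    """Decoy space from reversed proteins; collisions with targets removed."""
    config = config or ExpansionConfig()
    if target_space is None:
        target_space = build_search_space(proteome, variants, config)
    rev, rev_variants = reverse_proteome(proteome, variants)
    decoys = build_search_space(rev, rev_variants, config, is_decoy=True)
    return {seq: forms for seq, forms in decoys.items() if seq not in target_space}
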