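"""Personalized protein database construction and mutation context windows.

Maps coding SNVs onto protein sequences, emits one single-variant isoform per
amino-acid-changing variant next to the full reference proteome, and extracts
the <=23-residue windows (11 residues of flank on each side of the altered
position) that external MHC binding predictors take as input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_calling import VariantCall

__all__ = [
    "TranscriptRecord",
    "ProteinVariant",
    "PersonalizedEntry",
    "ContextWindow",
    "translate",
    "map_snv_to_protein",
    "apply_variant",
    "build_personalized_fasta",
    "extract_context_window",
    "dedupe_variants",
    "read_fasta",
    "write_fasta",
    "write_windows_tsv",
]

WINDOW_FLANK = 11  # residues of context on each side of the altered position


@dataclass(frozen=True)
class TranscriptRecord:
    """A coding-sense CDS and the protein it encodes."""

    transcript_id: str
    protein_id: str
    cds: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"CDS length {len(self.cds)} of {self.transcript_id} "
                "is not divisible by 3"
            )


@dataclass(frozen=True)
class ProteinVariant:
    """An amino-acid change, reported 1-based in the V600E convention."""

    protein_id: str
    aa_pos: int  # 1-based
    ref_aa: str
    alt_aa: str
    origin: VariantCall | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa must differ from alt_aa")
        if self.aa_pos < 1:
            raise ValueError("aa_pos is 1-based and must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.aa_pos}{self.alt_aa}"


@dataclass(frozen=True)
class PersonalizedEntry:
    isoform_id: str
    sequence: str
    carried_variants: tuple[ProteinVariant, ...]


@dataclass(frozen=True)
class ContextWindow:
    sequence: str
    mutation_offset: int  # 0-based index of the altered residue in `sequence`
    variant: ProteinVariant

    def __post_init__(self) -> None:
        if len(self.sequence) > 2 * WINDOW_FLANK + 1:
            raise ValueError("window exceeds maximum length")
        if self.sequence[self.mutation_offset] != self.variant.alt_aa:
            raise ValueError("residue at mutation offset must equal alt_aa")


def translate(cds: str) -> str:
    """Standard-table translation, stopping at the first stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate(to_stop=True))


def map_snv_to_protein(
    transcript: TranscriptRecord, call: VariantCall
) -> ProteinVariant | None:
    """Map a nucleotide SNV (1-based position within the CDS) to an
    amino-acid change.

    Returns ``None`` for synonymous changes.  Stop-gains are reported with
    ``alt_aa="*"`` (the isoform is truncated downstream).
    """
    if not 1 <= call.pos <= len(transcript.cds):
        raise ValueError(
            f"position {call.pos} outside CDS of {transcript.transcript_id} "
            f"(length {len(transcript.cds)})"
        )
    idx = call.pos - 1
    if transcript.cds[idx] != call.ref:
        raise ValueError(
            f"reference base mismatch at {transcript.transcript_id}:{call.pos}: "
            f"CDS has {transcript.cds[idx]}, call has {call.ref}"
        )
    codon_idx = idx // 3
    codon = transcript.cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = codon[: idx % 3] + call.alt + codon[idx % 3 + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return None
    return ProteinVariant(
        protein_id=transcript.protein_id,
        aa_pos=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        origin=call,
    )


def apply_variant(sequence: str, variant: ProteinVariant) -> str:
    """Apply a single amino-acid variant to a reference sequence.

    Stop-gain (``alt_aa="*"``) truncates the protein at the preceding residue.
    Raises if the reference residue disagrees with the sequence.
    """
    i = variant.aa_pos - 1
    if not 0 <= i < len(sequence):
        raise ValueError(
            f"{variant.protein_id} {variant.label}: position outside protein "
            f"of length {len(sequence)}"
        )
    if sequence[i] != variant.ref_aa:
        raise ValueError(
            f"{variant.protein_id} {variant.label}: reference residue is "
            f"{sequence[i]}, not {variant.ref_aa}"
        )
    if variant.alt_aa == "*":
        return sequence[:i]
    return sequence[:i] + variant.alt_aa + sequence[i + 1 :]


def dedupe_variants(variants: Iterable[ProteinVariant]) -> list[ProteinVariant]:
    """Collapse identical (protein, position, alt) variants, e.g. the same
    SNV observed through several transcripts of one protein."""
    seen: dict[tuple[str, int, str], ProteinVariant] = {}
    for v in variants:
        seen.setdefault((v.protein_id, v.aa_pos, v.alt_aa), v)
    return list(seen.values())


def isoform_id(variant: ProteinVariant) -> str:
    # `>PROTID|var:POSREF>ALT` header dialect, machine-parsable downstream
    return f"{variant.protein_id}|var:{variant.aa_pos}{variant.ref_aa}>{variant.alt_aa}"


def build_personalized_fasta(
    proteome: Mapping[str, str],
    variants: Sequence[ProteinVariant],
    path=None,
) -> list[PersonalizedEntry]:
    """Reference proteome plus one single-variant isoform per variant.

    Writes FASTA to ``path`` when given; always returns the entries.
    """
    entries: list[PersonalizedEntry] = [
        PersonalizedEntry(pid, seq, ()) for pid, seq in proteome.items()
    ]
    for v in dedupe_variants(variants):
        if v.protein_id not in proteome:
            raise ValueError(f"variant references unknown protein {v.protein_id}")
        mutated = apply_variant(proteome[v.protein_id], v)
        entries.append(PersonalizedEntry(isoform_id(v), mutated, (v,)))
    if path is not None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.isoform_id, description="")
            for e in entries
        ]
        SeqIO.write(records, str(path), "fasta")
    return entries


def extract_context_window(
    sequence: str, variant: ProteinVariant, flank: int = WINDOW_FLANK
) -> ContextWindow:
    """Window of up to ``2*flank + 1`` residues around the altered position,
    with the alternate residue substituted.  Shorter near protein ends."""
    i = variant.aa_pos - 1
    mutated = apply_variant(sequence, variant)
    if variant.alt_aa == "*":
        raise ValueError(
            f"{variant.protein_id} {variant.label}: no context window for a "
            "stop-gain (no altered residue remains)"
        )
    start = max(0, i - flank)
    end = min(len(mutated), i + flank + 1)
    return ContextWindow(
        sequence=mutated[start:end], mutation_offset=i - start, variant=variant
    )


# --- I/O ----------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_windows_tsv(windows: Sequence[ContextWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\taa_pos\tref\talt\twindow\toffset\n")
        for w in windows:
            v = w.variant
            fh.write(
                f"{v.protein_id}\t{v.aa_pos}\t{v.ref_aa}\t{v.alt_aa}\t"
                f"{w.sequence}\t{w.mutation_offset}\n"
            )
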