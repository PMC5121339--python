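"""Promiscuous SNV calling from pileup columns.

The caller is deliberately permissive ("promiscuous"): its purpose is to feed
every plausible coding SNV into the personalized search-space construction, so
that a real mutated HLA ligand is never lost because the variant was filtered
too early.  Stringent somatic calling is out of scope here.

Thresholds (defaults):
  * base quality >= 13 (Phred; Q13 corresponds to ~0.05 error probability) —
    lower-quality bases are dropped before anything is counted;
  * quality-filtered read depth strictly > 10;
  * variant-supporting reads strictly > 5;
  * variant allele frequency >= 5 % (inclusive).

Depth and VAF are computed AFTER base-quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PileupColumn",
    "CallerThresholds",
    "VariantCall",
    "phred_to_error",
    "filter_bases",
    "call_promiscuous",
    "read_pileup",
    "write_pileup",
    "read_vcf",
    "write_vcf",
]

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class PileupColumn:
    """One reference position with its aligned base observations."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    observations: tuple[tuple[str, int], ...]  # (base, Phred quality)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for base, _q in self.observations:
            if base not in _NUCLEOTIDES:
                raise ValueError(f"invalid base {base!r} at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class CallerThresholds:
    """Promiscuous-caller cutoffs.

    ``min_depth_exclusive`` and ``min_support_exclusive`` are strict
    (``>``); ``min_vaf_inclusive`` is inclusive (``>=``), in percent.
    """

    min_quality: int = 13
    min_depth_exclusive: int = 10
    min_support_exclusive: int = 5
    min_vaf_inclusive: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_quality, self.min_depth_exclusive,
               self.min_support_exclusive, self.min_vaf_inclusive) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_support_exclusive > self.min_depth_exclusive:
            raise ValueError("support threshold cannot exceed depth threshold")


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int  # after quality filtering
    alt_count: int
    vaf: float  # percent, 100 * alt_count / depth

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")


def phred_to_error(q: float) -> float:
    """Error probability for a Phred score: ``10 ** (-q / 10)``."""
    if q < 0:
        raise ValueError(f"Phred quality must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def filter_bases(column: PileupColumn, thresholds: CallerThresholds) -> PileupColumn:
    """Drop observations with base quality strictly below ``min_quality``."""
    kept = tuple(
        (b, q) for b, q in column.observations if q >= thresholds.min_quality
    )
    if len(kept) == len(column.observations):
        return column
    return PileupColumn(column.chrom, column.pos, column.ref_base, kept)


def call_promiscuous(
    columns: Iterable[PileupColumn],
    thresholds: CallerThresholds | None = None,
) -> list[VariantCall]:
    """Emit a call for every alt base passing all three thresholds.

    Per column, qualifying alts are reported most-frequent first (ties broken
    alphabetically); multi-allelic columns yield one call per qualifying alt.
    N bases are ignored entirely.
    """
    thresholds = thresholds or CallerThresholds()
    calls: list[VariantCall] = []
    for column in columns:
        column = filter_bases(column, thresholds)
        depth = column.depth
        if depth <= thresholds.min_depth_exclusive:
            continue
        counts: dict[str, int] = {}
        for base, _q in column.observations:
            if base == "N" or base == column.ref_base:
                continue
            counts[base] = counts.get(base, 0) + 1
        qualifying = [
            (alt, n)
            for alt, n in counts.items()
            if n > thresholds.min_support_exclusive
            and 100.0 * n / depth >= thresholds.min_vaf_inclusive
        ]
        qualifying.sort(key=lambda item: (-item[1], item[0]))
        for alt, n in qualifying:
            calls.append(
                VariantCall(
                    chrom=column.chrom,
                    pos=column.pos,
                    ref=column.ref_base,
                    alt=alt,
                    depth=depth,
                    alt_count=n,
                    vaf=100.0 * n / depth,
                )
            )
    return calls


# --- pileup text I/O ----------------------------------------------------
#
# samtools-mpileup-like TSV: chrom, pos (1-based), ref, depth, base string,
# quality string.  Base string: "." / "," for ref matches, ACGT/acgt for
# substitutions, "^X" read-start markers (X = mapping quality) and "$"
# read-end markers are tolerated on input and skipped.  Qualities are
# Phred+33 characters.


def write_pileup(columns: Iterable[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            bases = "".join(
                "." if b == col.ref_base else b for b, _q in col.observations
            )
            quals = "".join(chr(q + 33) for _b, q in col.observations)
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{col.depth}\t{bases}\t{quals}\n"
            )


def _parse_base_string(bases: str, ref: str, lineno: int) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":  # read start; next char is mapping quality
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in ".,":
            out.append(ref)
        elif c.upper() in "ACGTN":
            out.append(c.upper())
        elif c in "+-":  # indel: not supported by this caller
            raise ValueError(f"pileup line {lineno}: indels unsupported")
        else:
            raise ValueError(f"pileup line {lineno}: unexpected base symbol {c!r}")
        i += 1
    return out


def read_pileup(path) -> list[PileupColumn]:
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"pileup line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref, depth_s, bases_s, quals = fields[:6]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ValueError(f"pileup line {lineno}: non-numeric field: {exc}") from exc
            base_list = _parse_base_string(bases_s, ref.upper(), lineno)
            if len(base_list) != len(quals):
                raise ValueError(
                    f"pileup line {lineno}: {len(base_list)} bases vs "
                    f"{len(quals)} qualities"
                )
            if depth != len(base_list):
                raise ValueError(
                    f"pileup line {lineno}: declared depth {depth} != "
                    f"{len(base_list)} observations"
                )
            obs = tuple((b, ord(q) - 33) for b, q in zip(base_list, quals))
            columns.append(PileupColumn(chrom, pos, ref.upper(), obs))
    return columns


# --- minimal VCF 4.2 ----------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=neoligand
##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Variant-supporting read count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency, percent">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            info = f"DP={c.depth};AD={c.alt_count};AF={c.vaf:.6g}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"VCF line {lineno}: expected 8 fields")
            chrom, pos_s, _id, ref, alt, _qual, _filt, info = fields[:8]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            try:
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=int(pos_s),
                        ref=ref,
                        alt=alt,
                        depth=int(kv["DP"]),
                        alt_count=int(kv["AD"]),
                        vaf=float(kv["AF"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"VCF line {lineno}: {exc}") from exc
    return calls
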