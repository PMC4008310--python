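"""FASTA input, full-length ORF validation and filtering, positional slices.

A *full-length ORF* here is a coding sequence that starts with AUG, ends with
one of UAA/UAG/UGA, has length divisible by 3 and no internal stop codon.
Transcriptome-derived sets are additionally filtered for minimum length,
expression level (RPKM) and agreement with the length of a homologous
protein-coding sequence, mirroring standard quality filtering of assembled
mRNA before codon-usage analysis.

All sequences are normalised to the RNA alphabet (T -> U) on input; any
non-ACGU letter (IUPAC ambiguity codes included) is treated as N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import START_CODON, STOP_CODONS

log = logging.getLogger(__name__)

_RNA = frozenset("ACGU")
_STOPS = frozenset(STOP_CODONS)

#: fixed order in which exclusion rules are applied by filter_pipeline
FILTER_RULES = (
    "not_full_length",
    "ambiguous_nucleotide",
    "too_short",
    "internal_stop",
    "low_expression",
    "length_ratio_out_of_band",
)


def _normalise(nt: str) -> str:
    nt = nt.upper().replace("T", "U")
    if not set(nt) <= _RNA | {"N"}:
        nt = "".join(b if b in _RNA else "N" for b in nt)
    return nt


@dataclass(frozen=True)
class RawSequence:
    """One input record: an mRNA or CDS with optional expression metadata."""

    id: str
    nucleotides: str
    rpkm: float | None = None
    homolog_length_bp: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.nucleotides:
            raise ValueError(f"{self.id}: empty sequence")
        object.__setattr__(self, "nucleotides", _normalise(self.nucleotides))

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class CodingSequence:
    """A validated full-length ORF, stored as RNA codons (start and stop included)."""

    id: str
    codons: tuple[str, ...]
    rpkm: float | None = None
    homolog_length_bp: int | None = None

    @property
    def length_bp(self) -> int:
        return 3 * len(self.codons)

    @property
    def internal_codons(self) -> tuple[str, ...]:
        """Codons between the start AUG and the stop (both excluded)."""
        return self.codons[1:-1]


@dataclass
class FilterReport:
    input_count: int = 0
    kept_count: int = 0
    not_full_length: int = 0
    too_short: int = 0
    internal_stop: int = 0
    ambiguous_nucleotide: int = 0
    low_expression: int = 0
    length_ratio_out_of_band: int = 0

    def exclusions(self) -> dict[str, int]:
        return {rule: getattr(self, rule) for rule in FILTER_RULES}

    def balances(self) -> bool:
        return self.input_count == self.kept_count + sum(self.exclusions().values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_count", self.input_count), ("kept_count", self.kept_count)]
        rows += list(self.exclusions().items())
        return pd.DataFrame(rows, columns=["key", "count"])


@dataclass(frozen=True)
class PositionalSlice:
    """All codons observed at one position label, pooled across sequences.

    ``cod_1`` is the codon immediately after the start AUG; ``cod_-1`` the
    codon immediately before the stop.
    """

    position_label: str
    codons: tuple[str, ...]

    @property
    def index(self) -> int:
        return int(self.position_label.split("_", 1)[1])


def read_fasta(path: str | Path) -> list[RawSequence]:
    """Read a FASTA file into RawSequence records (T mapped to U, upper-cased).

    Ids are the first whitespace-delimited token of the header. Duplicate ids
    are kept with a warning; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            log.warning("duplicate FASTA id %r kept", rec.id)
        seen.add(rec.id)
        records.append(RawSequence(id=rec.id, nucleotides=str(rec.seq)))
    if not records:
        log.warning("no sequences found in %s", path)
    return records


def write_fasta(seqs: Iterable[RawSequence | CodingSequence], path: str | Path) -> None:
    recs = []
    for s in seqs:
        nt = s.nucleotides if isinstance(s, RawSequence) else "".join(s.codons)
        recs.append(SeqRecord(Seq(nt), id=s.id, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_two_column_table(path: str | Path, value_type=float) -> dict[str, float]:
    """Read a 2-column tab-separated table with a header line into a dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns")
    return {str(k): value_type(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def attach_metadata(
    seqs: Sequence[RawSequence],
    rpkm: Mapping[str, float] | None = None,
    homolog_lengths: Mapping[str, int] | None = None,
) -> list[RawSequence]:
    """Return copies of *seqs* with RPKM / homolog-length fields filled in."""
    out = []
    for s in seqs:
        out.append(
            replace(
                s,
                rpkm=rpkm.get(s.id, s.rpkm) if rpkm else s.rpkm,
                homolog_length_bp=(
                    homolog_lengths.get(s.id, s.homolog_length_bp)
                    if homolog_lengths
                    else s.homolog_length_bp
                ),
            )
        )
    return out


def validate_orf(seq: RawSequence) -> tuple[CodingSequence | None, str | None]:
    """Validate a full-length ORF; returns ``(coding_sequence, None)`` or
    ``(None, reason)`` with the first violated rule.

    Rule order: frame/start/stop (``not_full_length``), then
    ``ambiguous_nucleotide``, then ``internal_stop``.
    """
    nt = seq.nucleotides
    if len(nt) % 3 != 0 or len(nt) < 6:
        return None, "not_full_length"
    codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
    if codons[0] != START_CODON or codons[-1] not in _STOPS:
        return None, "not_full_length"
    if "N" in nt:
        return None, "ambiguous_nucleotide"
    if any(c in _STOPS for c in codons[:-1]):
        return None, "internal_stop"
    return (
        CodingSequence(
            id=seq.id,
            codons=codons,
            rpkm=seq.rpkm,
            homolog_length_bp=seq.homolog_length_bp,
        ),
        None,
    )


def apply_quality_filters(
    seqs: Sequence[CodingSequence],
    min_length_bp: int = 301,
    min_rpkm: float | None = 10.0,
    length_band: tuple[float, float] = (0.95, 1.05),
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the length / expression / homolog-length-ratio filters.

    Keeps sequences with ``length_bp >= min_length_bp`` (the default 301
    excludes sequences of at most 300 bp), ``rpkm >= min_rpkm`` (disabled by
    passing ``min_rpkm=None``; a missing RPKM counts as low expression when
    the filter is on), and length ratio to the homolog within the inclusive
    band. Sequences without a homolog length pass the ratio filter.
    """
    if min_length_bp < 0 or (min_rpkm is not None and min_rpkm < 0):
        raise ValueError("thresholds must be non-negative")
    lo, hi = length_band
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid length band {length_band}")
    report = FilterReport(input_count=len(seqs))
    kept = []
    for s in seqs:
        if s.length_bp < min_length_bp:
            report.too_short += 1
        elif min_rpkm is not None and (s.rpkm is None or s.rpkm < min_rpkm):
            if s.rpkm is None:
                log.warning("%s: no RPKM value; excluded as low_expression", s.id)
            report.low_expression += 1
        elif s.homolog_length_bp is not None and not (
            lo <= s.length_bp / s.homolog_length_bp <= hi
        ):
            report.length_ratio_out_of_band += 1
        else:
            kept.append(s)
    report.kept_count = len(kept)
    return kept, report


def filter_pipeline(
    seqs: Sequence[RawSequence],
    min_length_bp: int = 301,
    min_rpkm: float | None = 10.0,
    length_band: tuple[float, float] = (0.95, 1.05),
) -> tuple[list[CodingSequence], FilterReport]:
    """Validate and filter raw sequences in one pass with a fixed rule order.

    The first matching rule wins, in the order of :data:`FILTER_RULES`, so the
    report is reproducible regardless of input order.
    """
    if min_length_bp < 0 or (min_rpkm is not None and min_rpkm < 0):
        raise ValueError("thresholds must be non-negative")
    lo, hi = length_band
    report = FilterReport(input_count=len(seqs))
    kept: list[CodingSequence] = []
    for raw in seqs:
        nt = raw.nucleotides
        full = (
            len(nt) % 3 == 0
            and len(nt) >= 6
            and nt[:3] == START_CODON
            and nt[-3:] in _STOPS
        )
        if not full:
            report.not_full_length += 1
            continue
        if "N" in nt:
            report.ambiguous_nucleotide += 1
            continue
        if len(nt) < min_length_bp:
            report.too_short += 1
            continue
        codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
        if any(c in _STOPS for c in codons[:-1]):
            report.internal_stop += 1
            continue
        if min_rpkm is not None and (raw.rpkm is None or raw.rpkm < min_rpkm):
            report.low_expression += 1
            continue
        if raw.homolog_length_bp is not None and not (
            lo <= len(nt) / raw.homolog_length_bp <= hi
        ):
            report.length_ratio_out_of_band += 1
            continue
        kept.append(
            CodingSequence(
                id=raw.id,
                codons=codons,
                rpkm=raw.rpkm,
                homolog_length_bp=raw.homolog_length_bp,
            )
        )
    report.kept_count = len(kept)
    return kept, report


def positional_slices(
    seqs: Sequence[CodingSequence], depth: int = 50
) -> list[PositionalSlice]:
    """Pool codons by position: cod_1..cod_depth from the 5' end (after the
    start AUG) and cod_-1..cod_-depth from the 3' end (before the stop).

    A sequence with fewer than ``depth`` internal codons contributes only to
    the positions it possesses; start and stop codons never appear in any
    slice.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    fwd: list[list[str]] = [[] for _ in range(depth)]
    rev: list[list[str]] = [[] for _ in range(depth)]
    for s in seqs:
        internal = s.internal_codons
        for k in range(min(depth, len(internal))):
            fwd[k].append(internal[k])
            rev[k].append(internal[len(internal) - 1 - k])
    slices = [
        PositionalSlice(f"cod_{k + 1}", tuple(codons))
        for k, codons in enumerate(fwd)
        if codons
    ]
    slices += [
        PositionalSlice(f"cod_-{k + 1}", tuple(codons))
        for k, codons in enumerate(rev)
        if codons
    ]
    return slices
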