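"""Single-codon usage indices: counts, frequencies, GC partitions, RSCU,
ENC, CAI, the NCG:NCC ratio and high-frequency codons.

Definitions
-----------
RSCU (relative synonymous codon usage) of codon j in a family of size k with
counts x_1..x_k is ``x_j / mean(x)``; the family sums to k and 1 means the
codon takes exactly its equal share.

ENC (effective number of codons) follows Wright: within each amino-acid
family with codon tally n >= 2 the homozygosity is
``F = (n * sum(p_i^2) - 1) / (n - 1)``, the F values are averaged per
degeneracy class (2-, 3-, 4-, 6-fold) and
``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, clamped at 61. 20 means one codon
per amino acid; 61 means perfectly even usage.

CAI (codon adaptation index) follows Sharp & Li: from a reference count
table each codon gets a relative adaptiveness ``w = RSCU / RSCU_max`` within
its family, and a gene's CAI is the geometric mean of w over its codons,
with AUG, UGG and stops excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import ALL_CODONS, STANDARD_CODE, GeneticCode
from .orf_io import CodingSequence

log = logging.getLogger(__name__)

_GC = frozenset("GC")


@dataclass
class CodonCountTable:
    """Counts for all 64 codons (zeros allowed)."""

    counts: dict[str, int]
    provenance: str = "pooled"

    def __post_init__(self):
        full = {c: 0 for c in ALL_CODONS}
        for codon, x in self.counts.items():
            if codon not in full:
                raise ValueError(f"unknown codon {codon!r}")
            if x < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = int(x)
        self.counts = full

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    @classmethod
    def from_codons(cls, codons: Iterable[str], provenance: str = "pooled"):
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        return cls(counts, provenance=provenance)

    def family_total(self, aa: str, code: GeneticCode = STANDARD_CODE) -> int:
        return sum(self.counts[c] for c in code.families[aa])


@dataclass(frozen=True)
class GCPartitions:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float | None


@dataclass
class FamilyHomozygosity:
    """Wright's per-family homozygosity F and its per-degeneracy-class means."""

    per_family: dict[str, tuple[int, float]]  # aa -> (n, F), only n >= 2
    class_means: dict[int, float]
    missing_classes: tuple[int, ...] = ()


@dataclass
class CAIWeights:
    """Relative adaptiveness w per codon; family maxima are exactly 1.

    AUG, UGG and stop codons carry no weight. Codons of families absent from
    the reference are excluded (missing keys), not zero.
    """

    weights: dict[str, float]
    reference: str = "unspecified"

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.weights


def count_codons(
    seqs: Sequence[CodingSequence],
    exclude_start: bool = True,
    exclude_stop: bool = True,
    provenance: str = "pooled",
) -> CodonCountTable:
    """Pool codon counts over sequences, by default dropping the start AUG
    and the terminal stop of each ORF (internal AUGs are counted)."""
    counts: dict[str, int] = {}
    for s in seqs:
        codons = s.codons
        if exclude_start:
            codons = codons[1:]
        if exclude_stop:
            codons = codons[:-1]
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
    return CodonCountTable(counts, provenance=provenance)


def codon_frequencies_permille(table: CodonCountTable) -> dict[str, float]:
    """Occurrence frequency of each of the 64 codons in per-mille (sums to 1000)."""
    n = table.n
    if n == 0:
        raise ValueError("empty count table")
    return {c: 1000.0 * x / n for c, x in table.counts.items()}


def gc_partitions(
    source: CodonCountTable | Sequence[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
) -> GCPartitions:
    """GC content overall and by codon position; GC3s restricts position 3 to
    synonymous codons (AUG, UGG and stops excluded from numerator and
    denominator)."""
    if not isinstance(source, CodonCountTable):
        source = count_codons(source, exclude_start=False, exclude_stop=False)
    n = source.n
    if n == 0:
        raise ValueError("empty count table")
    gc_pos = [0, 0, 0]
    syn_n = syn_gc = 0
    syn = set(code.synonymous_codons)
    for codon, x in source.counts.items():
        if x == 0:
            continue
        for i in range(3):
            if codon[i] in _GC:
                gc_pos[i] += x
        if codon in syn:
            syn_n += x
            if codon[2] in _GC:
                syn_gc += x
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    gc3s = syn_gc / syn_n if syn_n else None
    return GCPartitions(gc=(gc1 + gc2 + gc3) / 3, gc1=gc1, gc2=gc2, gc3=gc3, gc3s=gc3s)


def rscu(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """RSCU per codon, including the stop family; families with zero total
    are reported as missing (absent keys), not as 0."""
    out: dict[str, float] = {}
    for aa, fam in code.families.items():
        total = sum(table.counts[c] for c in fam)
        if total == 0:
            continue
        k = len(fam)
        for c in fam:
            out[c] = table.counts[c] * k / total
    return out


def family_share(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Each codon's fraction of its synonymous family's total count."""
    out: dict[str, float] = {}
    for aa, fam in code.families.items():
        total = sum(table.counts[c] for c in fam)
        if total == 0:
            continue
        for c in fam:
            out[c] = table.counts[c] / total
    return out


def family_homozygosity(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> FamilyHomozygosity:
    per_family: dict[str, tuple[int, float]] = {}
    by_class: dict[int, list[float]] = {}
    for k, aas in code.degeneracy_classes.items():
        for aa in aas:
            fam = code.families[aa]
            n = sum(table.counts[c] for c in fam)
            if n < 2:
                continue
            sum_p2 = sum((table.counts[c] / n) ** 2 for c in fam)
            f = (n * sum_p2 - 1) / (n - 1)
            per_family[aa] = (n, f)
            by_class.setdefault(k, []).append(f)
    class_means = {k: float(np.mean(fs)) for k, fs in by_class.items()}
    missing = tuple(k for k in code.degeneracy_classes if k not in class_means)
    return FamilyHomozygosity(per_family, class_means, missing)


def enc(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> float | None:
    """Wright's effective number of codons, clamped at 61; None when a
    degeneracy class cannot be estimated.

    A missing 3-fold class is substituted by ``(F2 + F4) / 2`` per Wright's
    recommendation; any other missing class (or a zero class mean, possible
    only in pathological tiny tables) leaves ENC undefined.
    """
    fh = family_homozygosity(table, code)
    fbar = dict(fh.class_means)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    contributions = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    value = 2.0
    for k, mult in contributions.items():
        if k not in fbar or fbar[k] <= 0:
            log.debug("ENC undefined: degeneracy class %d unavailable", k)
            return None
        value += mult / fbar[k]
    return min(value, 61.0)


def expected_enc(gc3s: float) -> float:
    """Expected ENC for a gene under mutational GC3s pressure alone:
    ``2 + s + 29 / (s^2 + (1 - s)^2)``; maximum 60.5 at s = 0.5."""
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError("gc3s must be within [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def cai_weights(
    reference: CodonCountTable,
    pseudo_count: float = 0.5,
    code: GeneticCode = STANDARD_CODE,
    reference_name: str = "unspecified",
) -> CAIWeights:
    """Sharp & Li relative adaptiveness from a reference count table.

    Zero-count codons in a nonzero family receive *pseudo_count* before
    forming ``w = x / x_max``, so CAI never collapses to 0; families wholly
    absent from the reference are excluded from CAI.
    """
    if reference.n == 0:
        raise ValueError("empty reference table")
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    weights: dict[str, float] = {}
    for aa, fam in code.families.items():
        if aa in ("*", *code.single_codon_aas):
            continue
        xs = {c: reference.counts[c] for c in fam}
        if sum(xs.values()) == 0:
            log.warning("family %s absent from CAI reference; excluded", aa)
            continue
        adj = {c: (x if x > 0 else pseudo_count) for c, x in xs.items()}
        x_max = max(adj.values())
        for c, x in adj.items():
            weights[c] = x / x_max
    log.info("CAI weights from reference %r (%d codons)", reference_name, len(weights))
    return CAIWeights(weights, reference=reference_name)


def cai(
    seq: CodingSequence | Iterable[str], weights: CAIWeights
) -> float | None:
    """Geometric mean of w over a gene's weighted codons (start and stop of a
    CodingSequence are dropped first); None when no codon carries a weight."""
    codons = seq.internal_codons if isinstance(seq, CodingSequence) else tuple(seq)
    log_sum = 0.0
    n = 0
    for c in codons:
        w = weights.weights.get(c)
        if w is not None:
            log_sum += math.log(w)
            n += 1
    if n == 0:
        return None
    return math.exp(log_sum / n)


def reference_from_top_rpkm(
    seqs: Sequence[CodingSequence], fraction: float = 0.05
) -> tuple[CodonCountTable, str]:
    """Pooled counts of the top *fraction* of sequences by RPKM — the default
    CAI reference set (highly expressed genes). Falls back to the whole input
    when no sequence has an RPKM value."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    with_rpkm = [s for s in seqs if s.rpkm is not None]
    if not with_rpkm:
        log.warning("no RPKM values; CAI reference = pooled input")
        return count_codons(seqs, provenance="per-gene"), "pooled-input"
    k = max(1, int(round(fraction * len(with_rpkm))))
    top = sorted(with_rpkm, key=lambda s: (-s.rpkm, s.id))[:k]
    name = f"top-rpkm:{fraction:g} ({k} sequences)"
    return count_codons(top, provenance="reference"), name


def ncg_ncc_ratio(table: CodonCountTable) -> float | None:
    """CpG-suppression index: (UCG+CCG+ACG+GCG) / (UCC+CCC+ACC+GCC).

    Low values indicate avoidance of CG dinucleotides at codon positions 2-3,
    associated with heavier DNA methylation. None when the denominator is 0.
    """
    num = sum(table.counts[n + "CG"] for n in "UCAG")
    den = sum(table.counts[n + "CC"] for n in "UCAG")
    if den == 0:
        log.warning("NCG:NCC undefined (no NCC codons)")
        return None
    return num / den


def high_frequency_codons(
    table: CodonCountTable,
    rscu_cut: float = 1.5,
    share_cut: float = 0.60,
    code: GeneticCode = STANDARD_CODE,
) -> set[str]:
    """Codons with RSCU strictly above *rscu_cut* or a family share strictly
    above *share_cut*. Singleton families (Met, Trp) and stops are not
    eligible."""
    if table.n == 0:
        raise ValueError("empty count table")
    rs = rscu(table, code)
    shares = family_share(table, code)
    out = set()
    for aa, fam in code.families.items():
        if aa == "*" or len(fam) < 2:
            continue
        for c in fam:
            if c in rs and (rs[c] > rscu_cut or shares[c] > share_cut):
                out.add(c)
    return out


def summarize_codon_table(
    table: CodonCountTable,
    weights: CAIWeights | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Single-pass per-codon summary: count, per-mille frequency, RSCU,
    family share, and (optionally) CAI weight, for all 64 codons."""
    freqs = codon_frequencies_permille(table)
    rs = rscu(table, code)
    shares = family_share(table, code)
    rows = []
    for aa, fam in code.families.items():
        for c in fam:
            rows.append(
                {
                    "codon": c,
                    "amino_acid": aa,
                    "count": table.counts[c],
                    "frequency_permille": freqs[c],
                    "rscu": rs.get(c, float("nan")),
                    "family_share": shares.get(c, float("nan")),
                    "cai_weight": (
                        weights.weights.get(c, float("nan")) if weights else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def gene_metrics(
    seqs: Sequence[CodingSequence],
    weights: CAIWeights,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-gene metrics table: n_codons, GC partitions, GC3s, ENC, CAI."""
    rows = []
    for s in seqs:
        table = count_codons([s], provenance="per-gene")
        parts = gc_partitions(table, code)
        rows.append(
            {
                "id": s.id,
                "n_codons": table.n,
                "gc": parts.gc,
                "gc1": parts.gc1,
                "gc2": parts.gc2,
                "gc3": parts.gc3,
                "gc3s": parts.gc3s,
                "enc": enc(table, code),
                "cai": cai(s, weights),
            }
        )
    return pd.DataFrame(rows)
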