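"""Codon-pair bias: counting pairs at 0-8 intervening codons, testing
observed against expected frequency with the Audic-Claverie statistic, and
classifying preferred / avoided pairs.

The expected frequency of a pair is the product of the two codons' marginal
frequencies among the 61 sense codons (internal codons only: the start AUG
and the stop codon never enter the counts), so a preferred pair is one used
far more often than independence predicts. The Audic-Claverie test is the
exact conditional test for a count observed in one library against a count
in an equal-sized library; here the rounded expected count plays the second
library's part (N2/N1 = 1), which reduces the conditional distribution of
the observed count y given the expected count x to a negative binomial:
``p(y | x) = C(x + y, y) / 2^(x + y + 1)``. The reported p is the two-sided
``min(1, 2 * min(lower tail, upper tail))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .codon_metrics import CodonCountTable
from .genetic_code import STANDARD_CODE, GeneticCode
from .orf_io import CodingSequence

log = logging.getLogger(__name__)

P_FLOOR = 1e-10


@dataclass
class PairCountTable:
    """Counts of ordered codon pairs at a fixed separation.

    ``separation`` is the number of intervening codons (0 = neighboring).
    Only pairs lying within a single ORF's internal codons are counted, so
    the table covers the 61x61 sense-codon pairs.
    """

    separation: int
    counts: dict[tuple[str, str], int]
    m: int

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.counts.get(pair, 0)


@dataclass(frozen=True)
class PairBiasRecord:
    first: str
    second: str
    separation: int
    observed_freq: float
    expected_freq: float
    ratio: float
    p_value: float  # floored at P_FLOOR for reporting
    classification: str  # preferred | avoided | unbiased
    degenerate: bool = False  # expected frequency 0; excluded from classification


@dataclass(frozen=True)
class HighFrequencyPair:
    first: str
    second: str
    second_aa: str
    count: int
    context_total: int
    share: float
    fold_over_mean: float


def count_pairs(
    seqs: Sequence[CodingSequence],
    separation: int = 0,
    max_separation: int = 8,
) -> PairCountTable:
    """Count ordered codon pairs with *separation* intervening codons over the
    internal codons of each ORF (start and stop excluded).

    A sequence with L internal codons contributes ``max(0, L - separation - 1)``
    pairs.
    """
    if not 0 <= separation <= max_separation:
        raise ValueError(
            f"separation must be within [0, {max_separation}], got {separation}"
        )
    counts: dict[tuple[str, str], int] = {}
    m = 0
    step = separation + 1
    for s in seqs:
        internal = s.internal_codons
        for t in range(len(internal) - step):
            pair = (internal[t], internal[t + step])
            counts[pair] = counts.get(pair, 0) + 1
            m += 1
    return PairCountTable(separation=separation, counts=counts, m=m)


def expected_codon_frequencies(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Marginal frequency of each of the 61 sense codons; the table should
    hold internal-codon counts (start and stop codons excluded)."""
    total = sum(table.counts[c] for c in code.sense_codons)
    if total == 0:
        raise ValueError("no sense-codon counts")
    return {c: table.counts[c] / total for c in code.sense_codons}


def expected_pair_frequency(f_first: float, f_second: float) -> float:
    """Independence expectation: the product of the marginal frequencies."""
    return f_first * f_second


def audic_claverie_p(
    observed_count: int, expected_count: float, floor: float | None = None
) -> float:
    """Two-sided Audic-Claverie p for an observed count against a (possibly
    non-integer) expected count, in equal-size pseudo-libraries.

    The expected count is rounded to the nearest integer x; given x the
    observed count follows ``NegBin(x + 1, 1/2)``, and
    ``p = min(1, 2 * min(P(Y <= y), P(Y >= y)))``. When *floor* is given the
    returned value is floored there (reporting convention); pass None for
    the raw p.
    """
    if observed_count < 0 or expected_count < 0:
        raise ValueError("counts must be non-negative")
    p = float(
        _ac_p_vector(np.asarray([observed_count]), np.asarray([expected_count]))[0]
    )
    return max(p, floor) if floor is not None else p


def _ac_p_vector(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    x = np.rint(expected).astype(np.int64)
    y = np.asarray(observed, dtype=np.int64)
    lower = nbinom.cdf(y, x + 1, 0.5)
    upper = nbinom.sf(y - 1, x + 1, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def classify_pairs(
    pairs: PairCountTable,
    codon_freqs: Mapping[str, float],
    alpha: float = 0.01,
    fold: float = 2.0,
    floor: float = P_FLOOR,
    code: GeneticCode = STANDARD_CODE,
) -> list[PairBiasRecord]:
    """Classify all 61x61 sense-codon pairs as preferred / avoided / unbiased.

    preferred: p < alpha and observed/expected > fold;
    avoided:   p < alpha and observed/expected < 1/fold.
    Pairs with expected frequency 0 are flagged degenerate and left
    unbiased-by-convention. Classification uses the raw p; the stored
    p_value is floored at *floor* for reporting.
    """
    if pairs.m <= 0:
        raise ValueError("empty pair table")
    codons = code.sense_codons
    k = len(codons)
    f = np.array([codon_freqs[c] for c in codons])
    obs = np.zeros((k, k), dtype=np.int64)
    index = {c: i for i, c in enumerate(codons)}
    for (a, b), x in pairs.counts.items():
        if a in index and b in index:
            obs[index[a], index[b]] = x
    exp_freq = np.outer(f, f)
    obs_freq = obs / pairs.m
    exp_count = exp_freq * pairs.m
    p_raw = _ac_p_vector(obs.ravel(), exp_count.ravel()).reshape(k, k)

    records = []
    for i, a in enumerate(codons):
        for j, b in enumerate(codons):
            ef = exp_freq[i, j]
            degenerate = ef == 0.0
            ratio = obs_freq[i, j] / ef if not degenerate else float("nan")
            if degenerate:
                cls = "unbiased"
            elif p_raw[i, j] < alpha and ratio > fold:
                cls = "preferred"
            elif p_raw[i, j] < alpha and ratio < 1.0 / fold:
                cls = "avoided"
            else:
                cls = "unbiased"
            records.append(
                PairBiasRecord(
                    first=a,
                    second=b,
                    separation=pairs.separation,
                    observed_freq=obs_freq[i, j],
                    expected_freq=ef,
                    ratio=ratio,
                    p_value=max(p_raw[i, j], floor),
                    classification=cls,
                    degenerate=degenerate,
                )
            )
    return records


def pair_records_to_frame(records: Sequence[PairBiasRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    with np.errstate(divide="ignore"):
        df["log2_ratio"] = np.log2(df["ratio"].to_numpy())
    return df


def junction_dinucleotide_summary(
    records: Sequence[PairBiasRecord],
) -> pd.DataFrame:
    """Group neighboring-pair records by the junction dinucleotide (last base
    of the first codon | first base of the second codon) and summarise the
    observed/expected ratios of each of the 16 cells."""
    rows = {}
    for r in records:
        if r.separation != 0:
            raise ValueError("junction summary is defined for neighboring pairs (d=0)")
        key = f"{r.first[2]}|{r.second[0]}"
        rows.setdefault(key, []).append(r.ratio)
    out = []
    for key in sorted(rows):
        ratios = np.array(rows[key])
        ratios = ratios[~np.isnan(ratios)]
        out.append(
            {
                "junction": key,
                "n_pairs": len(rows[key]),
                "mean_ratio": float(np.mean(ratios)) if ratios.size else float("nan"),
                "median_ratio": float(np.median(ratios)) if ratios.size else float("nan"),
                "min_ratio": float(np.min(ratios)) if ratios.size else float("nan"),
                "max_ratio": float(np.max(ratios)) if ratios.size else float("nan"),
            }
        )
    return pd.DataFrame(out)


def high_frequency_pairs(
    pairs: PairCountTable,
    fold_cut: float = 1.5,
    share_cut: float = 0.60,
    code: GeneticCode = STANDARD_CODE,
) -> list[HighFrequencyPair]:
    """High-frequency neighboring pairs, evaluated per (first codon, second
    amino acid) context.

    Within the context of first codon X followed by any codon of a
    synonymous family Y_1..Y_i (i >= 2), pair X-Y_j qualifies when its count
    strictly exceeds ``fold_cut`` times the context mean (total / i) or its
    share of the context total strictly exceeds *share_cut*.
    """
    if pairs.m <= 0:
        raise ValueError("empty pair table")
    out = []
    for first in code.sense_codons:
        for aa, fam in code.families.items():
            if aa == "*" or len(fam) < 2:
                continue
            counts = {y: pairs.counts.get((first, y), 0) for y in fam}
            total = sum(counts.values())
            if total == 0:
                continue
            mean = total / len(fam)
            for y, x in counts.items():
                if x > fold_cut * mean or x / total > share_cut:
                    out.append(
                        HighFrequencyPair(
                            first=first,
                            second=y,
                            second_aa=aa,
                            count=x,
                            context_total=total,
                            share=x / total,
                            fold_over_mean=x / mean,
                        )
                    )
    return out
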