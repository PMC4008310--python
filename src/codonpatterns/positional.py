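"""Position-dependent codon usage: positional CAI profiles along the first
and last 50 codons, codon bias immediately after the start AUG versus after
internal AUGs, and the 13-nt Kozak window (n9AUGn) around the start codon.

Codon adaptation typically rises over the first ~50 codons of plant ORFs (a
translational "ramp"), and the codon right after the start AUG is the most
biased position because it overlaps the Kozak initiation context (a G at +4
favours initiation). Both effects are measured here with the same
observed-vs-expected machinery used for codon pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CAIWeights, CodonCountTable, count_codons
from .codon_pairs import P_FLOOR, _ac_p_vector, expected_codon_frequencies
from .genetic_code import BASES, START_CODON, STANDARD_CODE, GeneticCode
from .orf_io import CodingSequence, PositionalSlice, RawSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionalFit:
    slope: float
    intercept: float
    r: float
    p: float
    positions: tuple[int, ...]


@dataclass(frozen=True)
class StartContextRecord:
    codon: str
    focal: str  # after_start_AUG | after_internal_AUG
    observed_freq: float
    expected_freq: float
    ratio: float
    p_value: float
    classification: str


@dataclass
class KozakWindowMatrix:
    """Position frequency matrix of the 13-nt window -9..-1, AUG, +1.

    ``counts`` is 13 x 4 over (A, C, G, U); N-padded or undetermined bases
    are simply absent from their column. ``information_content`` is
    2 - H(column) in bits against the uniform 4-letter background.
    """

    counts: pd.DataFrame  # index: position labels, columns: A C G U
    n_windows: int

    POSITIONS = tuple(
        [f"-{i}" for i in range(9, 0, -1)] + ["AUG_1", "AUG_2", "AUG_3", "+1"]
    )

    @property
    def information_content(self) -> pd.Series:
        ic = {}
        for pos, row in self.counts.iterrows():
            total = row.sum()
            if total == 0:
                ic[pos] = 0.0
                continue
            p = row[row > 0] / total
            ic[pos] = 2.0 + float((p * np.log2(p)).sum())
        return pd.Series(ic, name="information_content")

    def consensus(self, threshold: float = 0.25) -> str:
        """IUPAC consensus: at each position the degenerate code of all bases
        with relative frequency >= threshold (uniform expectation)."""
        iupac = {
            frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
            frozenset("U"): "U", frozenset("AG"): "R", frozenset("CU"): "Y",
            frozenset("GU"): "K", frozenset("AC"): "M", frozenset("CG"): "S",
            frozenset("AU"): "W", frozenset("CGU"): "B", frozenset("AGU"): "D",
            frozenset("ACU"): "H", frozenset("ACG"): "V", frozenset("ACGU"): "N",
        }
        out = []
        for pos, row in self.counts.iterrows():
            total = row.sum()
            if total == 0:
                out.append("N")
                continue
            picked = frozenset(b for b in "ACGU" if row[b] / total >= threshold)
            out.append(iupac.get(picked, "N") if picked else "N")
        return "".join(out)


def positional_cai(
    slices: Sequence[PositionalSlice], weights: CAIWeights
) -> pd.DataFrame:
    """Positional CAI profile: per position label, the geometric mean of w
    over the pooled codons at that position (codons without a weight - AUG,
    UGG, stops - count toward n but not the mean)."""
    if not slices:
        raise ValueError("no positional slices")
    rows = []
    for sl in slices:
        log_sum = 0.0
        n_weighted = 0
        for c in sl.codons:
            w = weights.weights.get(c)
            if w is not None:
                log_sum += math.log(w)
                n_weighted += 1
        value = math.exp(log_sum / n_weighted) if n_weighted else float("nan")
        rows.append(
            {
                "position": sl.position_label,
                "index": sl.index,
                "n": len(sl.codons),
                "n_weighted": n_weighted,
                "positional_cai": value,
            }
        )
    return pd.DataFrame(rows)


def fit_positional_trend(
    profile: pd.DataFrame, positions: Iterable[int] = range(2, 51)
) -> PositionalFit:
    """Ordinary least squares of positional CAI on codon position (default:
    positions 2-50 of the 5' profile), with Pearson r and its two-sided p."""
    wanted = set(positions)
    sub = profile[(profile["index"].isin(wanted)) & profile["positional_cai"].notna()]
    if len(sub) < 3:
        raise ValueError("need at least 3 defined positions to fit a trend")
    y = sub["positional_cai"].to_numpy()
    if np.ptp(y) == 0.0:
        # perfectly flat profile: no trend, by convention r = 0
        return PositionalFit(
            slope=0.0, intercept=float(y[0]), r=0.0, p=1.0,
            positions=tuple(sorted(sub["index"])),
        )
    res = stats.linregress(sub["index"], sub["positional_cai"])
    return PositionalFit(
        slope=res.slope,
        intercept=res.intercept,
        r=res.rvalue,
        p=res.pvalue,
        positions=tuple(sorted(sub["index"])),
    )


def _focal_codons(seqs: Sequence[CodingSequence], focal: str) -> list[str]:
    out = []
    if focal == "after_start_AUG":
        for s in seqs:
            internal = s.internal_codons
            if internal:
                out.append(internal[0])
    elif focal == "after_internal_AUG":
        for s in seqs:
            internal = s.internal_codons
            for t, c in enumerate(internal[:-1]):
                if c == START_CODON:
                    out.append(internal[t + 1])
    else:
        raise ValueError(f"unknown focal position {focal!r}")
    return out


def start_context_bias(
    seqs: Sequence[CodingSequence],
    focal: str = "after_start_AUG",
    alpha: float = 0.01,
    fold: float = 2.0,
    floor: float = P_FLOOR,
    code: GeneticCode = STANDARD_CODE,
) -> list[StartContextRecord]:
    """Observed vs expected codon usage at a focal position: the codon after
    the start AUG, or after every non-start internal AUG (a gene contributes
    one observation per internal AUG).

    The expected distribution is the marginal sense-codon frequency over the
    same sequences' internal codons; classification follows the pair rule
    (Audic-Claverie p < alpha and ratio > fold or < 1/fold).
    """
    focal_codons = [c for c in _focal_codons(seqs, focal) if not code.is_stop(c)]
    if not focal_codons:
        raise ValueError(f"no occurrences of focal position {focal!r}")
    m = len(focal_codons)
    background = count_codons(seqs, provenance="pooled")
    expected = expected_codon_frequencies(background, code)
    obs_counts = {c: 0 for c in code.sense_codons}
    for c in focal_codons:
        obs_counts[c] += 1

    codons = code.sense_codons
    obs = np.array([obs_counts[c] for c in codons])
    exp_freq = np.array([expected[c] for c in codons])
    p_raw = _ac_p_vector(obs, exp_freq * m)
    records = []
    for i, c in enumerate(codons):
        ef = exp_freq[i]
        of = obs[i] / m
        ratio = of / ef if ef > 0 else float("nan")
        if ef > 0 and p_raw[i] < alpha and ratio > fold:
            cls = "preferred"
        elif ef > 0 and p_raw[i] < alpha and ratio < 1.0 / fold:
            cls = "avoided"
        else:
            cls = "unbiased"
        records.append(
            StartContextRecord(
                codon=c,
                focal=focal,
                observed_freq=of,
                expected_freq=ef,
                ratio=ratio,
                p_value=max(p_raw[i], floor),
                classification=cls,
            )
        )
    return records


def start_context_to_frame(records: Sequence[StartContextRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def nucleotide_class_summary(
    records: Sequence[StartContextRecord], patterns: Iterable[str]
) -> dict[str, float]:
    """Aggregate focal-position records into nucleotide classes given as
    3-letter patterns over {A, C, G, U, n} ('n' = any base), e.g. 'Gnn' for
    codons starting with G or 'nCG'. Returns the aggregated
    observed/expected ratio per pattern."""
    out = {}
    for pattern in patterns:
        if len(pattern) != 3 or any(ch not in "ACGUn" for ch in pattern):
            raise ValueError(f"invalid pattern {pattern!r}")
        obs = exp = 0.0
        for r in records:
            if all(p == "n" or p == b for p, b in zip(pattern, r.codon)):
                obs += r.observed_freq
                exp += r.expected_freq
        out[pattern] = obs / exp if exp > 0 else float("nan")
    return out


def kozak_window_matrix(
    mrnas: Sequence[RawSequence], start_offsets: Mapping[str, int]
) -> KozakWindowMatrix:
    """Position frequency matrix of the 13 nucleotides n9AUGn around each
    annotated start codon.

    *start_offsets* maps sequence id to the 0-based offset of the A of the
    start AUG within the mRNA. Windows with fewer than 9 upstream bases are
    N-padded; N never enters the counts. Records whose annotated start does
    not read AUG (or lies outside the sequence) are skipped with a warning.
    """
    counts = np.zeros((13, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate("ACGU")}
    n_windows = 0
    for s in mrnas:
        if s.id not in start_offsets:
            continue
        start = start_offsets[s.id]
        nt = s.nucleotides
        if start < 0 or start + 4 > len(nt):
            log.warning("%s: start offset %d outside sequence; skipped", s.id, start)
            continue
        if nt[start : start + 3] != START_CODON:
            log.warning("%s: no AUG at annotated start; skipped", s.id)
            continue
        upstream = nt[max(0, start - 9) : start].rjust(9, "N")
        window = upstream + nt[start : start + 4]
        n_windows += 1
        for pos, b in enumerate(window):
            if b in base_index:
                counts[pos, base_index[b]] += 1
    frame = pd.DataFrame(
        counts, index=list(KozakWindowMatrix.POSITIONS), columns=list("ACGU")
    )
    return KozakWindowMatrix(counts=frame, n_windows=n_windows)
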