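"""Synthetic CDS datasets with controllable codon usage, neighboring-pair
coupling, positional adaptiveness ramps, start contexts and expression, so
every pipeline stage runs (and is testable) without any downloads.

The generator draws an i.i.d. amino-acid sequence per gene, then emits
codons from per-amino-acid probability vectors with three optional
modifiers: a positional ramp that mixes the family's designated preferred
codon in with weight rising along the ORF (a translational-ramp surrogate),
Markovian pair coupling that multiplies the within-family probability of a
target codon when a trigger codon sits d positions upstream, and an
override distribution for the codon right after the start AUG (a Kozak-like
start context). Pair coupling at nominal enrichment e realizes an
observed/expected ratio of roughly ``e / (1 + (e - 1) q)`` (q = the target
codon's within-family base probability), and the truth table stores this
realized value, not the nominal one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import START_CODON, STANDARD_CODE, GeneticCode
from .orf_io import CodingSequence, RawSequence

#: stop-codon usage matching the relative stop usage seen in plant
#: transcriptomes (UGA > UAA > UAG, RSCU 1.39 / 0.94 / 0.67).
DEFAULT_STOP_PROBS = {"UGA": 1.39 / 3, "UAA": 0.94 / 3, "UAG": 0.67 / 3}


@dataclass(frozen=True)
class PairRule:
    """Multiply the within-family probability of *second* by *enrichment*
    whenever *first* occurred *separation* + 1 codons upstream."""

    first: str
    second: str
    enrichment: float
    separation: int = 0

    def __post_init__(self):
        if self.enrichment <= 0:
            raise ValueError("enrichment must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass(frozen=True)
class Ramp:
    """Linear mixing weight toward each family's preferred codon: weight
    *start* at the first internal codon rising to *end* at codon *length*,
    constant thereafter."""

    start: float = 0.0
    end: float = 0.0
    length: int = 50

    def weight(self, position: int) -> float:
        if self.length <= 1:
            return self.end
        frac = min(position - 1, self.length - 1) / (self.length - 1)
        return self.start + (self.end - self.start) * frac


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic CDS set.

    Defaults emulate a filtered plant transcriptome: about a thousand
    full-length ORFs averaging ~330 internal codons, uniform amino-acid and
    within-family codon usage unless biased vectors are supplied, stop usage
    UGA > UAA > UAG, and a broad lognormal RPKM distribution.
    """

    n_genes: int = 1066
    min_codons: int = 100  # internal codons (start/stop excluded)
    max_codons: int = 560
    aa_probs: dict[str, float] | None = None  # default uniform over 20
    codon_probs: dict[str, dict[str, float]] | None = None  # aa -> codon -> p
    pair_rules: tuple[PairRule, ...] = ()
    ramp: Ramp | None = None
    start_context: dict[str, float] | None = None  # distribution over cod_1
    stop_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_PROBS)
    )
    utr_length: tuple[int, int] = (5, 80)
    utr_gc: float = 0.5
    rpkm_log_mean: float = 3.0
    rpkm_log_sigma: float = 1.5
    seed: int = 0


@dataclass
class SyntheticDataset:
    cds: list[CodingSequence]
    mrnas: list[RawSequence]
    start_offsets: dict[str, int]
    rpkm: dict[str, float]
    truth: dict


def gc3_codon_probs(
    gc3: float, code: GeneticCode = STANDARD_CODE
) -> dict[str, dict[str, float]]:
    """Within-family codon vectors whose third-position GC probability is
    exactly *gc3* in every multi-codon family (GC-ending codons share mass
    gc3, AU-ending codons share 1 - gc3)."""
    if not 0 < gc3 < 1:
        raise ValueError("gc3 must be in (0, 1)")
    out: dict[str, dict[str, float]] = {}
    for aa, fam in code.families.items():
        if aa == "*":
            continue
        gc_enders = [c for c in fam if c[2] in "GC"]
        au_enders = [c for c in fam if c[2] not in "GC"]
        probs = {}
        if not gc_enders or not au_enders:
            for c in fam:
                probs[c] = 1.0 / len(fam)
        else:
            for c in gc_enders:
                probs[c] = gc3 / len(gc_enders)
            for c in au_enders:
                probs[c] = (1 - gc3) / len(au_enders)
        out[aa] = probs
    return out


def _validate_dist(dist: Mapping[str, float], what: str) -> None:
    total = sum(dist.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"{what} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{what} has negative probabilities")


class _Emitter:
    """Precompiled per-amino-acid emission tables for fast sequential draws."""

    def __init__(self, config: GeneratorConfig, code: GeneticCode):
        self.code = code
        sense_aas = sorted(aa for aa in code.families if aa != "*")
        if config.aa_probs is None:
            self.aas = sense_aas
            self.aa_p = np.full(len(sense_aas), 1.0 / len(sense_aas))
        else:
            _validate_dist(config.aa_probs, "amino acid")
            self.aas = sorted(config.aa_probs)
            self.aa_p = np.array([config.aa_probs[a] for a in self.aas])
        self.fam: dict[str, tuple[str, ...]] = {}
        self.base: dict[str, list[float]] = {}
        self.preferred: dict[str, int] = {}
        for aa in self.aas:
            fam = code.families[aa]
            self.fam[aa] = fam
            if config.codon_probs and aa in config.codon_probs:
                dist = config.codon_probs[aa]
                _validate_dist(dist, f"codon family {aa}")
                probs = [dist.get(c, 0.0) for c in fam]
            else:
                probs = [1.0 / len(fam)] * len(fam)
            self.base[aa] = probs
            self.preferred[aa] = int(np.argmax(probs)) if max(probs) > min(probs) else 0
        # rules indexed by the amino acid of the target codon
        self.rules_by_aa: dict[str, list[tuple[str, int, float, int]]] = {}
        for rule in config.pair_rules:
            aa = code.codon_to_aa[rule.second]
            fam = code.families[aa]
            self.rules_by_aa.setdefault(aa, []).append(
                (rule.first, fam.index(rule.second), rule.enrichment, rule.separation)
            )

    def marginal(self, codon: str) -> float:
        """Base marginal probability of a codon (no ramp/coupling applied)."""
        aa = self.code.codon_to_aa[codon]
        if aa not in self.fam:
            return 0.0
        i = self.aas.index(aa)
        return self.aa_p[i] * self.base[aa][self.fam[aa].index(codon)]


def _realized_ratio(rule: PairRule, emitter: _Emitter, code: GeneticCode) -> float:
    """Analytic observed/expected ratio the Markov reweighting realizes."""
    aa = code.codon_to_aa[rule.second]
    fam = code.families[aa]
    q = emitter.base[aa][fam.index(rule.second)]
    cond = rule.enrichment * q / (1.0 + (rule.enrichment - 1.0) * q)
    p_first = emitter.marginal(rule.first)
    marginal = q * (1.0 - p_first) + cond * p_first
    return cond / marginal if marginal > 0 else float("nan")


def generate(
    config: GeneratorConfig, code: GeneticCode = STANDARD_CODE
) -> SyntheticDataset:
    """Generate a synthetic dataset; byte-identical under a fixed seed."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 2 <= config.min_codons <= config.max_codons:
        raise ValueError("need 2 <= min_codons <= max_codons")
    _validate_dist(config.stop_probs, "stop codon")
    if config.start_context is not None:
        _validate_dist(config.start_context, "start context")
        for c in config.start_context:
            if code.codon_to_aa.get(c, "*") == "*":
                raise ValueError(f"start context codon {c} is a stop or unknown")
    for rule in config.pair_rules:
        aa = code.codon_to_aa.get(rule.second, "*")
        if aa == "*" or code.codon_to_aa.get(rule.first, "*") == "*":
            raise ValueError(f"pair rule {rule} involves a stop or unknown codon")

    rng = np.random.default_rng(config.seed)
    emitter = _Emitter(config, code)
    stops = sorted(config.stop_probs)
    stop_p = np.array([config.stop_probs[s] for s in stops])
    start_ctx = None
    if config.start_context is not None:
        start_ctx = (
            sorted(config.start_context),
            np.array([config.start_context[c] for c in sorted(config.start_context)]),
        )
    utr_lo, utr_hi = config.utr_length
    utr_base_p = np.array(
        [(1 - config.utr_gc) / 2, config.utr_gc / 2, config.utr_gc / 2,
         (1 - config.utr_gc) / 2]
    )
    utr_bases = np.array(list("ACGU"))

    cds: list[CodingSequence] = []
    mrnas: list[RawSequence] = []
    start_offsets: dict[str, int] = {}
    rpkm: dict[str, float] = {}

    lengths = rng.integers(config.min_codons, config.max_codons + 1, config.n_genes)
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"synth_{g + 1:0{width}d}"
        length = int(lengths[g])
        aa_seq = rng.choice(emitter.aas, size=length, p=emitter.aa_p)
        uniforms = rng.random(length)
        chosen: list[str] = []
        for t in range(length):
            if t == 0 and start_ctx is not None:
                labels, probs = start_ctx
                u = uniforms[t]
                acc = 0.0
                pick = labels[-1]
                for lab, p in zip(labels, probs):
                    acc += p
                    if u < acc:
                        pick = lab
                        break
                chosen.append(pick)
                continue
            aa = aa_seq[t]
            fam = emitter.fam[aa]
            weights = list(emitter.base[aa])
            if config.ramp is not None:
                lam = config.ramp.weight(t + 1)
                if lam:
                    pref = emitter.preferred[aa]
                    weights = [(1 - lam) * w for w in weights]
                    weights[pref] += lam
            for first, idx, enrich, sep in emitter.rules_by_aa.get(aa, ()):
                back = t - sep - 1
                if back >= 0 and chosen[back] == first:
                    weights[idx] *= enrich
            total = sum(weights)
            u = uniforms[t] * total
            acc = 0.0
            pick = fam[-1]
            for c, w in zip(fam, weights):
                acc += w
                if u < acc:
                    pick = c
                    break
            chosen.append(pick)
        stop = stops[int(rng.choice(len(stops), p=stop_p))]
        codons = (START_CODON, *chosen, stop)
        gene_rpkm = float(
            np.exp(rng.normal(config.rpkm_log_mean, config.rpkm_log_sigma))
        )
        cds.append(CodingSequence(id=gene_id, codons=codons, rpkm=gene_rpkm))
        rpkm[gene_id] = gene_rpkm

        utr_len = int(rng.integers(utr_lo, utr_hi + 1))
        utr = "".join(rng.choice(utr_bases, size=utr_len, p=utr_base_p))
        mrna = utr + "".join(codons)
        mrnas.append(RawSequence(id=gene_id, nucleotides=mrna, rpkm=gene_rpkm))
        start_offsets[gene_id] = utr_len

    truth = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "pair_rules": [
            {
                "first": r.first,
                "second": r.second,
                "separation": r.separation,
                "nominal_enrichment": r.enrichment,
                "realized_ratio": _realized_ratio(r, emitter, code),
            }
            for r in config.pair_rules
        ],
        "ramp": (
            {"start": config.ramp.start, "end": config.ramp.end,
             "length": config.ramp.length}
            if config.ramp
            else None
        ),
        "start_context": dict(config.start_context or {}),
    }
    return SyntheticDataset(
        cds=cds, mrnas=mrnas, start_offsets=start_offsets, rpkm=rpkm, truth=truth
    )


def generate_species_panel(
    configs: Mapping[str, GeneratorConfig], code: GeneticCode = STANDARD_CODE
) -> dict[str, list[CodingSequence]]:
    """Generate one CDS set per species label (fixtures for the comparative
    analyses); each config carries its own seed."""
    if len(configs) < 2:
        raise ValueError("need at least 2 species configs")
    return {label: generate(cfg, code).cds for label, cfg in configs.items()}


def regime_panel_configs(
    regimes: Mapping[str, float],
    species_per_regime: int = 5,
    n_genes: int = 120,
    min_codons: int = 80,
    max_codons: int = 300,
    base_seed: int = 0,
) -> dict[str, GeneratorConfig]:
    """Convenience: a panel of species configs spanning GC3s regimes (e.g.
    ``{"low": 0.30, "high": 0.75}``), species within a regime differing only
    by seed plus a small GC3s jitter between 0 and 0.02."""
    configs = {}
    k = 0
    for regime, gc3 in sorted(regimes.items()):
        for i in range(species_per_regime):
            jitter = 0.02 * (i / max(1, species_per_regime - 1)) - 0.01
            configs[f"{regime}_{i + 1}"] = GeneratorConfig(
                n_genes=n_genes,
                min_codons=min_codons,
                max_codons=max_codons,
                codon_probs=gc3_codon_probs(min(max(gc3 + jitter, 0.01), 0.99)),
                seed=base_seed + k,
            )
            k += 1
    return configs
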