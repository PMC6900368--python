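"""Rare-variant prioritization cascade for candidate lipid genes.

The cascade mirrors a standard exome workup for monogenic dyslipidemia:

1. drop silent / non-coding consequences (synonymous, intronic, intergenic, UTR);
2. drop variants with weak read-depth support (default: keep depth >= 20);
3. intersect with a curated candidate-gene list (lipid metabolism + GWAS hits);
4. drop common variants (minor allele frequency > 1% in any of the configured
   population databases) — *except* variants whose pathogenicity-predictor
   consensus is predominantly damaging, which are retained as flagged
   exceptions;
5. rank survivors by predictor consensus (fraction of damaging calls), then
   meta-score, then genomic coordinate.

Predictor call vocabulary: D (damaging/deleterious), H/M (high/medium impact)
count as damaging; T (tolerated), B (benign), P (possibly damaging), L (low
impact), N (neutral) count as non-damaging; U (undetermined) is an abstention
and does not enter the consensus denominator.  A variant no predictor scores
at all (typical for in-frame indels) cannot be dismissed as benign and is
retained as an exception when its frequency alone would discard it; this is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import AnnotatedVariant, FormatError, CONSEQUENCES

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "ConsensusScore",
    "consensus_score",
    "filter_consequence",
    "filter_depth",
    "filter_genes",
    "maf_filter",
    "run_cascade",
]

EXCLUDED_CONSEQUENCES = frozenset({"synonymous", "intronic", "intergenic", "utr"})
DAMAGING_CALLS = frozenset({"D", "H", "M"})
BENIGN_CALLS = frozenset({"T", "B", "P", "L", "N"})
ABSTAIN_CALLS = frozenset({"U"})


class ConfigError(ValueError):
    """Raised for invalid filter configuration."""


@dataclass
class FilterConfig:
    """Tunable knobs of the cascade.

    ``exception_min_damaging_fraction`` is the consensus level at which a
    common variant escapes the frequency filter (default 0.5: at least half
    of the predictors that made a call said damaging).
    """

    gene_list: frozenset[str] = frozenset()
    min_depth: int = 20
    maf_cutoff: float = 0.01
    exception_min_damaging_fraction: float = 0.5
    databases: tuple[str, ...] = ("gnomad", "topmed", "exac")
    meta_score_name: str = "metasvm"
    uncalled_is_damaging: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_cutoff < 1.0):
            raise ConfigError(f"maf_cutoff must be in (0,1), got {self.maf_cutoff}")
        if isinstance(self.gene_list, (list, set, tuple)):
            self.gene_list = frozenset(self.gene_list)


@dataclass
class FilterTrace:
    """Per-stage audit: (n_in, n_out, removed variant keys)."""

    stages: dict[str, tuple[int, int, list[str]]] = field(default_factory=dict)
    exception_flags: set[str] = field(default_factory=set)
    n_null_depth: int = 0

    def record(self, name: str, before: Sequence[AnnotatedVariant],
               after: Sequence[AnnotatedVariant]) -> None:
        kept = {id(v) for v in after}
        removed = [v.key for v in before if id(v) not in kept]
        self.stages[name] = (len(before), len(after), removed)


@dataclass
class ConsensusScore:
    """Predictor consensus for one variant.

    ``fraction_damaging`` is None when no predictor made a call.
    """

    variant_key: str
    n_predictors_called: int
    n_damaging: int
    fraction_damaging: float | None
    meta_score: float | None
    rank: int | None = None


def consensus_score(variant: AnnotatedVariant,
                    meta_score_name: str = "metasvm") -> ConsensusScore:
    """Tally damaging vs non-damaging predictor calls for one variant."""
    n_called = 0
    n_damaging = 0
    for call in variant.predictor_calls.values():
        if call is None or call in ABSTAIN_CALLS:
            continue
        if call in DAMAGING_CALLS:
            n_damaging += 1
            n_called += 1
        elif call in BENIGN_CALLS:
            n_called += 1
        # any other symbol is ignored as unrecognized rather than fatal:
        # predictor vocabularies drift between annotation versions
    frac = n_damaging / n_called if n_called else None
    return ConsensusScore(
        variant_key=variant.key,
        n_predictors_called=n_called,
        n_damaging=n_damaging,
        fraction_damaging=frac,
        meta_score=variant.scores.get(meta_score_name),
    )


def filter_consequence(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Drop synonymous / intronic / intergenic / UTR variants."""
    kept = []
    for v in variants:
        if v.consequence is None or v.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence label {v.consequence!r} on {v.key}")
        if v.consequence not in EXCLUDED_CONSEQUENCES:
            kept.append(v)
    return kept


def filter_depth(variants: Iterable[AnnotatedVariant], min_depth: int = 20,
                 trace: FilterTrace | None = None) -> list[AnnotatedVariant]:
    """Keep variants with read depth >= ``min_depth``; null depth is removed
    (and counted separately on the trace)."""
    kept = []
    for v in variants:
        if v.depth is not None and v.depth < 0:
            raise FormatError(f"negative depth on {v.key}")
        if v.depth is None:
            if trace is not None:
                trace.n_null_depth += 1
            continue
        if v.depth >= min_depth:
            kept.append(v)
    return kept


def filter_genes(variants: Iterable[AnnotatedVariant],
                 gene_list: frozenset[str]) -> list[AnnotatedVariant]:
    """Intersect with the candidate-gene list."""
    return [v for v in variants if v.gene in gene_list]


def maf_filter(variant: AnnotatedVariant, config: FilterConfig,
               consensus: ConsensusScore | None = None) -> str:
    """Classify one variant against the frequency rule.

    Returns ``"keep"`` (rare or novel), ``"exception"`` (common but the
    predictor consensus is predominantly damaging, or unscoreable), or
    ``"discard"`` (common and not convincingly damaging).
    """
    top = variant.max_af(config.databases)
    if top is not None and not (0.0 <= top <= 1.0):
        raise FormatError(f"allele frequency out of range on {variant.key}: {top}")
    if top is None or top < config.maf_cutoff:
        return "keep"
    if consensus is None:
        consensus = consensus_score(variant, config.meta_score_name)
    if consensus.fraction_damaging is None:
        return "exception" if config.uncalled_is_damaging else "discard"
    if consensus.fraction_damaging >= config.exception_min_damaging_fraction:
        return "exception"
    return "discard"


def _rank_key(v: AnnotatedVariant, c: ConsensusScore) -> tuple:
    frac = c.fraction_damaging if c.fraction_damaging is not None else -1.0
    meta = c.meta_score if c.meta_score is not None else float("-inf")
    chrom = v.chrom.lstrip("chr")
    chrom_num = int(chrom) if chrom.isdigit() else 100 + hash(chrom) % 100
    return (-frac, -meta, chrom_num, v.pos)


def run_cascade(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> tuple[list[AnnotatedVariant], FilterTrace, list[ConsensusScore]]:
    """Run the full cascade and rank the survivors.

    Returns (candidates in rank order, per-stage trace, ranked consensus
    scores).  The trace accounts for every input variant: at each stage
    removed + retained partitions that stage's input.
    """
    if not config.gene_list:
        raise ConfigError("gene_list must be non-empty")
    trace = FilterTrace()

    stage1 = filter_consequence(variants)
    trace.record("consequence", list(variants), stage1)

    stage2 = filter_depth(stage1, config.min_depth, trace)
    trace.record("depth", stage1, stage2)

    stage3 = filter_genes(stage2, config.gene_list)
    trace.record("gene_list", stage2, stage3)

    scored = {id(v): consensus_score(v, config.meta_score_name) for v in stage3}
    stage4 = []
    for v in stage3:
        verdict = maf_filter(v, config, scored[id(v)])
        if verdict == "keep":
            stage4.append(v)
        elif verdict == "exception":
            stage4.append(v)
            trace.exception_flags.add(v.key)
    trace.record("maf", stage3, stage4)

    ranked = sorted(stage4, key=lambda v: _rank_key(v, scored[id(v)]))
    scores = []
    for i, v in enumerate(ranked):
        s = scored[id(v)]
        s.rank = i + 1
        scores.append(s)
    return ranked, trace, scores
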