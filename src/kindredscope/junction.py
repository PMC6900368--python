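"""Deletion-junction characterization and the in-silico multiplex PCR screen.

A large promoter/exon deletion is described by its breakpoints — the last
retained reference base on the left and the first retained base on the right
(1-based, both retained, build-tagged).  Sanger reads across the novel
adjacency reveal either a non-templated insert (bases matching neither flank)
or microhomology (identical sequence shared by the two flank termini); the
two observations are mutually exclusive.

The screening assay is a multiplex PCR with two primer pairs: one spanning
the breakpoints (amplifies only the deleted allele — on the wild-type allele
the primers are too far apart) and one internal to the deleted region
(amplifies only the wild-type allele).  Band presence/absence then genotypes
each sample: both bands = heterozygote, wild-type band only = non-carrier,
breakpoint band only = homozygous deletion, no band = assay failure.
Primer matching is exact-string on both strands; the assay logic needs
presence/absence, not amplification efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Breakpoints",
    "PrimerPair",
    "BandPattern",
    "SVGenotype",
    "AssayConfig",
    "deletion_length",
    "characterize_junction",
    "in_silico_pcr",
    "genotype_from_bands",
    "screen_cohort",
]

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class Breakpoints:
    """Deletion breakpoints: both coordinates are retained bases (1-based)."""

    chrom: str
    left_last_retained: int
    right_first_retained: int
    build: str = "hg19"
    insert_seq: str = ""

    def __post_init__(self) -> None:
        if self.right_first_retained <= self.left_last_retained + 1:
            raise ValueError(
                "not a deletion: right_first_retained must exceed "
                "left_last_retained + 1"
            )


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair, both sequences written 5'->3'."""

    name: str
    forward_seq: str
    reverse_seq: str
    expected_product_bp: int | None = None

    def __post_init__(self) -> None:
        for seq in (self.forward_seq, self.reverse_seq):
            if len(seq) < 15:
                raise ValueError(f"primer {self.name!r}: length < 15 ({seq})")
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"primer {self.name!r} contains unsupported symbols {sorted(bad)} "
                    "(ambiguity codes are not supported)"
                )


@dataclass
class BandPattern:
    sample_id: str
    product_sizes_bp: set[int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.product_sizes_bp):
            raise ValueError("band sizes must be positive")


@dataclass(frozen=True)
class SVGenotype:
    sample_id: str
    call: str  # wt/wt | wt/del | del/del | fail


@dataclass(frozen=True)
class AssayConfig:
    """Band sizes of the assay and the gel-resolution matching tolerance."""

    wt_band_bp: int = 481
    del_band_bp: int = 254
    tolerance_bp: int = 10


def deletion_length(bp: Breakpoints) -> int:
    """Number of deleted reference bases (junction insert not subtracted)."""
    return bp.right_first_retained - bp.left_last_retained - 1


def characterize_junction(
    left_flank_seq: str,
    right_flank_seq: str,
    junction_read: str,
    min_anchor: int = 10,
) -> tuple[str, int]:
    """Resolve a junction read into (non-templated insert, microhomology length).

    The read must anchor on each flank with at least ``min_anchor`` exactly
    matching bases: its prefix against the left flank's terminus, its suffix
    against the right flank's start.  Bases between the anchors that belong
    to neither flank are the insert.  Microhomology — the longest exact
    sequence shared by the left flank's end and the right flank's start — is
    reported only for insert-free junctions (the two are mutually exclusive
    descriptions of the same junction).
    """
    left = left_flank_seq.upper()
    right = right_flank_seq.upper()
    read = junction_read.upper()

    a = 0  # longest read prefix that is a suffix of the left flank
    for k in range(min(len(read), len(left)), 0, -1):
        if read[:k] == left[-k:]:
            a = k
            break
    b = 0  # longest read suffix that is a prefix of the right flank
    for k in range(min(len(read), len(right)), 0, -1):
        if read[-k:] == right[:k]:
            b = k
            break
    if a < min_anchor or b < min_anchor:
        raise ValueError(
            f"no anchor: read matches left flank over {a} and right flank over "
            f"{b} bases (need >= {min_anchor} on each side)"
        )

    if a + b < len(read):
        insert = read[a : len(read) - b]
        return insert, 0

    # insert-free junction: report terminal microhomology between the flanks
    mh = 0
    for k in range(min(len(left), len(right)), 0, -1):
        if left[-k:] == right[:k]:
            mh = k
            break
    return "", mh


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _pcr_one_strand(
    template: str, fwd: str, rev: str, max_product_bp: int
) -> list[int]:
    """Products on one strand: forward primer matches as-is, the reverse
    primer's reverse-complement matches downstream.  Product size spans the
    forward primer's 5' start through the reverse primer's 5' start (the last
    base of its reverse-complement match), inclusive."""
    rc_rev = str(Seq(rev).reverse_complement())
    sizes = []
    rev_sites = _find_all(template, rc_rev)
    for f0 in _find_all(template, fwd):
        for r0 in rev_sites:
            size = r0 + len(rc_rev) - f0
            if size >= max(len(fwd), len(rc_rev)) and size <= max_product_bp:
                sizes.append(size)
    return sizes


def in_silico_pcr(
    template_seq: str,
    pairs: Iterable[PrimerPair],
    max_product_bp: int = 2000,
) -> list[tuple[str, int]]:
    """Predict PCR products by exact primer matching on both template strands.

    Returns (pair name, product size) for every priming arrangement producing
    a product of at most ``max_product_bp``.
    """
    template = template_seq.upper()
    bad = set(template) - _VALID_BASES
    if bad:
        raise ValueError(f"template contains unsupported symbols {sorted(bad)}")
    products: list[tuple[str, int]] = []
    for pair in pairs:
        fwd = pair.forward_seq.upper()
        rev = pair.reverse_seq.upper()
        sizes = _pcr_one_strand(template, fwd, rev, max_product_bp)
        # opposite orientation: reverse primer primes the plus strand,
        # forward primer primes the minus strand
        sizes += _pcr_one_strand(template, rev, fwd, max_product_bp)
        for s in sorted(set(sizes)):
            products.append((pair.name, s))
    return products


def genotype_from_bands(pattern: BandPattern, assay: AssayConfig) -> SVGenotype:
    """Call the deletion genotype from gel band sizes.

    A band matches when within ``tolerance_bp`` of the configured size.
    """
    def has(size: int) -> bool:
        return any(abs(b - size) <= assay.tolerance_bp for b in pattern.product_sizes_bp)

    wt = has(assay.wt_band_bp)
    dele = has(assay.del_band_bp)
    if wt and dele:
        call = "wt/del"
    elif wt:
        call = "wt/wt"
    elif dele:
        call = "del/del"
    else:
        call = "fail"
    return SVGenotype(pattern.sample_id, call)


@dataclass
class CohortScreen:
    counts: dict[str, int] = field(default_factory=dict)
    carriers: list[str] = field(default_factory=list)
    genotypes: list[SVGenotype] = field(default_factory=list)


def screen_cohort(
    band_patterns: Sequence[BandPattern], assay: AssayConfig
) -> CohortScreen:
    """Genotype every sample and tabulate {wt/wt, wt/del, del/del, fail}.

    Carriers are samples with at least one deletion allele.
    """
    if not band_patterns:
        raise ValueError("no band patterns to screen")
    seen: set[str] = set()
    out = CohortScreen(counts={"wt/wt": 0, "wt/del": 0, "del/del": 0, "fail": 0})
    for pat in band_patterns:
        if pat.sample_id in seen:
            raise ValueError(f"duplicate sample id {pat.sample_id!r}")
        seen.add(pat.sample_id)
        g = genotype_from_bands(pat, assay)
        out.genotypes.append(g)
        out.counts[g.call] += 1
        if g.call in ("wt/del", "del/del"):
            out.carriers.append(pat.sample_id)
    return out
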