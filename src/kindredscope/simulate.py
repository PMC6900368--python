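"""Synthetic-data generators for every pipeline input.

Patient-level data behind this kind of study are protected, so the package
ships generators that reproduce the *statistical structure* the analysis
assumes:

* multi-population SNP panels under the Balding–Nichols model — a single
  differentiation knob F (an F_ST analogue): per-site ancestral frequency
  p ~ Uniform(0.05, 0.95), population frequency ~ Beta(p(1-F)/F,
  (1-p)(1-F)/F), diploid genotypes ~ Binomial(2, freq);
* two-to-three-generation pedigrees with Mendelian transmission of SNVs and
  one deletion allele, including a "kindred1-like" structure (two deleterious
  alleles entering from opposite parental branches, meeting in one
  compound-heterozygous proband) and a "kindred2-like" structure
  (consanguineous loop, homozygous probands);
* LDL-C phenotypes with genotype-dose effects — default class means follow
  the classic clinical figures of 298 mg/dl for one deleterious allele and
  625 mg/dl for two, 130 mg/dl for non-carriers — with TC/HDL/TG back-filled
  so the Friedewald identity holds;
* wild-type and deleted allele sequences harboring a junction insert and the
  four primer sites of the multiplex screening assay.

Everything is driven by one integer seed; a fixed seed yields byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Individual, LipidPanel, Pedigree
from .junction import Breakpoints, PrimerPair, deletion_length
from .segregation import GenotypeTable
from .ancestry import ReferencePanel

__all__ = [
    "SimConfig",
    "EffectModel",
    "DEFAULT_BREAKPOINTS",
    "DEFAULT_PRIMERS",
    "simulate_panel",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_sequences",
    "simulate_haplotype_from_population",
    "annotate_variants",
]

#: Default deletion: the 2,977 bp promoter/exon-1 deletion geometry with its
#: 4-base junction insert.
DEFAULT_BREAKPOINTS = Breakpoints(
    chrom="19",
    left_last_retained=11_198_406,
    right_first_retained=11_201_384,
    build="hg19",
    insert_seq="TTCG",
)

#: Default multiplex assay primers: breakpoint-flanking pair and an internal
#: (within-deletion) control pair.
DEFAULT_PRIMERS = (
    PrimerPair("flanking", "AGCTCCTAGAACTTGCCTATCCT", "TCGCCACAGAGCACAGCGGAA", 254),
    PrimerPair("internal", "CAACAAATCAAGTCGCCTGCC", "TGCCATTACCCCACAAGTCTC", 481),
)


@dataclass
class EffectModel:
    """Per-genotype LDL-C means (mg/dl) keyed by deleterious-allele count,
    and a common noise standard deviation."""

    mean_by_dose: dict[int, float] = field(
        default_factory=lambda: {0: 130.0, 1: 298.0, 2: 625.0}
    )
    sd: float = 40.0


@dataclass
class SimConfig:
    seed: int = 0
    n_populations: int = 6
    n_snps: int = 500
    n_per_population: int = 50
    fst: float = 0.05
    pedigree_spec: str = "kindred1-like"
    effect_model: EffectModel = field(default_factory=EffectModel)
    deletion_spec: Breakpoints = DEFAULT_BREAKPOINTS
    primer_spec: tuple[PrimerPair, ...] = DEFAULT_PRIMERS

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------


def simulate_panel(
    config: SimConfig,
) -> tuple[ReferencePanel, np.ndarray, list[str]]:
    """Balding–Nichols panel.

    Returns (panel, genotype matrix of shape (n_pops * n_per_population,
    n_snps), per-sample population labels).  The panel's ``freq`` holds the
    *generating* per-population frequencies and ``counts`` the simulated
    chromosome counts (2 * n_per_population everywhere).
    """
    rng = np.random.default_rng(config.seed)
    K, S, N = config.n_populations, config.n_snps, config.n_per_population
    F = config.fst
    p_anc = rng.uniform(0.05, 0.95, size=S)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    freq = rng.beta(a[:, None], b[:, None], size=(S, K))

    pops = [f"POP{i + 1}" for i in range(K)]
    genos = np.empty((K * N, S), dtype=np.int8)
    labels: list[str] = []
    for k in range(K):
        genos[k * N : (k + 1) * N] = rng.binomial(2, freq[:, k], size=(N, S)).astype(
            np.int8
        )
        labels += [pops[k]] * N

    snps = pd.DataFrame(
        {
            "chrom": ["1"] * S,
            "pos": np.arange(1, S + 1) * 1000,
            "ref": ["A"] * S,
            "alt": ["G"] * S,
        }
    )
    panel = ReferencePanel(
        populations=pops,
        snps=snps,
        freq=freq,
        counts=np.full((S, K), 2 * N, dtype=float),
        superpop={p: "EUR" for p in pops},
    )
    return panel, genos, labels


def simulate_haplotype_from_population(
    panel: ReferencePanel,
    population: str,
    n_sites: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """Draw one haplotype from a population's *generating* frequencies over
    the first ``n_sites`` panel sites.  Returns (0/1 alleles, site indices)."""
    k = panel.populations.index(population)
    idx = list(range(n_sites))
    hap = (rng.random(n_sites) < panel.freq[idx, k]).astype(int)
    return hap, idx


def simulate_phased_block(
    panel: ReferencePanel,
    population: str,
    n_sites: int,
    rng: np.random.Generator,
):
    """Draw a phased block (two independent haplotypes) from one population.

    Returns (:class:`~kindredscope.ancestry.PhasedBlock`, site indices)."""
    from .ancestry import PhasedBlock

    h0, idx = simulate_haplotype_from_population(panel, population, n_sites, rng)
    h1, _ = simulate_haplotype_from_population(panel, population, n_sites, rng)
    sites = [
        (str(panel.snps.loc[i, "chrom"]), int(panel.snps.loc[i, "pos"])) for i in idx
    ]
    return PhasedBlock(sites=sites, hap_with_sv=h0, hap_other=h1), idx


# ---------------------------------------------------------------------------
# Pedigrees with Mendelian transmission
# ---------------------------------------------------------------------------


@dataclass
class _VariantDef:
    variant_id: str
    gene: str
    ref: str
    alt: str
    is_deletion: bool = False


def _format_gt(ref: str, alt: str, alleles: Sequence[str]) -> str:
    if len(ref) == 1 and len(alt) == 1 and "-" not in (ref, alt) and "del" not in (
        ref,
        alt,
    ):
        return "".join(alleles)
    return "/".join(alleles)


def simulate_pedigree(
    config: SimConfig,
) -> tuple[Pedigree, GenotypeTable, dict[str, object]]:
    """Simulate a pedigree with Mendelian transmission of the configured
    variants.

    Built-in specs:

    * ``kindred1-like`` — three generations; a structural deletion allele
      enters through the paternal branch and a deleterious SNV through the
      maternal branch; the proband is constructed to inherit both (compound
      heterozygote), her siblings receive independent Mendelian draws.
    * ``kindred2-like`` — a consanguineous two-branch loop in which both
      parents are heterozygous for the same frameshift allele; the proband
      and one sibling are constructed homozygous.

    Returns (pedigree, genotype table, truth dict naming the planted causal
    variants and the designated proband).
    """
    rng = np.random.default_rng(config.seed + 1)
    spec = config.pedigree_spec
    if spec == "kindred1-like":
        return _kindred1_like(rng)
    if spec == "kindred2-like":
        return _kindred2_like(rng)
    raise ValueError(f"unknown pedigree spec {spec!r}")


def _mendel(
    rng: np.random.Generator, father: Sequence[str], mother: Sequence[str]
) -> list[str]:
    """One allele per parent per locus."""
    return [father[rng.integers(2)], mother[rng.integers(2)]]


def _kindred1_like(rng):
    sv = _VariantDef("SV_DEL", "LDLR", "-", "del", is_deletion=True)
    snv = _VariantDef("SNV_MIS", "LDLR", "G", "A")
    decoy = _VariantDef("SNV_DECOY", "ABCA1", "G", "C")
    variants = [sv, snv, decoy]

    # founders: paternal grandmother carries the deletion, maternal grandfather
    # carries the SNV; a decoy enters through the paternal branch
    hap: dict[str, dict[str, list[str]]] = {}
    hap["gm_pat"] = {"SV_DEL": ["-", "del"], "SNV_MIS": ["G", "G"], "SNV_DECOY": ["G", "C"]}
    hap["gf_pat"] = {"SV_DEL": ["-", "-"], "SNV_MIS": ["G", "G"], "SNV_DECOY": ["G", "G"]}
    hap["gf_mat"] = {"SV_DEL": ["-", "-"], "SNV_MIS": ["G", "A"], "SNV_DECOY": ["G", "G"]}
    hap["gm_mat"] = {"SV_DEL": ["-", "-"], "SNV_MIS": ["G", "G"], "SNV_DECOY": ["G", "G"]}

    # father inherits the deletion, mother inherits the SNV (forced so the
    # kindred structure is guaranteed regardless of seed)
    hap["father"] = {
        "SV_DEL": ["del", "-"],
        "SNV_MIS": ["G", "G"],
        "SNV_DECOY": _mendel(rng, hap["gm_pat"]["SNV_DECOY"], hap["gf_pat"]["SNV_DECOY"]),
    }
    hap["mother"] = {
        "SV_DEL": ["-", "-"],
        "SNV_MIS": ["A", "G"],
        "SNV_DECOY": ["G", "G"],
    }
    # proband forced compound heterozygous; sibs are free Mendelian draws
    hap["proband"] = {
        "SV_DEL": ["del", "-"],
        "SNV_MIS": ["G", "A"],
        "SNV_DECOY": _mendel(rng, hap["father"]["SNV_DECOY"], hap["mother"]["SNV_DECOY"]),
    }
    for sib in ("sib1", "sib2"):
        hap[sib] = {
            v.variant_id: _mendel(rng, hap["father"][v.variant_id], hap["mother"][v.variant_id])
            for v in variants
        }
        # the structure plants exactly one compound heterozygote (the
        # proband); a sib who drew both alleles keeps the deletion and takes
        # the maternal reference allele instead
        if "del" in hap[sib]["SV_DEL"] and "A" in hap[sib]["SNV_MIS"]:
            hap[sib]["SNV_MIS"] = ["G", "G"]

    parents = {
        "proband": ("father", "mother"),
        "sib1": ("father", "mother"),
        "sib2": ("father", "mother"),
        "father": ("gf_pat", "gm_pat"),
        "mother": ("gf_mat", "gm_mat"),
    }
    sexes = {
        "proband": "F", "sib1": "F", "sib2": "M", "father": "M", "mother": "F",
        "gf_pat": "M", "gm_pat": "F", "gf_mat": "M", "gm_mat": "F",
    }
    members = [
        Individual(
            subject_id=sid,
            father_id=parents.get(sid, (None, None))[0],
            mother_id=parents.get(sid, (None, None))[1],
            sex=sexes[sid],
        )
        for sid in hap
    ]
    ped = Pedigree("SYN1", members)
    table = _table_from_haplotypes(variants, hap)
    truth = {
        "causal_variants": ("SNV_MIS", "SV_DEL"),
        "causal_gene": "LDLR",
        "model": "compound_heterozygous",
        "proband": "proband",
    }
    return ped, table, truth


def _kindred2_like(rng):
    fs = _VariantDef("SNV_FS", "LDLR", "-", "G")  # duplication/frameshift allele
    decoy = _VariantDef("SNV_DECOY", "MSR1", "C", "T")
    variants = [fs, decoy]

    hap: dict[str, dict[str, list[str]]] = {}
    # the consanguineous loop is represented by both parents carrying the same
    # founder frameshift allele
    hap["father"] = {"SNV_FS": ["G", "-"], "SNV_DECOY": ["C", "T"]}
    hap["mother"] = {"SNV_FS": ["G", "-"], "SNV_DECOY": ["C", "C"]}
    hap["proband"] = {"SNV_FS": ["G", "G"],
                      "SNV_DECOY": _mendel(rng, hap["father"]["SNV_DECOY"],
                                           hap["mother"]["SNV_DECOY"])}
    hap["sib_hom"] = {"SNV_FS": ["G", "G"],
                      "SNV_DECOY": _mendel(rng, hap["father"]["SNV_DECOY"],
                                           hap["mother"]["SNV_DECOY"])}
    hap["sib_het"] = {"SNV_FS": ["G", "-"],
                      "SNV_DECOY": _mendel(rng, hap["father"]["SNV_DECOY"],
                                           hap["mother"]["SNV_DECOY"])}

    parents = {s: ("father", "mother") for s in ("proband", "sib_hom", "sib_het")}
    sexes = {"proband": "F", "sib_hom": "F", "sib_het": "F",
             "father": "M", "mother": "F"}
    members = [
        Individual(
            subject_id=sid,
            father_id=parents.get(sid, (None, None))[0],
            mother_id=parents.get(sid, (None, None))[1],
            sex=sexes[sid],
        )
        for sid in hap
    ]
    ped = Pedigree("SYN2", members)
    table = _table_from_haplotypes(variants, hap)
    truth = {
        "causal_variants": ("SNV_FS",),
        "causal_gene": "LDLR",
        "model": "recessive_homozygous",
        "proband": "proband",
    }
    return ped, table, truth


def _table_from_haplotypes(
    variants: Sequence[_VariantDef], hap: Mapping[str, Mapping[str, Sequence[str]]]
) -> GenotypeTable:
    vdf = pd.DataFrame(
        [
            {"variant_id": v.variant_id, "gene": v.gene, "ref": v.ref, "alt": v.alt}
            for v in variants
        ]
    )
    calls = {
        v.variant_id: {
            sid: _format_gt(v.ref, v.alt, sorted(alleles[v.variant_id],
                                                 key=lambda a: a != v.ref))
            for sid, alleles in hap.items()
        }
        for v in variants
    }
    return GenotypeTable(vdf, calls)


def annotate_variants(table: GenotypeTable, truth: Mapping[str, object],
                      seed: int = 0) -> list["AnnotatedVariant"]:
    """Build a synthetic annotated exome table around a simulated kindred.

    The planted causal SNVs become rare, consensus-damaging missense rows
    (structural alleles are invisible to an exome table and are skipped);
    simulated decoys become plausible co-candidates; and a handful of
    filler rows exercise every cascade stage: a synonymous variant, a UTR
    variant, a low-depth variant, an off-panel-gene variant, and a common
    benign variant.
    """
    from .io import AnnotatedVariant

    damaging = {
        "sift": "D", "polyphen2_hdiv": "D", "polyphen2_hvar": "D",
        "mutation_taster": "D", "provean": "D", "fathmm": "D", "metasvm": "D",
    }
    benign = {
        "sift": "T", "polyphen2_hdiv": "B", "polyphen2_hvar": "B",
        "mutation_taster": "N", "provean": "N", "fathmm": "T", "metasvm": "T",
    }
    causal = set(truth["causal_variants"])  # type: ignore[index]
    out: list[AnnotatedVariant] = []
    pos = 1_000_000
    for _, row in table.variants.iterrows():
        if row["alt"] == "del":
            continue  # structural allele: not an exome-table row
        pos += 10_000
        is_causal = row["variant_id"] in causal
        out.append(
            AnnotatedVariant(
                chrom="19" if row["gene"] == "LDLR" else "9",
                pos=pos,
                variant_id=row["variant_id"],
                gene=row["gene"],
                consequence="missense",
                depth=60,
                ref_symbol=row["ref"],
                alt_symbol=row["alt"],
                af={"gnomad": 0.00005 if is_causal else 0.004},
                predictor_calls=dict(damaging if is_causal else benign),
                scores={"metasvm": 1.0 if is_causal else -0.5},
            )
        )
    fillers = [
        dict(gene="LDLR", consequence="synonymous", depth=60, af=0.001, calls=benign),
        dict(gene="APOB", consequence="utr", depth=60, af=0.001, calls=benign),
        dict(gene="LCAT", consequence="missense", depth=5, af=0.001, calls=damaging),
        dict(gene="NOT_A_PANEL_GENE", consequence="missense", depth=60, af=0.001,
             calls=damaging),
        dict(gene="MSR1", consequence="missense", depth=60, af=0.12, calls=benign),
    ]
    for i, f in enumerate(fillers):
        out.append(
            AnnotatedVariant(
                chrom="2",
                pos=2_000_000 + i * 1_000,
                variant_id=f"FILLER_{i}",
                gene=f["gene"],
                consequence=f["consequence"],
                depth=f["depth"],
                ref_symbol="A",
                alt_symbol="G",
                af={"gnomad": f["af"]},
                predictor_calls=dict(f["calls"]),
                scores={"metasvm": 0.0},
            )
        )
    return out


def deleterious_dose(table: GenotypeTable, subject: str,
                     causal_variants: Sequence[str]) -> int:
    """Total deleterious-allele count over the causal variants."""
    return sum(table.dose(subject, v) or 0 for v in causal_variants)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    pedigree: Pedigree,
    table: GenotypeTable,
    causal_variants: Sequence[str],
    effect_model: EffectModel | None = None,
    seed: int = 0,
) -> Pedigree:
    """Draw lipid panels with genotype-dose LDL-C effects.

    LDL-C ~ Normal(mean(dose), sd), truncated at 0, where dose is the total
    deleterious-allele count over ``causal_variants`` (capped at 2).  HDL-C
    and TG are drawn from unremarkable distributions and TC is back-computed
    so the Friedewald identity TC - HDL - TG/5 = LDL holds exactly.
    Mutates and returns the pedigree.
    """
    em = effect_model or EffectModel()
    rng = np.random.default_rng(seed)
    for sid in sorted(pedigree.members):
        ind = pedigree[sid]
        dose = min(deleterious_dose(table, sid, causal_variants), 2)
        ldl = max(0.0, float(rng.normal(em.mean_by_dose[dose], em.sd)))
        hdl = float(np.clip(rng.normal(50.0, 8.0), 20.0, 100.0))
        tg = float(np.clip(rng.normal(120.0, 30.0), 40.0, 395.0))
        tc = ldl + hdl + tg / 5.0
        ind.lipids = LipidPanel(
            tc=round(tc, 1), hdl=round(hdl, 1), tg=round(tg, 1),
            ldl=round(ldl, 1), ldl_method="friedewald",
        )
        # keep the Friedewald identity exact after rounding
        ind.lipids.tc = round(ind.lipids.ldl + ind.lipids.hdl + ind.lipids.tg / 5.0, 2)
    return pedigree


# ---------------------------------------------------------------------------
# Allele sequences for the PCR screen
# ---------------------------------------------------------------------------


@dataclass
class AllelePair:
    """Wild-type and deleted allele sequences plus primer placement facts."""

    wild_type: str
    deleted: str
    left_flank: str
    right_flank: str
    deleted_interval: str
    breakpoints: Breakpoints
    flanking_product_bp: int
    internal_product_bp: int


def simulate_sequences(
    deletion_spec: Breakpoints | None = None,
    primer_spec: Sequence[PrimerPair] | None = None,
    seed: int = 0,
    flank_len: int = 600,
) -> AllelePair:
    """Construct toy wild-type and deleted alleles for the multiplex assay.

    The wild-type allele is ``left_flank + deleted_interval + right_flank``
    with the internal primer pair planted inside the deleted interval (product
    size = the internal pair's ``expected_product_bp``) and the
    breakpoint-flanking pair planted so its product across the junction of the
    *deleted* allele (left flank tail + insert + right flank head) equals the
    flanking pair's ``expected_product_bp``.  The deleted allele is the two
    flanks joined around the junction insert.
    """
    bp = deletion_spec or DEFAULT_BREAKPOINTS
    primers = list(primer_spec or DEFAULT_PRIMERS)
    if len(primers) != 2:
        raise ValueError("expected a flanking pair and an internal pair")
    flanking, internal = primers
    del_len = deletion_length(bp)
    insert = bp.insert_seq.upper()

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    f_prod = flanking.expected_product_bp or 254
    i_prod = internal.expected_product_bp or 481

    # flanking pair geometry on the deleted allele:
    # product = left_tail + insert + right_head
    left_tail = (f_prod - len(insert)) // 2
    right_head = f_prod - len(insert) - left_tail
    if left_tail < len(flanking.forward_seq) or right_head < len(flanking.reverse_seq):
        raise ValueError("flanking product too small for the primer lengths")
    if flank_len < max(left_tail, right_head):
        raise ValueError("flank_len shorter than the primer offsets")

    from Bio.Seq import Seq

    left = list(rand_seq(flank_len))
    right = list(rand_seq(flank_len))
    # plant flanking-forward so its 5' start is left_tail bases before the junction
    fstart = flank_len - left_tail
    left[fstart : fstart + len(flanking.forward_seq)] = flanking.forward_seq
    # plant flanking-reverse (as revcomp) so its 5' end is right_head bases into the right flank
    rc = str(Seq(flanking.reverse_seq).reverse_complement())
    right[right_head - len(rc) : right_head] = rc

    # internal pair inside the deleted interval
    if del_len < i_prod + 40:
        raise ValueError("deleted interval too short for the internal product")
    interval = list(rand_seq(del_len))
    istart = 20
    interval[istart : istart + len(internal.forward_seq)] = internal.forward_seq
    irc = str(Seq(internal.reverse_seq).reverse_complement())
    iend = istart + i_prod  # one past the reverse primer's 5' end
    interval[iend - len(irc) : iend] = irc

    left_s, right_s, interval_s = "".join(left), "".join(right), "".join(interval)
    wild_type = left_s + interval_s + right_s
    deleted = left_s + insert + right_s
    return AllelePair(
        wild_type=wild_type,
        deleted=deleted,
        left_flank=left_s,
        right_flank=right_s,
        deleted_interval=interval_s,
        breakpoints=bp,
        flanking_product_bp=f_prod,
        internal_product_bp=i_prod,
    )
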