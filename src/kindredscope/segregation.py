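"""Pedigree cosegregation: which variant set explains the lipid phenotypes.

Familial hypercholesterolemia is dose-dependent: one deleterious LDLR allele
gives the heterozygous phenotype (moderately elevated LDL-C), two alleles of
the same gene — homozygous or in-trans compound heterozygous — give the
severe homozygous phenotype.  The search therefore scores three model kinds
over a pedigree with genotypes and LDL-C-derived affection status:

* ``dominant_single`` — carriers and only carriers are affected;
* ``recessive_homozygous`` — homozygous-alt individuals must be affected;
  heterozygous carriers may show the intermediate phenotype, so only affected
  *non-carriers* contradict the model;
* ``compound_heterozygous`` — two distinct variants of one gene; individuals
  carrying both in trans must be affected, single carriers are intermediate,
  affected individuals carrying neither contradict the model.  Trans/cis
  phase is resolved from parental genotypes where possible, otherwise the
  pair is flagged phase-ambiguous and ranked below phased explanations.

A recessive or compound model whose causal genotype class is empty among the
affected (no affected homozygote / no affected double carrier) explains no
severe case; such degenerate models rank below any model with an inhabited
causal class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import FormatError, Pedigree

__all__ = [
    "AffectionRule",
    "InheritanceModel",
    "SegregationResult",
    "GenotypeTable",
    "FriedewaldResult",
    "friedewald_ldl",
    "assign_affection",
    "evaluate_model",
    "search_explanations",
]

FRIEDEWALD_TG_LIMIT = 400.0  # mg/dl; above this the TG/5 VLDL estimate breaks down


@dataclass(frozen=True)
class FriedewaldResult:
    ldl: float
    valid: bool


def friedewald_ldl(tc: float, hdl: float, tg: float) -> FriedewaldResult:
    """Estimate LDL-C as TC − HDL-C − TG/5 (all mg/dl).

    The TG/5 term estimates VLDL cholesterol and is unreliable at triglyceride
    levels of 400 mg/dl or more; such inputs return ``valid=False``.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid inputs must be non-negative mg/dl")
    return FriedewaldResult(ldl=tc - hdl - tg / 5.0, valid=tg < FRIEDEWALD_TG_LIMIT)


@dataclass
class AffectionRule:
    """LDL-C cutoff rule standing in for age/sex-adjusted 95th-percentile
    tables.

    Default: 190 mg/dl for adults, 160 mg/dl below ``pediatric_max_age``.
    A full (age-range, sex) -> cutoff table can be plugged in via
    ``threshold_table``: list of (age_lo, age_hi, sex-or-None, cutoff).
    """

    adult_cutoff: float = 190.0
    pediatric_cutoff: float = 160.0
    pediatric_max_age: float = 20.0
    threshold_table: list[tuple[float, float, str | None, float]] | None = None

    def cutoff_for(self, age: float | None, sex: str = "unknown") -> float:
        if self.threshold_table:
            for lo, hi, s, cut in self.threshold_table:
                if (age is None or lo <= age < hi) and (s is None or s == sex):
                    return cut
        if age is not None and age < self.pediatric_max_age:
            return self.pediatric_cutoff
        return self.adult_cutoff


def assign_affection(pedigree: Pedigree, rule: AffectionRule | None = None) -> Pedigree:
    """Fill affection status from LDL-C: affected iff LDL-C >= the applicable
    cutoff, unknown when no lipid panel (or no LDL-C) is available.

    Mutates and returns the pedigree.
    """
    rule = rule or AffectionRule()
    for ind in pedigree:
        ldl = ind.lipids.ldl if ind.lipids is not None else None
        if ldl is None:
            ind.affection = "unknown"
        elif ldl >= rule.cutoff_for(ind.age, ind.sex):
            ind.affection = "affected"
        else:
            ind.affection = "unaffected"
    return pedigree


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------


class GenotypeTable:
    """Per-subject diploid genotypes for a set of variants.

    Genotypes are strings whose alleles are drawn from the variant's
    ``ref``/``alt`` symbols: two-character SNV strings ("GA"), or
    slash-separated allele pairs for indels and structural alleles
    ("AGA/-", "-/del", "G/G").
    """

    def __init__(self, variants: pd.DataFrame, calls: Mapping[str, Mapping[str, str]]):
        """``variants``: DataFrame with columns variant_id, gene, ref, alt.
        ``calls``: variant_id -> {subject_id -> genotype string}."""
        required = {"variant_id", "gene", "ref", "alt"}
        if not required.issubset(variants.columns):
            raise FormatError(f"genotype table needs columns {sorted(required)}")
        self.variants = variants.reset_index(drop=True)
        self.calls = {k: dict(v) for k, v in calls.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        """Read a TSV with columns variant_id, gene, ref, alt, then one column
        per subject id."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        meta_cols = ["variant_id", "gene", "ref", "alt"]
        subjects = [c for c in df.columns if c not in meta_cols]
        calls = {
            row["variant_id"]: {
                s: row[s] for s in subjects if row[s] not in ("", ".", "-?")
            }
            for _, row in df.iterrows()
        }
        return cls(df[meta_cols], calls)

    def to_tsv(self, path: str | Path) -> None:
        subjects = sorted({s for gt in self.calls.values() for s in gt})
        out = self.variants.copy()
        for s in subjects:
            out[s] = [self.calls.get(vid, {}).get(s, ".") for vid in out["variant_id"]]
        out.to_csv(path, sep="\t", index=False)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def gene_of(self, variant_id: str) -> str:
        row = self.variants.loc[self.variants["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(f"variant {variant_id!r} not in genotype table")
        return row.iloc[0]["gene"]

    def _alleles(self, variant_id: str) -> tuple[str, str]:
        row = self.variants.loc[self.variants["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(f"variant {variant_id!r} not in genotype table")
        return row.iloc[0]["ref"], row.iloc[0]["alt"]

    def dose(self, subject_id: str, variant_id: str) -> int | None:
        """Number of alternate alleles this subject carries (0/1/2), or None
        when the subject was not genotyped for the variant."""
        ref, alt = self._alleles(variant_id)
        gt = self.calls.get(variant_id, {}).get(subject_id)
        if gt is None:
            return None
        if "/" in gt:
            alleles = gt.split("/")
        elif len(gt) == 2 and len(ref) == 1 and len(alt) == 1:
            alleles = list(gt)
        else:
            raise FormatError(
                f"cannot parse genotype {gt!r} for {variant_id} ({ref}/{alt})"
            )
        for a in alleles:
            if a not in (ref, alt):
                raise FormatError(
                    f"allele {a!r} not in {{{ref},{alt}}} for {variant_id}"
                )
        return sum(1 for a in alleles if a == alt)

    def subjects(self) -> list[str]:
        return sorted({s for gt in self.calls.values() for s in gt})


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InheritanceModel:
    """A candidate explanation: one variant (dominant or recessive) or an
    unordered same-gene pair (compound heterozygous)."""

    kind: str  # dominant_single | recessive_homozygous | compound_heterozygous
    variant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "compound_heterozygous":
            if len(self.variant_ids) != 2 or len(set(self.variant_ids)) != 2:
                raise ValueError("compound model needs two distinct variants")
        elif len(self.variant_ids) != 1:
            raise ValueError(f"{self.kind} model needs exactly one variant")
        object.__setattr__(self, "variant_ids", tuple(sorted(self.variant_ids)))

    def describe(self, table: GenotypeTable | None = None) -> str:
        vids = "+".join(self.variant_ids)
        gene = ""
        if table is not None:
            genes = sorted({table.gene_of(v) for v in self.variant_ids})
            gene = f" [{'/'.join(genes)}]"
        return f"{self.kind}({vids}){gene}"


@dataclass
class SegregationResult:
    model: InheritanceModel
    per_individual: dict[str, str]  # consistent | inconsistent | unknown
    n_inconsistent: int
    explains_all_affected: bool
    unexplained_affected: list[str]
    n_causal_affected: int = 0  # affected individuals in the causal genotype class
    phase_ambiguous: bool = False
    rank: int | None = None

    def sort_key(self, table: GenotypeTable) -> tuple:
        genes = tuple(sorted(table.gene_of(v) for v in self.model.variant_ids))
        return (
            not self.explains_all_affected,   # explainers first
            self.n_causal_affected == 0,      # degenerate causal class last
            self.phase_ambiguous,             # phased explanations first
            self.n_inconsistent,
            len(self.model.variant_ids),
            genes,
            self.model.variant_ids,
        )


def _trans_phase(
    subject: str, v1: str, v2: str, pedigree: Pedigree, table: GenotypeTable
) -> str:
    """Phase a double carrier from parental genotypes.

    Returns "trans", "cis", or "ambiguous".  A variant is assigned a parental
    origin when exactly one typed parent carries it.
    """
    ind = pedigree.members.get(subject)
    if ind is None or ind.father_id is None or ind.mother_id is None:
        return "ambiguous"

    def origin(v: str) -> str:
        fd = table.dose(ind.father_id, v)
        md = table.dose(ind.mother_id, v)
        if fd is None or md is None:
            return "ambiguous"
        if fd > 0 and md == 0:
            return "paternal"
        if md > 0 and fd == 0:
            return "maternal"
        return "ambiguous"

    o1, o2 = origin(v1), origin(v2)
    if "ambiguous" in (o1, o2):
        return "ambiguous"
    return "trans" if o1 != o2 else "cis"


def evaluate_model(
    pedigree: Pedigree, table: GenotypeTable, model: InheritanceModel
) -> SegregationResult:
    """Score one inheritance model against every pedigree member.

    Individuals with unknown affection score "unknown" and never count as
    inconsistent.  See the module docstring for the per-model consistency
    rules.
    """
    for vid in model.variant_ids:
        if vid not in table.calls:
            raise KeyError(f"model variant {vid!r} absent from genotype table")

    per: dict[str, str] = {}
    n_causal_affected = 0
    phase_ambiguous = False
    # deterministic member order: sorted ids (results are order-invariant anyway)
    for sid in sorted(pedigree.members):
        ind = pedigree[sid]
        status = ind.affection
        if status == "unknown":
            per[sid] = "unknown"
            continue
        doses = {v: table.dose(sid, v) for v in model.variant_ids}
        if any(d is None for d in doses.values()):
            per[sid] = "unknown"
            continue
        affected = status == "affected"

        if model.kind == "dominant_single":
            carrier = doses[model.variant_ids[0]] > 0
            ok = carrier == affected
            if carrier and affected:
                n_causal_affected += 1
        elif model.kind == "recessive_homozygous":
            d = doses[model.variant_ids[0]]
            if d == 2:
                ok = affected
                if affected:
                    n_causal_affected += 1
            elif d == 1:
                ok = True  # heterozygotes may show the intermediate phenotype
            else:
                ok = not affected
        else:  # compound_heterozygous
            v1, v2 = model.variant_ids
            both = doses[v1] > 0 and doses[v2] > 0
            either = doses[v1] > 0 or doses[v2] > 0
            if both:
                phase = _trans_phase(sid, v1, v2, pedigree, table)
                if phase == "ambiguous":
                    phase_ambiguous = True
                if phase == "cis":
                    # both on one homolog: effectively a single-allele carrier
                    ok = True
                else:
                    ok = affected
                    if affected:
                        n_causal_affected += 1
            elif either:
                ok = True
            else:
                ok = not affected
        per[sid] = "consistent" if ok else "inconsistent"

    inconsistent = [s for s, v in per.items() if v == "inconsistent"]
    unexplained = [
        s for s in inconsistent if pedigree[s].affection == "affected"
    ]
    return SegregationResult(
        model=model,
        per_individual=per,
        n_inconsistent=len(inconsistent),
        explains_all_affected=len(unexplained) == 0,
        unexplained_affected=unexplained,
        n_causal_affected=n_causal_affected,
        phase_ambiguous=phase_ambiguous,
    )


def enumerate_models(table: GenotypeTable) -> list[InheritanceModel]:
    """All dominant singles, recessive singles, and same-gene compound pairs."""
    models: list[InheritanceModel] = []
    vids = table.variant_ids
    for v in vids:
        models.append(InheritanceModel("dominant_single", (v,)))
        models.append(InheritanceModel("recessive_homozygous", (v,)))
    by_gene: dict[str, list[str]] = {}
    for v in vids:
        by_gene.setdefault(table.gene_of(v), []).append(v)
    for gene_vids in by_gene.values():
        for v1, v2 in itertools.combinations(gene_vids, 2):
            models.append(InheritanceModel("compound_heterozygous", (v1, v2)))
    return models


def search_explanations(
    pedigree: Pedigree, table: GenotypeTable
) -> list[SegregationResult]:
    """Enumerate and rank all candidate inheritance models.

    Ranking: models explaining every affected individual first; models whose
    causal genotype class is inhabited by at least one affected individual
    before degenerate ones; phased before phase-ambiguous; then fewer
    inconsistencies, fewer variants, lexical gene order.
    """
    if not any(ind.affection == "affected" for ind in pedigree):
        raise ValueError("pedigree has no affected individual to explain")
    results = [evaluate_model(pedigree, table, m) for m in enumerate_models(table)]
    results.sort(key=lambda r: r.sort_key(table))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results
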