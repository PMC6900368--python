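"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* Annotated variant tables: tab-separated ANNOVAR-style dialect, one row per
  exome variant, with per-database allele frequencies and per-predictor
  pathogenicity calls.  The column-name -> field mapping is a dialect config
  so that tables from different annotation runs can be consumed.
* Pedigrees: 6-column PED extended with optional named phenotype columns
  (AGE, BMI, TC, HDL, TG, LDL), headered with a leading ``#``.
* Phased genotypes: VCF with GT and PS tags (read through cyvcf2).

Coordinates are 1-based and inclusive, and every genomic position carries a
genome-build tag ("hg19"/"hg38") because breakpoints are routinely reported
against both builds; no liftover is performed here.

Missing table cells (em-dash or ``-`` or ``.``) become ``None``, never 0 —
a variant absent from gnomAD is *novel*, not common, and downstream frequency
filters rely on that distinction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AnnotatedVariant",
    "LipidPanel",
    "Individual",
    "Pedigree",
    "HaplotypeBlock",
    "PhasedGenotypes",
    "FormatError",
    "DEFAULT_DIALECT",
    "CONSEQUENCES",
    "read_annovar_table",
    "write_annovar_table",
    "read_pedigree",
    "write_pedigree",
    "read_phased_genotypes",
]

#: Closed consequence vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "stopgain",
        "frameshift",
        "nonframeshift_indel",
        "intronic",
        "intergenic",
        "utr",
        "splicing",
    }
)

#: Strings treated as missing cells in variant tables.
MISSING_TOKENS = {"", "-", ".", "—", "–", "NA", "na", "None"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return str(cell).strip() in MISSING_TOKENS


@dataclass
class AnnotatedVariant:
    """One annotated exome variant (a row of an ANNOVAR-style table).

    ``af`` maps database name -> allele frequency in [0, 1]; a database the
    variant is absent from is simply not a key (or maps to None).
    ``predictor_calls`` maps predictor name -> categorical call
    (D/T/P/B/N/U/H/M/L); ``scores`` maps score name -> real value.
    ``genotypes`` maps subject id -> diploid genotype string whose alleles
    are drawn from {ref_symbol, alt_symbol}.
    """

    chrom: str
    pos: int
    build: str = "hg19"
    variant_id: str | None = None
    gene: str | None = None
    exon: str | None = None
    cdna_change: str | None = None
    protein_change: str | None = None
    consequence: str | None = None
    depth: int | None = None
    ref_symbol: str = "N"
    alt_symbol: str = "N"
    af: dict[str, float | None] = field(default_factory=dict)
    predictor_calls: dict[str, str | None] = field(default_factory=dict)
    scores: dict[str, float | None] = field(default_factory=dict)
    clinvar: str | None = None
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence label: {self.consequence!r}")
        for db, value in self.af.items():
            if value is not None and not (0.0 <= value <= 1.0):
                raise FormatError(f"allele frequency out of [0,1] for {db}: {value}")

    @property
    def key(self) -> str:
        """Stable identifier: dbSNP id when present, else coordinate string."""
        if self.variant_id:
            return self.variant_id
        return f"{self.chrom}:{self.pos}:{self.gene or '?'}"

    def max_af(self, databases: Iterable[str] | None = None) -> float | None:
        """Maximum observed allele frequency across the given databases.

        None when the variant is absent from every queried database.
        """
        names = list(databases) if databases is not None else list(self.af)
        seen = [self.af[n] for n in names if self.af.get(n) is not None]
        return max(seen) if seen else None


@dataclass
class LipidPanel:
    """Fasting lipid panel in mg/dl."""

    tc: float | None = None
    hdl: float | None = None
    tg: float | None = None
    ldl: float | None = None
    ldl_method: str = "measured"  # or "friedewald"

    def __post_init__(self) -> None:
        for name in ("tc", "hdl", "tg", "ldl"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise FormatError(f"negative lipid value {name}={v}")


@dataclass
class Individual:
    """One pedigree member; subject ids follow the generation-index convention
    (e.g. ``1-1``) and are treated as opaque strings."""

    subject_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # M / F / unknown
    age: float | None = None
    bmi: float | None = None
    lipids: LipidPanel | None = None
    affection: str = "unknown"  # affected / unaffected / unknown


class Pedigree:
    """A family graph: unique member ids, resolvable parental links, acyclic."""

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.subject_id in self.members:
                raise FormatError(f"duplicate subject id {ind.subject_id!r}")
            self.members[ind.subject_id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise FormatError(
                        f"dangling parent id {pid!r} referenced by {ind.subject_id!r}"
                    )
        # cycle check: walk ancestors of each member
        for start in self.members:
            seen = []
            frontier = [start]
            visited: set[str] = set()
            while frontier:
                cur = frontier.pop()
                ind = self.members[cur]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    if pid == start:
                        chain = " -> ".join(seen + [cur, pid])
                        raise FormatError(f"pedigree cycle: {chain}")
                    if pid not in visited:
                        visited.add(pid)
                        seen.append(cur)
                        frontier.append(pid)

    @property
    def founders(self) -> set[str]:
        return {
            sid
            for sid, ind in self.members.items()
            if ind.father_id is None and ind.mother_id is None
        }

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, subject_id: str) -> Individual:
        return self.members[subject_id]


# ---------------------------------------------------------------------------
# Annotated variant tables
# ---------------------------------------------------------------------------

#: Default dialect: column name -> field. ``af:<db>`` routes into the af map,
#: ``pred:<name>`` into predictor_calls, ``score:<name>`` into scores.
DEFAULT_DIALECT: dict[str, str] = {
    "Chromosome": "chrom",
    "Position": "pos",
    "Build": "build",
    "ID": "variant_id",
    "Gene": "gene",
    "Mutation": "mutation",  # combined exonN: c.X: p.Y string
    "Consequence": "consequence",
    "Depth": "depth",
    "Ref": "ref_symbol",
    "Alt": "alt_symbol",
    "Clinvar": "clinvar",
    "GnomAD": "af:gnomad",
    "TOPMED": "af:topmed",
    "ExAC": "af:exac",
    "SIFT": "pred:sift",
    "Polyphen2 HDIV": "pred:polyphen2_hdiv",
    "Polyphen2 HVAR": "pred:polyphen2_hvar",
    "LRT": "pred:lrt",
    "Mutation Taster": "pred:mutation_taster",
    "Mutation Assessor": "pred:mutation_assessor",
    "PROVEAN": "pred:provean",
    "FATHMM": "pred:fathmm",
    "MetaSVM pred": "pred:metasvm",
    "GERP_RS": "score:gerp_rs",
    "MetaSVM score": "score:metasvm",
}

REQUIRED_FIELDS = {"chrom", "pos", "gene"}

_MUTATION_RE = re.compile(
    r"(?P<exon>exon\s?\w+)?[:\s]*(?P<cdna>c\.[^:\s]+(?:\s?[^:]*?)?)?[:\s]*(?P<prot>p\.\S.*)?$"
)


def _split_mutation(text: str) -> tuple[str | None, str | None, str | None]:
    """Split a combined ``exon12: c.G1775A: p.G592E`` string into parts."""
    exon = cdna = prot = None
    for part in (p.strip() for p in text.split(":")):
        if not part:
            continue
        if part.lower().startswith("exon"):
            exon = part
        elif part.startswith("c."):
            cdna = part
        elif part.startswith("p."):
            prot = part
        elif cdna is not None and prot is None:
            # continuation of a cdna description, e.g. "c.320_322del AGA"
            cdna = f"{cdna} {part}" if part not in ("",) else cdna
        elif prot is not None:
            prot = f"{prot} {part}"
    return exon, cdna, prot


def read_annovar_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Read a tab-separated annotated variant table.

    Parameters
    ----------
    path
        TSV file, UTF-8, with a header row.
    dialect
        Column-name -> field mapping; defaults to :data:`DEFAULT_DIALECT`.
        Unmapped columns whose names start with ``GT:`` are read as per-subject
        genotype columns (subject id after the colon).

    Raises
    ------
    FormatError
        If a required column is unmappable, or a frequency cell is non-numeric
        (the error names the 1-based data row).
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    mapped_fields = set(dialect.values())
    for req in REQUIRED_FIELDS:
        if req not in mapped_fields:
            raise FormatError(f"dialect config maps no column onto {req!r}")
        cols = [c for c, f in dialect.items() if f == req]
        if not any(c in df.columns for c in cols):
            raise FormatError(
                f"required column for field {req!r} missing from header "
                f"(expected one of {cols})"
            )

    out: list[AnnotatedVariant] = []
    for i, row in df.iterrows():
        kwargs: dict = {"af": {}, "predictor_calls": {}, "scores": {}, "genotypes": {}}
        for col in df.columns:
            cell = row[col]
            if col.startswith("GT:"):
                if not _is_missing(cell):
                    kwargs["genotypes"][col[3:]] = str(cell).strip()
                continue
            target = dialect.get(col)
            if target is None:
                continue
            if _is_missing(cell):
                if target.startswith("af:"):
                    kwargs["af"][target[3:]] = None
                elif target.startswith("pred:"):
                    kwargs["predictor_calls"][target[5:]] = None
                elif target.startswith("score:"):
                    kwargs["scores"][target[6:]] = None
                continue
            cell = str(cell).strip()
            if target.startswith("af:"):
                try:
                    kwargs["af"][target[3:]] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric allele frequency {cell!r} in column "
                        f"{col!r}, data row {i + 1}"
                    ) from None
            elif target.startswith("pred:"):
                kwargs["predictor_calls"][target[5:]] = cell.strip("*")
            elif target.startswith("score:"):
                try:
                    kwargs["scores"][target[6:]] = float(
                        cell.replace("−", "-")
                    )
                except ValueError:
                    kwargs["scores"][target[6:]] = None
            elif target == "pos":
                kwargs["pos"] = int(cell.replace(",", ""))
            elif target == "depth":
                depth = int(cell)
                if depth < 0:
                    raise FormatError(f"negative depth {depth} in data row {i + 1}")
                kwargs["depth"] = depth
            elif target == "mutation":
                exon, cdna, prot = _split_mutation(cell)
                kwargs.setdefault("exon", exon)
                kwargs.setdefault("cdna_change", cdna)
                kwargs.setdefault("protein_change", prot)
            else:
                kwargs[target] = cell
        out.append(AnnotatedVariant(**kwargs))
    return out


def write_annovar_table(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    missing: str = "-",
) -> None:
    """Write variants back out in the given dialect (inverse of the reader).

    Genotype maps are emitted as ``GT:<subject>`` columns.  The combined
    ``mutation`` column is reassembled from exon/cdna/protein parts.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    variants = list(variants)
    subjects: list[str] = []
    for v in variants:
        for s in v.genotypes:
            if s not in subjects:
                subjects.append(s)

    rows = []
    for v in variants:
        row: dict[str, str] = {}
        for col, target in dialect.items():
            if target == "mutation":
                parts = [p for p in (v.exon, v.cdna_change, v.protein_change) if p]
                row[col] = ": ".join(parts) if parts else missing
            elif target.startswith("af:"):
                val = v.af.get(target[3:])
                row[col] = missing if val is None else repr(val)
            elif target.startswith("pred:"):
                val = v.predictor_calls.get(target[5:])
                row[col] = missing if val is None else val
            elif target.startswith("score:"):
                val = v.scores.get(target[6:])
                row[col] = missing if val is None else repr(val)
            else:
                val = getattr(v, target, None)
                row[col] = missing if val is None else str(val)
        for s in subjects:
            row[f"GT:{s}"] = v.genotypes.get(s, missing)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

_PED_CORE = ["FID", "IID", "FAT", "MOT", "SEX", "PHENO"]
_PED_OPTIONAL = ["AGE", "BMI", "TC", "HDL", "TG", "LDL"]
_SEX_CODE = {"1": "M", "2": "F"}
_AFFECTION_CODE = {"1": "unaffected", "2": "affected"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an extended PED file.

    Layout: the six classic columns (family, individual, father, mother, sex,
    phenotype) optionally followed by named columns AGE, BMI, TC, HDL, TG, LDL
    declared in a ``#``-prefixed header line.  ``0`` means "no parent";
    phenotype 1/2 maps to unaffected/affected, anything else to unknown.
    """
    path = Path(path)
    header = _PED_CORE
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header = line.lstrip("#").split()
            continue
        rows.append(line.split("\t") if "\t" in line else line.split())

    if not set(_PED_CORE).issubset(header):
        raise FormatError(f"pedigree header must contain {_PED_CORE}, got {header}")

    members = []
    family_id = "FAM"
    for fields_ in rows:
        if len(fields_) < len(header):
            fields_ = fields_ + ["-"] * (len(header) - len(fields_))
        rec = dict(zip(header, fields_))
        family_id = rec["FID"]

        def fnum(key: str) -> float | None:
            val = rec.get(key)
            if val is None or _is_missing(val) or val == "0":
                return None
            return float(val)

        lipid_vals = {k.lower(): fnum(k) for k in ("TC", "HDL", "TG", "LDL")}
        lipids = (
            LipidPanel(**lipid_vals)
            if any(v is not None for v in lipid_vals.values())
            else None
        )
        members.append(
            Individual(
                subject_id=rec["IID"],
                father_id=None if rec["FAT"] in ("0", "-") else rec["FAT"],
                mother_id=None if rec["MOT"] in ("0", "-") else rec["MOT"],
                sex=_SEX_CODE.get(rec["SEX"], "unknown"),
                age=fnum("AGE"),
                bmi=fnum("BMI"),
                lipids=lipids,
                affection=_AFFECTION_CODE.get(rec["PHENO"], "unknown"),
            )
        )
    return Pedigree(family_id, members)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write an extended PED file readable by :func:`read_pedigree`."""
    sex_code = {"M": "1", "F": "2", "unknown": "0"}
    aff_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    lines = ["#" + "\t".join(_PED_CORE + _PED_OPTIONAL)]
    for ind in ped:
        lp = ind.lipids or LipidPanel()
        cells = [
            ped.family_id,
            ind.subject_id,
            ind.father_id or "0",
            ind.mother_id or "0",
            sex_code[ind.sex],
            aff_code[ind.affection],
        ] + [
            "-" if v is None else f"{v:g}"
            for v in (ind.age, ind.bmi, lp.tc, lp.hdl, lp.tg, lp.ldl)
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phased genotypes (VCF with GT + PS)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlock:
    """Sites of one phase set with the two ordered haplotype allele strings."""

    phase_set: str
    sites: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)
    hap0: list[str]
    hap1: list[str]


@dataclass
class PhasedGenotypes:
    """Phased biallelic calls for one sample, grouped by phase set."""

    sample: str
    blocks: dict[str, HaplotypeBlock]
    n_unphased: int = 0
    n_multiallelic: int = 0


def read_phased_genotypes(path: str | Path, sample: str | None = None) -> PhasedGenotypes:
    """Read phased biallelic genotypes for one sample from a VCF.

    Heterozygous phased calls are grouped by their PS tag; a phased call with
    no PS tag becomes its own singleton block keyed by position.  Unphased
    heterozygous sites are excluded and counted; homozygous sites are phased
    trivially and join the current convention of being included only when they
    carry a PS tag.  Multi-allelic records are skipped with a count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise FormatError("VCF has no sample columns")
    if sample is None:
        sample = samples[0]
    try:
        si = samples.index(sample)
    except ValueError:
        raise FormatError(f"sample {sample!r} not in VCF ({samples})") from None

    blocks: dict[str, HaplotypeBlock] = {}
    n_unphased = 0
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = rec.genotypes[si]  # [a0, a1, phased]
        a0, a1, phased = gt[0], gt[1], bool(gt[2])
        if a0 < 0 or a1 < 0:
            continue
        hom = a0 == a1
        if not phased and not hom:
            n_unphased += 1
            continue
        ps = None
        try:
            ps_arr = rec.format("PS")
            if ps_arr is not None:
                ps = str(ps_arr[si][0]) if ps_arr[si][0] is not None else None
        except (KeyError, TypeError):
            ps = None
        if ps is None or ps in ("None", "nan", "."):
            ps = f"singleton:{rec.CHROM}:{rec.POS}"
        block = blocks.setdefault(ps, HaplotypeBlock(ps, [], [], []))
        alleles = [rec.REF, rec.ALT[0]]
        block.sites.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        block.hap0.append(alleles[a0])
        block.hap1.append(alleles[a1])
    return PhasedGenotypes(sample, blocks, n_unphased, n_multi)
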