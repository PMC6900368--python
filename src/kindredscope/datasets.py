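"""Bundled worked-example data.

Two familial-hypercholesterolemia kindreds transcribed from published summary
tables: per-proband annotated candidate-variant tables, family genotype
tables, and extended PED files with LDL-C/HDL-C values.

Notes on the transcription (see docs/methods.md):

* read depths are not part of the published tables; every row carries a
  nominal passing depth of 50, since these variants survived the original
  depth filter;
* ages are not part of the published genotype tables, so the PED files carry
  none and affection assignment falls back to the adult LDL-C cutoff;
* relationships for three kindred-1 members are not derivable from the
  published text; the PED places them as one aunt's spouse and children,
  consistent with their genotypes (synthetic-relationship stand-in).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import AnnotatedVariant, Pedigree, read_annovar_table, read_pedigree
from .segregation import GenotypeTable

__all__ = ["data_path", "load_gene_panel", "load_kindred"]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files("kindredscope.data").joinpath(name)))


def load_gene_panel() -> frozenset[str]:
    """The bundled candidate lipid-gene panel."""
    lines = data_path("gene_panel.txt").read_text().splitlines()
    return frozenset(
        ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
    )


def load_kindred(
    name: str,
) -> tuple[list[AnnotatedVariant], Pedigree, GenotypeTable]:
    """Load one worked-example kindred: (variants, pedigree, genotype table).

    ``name`` is ``"kindred1"`` (compound-heterozygous LDLR: missense +
    promoter/exon-1 deletion) or ``"kindred2"`` (homozygous LDLR frameshift).
    """
    if name not in ("kindred1", "kindred2"):
        raise ValueError(f"unknown kindred {name!r}")
    variants = read_annovar_table(data_path(f"{name}_variants.tsv"))
    pedigree = read_pedigree(data_path(f"{name}_pedigree.ped"))
    table = GenotypeTable.from_tsv(data_path(f"{name}_genotypes.tsv"))
    return variants, pedigree, table
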