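"""Deletion-junction arithmetic and the in-silico multiplex PCR screen.

Builds synthetic wild-type/deleted alleles around the published hg19
breakpoint pair (2,977 bp deletion, TTCG junction insert), characterizes the
junction from a spanning read, and genotypes all three allele combinations
from their predicted band patterns.
"""

from kindredscope.junction import (
    AssayConfig,
    BandPattern,
    Breakpoints,
    characterize_junction,
    deletion_length,
    genotype_from_bands,
    in_silico_pcr,
)
from kindredscope.simulate import DEFAULT_PRIMERS, simulate_sequences

bp = Breakpoints("19", 11_198_406, 11_201_384, build="hg19", insert_seq="TTCG")
print(f"deletion length: {deletion_length(bp):,} bp "
      f"({bp.chrom}:{bp.left_last_retained:,}-{bp.right_first_retained:,}, {bp.build})")

alleles = simulate_sequences(deletion_spec=bp, seed=3)
j = len(alleles.left_flank)
read = alleles.deleted[j - 40 : j + len(bp.insert_seq) + 40]
insert, microhomology = characterize_junction(
    alleles.left_flank, alleles.right_flank, read
)
print(f"junction read resolves: insert={insert!r} ({len(insert)} bp), "
      f"microhomology={microhomology}")

assay = AssayConfig()  # 481 bp wild-type band, 254 bp breakpoint band
for label, pair in {
    "wt/wt": (alleles.wild_type, alleles.wild_type),
    "wt/del": (alleles.wild_type, alleles.deleted),
    "del/del": (alleles.deleted, alleles.deleted),
}.items():
    bands = set()
    for seq in pair:
        bands |= {size for _, size in in_silico_pcr(seq, DEFAULT_PRIMERS)}
    call = genotype_from_bands(BandPattern(label, bands), assay).call
    print(f"constructed {label:<8} bands={sorted(bands)}  ->  called {call}")

# Both bands = heterozygote; the 481 bp internal band alone = no deletion;
# the 254 bp breakpoint band alone = homozygous deletion.
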