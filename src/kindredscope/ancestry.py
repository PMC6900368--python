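"""Reference-panel QC, LD pruning, PCA projection, and phased-block
population-of-origin inference.

The question answered here: given one phased haplotype flanking a structural
variant, and a multi-population SNP reference panel, which population did
that haplotype most plausibly originate from?  After LD pruning the panel
sites are treated as independent, so the haplotype likelihood under
population *k* is a product of per-site allele probabilities with additive
(Laplace) smoothing:

    P(hap | k) = prod_s (c_{k,s,allele} + alpha) / (c_{k,s,total} + 2 alpha)

where c are the population's allele counts at site s (or frequencies times a
nominal panel size when only frequencies are known).  Per-population
posteriors are the softmax of these log-likelihoods times a prior (uniform
by default).  This is a deliberately simple independent-sites model — no
haplotype-copying, no recombination map — adequate for ranking candidate
source populations when the block is short and the panel is pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePanel",
    "LDPruneConfig",
    "PhasedBlock",
    "AncestryPosterior",
    "qc_panel",
    "ld_prune",
    "pca_project",
    "block_loglik",
    "phased_block_loglik",
    "block_origin_posterior",
    "population_posterior",
    "rank_populations",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24", "25"}


@dataclass
class ReferencePanel:
    """Population-labelled SNP allele frequencies.

    ``snps``: DataFrame with columns chrom, pos, ref, alt (one row per site,
    position-sorted within chromosome).  ``freq``: (n_snps, n_pops) array of
    alternate-allele frequencies.  ``counts``: optional (n_snps, n_pops)
    array of total allele counts (2N per population); when absent, smoothing
    assumes ``nominal_chromosomes`` per population.
    """

    populations: list[str]
    snps: pd.DataFrame
    freq: np.ndarray
    counts: np.ndarray | None = None
    superpop: dict[str, str] = field(default_factory=dict)
    nominal_chromosomes: int = 100

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.snps), len(self.populations)):
            raise ValueError(
                f"freq shape {self.freq.shape} != "
                f"({len(self.snps)}, {len(self.populations)})"
            )
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def site_index(self, chrom: str, pos: int) -> int:
        hits = self.snps.index[
            (self.snps["chrom"].astype(str) == str(chrom)) & (self.snps["pos"] == pos)
        ]
        if len(hits) == 0:
            raise KeyError(f"site {chrom}:{pos} absent from panel")
        return int(hits[0])


@dataclass
class LDPruneConfig:
    """Windowed pairwise pruning parameters (window size and step in SNPs,
    squared-correlation ceiling), plink indep-pairwise style."""

    window_snps: int = 1000
    step_snps: int = 5
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")
        if self.step_snps > self.window_snps:
            raise ValueError("step must not exceed window")


@dataclass
class PhasedBlock:
    """One phased block flanking the structural variant: the haplotype that
    carries the SV and its homolog, as 0/1 alternate-allele indicators over
    ``sites`` (list of (chrom, pos) sorted by position)."""

    sites: list[tuple[str, int]]
    hap_with_sv: np.ndarray
    hap_other: np.ndarray | None = None
    sv_position: int | None = None

    def __post_init__(self) -> None:
        self.hap_with_sv = np.asarray(self.hap_with_sv, dtype=int)
        if len(self.hap_with_sv) != len(self.sites):
            raise ValueError("one allele per site required")
        if self.hap_other is not None:
            self.hap_other = np.asarray(self.hap_other, dtype=int)
            if len(self.hap_other) != len(self.sites):
                raise ValueError("one allele per site required on the homolog")
        positions = [p for _, p in self.sites]
        if positions != sorted(positions):
            raise ValueError("block sites must be position-sorted")


@dataclass
class AncestryPosterior:
    populations: list[str]
    log_likelihood: dict[str, float]
    probability: dict[str, float]
    alpha: float
    n_sites: int


# ---------------------------------------------------------------------------


def qc_panel(
    snps: pd.DataFrame,
    freq: np.ndarray,
    populations: Sequence[str],
    maf_min: float = 0.05,
    counts: np.ndarray | None = None,
    superpop: Mapping[str, str] | None = None,
) -> ReferencePanel:
    """Panel QC: drop multi-allelic sites, sex-chromosome sites, and sites
    with pooled minor allele frequency below ``maf_min`` (exactly ``maf_min``
    is retained).

    Multi-allelic sites are recognized by an ``alt`` cell listing several
    alleles (comma-separated) or an ``n_alleles`` column > 2.
    """
    snps = snps.reset_index(drop=True)
    freq = np.asarray(freq, dtype=float)
    keep = np.ones(len(snps), dtype=bool)

    alt = snps["alt"].astype(str)
    keep &= ~alt.str.contains(",").to_numpy()
    if "n_alleles" in snps.columns:
        keep &= (snps["n_alleles"].astype(int) <= 2).to_numpy()

    keep &= ~snps["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()

    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        tot = counts.sum(axis=1)
        pooled = np.divide(
            (freq * counts).sum(axis=1), tot, out=np.zeros(len(snps)), where=tot > 0
        )
    else:
        pooled = freq.mean(axis=1)
    maf = np.minimum(pooled, 1.0 - pooled)
    keep &= maf >= maf_min

    idx = np.flatnonzero(keep)
    return ReferencePanel(
        populations=list(populations),
        snps=snps.loc[idx].reset_index(drop=True),
        freq=freq[idx],
        counts=None if counts is None else counts[idx],
        superpop=dict(superpop or {}),
    )


def ld_prune(genotypes: np.ndarray, config: LDPruneConfig | None = None) -> list[int]:
    """Windowed pairwise LD pruning of dosage-coded genotypes.

    ``genotypes``: (n_samples, n_sites) array of 0/1/2 dosages, sites sorted
    by position.  Within each sliding window, whenever a retained pair has
    squared Pearson correlation above ``r2_max`` the *later* site (in
    position order) is dropped.  Windows advance by ``step_snps``.  Returns
    the retained site indices in input order.
    """
    config = config or LDPruneConfig()
    G = np.asarray(genotypes, dtype=float)
    n_sites = G.shape[1]
    if n_sites < 2:
        return list(range(n_sites))
    keep = np.ones(n_sites, dtype=bool)

    start = 0
    while True:
        end = min(start + config.window_snps, n_sites)
        idx = [i for i in range(start, end) if keep[i]]
        for ai in range(len(idx)):
            i = idx[ai]
            if not keep[i]:
                continue
            for bi in range(ai + 1, len(idx)):
                j = idx[bi]
                if not keep[j]:
                    continue
                r2 = _r2(G[:, i], G[:, j])
                if r2 > config.r2_max:
                    keep[j] = False
        if end >= n_sites:
            break
        start += config.step_snps
    return [i for i in range(n_sites) if keep[i]]


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic sites carry no LD information
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def pca_project(
    panel_genotypes: np.ndarray,
    query_genotypes: np.ndarray,
    n_pcs: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the panel with projection of query samples.

    Panel dosages (n_samples, n_sites) are centered at 2p and scaled by
    sqrt(2p(1-p)) per site (p = panel alternate-allele frequency); missing
    dosages (NaN) are mean-imputed per site before scaling.  Queries
    ((n_query, n_sites), same site set and order) are standardized with the
    *panel's* statistics and projected onto the panel's right singular
    vectors.  Returns (panel coordinates, query coordinates), each with
    ``n_pcs`` columns.
    """
    P = np.array(panel_genotypes, dtype=float)
    Q = np.atleast_2d(np.array(query_genotypes, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValueError("panel and query must share the same site set")
    if P.shape[1] < n_pcs:
        raise ValueError(f"need at least {n_pcs} sites, got {P.shape[1]}")

    col_mean = np.nanmean(P, axis=0)
    P = np.where(np.isnan(P), col_mean, P)
    Q = np.where(np.isnan(Q), col_mean, Q)

    p = col_mean / 2.0
    scale = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
    Pz = (P - col_mean) / scale
    Qz = (Q - col_mean) / scale

    # right singular vectors of the standardized panel are the SNP loadings
    _, _, vt = np.linalg.svd(Pz, full_matrices=False)
    loadings = vt[:n_pcs].T  # (n_sites, n_pcs)
    return Pz @ loadings, Qz @ loadings


def block_loglik(
    block_hap: np.ndarray | Sequence[int],
    panel: ReferencePanel,
    population: str,
    alpha: float = 0.5,
    site_indices: Sequence[int] | None = None,
) -> float:
    """Log-likelihood of one haplotype under one population's frequencies.

    ``block_hap``: 0/1 alternate-allele indicators, aligned to
    ``site_indices`` into the panel (defaults to the first len(hap) panel
    sites).  Smoothing: P(allele) = (c_allele + alpha) / (c_total + 2 alpha)
    with c from population allele counts, or frequency times the panel's
    nominal chromosome count when counts are unavailable.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    try:
        k = panel.populations.index(population)
    except ValueError:
        raise KeyError(f"population {population!r} not in panel") from None
    hap = np.asarray(block_hap, dtype=int)
    if site_indices is None:
        site_indices = list(range(len(hap)))
    site_indices = list(site_indices)
    if len(site_indices) != len(hap):
        raise ValueError("one site index per haplotype allele required")
    bad = [i for i in site_indices if i < 0 or i >= len(panel.snps)]
    if bad:
        raise KeyError(f"sites absent from panel: indices {bad}")

    if panel.counts is not None:
        totals = panel.counts[site_indices, k]
    else:
        totals = np.full(len(hap), float(panel.nominal_chromosomes))
    alt_counts = panel.freq[site_indices, k] * totals
    c_allele = np.where(hap == 1, alt_counts, totals - alt_counts)
    probs = (c_allele + alpha) / (totals + 2.0 * alpha)
    return float(np.sum(np.log(probs)))


def phased_block_loglik(
    block: PhasedBlock,
    panel: ReferencePanel,
    population: str,
    alpha: float = 0.5,
    site_indices: Sequence[int] | None = None,
) -> float:
    """Log-likelihood of a phased block's *genotype* under one population.

    The observation is the pair of haplotypes over the block's sites; given
    the population they are independent, so the block log-likelihood is the
    sum of the two per-haplotype terms (or the single available haplotype
    when the homolog is unknown).  Site indices default to a lookup of the
    block's (chrom, pos) sites in the panel.
    """
    if site_indices is None:
        site_indices = [panel.site_index(c, p) for c, p in block.sites]
    total = block_loglik(block.hap_with_sv, panel, population, alpha, site_indices)
    if block.hap_other is not None:
        total += block_loglik(block.hap_other, panel, population, alpha, site_indices)
    return total


def block_origin_posterior(
    block: PhasedBlock,
    panel: ReferencePanel,
    alpha: float = 0.5,
    prior: Mapping[str, float] | None = None,
    site_indices: Sequence[int] | None = None,
) -> AncestryPosterior:
    """Posterior population-of-origin of one phased block over the whole panel."""
    logliks = {
        pop: phased_block_loglik(block, panel, pop, alpha, site_indices)
        for pop in panel.populations
    }
    return population_posterior(logliks, prior, alpha=alpha, n_sites=len(block.sites))


def population_posterior(
    logliks: Mapping[str, float],
    prior: Mapping[str, float] | None = None,
    alpha: float = 0.5,
    n_sites: int = 0,
) -> AncestryPosterior:
    """Normalize per-population log-likelihoods into posterior probabilities.

    probability_k = prior_k * exp(loglik_k) / sum_j prior_j * exp(loglik_j),
    computed with max-subtraction for stability.  Default prior is uniform.
    """
    pops = sorted(logliks)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    ll = np.array([logliks[p] for p in pops], dtype=float)
    if np.all(np.isneginf(ll)):
        raise ValueError("all log-likelihoods are -inf")
    if prior is None:
        logprior = np.zeros(len(pops))
    else:
        pr = np.array([prior[p] for p in pops], dtype=float)
        if np.any(pr < 0) or pr.sum() <= 0:
            raise ValueError("prior must be non-negative and not all zero")
        with np.errstate(divide="ignore"):
            logprior = np.log(pr / pr.sum())
    z = ll + logprior
    z = z - np.max(z[np.isfinite(z)])
    w = np.exp(z)
    probs = w / w.sum()
    return AncestryPosterior(
        populations=pops,
        log_likelihood={p: float(v) for p, v in zip(pops, ll)},
        probability={p: float(v) for p, v in zip(pops, probs)},
        alpha=alpha,
        n_sites=n_sites,
    )


@dataclass
class PopulationRank:
    population: str
    probability: float
    tied: bool = False


def rank_populations(posterior: AncestryPosterior) -> list[PopulationRank]:
    """Populations ordered by posterior probability (descending), ties broken
    lexically and flagged."""
    items = sorted(
        posterior.probability.items(), key=lambda kv: (-kv[1], kv[0])
    )
    out = []
    for i, (pop, p) in enumerate(items):
        tied = any(
            j != i and abs(items[j][1] - p) < 1e-12 for j in (i - 1, i + 1)
            if 0 <= j < len(items)
        )
        out.append(PopulationRank(pop, p, tied))
    return out
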