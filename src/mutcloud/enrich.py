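"""Replicate-convergence test for putatively beneficial genes.

Under the null, each high-frequency mutant gene observed in a replicate is
placed on an annotated gene with probability proportional to gene length.
For a gene hit in ``n_g`` of ``R`` replicates the statistic is the point
probability that exactly that set size is hit:

    P_g = p_g**n_g * sum over size-n_g replicate subsets S of
          (prod_{r in S} n_r) * (1 - p_g)**(n_tot - sum_{r in S} n_r)

where ``n_r`` is the number of distinct mutant genes in replicate ``r`` and
``n_tot = sum_r n_r``.  With every ``n_r = 1`` this reduces to the binomial
pmf ``C(R, n_g) p^n_g (1-p)^(R-n_g)``.

Note this is a point probability ("exactly n_g replicates"), not an upper
tail; the Monte-Carlo oracle reports both for comparison.  No multiple-
testing correction is applied beyond the fixed significance threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "gene_hit_probability",
    "gene_hit_probabilities",
    "count_replicate_subsets",
    "enrichment_probability",
    "HitMatrix",
    "build_hit_matrix",
    "scan_genes",
    "call_significant",
    "monte_carlo_null",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 5e-5  # 0.005 percent
ENUMERATION_LIMIT = 200_000


def gene_hit_probabilities(gene_table: pd.DataFrame) -> pd.Series:
    """Per-gene null hit probability p_g = l_g / sum(l), indexed by gene_id."""
    lengths = (gene_table["end"] - gene_table["start"] + 1).astype(float)
    if (lengths < 1).any():
        bad = gene_table.loc[lengths < 1, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    p = lengths / lengths.sum()
    p.index = gene_table["gene_id"].values
    return p


def gene_hit_probability(gene_table: pd.DataFrame, gene_id: str) -> float:
    """Null probability that one length-proportional hit lands in `gene_id`."""
    p = gene_hit_probabilities(gene_table)
    if gene_id not in p.index:
        raise KeyError(f"gene {gene_id!r} not in gene table")
    return float(p.loc[gene_id])


def count_replicate_subsets(R_size: int, n_g: int) -> int:
    """Number of ways n_g hits can be distributed over R_size replicates."""
    return math.comb(R_size, n_g)


def _enrichment_enumeration(n_rs: np.ndarray, n_g: int, p_g: float) -> float:
    n_tot = int(n_rs.sum())
    total = 0.0
    for subset in itertools.combinations(range(len(n_rs)), n_g):
        chosen = n_rs[list(subset)]
        ssum = int(chosen.sum())
        assert n_tot - ssum >= 0
        total += np.prod(chosen.astype(float)) * (1.0 - p_g) ** (n_tot - ssum)
    return p_g**n_g * total


def _enrichment_dp(n_rs: np.ndarray, n_g: int, p_g: float) -> float:
    # f[j, t] = sum over size-j subsets with count-sum t of prod n_r
    n_tot = int(n_rs.sum())
    f = np.zeros((n_g + 1, n_tot + 1))
    f[0, 0] = 1.0
    for n_r in n_rs:
        n_r = int(n_r)
        for j in range(n_g, 0, -1):
            f[j, n_r:] += f[j - 1, : n_tot + 1 - n_r] * n_r
    weights = (1.0 - p_g) ** (n_tot - np.arange(n_tot + 1))
    return p_g**n_g * float(f[n_g] @ weights)


def enrichment_probability(
    n_rs,
    n_g: int,
    p_g: float,
    method: str = "auto",
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> float:
    """Point probability P_g that exactly n_g replicates hit a gene.

    ``n_rs`` are per-replicate mutant-gene counts.  ``method`` is one of
    "auto", "enumeration", "dp"; "auto" enumerates subsets when
    ``C(R, n_g)`` is small and otherwise uses a dynamic program over
    (subset size, chosen count-sum), which is exact.
    """
    n_rs = np.asarray(n_rs, dtype=int)
    R = len(n_rs)
    if not 1 <= n_g <= R:
        raise ValueError(f"n_g must be in [1, {R}], got {n_g}")
    if (n_rs < 0).any():
        raise ValueError("replicate mutant-gene counts must be >= 0")
    if not 0.0 <= p_g < 1.0:
        raise ValueError(f"p_g must be in [0, 1), got {p_g}")
    if p_g == 0.0:
        return 0.0
    if method == "auto":
        method = (
            "enumeration"
            if count_replicate_subsets(R, n_g) <= enumeration_limit
            else "dp"
        )
    if method == "enumeration":
        return _enrichment_enumeration(n_rs, n_g, p_g)
    if method == "dp":
        return _enrichment_dp(n_rs, n_g, p_g)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class HitMatrix:
    """Per-replicate sets of genes carrying a high-frequency derived allele."""

    gene_sets: dict[str, set[str]]
    intergenic: dict[str, int] = field(default_factory=dict)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.gene_sets)

    @property
    def n_r(self) -> dict[str, int]:
        return {r: len(s) for r, s in self.gene_sets.items()}

    @property
    def n_tot(self) -> int:
        return sum(len(s) for s in self.gene_sets.values())

    def n_g(self, gene_id: str) -> int:
        return sum(gene_id in s for s in self.gene_sets.values())

    def genes_hit(self) -> set[str]:
        out: set[str] = set()
        for s in self.gene_sets.values():
            out |= s
        return out


def build_hit_matrix(
    variants: pd.DataFrame,
    gene_table: pd.DataFrame,
    generation: int | None = None,
    threshold: float = 0.5,
    ancestral_mask: pd.DataFrame | None = None,
) -> HitMatrix:
    """Collect, per replicate population, the genes with a derived allele at
    frequency strictly above `threshold` at the focal generation.

    A gene with several qualifying mutations in one replicate counts once.
    High-frequency intergenic alleles are tallied separately and excluded
    from the test.  ``ancestral_mask`` optionally removes (position,
    derived_base) pairs already segregating in the ancestor.
    """
    if generation is None:
        generation = int(variants["generation"].max())
    sub = variants[variants["generation"] == generation]
    sub = sub[sub["frequency"] > threshold]
    if ancestral_mask is not None and len(ancestral_mask):
        key = sub["position"].astype(str) + ":" + sub["derived_base"]
        mask_key = set(
            ancestral_mask["position"].astype(str) + ":" + ancestral_mask["derived_base"]
        )
        sub = sub[~key.isin(mask_key)]
    known = set(gene_table["gene_id"])
    gene_sets: dict[str, set[str]] = {}
    intergenic: dict[str, int] = {}
    for pop, grp in sub.groupby("population_id", sort=True):
        in_genes = grp[grp["gene_id"].isin(known)]
        gene_sets[str(pop)] = set(in_genes["gene_id"])
        intergenic[str(pop)] = int((~grp["gene_id"].isin(known)).sum())
    # replicates with no qualifying hits still need an entry (n_r = 0)
    for pop in variants["population_id"].unique():
        gene_sets.setdefault(str(pop), set())
        intergenic.setdefault(str(pop), 0)
    return HitMatrix(gene_sets=dict(sorted(gene_sets.items())), intergenic=intergenic)


def scan_genes(
    hits: HitMatrix,
    gene_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Compute n_g, p_g and P_g for every gene hit in at least one replicate."""
    p_all = gene_hit_probabilities(gene_table)
    n_rs = np.array([len(hits.gene_sets[r]) for r in hits.replicate_ids])
    rows = []
    for gene in sorted(hits.genes_hit()):
        if gene not in p_all.index:
            logger.warning("gene %r hit but absent from gene table; skipped", gene)
            continue
        n_g = hits.n_g(gene)
        p_g = float(p_all.loc[gene])
        P_g = enrichment_probability(n_rs, n_g, p_g)
        rows.append({"gene_id": gene, "n_g": n_g, "p_g": p_g, "P_g": P_g})
    result = pd.DataFrame(rows, columns=["gene_id", "n_g", "p_g", "P_g"])
    return call_significant(result, alpha)


def call_significant(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Flag genes with P_g strictly below `alpha` (default 0.005%)."""
    out = results.copy()
    out["significant"] = out["P_g"] < alpha
    return out


def monte_carlo_null(
    n_rs,
    n_g: int,
    p_g: float,
    n_sims: int = 100_000,
    seed: int | None = None,
) -> dict:
    """Monte-Carlo estimate of the null probability of the observed hit count.

    Each simulation throws, per replicate r, its n_r observed mutant genes
    independently, each landing in the focal gene with probability p_g; the
    replicate is a "hit" if at least one lands there.  Returns the fraction
    of simulations with exactly (and with at least) n_g hit replicates, with
    binomial standard errors.
    """
    n_rs = np.asarray(n_rs, dtype=int)
    rng = np.random.default_rng(seed)
    hit_prob = 1.0 - (1.0 - p_g) ** n_rs
    hits = (rng.random((n_sims, len(n_rs))) < hit_prob).sum(axis=1)
    p_exact = float(np.mean(hits == n_g))
    p_tail = float(np.mean(hits >= n_g))

    def se(p: float) -> float:
        return math.sqrt(p * (1.0 - p) / n_sims)

    return {
        "p_exact": p_exact,
        "se_exact": se(p_exact),
        "p_tail": p_tail,
        "se_tail": se(p_tail),
        "n_sims": n_sims,
    }
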