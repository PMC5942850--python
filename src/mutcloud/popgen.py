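"""Mutant-cloud and diversity metrics from pooled-sequencing allele tables.

All metrics consume a variant table with one row per (population,
generation, position, derived allele):

    population_id, generation, position (1-based), ref_base, derived_base,
    frequency, depth, majority_reads, gene_id, effect_class

Site diversity is computed as mismatching read pairs over total pairs,
``m_p (m - m_p) / (m (m - 1) / 2)`` with ``m_p`` the majority-allele read
count out of ``m`` reads.  NOTE: a printed variant of this formula with a
proportion in the numerator is dimensionally inconsistent with pairwise
read counting; the pair-counting form is used throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "site_spread",
    "cloud_spread",
    "consensus_distance",
    "site_diversity",
    "mean_diversity",
    "high_frequency_derived",
    "mutational_spectrum",
    "CloudSummary",
    "summarize_populations",
    "SpectrumProfile",
    "SPECTRUM_CLASSES",
]

VARIANT_COLUMNS = [
    "population_id",
    "generation",
    "position",
    "ref_base",
    "derived_base",
    "frequency",
    "depth",
    "majority_reads",
    "gene_id",
    "effect_class",
]

SPECTRUM_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def site_spread(p_majority: float) -> float:
    """Fraction of the population not carrying the site's majority allele."""
    if not 0.5 < p_majority <= 1.0:
        raise ValueError(
            f"majority-allele frequency must be in (0.5, 1], got {p_majority}"
        )
    return 1.0 - p_majority


def _site_alleles(table: pd.DataFrame):
    """Yield (position, majority_freq, majority_is_derived) per variant site.

    Handles multi-allelic sites (several derived alleles at one position):
    the majority allele is the most frequent among ancestral + derived.
    Exact frequency ties (no majority) are excluded with a warning.
    """
    multi = table["position"].duplicated(keep=False)
    simple = table[~multi]
    for pos, freq in zip(simple["position"].values, simple["frequency"].values):
        if freq == 0.5:
            logger.warning("site %d has no majority allele (p = 0.5); excluded", pos)
            continue
        p_maj = max(freq, 1.0 - freq)
        yield int(pos), float(p_maj), bool(freq > 0.5)
    if multi.any():
        for pos, grp in table[multi].groupby("position"):
            derived = grp["frequency"].values
            anc = 1.0 - derived.sum()
            freqs = np.append(derived, max(anc, 0.0))
            order = np.argsort(freqs)[::-1]
            if len(freqs) > 1 and freqs[order[0]] == freqs[order[1]]:
                logger.warning(
                    "site %d has tied top alleles; excluded from spread/distance", pos
                )
                continue
            yield int(pos), float(freqs[order[0]]), bool(order[0] < len(derived))


def cloud_spread(table: pd.DataFrame, denominator_sites: int) -> float:
    """Population spread C: mean non-majority fraction over all genome sites.

    Variant rows contribute ``1 - p_majority``; the remaining
    ``denominator_sites`` - (variant sites) monomorphic sites contribute 0.
    """
    contributions = [1.0 - p_maj for _, p_maj, _ in _site_alleles(table)]
    if denominator_sites < len(contributions):
        raise ValueError(
            f"denominator ({denominator_sites}) smaller than number of variant "
            f"sites ({len(contributions)})"
        )
    if denominator_sites == 0:
        return 0.0
    return float(np.sum(contributions)) / denominator_sites


def consensus_distance(table: pd.DataFrame) -> int:
    """Number of sites whose majority allele differs from the ancestral allele."""
    return sum(is_derived for _, _, is_derived in _site_alleles(table))


def site_diversity(m_p: int, m: int) -> float:
    """Per-site diversity: mismatching read pairs over all read pairs."""
    if m < 2:
        raise ValueError(f"site diversity needs >= 2 reads, got m = {m}")
    if not 0 <= m_p <= m:
        raise ValueError(f"majority reads m_p = {m_p} outside [0, m = {m}]")
    return m_p * (m - m_p) / (m * (m - 1) / 2.0)


def mean_diversity(table: pd.DataFrame, L_covered: int) -> float:
    """Mean nucleotide site diversity over the L covered genome positions.

    Sites with fewer than 2 reads are excluded (and logged); invariant
    covered positions contribute 0 to the numerator.
    """
    if L_covered <= 0:
        raise ValueError("L_covered must be positive")
    m = table["depth"].to_numpy(dtype=float)
    m_p = table["majority_reads"].to_numpy(dtype=float)
    usable = m >= 2
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("%d variant sites with depth < 2 excluded from pi", n_dropped)
    m, m_p = m[usable], m_p[usable]
    total = np.sum(m_p * (m - m_p) / (m * (m - 1) / 2.0))
    return float(total) / L_covered


def high_frequency_derived(table: pd.DataFrame, threshold: float = 0.5) -> int:
    """Number of sites with a derived allele strictly above `threshold`."""
    return int((table["frequency"] > threshold).sum())


@dataclass
class SpectrumProfile:
    """Folded point-mutation spectrum over the six strand-symmetric classes."""

    counts: dict[str, int]
    frequencies: dict[str, float]
    total: int


def fold_change(ref_base: str, derived_base: str) -> str:
    """Map a point mutation onto its folded class (purine-ref orientation).

    Reverse-complement pairs collapse: e.g. T>G is reported as A>C.
    """
    ref, der = ref_base.upper(), derived_base.upper()
    if ref not in _COMPLEMENT or der not in _COMPLEMENT:
        raise ValueError(f"invalid bases {ref_base!r} -> {derived_base!r}")
    if ref == der:
        raise ValueError(f"ref and derived base identical: {ref}")
    if ref in ("T", "G"):
        ref, der = _COMPLEMENT[ref], _COMPLEMENT[der]
    return f"{ref}>{der}"


def mutational_spectrum(
    table: pd.DataFrame, site_mask=None
) -> SpectrumProfile:
    """Relative frequencies of the six folded mutational classes.

    ``site_mask`` optionally restricts to designated positions (e.g.
    four-fold-degenerate sites); it may be a set/sequence of positions.
    """
    sub = table
    if site_mask is not None:
        mask = set(int(p) for p in site_mask)
        sub = table[table["position"].isin(mask)]
    counts = Counter(
        fold_change(r, d) for r, d in zip(sub["ref_base"], sub["derived_base"])
    )
    full = {c: int(counts.get(c, 0)) for c in SPECTRUM_CLASSES}
    total = sum(full.values())
    freqs = {c: (n / total if total else 0.0) for c, n in full.items()}
    return SpectrumProfile(counts=full, frequencies=freqs, total=total)


@dataclass
class CloudSummary:
    population_id: str
    generation: int
    C: float
    D: int
    pi: float
    hf_count: int
    L_covered: int


def summarize_populations(
    table: pd.DataFrame,
    genome_length: int,
    L_covered: int | None = None,
    hf_threshold: float = 0.5,
) -> pd.DataFrame:
    """One tidy row of cloud metrics per (population, generation).

    C is averaged over the whole genome length; pi over the covered-position
    count (defaults to the genome length when no coverage report is given).
    """
    if L_covered is None:
        L_covered = genome_length
    rows = []
    for (pop, gen), grp in table.groupby(["population_id", "generation"], sort=True):
        rows.append(
            CloudSummary(
                population_id=str(pop),
                generation=int(gen),
                C=cloud_spread(grp, genome_length),
                D=consensus_distance(grp),
                pi=mean_diversity(grp, L_covered),
                hf_count=high_frequency_derived(grp, hf_threshold),
                L_covered=L_covered,
            ).__dict__
        )
    return pd.DataFrame(
        rows, columns=["population_id", "generation", "C", "D", "pi", "hf_count", "L_covered"]
    )
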