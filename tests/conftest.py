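import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def gene_table() -> pd.DataFrame:
    """Ten genes of varying length on a 10 kb toy genome."""
    rows = []
    pos = 1
    lengths = [100, 300, 600, 150, 450, 200, 800, 120, 500, 280]
    for i, ln in enumerate(lengths):
        rows.append(
            {"gene_id": f"g{i + 1:02d}", "start": pos, "end": pos + ln - 1, "strand": "+"}
        )
        pos += ln + 50
    df = pd.DataFrame(rows)
    df["length"] = df["end"] - df["start"] + 1
    return df


def make_variants(records, population_id="p1", generation=100):
    """Variant-table rows from (position, frequency[, extras]) tuples."""
    rows = []
    for rec in records:
        row = {
            "population_id": population_id,
            "generation": generation,
            "position": rec[0],
            "ref_base": "A",
            "derived_base": "G",
            "frequency": rec[1],
            "depth": 100,
            "majority_reads": round(100 * max(rec[1], 1 - rec[1])),
            "gene_id": "intergenic",
            "effect_class": "intergenic",
        }
        if len(rec) > 2:
            row.update(rec[2])
        rows.append(row)
    columns = [
        "population_id", "generation", "position", "ref_base", "derived_base",
        "frequency", "depth", "majority_reads", "gene_id", "effect_class",
    ]
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture
def random_variant_table():
    """Factory for random but valid single-population variant tables."""

    def build(n_sites: int, seed: int, pop="p1", gen=100) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        positions = rng.choice(np.arange(1, 100_000), size=n_sites, replace=False)
        freqs = rng.uniform(0.01, 0.99, size=n_sites)
        depths = rng.integers(2, 400, size=n_sites)
        bases = np.array(list("ACGT"))
        refs = rng.integers(0, 4, size=n_sites)
        ders = (refs + rng.integers(1, 4, size=n_sites)) % 4
        rows = []
        for i in range(n_sites):
            m = int(depths[i])
            m_p = int(round(m * max(freqs[i], 1 - freqs[i])))
            rows.append(
                {
                    "population_id": pop,
                    "generation": gen,
                    "position": int(positions[i]),
                    "ref_base": bases[refs[i]],
                    "derived_base": bases[ders[i]],
                    "frequency": float(freqs[i]),
                    "depth": m,
                    "majority_reads": min(m_p, m),
                    "gene_id": "intergenic",
                    "effect_class": "intergenic",
                }
            )
        return pd.DataFrame(rows)

    return build
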