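"""Readers/writers for interchange formats, run configuration and pipeline.

All tabular interchange is plain text: tab-separated variant/gene tables
and comma-separated count, fluctuation, growth and plate tables, UTF-8,
'.' decimal.  Genome coordinates are 1-based inclusive everywhere (GFF3
convention); a position of 0 on input is rejected as a coordinate-
convention error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effective_size, enrich, fluctuation, phenotype, popgen, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_gene_table",
    "write_gene_table",
    "read_count_series",
    "write_count_series",
    "read_fluctuation",
    "write_fluctuation",
    "read_plate",
    "write_plate",
    "read_growth_curves",
    "write_growth_curves",
    "load_config",
    "run_pipeline",
]

VARIANT_DTYPES = {
    "population_id": str,
    "generation": int,
    "position": int,
    "ref_base": str,
    "derived_base": str,
    "frequency": float,
    "depth": int,
    "majority_reads": int,
    "gene_id": str,
    "effect_class": str,
}


def read_variant_table(path, genome_length: int | None = None) -> pd.DataFrame:
    """Read and validate a variant table TSV (see VARIANT_DTYPES for schema)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_DTYPES) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.astype(VARIANT_DTYPES)
    # +2 -> 1-based data lines after the header line
    for idx, freq in df["frequency"].items():
        if not 0.0 <= freq <= 1.0:
            raise ValueError(
                f"{path}: line {idx + 2}, column 'frequency': {freq} outside [0, 1]"
            )
    zero = df.index[df["position"] == 0]
    if len(zero):
        raise ValueError(
            f"{path}: line {zero[0] + 2}: position 0 found - positions are "
            "1-based inclusive; input looks 0-based"
        )
    if (df["position"] < 1).any():
        bad = df.index[df["position"] < 1][0]
        raise ValueError(f"{path}: line {bad + 2}: negative position")
    if genome_length is not None and (df["position"] > genome_length).any():
        bad = df.index[df["position"] > genome_length][0]
        raise ValueError(
            f"{path}: line {bad + 2}: position exceeds genome length {genome_length}"
        )
    if (df["majority_reads"] > df["depth"]).any():
        bad = df.index[df["majority_reads"] > df["depth"]][0]
        raise ValueError(f"{path}: line {bad + 2}: majority_reads exceeds depth")
    if (df["ref_base"] == df["derived_base"]).any():
        bad = df.index[df["ref_base"] == df["derived_base"]][0]
        raise ValueError(f"{path}: line {bad + 2}: ref_base equals derived_base")
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    df[list(VARIANT_DTYPES)].to_csv(path, sep="\t", index=False)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Read gene annotation from GFF3 or a 4-column TSV.

    The TSV form has a header ``gene_id, start, end, strand``.  GFF3 input
    keeps ``gene`` features (or all features if none are typed ``gene``),
    naming each by ID, locus_tag, gene or Name attribute.  Coordinates are
    1-based inclusive; lengths are ``end - start + 1``.  Overlapping genes
    are preserved unmerged.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    is_gff = first.startswith("##gff") or (
        len(first.split("\t")) == 9 and not first.startswith("gene_id")
    )
    if is_gff:
        rows = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = fields
            rows.append(
                {
                    "feature_type": ftype,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "attrs": _parse_gff_attributes(attrs),
                }
            )
        genes = [r for r in rows if r["feature_type"] == "gene"] or rows
        records = []
        for r in genes:
            a = r["attrs"]
            gene_id = a.get("ID") or a.get("locus_tag") or a.get("gene") or a.get("Name")
            if gene_id is None:
                raise ValueError(f"{path}: gene feature without an identifier attribute")
            records.append(
                {"gene_id": gene_id, "start": r["start"], "end": r["end"], "strand": r["strand"]}
            )
        df = pd.DataFrame(records, columns=["gene_id", "start", "end", "strand"])
    else:
        df = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "start", "end", "strand"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.astype({"gene_id": str, "start": int, "end": int, "strand": str})
    if (df["start"] < 1).any():
        raise ValueError(f"{path}: gene start < 1 (coordinates are 1-based)")
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: gene end < start")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    df["length"] = df["end"] - df["start"] + 1
    return df.reset_index(drop=True)


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[["gene_id", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def read_count_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"day", "population_id", "n_max"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_count_series(df: pd.DataFrame, path) -> None:
    df[["day", "population_id", "n_max"]].to_csv(path, index=False)


def read_fluctuation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"culture_id", "mutant_count", "n_final"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["n_final"].isna().any():
        raise ValueError(f"{path}: missing n_final values")
    return df


def write_fluctuation(df: pd.DataFrame, path) -> None:
    df[["culture_id", "mutant_count", "n_final"]].to_csv(path, index=False)


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "compound", "well", "time_label", "od600"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_plate(df: pd.DataFrame, path) -> None:
    df[["sample_id", "compound", "well", "time_label", "od600"]].to_csv(path, index=False)


def read_growth_curves(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"plate_id", "well", "sample_id", "time_h", "od600"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_growth_curves(df: pd.DataFrame, path) -> None:
    df[["plate_id", "well", "sample_id", "time_h", "od600"]].to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the full synthetic experiment: simulate every replicate of every
    mutation-rate class, then chain diversity metrics, the gene enrichment
    scan, effective-size and fluctuation-rate estimation, and growth fits.

    Returns the manifest (also written to ``manifest.json``), which records
    the configuration, seeds, output checksums and per-stage row counts so
    that identical config + seed reruns are verifiably byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config["simulation"]
    if seed is None:
        seed = int(config.get("seed", 0))
    genome_length = int(sim_cfg["genome_length"])
    gene_path = config.get("gene_table")
    if gene_path is not None and not Path(gene_path).exists():
        raise FileNotFoundError(f"gene table not found before run: {gene_path}")
    genes = read_gene_table(gene_path) if gene_path else _default_genes(genome_length)
    classes = sim_cfg["mutation_rates"]  # {class label: U}
    replicates = int(sim_cfg.get("replicates", 2))
    days = int(sim_cfg.get("days", 20))
    dilution = float(sim_cfg.get("dilution", 1000.0))
    n_max = int(sim_cfg.get("n_max", 20_000))
    depth = float(sim_cfg.get("seq_depth", 200.0))
    threshold = float(sim_cfg.get("detection_threshold", 0.05))

    variant_frames, count_rows = [], []
    root = np.random.SeedSequence(seed)
    class_seeds = root.spawn(len(classes) + 2)
    for (label, U), ss in zip(sorted(classes.items()), class_seeds):
        cfg = simulate.SimulationConfig(
            genome_length=genome_length,
            U=float(U),
            n_max=n_max,
            dilution=dilution,
            days=days,
            replicates=replicates,
            dfe=simulate.DFE(
                fraction_beneficial=float(sim_cfg.get("fraction_beneficial", 0.01)),
                beneficial_effect=float(sim_cfg.get("beneficial_effect", 0.05)),
                fraction_deleterious=float(sim_cfg.get("fraction_deleterious", 0.3)),
                deleterious_effect=float(sim_cfg.get("deleterious_effect", 0.03)),
            ),
            gene_table=genes,
            seq_depth=depth,
            detection_threshold=threshold,
        )
        for rep, rep_ss in enumerate(ss.spawn(replicates), start=1):
            pop_id = f"{label}_{rep}"
            snaps = simulate.simulate_replicate(cfg, rep_ss)
            snap = snaps[-1]
            table, _ = simulate.sample_reads(
                snap.population.allele_frequencies(),
                depth,
                threshold,
                rep_ss.spawn(1)[0],
                population_id=pop_id,
                generation=snap.generation,
                gene_table=genes,
            )
            variant_frames.append(table)
            count_rows.append({"day": days, "population_id": pop_id, "n_max": n_max})

    variants = pd.concat(variant_frames, ignore_index=True)
    write_variant_table(variants, out / "variants.tsv")
    write_gene_table(genes, out / "genes.tsv")
    write_count_series(pd.DataFrame(count_rows), out / "counts.csv")

    metrics = popgen.summarize_populations(variants, genome_length)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    hits = enrich.build_hit_matrix(variants, genes)
    scan = enrich.scan_genes(hits, genes)
    scan.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    (out / "hits.json").write_text(
        json.dumps({r: sorted(s) for r, s in hits.gene_sets.items()}, indent=1)
    )

    series = effective_size.CountSeries(
        [n_max] * days, dilution=dilution, population_id="all"
    )
    ne = effective_size.nominal_ne(series)
    pd.DataFrame(
        [{"population_id": "all", "days_used": series.days_used, "N_e": ne}]
    ).to_csv(out / "ne.tsv", sep="\t", index=False)

    fluct_cfg = config.get("fluctuation", {})
    mu_true = float(fluct_cfg.get("mu", 2e-8))
    fl = simulate.simulate_fluctuation(
        mu_true,
        float(fluct_cfg.get("n_final", 1e8)),
        int(fluct_cfg.get("cultures", 30)),
        class_seeds[-2],
    )
    write_fluctuation(fl, out / "fluctuation.csv")
    est = fluctuation.estimate_mu(fl)
    (out / "mutation_rate.json").write_text(json.dumps(est.__dict__, indent=1))

    growth_cfg = config.get("growth", {})
    times = np.arange(0.0, float(growth_cfg.get("hours", 18.0)), 1.0 / 6.0)
    curve = simulate.simulate_growth_curve(
        float(growth_cfg.get("r", 0.5)),
        float(growth_cfg.get("K", 1.0)),
        float(growth_cfg.get("n0", 0.02)),
        times,
        noise_sd=float(growth_cfg.get("noise_sd", 0.0)),
        seed=class_seeds[-1],
    )
    fit = phenotype.fit_logistic(curve)
    (out / "growth_fit.json").write_text(json.dumps(fit.__dict__, indent=1))

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config": config,
        "row_counts": {
            "variants": int(len(variants)),
            "metrics": int(len(metrics)),
            "enrichment": int(len(scan)),
            "fluctuation": int(len(fl)),
        },
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _default_genes(genome_length: int, n_genes: int = 20) -> pd.DataFrame:
    """Evenly spaced same-length genes covering ~60% of a toy genome."""
    gene_len = max(1, int(genome_length * 0.6 / n_genes))
    spacing = genome_length // n_genes
    rows = []
    for i in range(n_genes):
        start = i * spacing + 1
        rows.append(
            {
                "gene_id": f"g{i + 1:03d}",
                "start": start,
                "end": min(start + gene_len - 1, genome_length),
                "strand": "+",
            }
        )
    df = pd.DataFrame(rows)
    df["length"] = df["end"] - df["start"] + 1
    return df
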