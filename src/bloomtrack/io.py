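"""TSV readers and writers for every pipeline table.

All files are UTF-8, tab-separated, with a header row and feature or sample
ids in the first column.  Absent count cells mean zero; taxonomy tail ranks
are explicit empty strings ("." is never used as a missing-value marker).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import (
    DENOMINATOR_COLS,
    TAXONOMY_RANKS,
    Dataset,
    EnvSeries,
    VotuQuant,
    assign_phase,
    Treatment,
)

logger = logging.getLogger("bloomtrack")

_SILVA_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = "feature_id"
    if df.empty:
        return df.astype(int) if df.shape[1] else df
    df = df.fillna(0)
    arr = df.to_numpy()
    if (arr < 0).any():
        raise ValueError(f"negative counts in {path}")
    if np.allclose(arr, np.round(arr)):
        df = df.round().astype(np.int64)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    md["day"] = md["day"].astype(int)
    md["replicate"] = md.get("replicate", pd.Series("", index=md.index)).fillna("")
    known = {t.value for t in Treatment}
    bad = set(md["treatment"]) - known
    if bad:
        raise ValueError(f"unknown treatment label(s): {sorted(bad)}")
    md["phase"] = [
        assign_phase(d).value if t != Treatment.ENVIRONMENT.value else ""
        for t, d in zip(md["treatment"], md["day"])
    ]
    return md


def _split_silva(lineage: str) -> list[str]:
    parts = [p.strip() for p in str(lineage).split(";")]
    out = []
    for p in parts[: len(TAXONOMY_RANKS)]:
        for pref in _SILVA_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        out.append(p)
    out += [""] * (len(TAXONOMY_RANKS) - len(out))
    return out


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read taxonomy in per-rank columns or SILVA semicolon-joined dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = "feature_id"
    if "lineage" in df.columns:
        ranks = pd.DataFrame(
            [_split_silva(v) for v in df["lineage"]],
            index=df.index,
            columns=list(TAXONOMY_RANKS),
        )
        out = ranks
        if "confidence" in df.columns:
            out["confidence"] = df["confidence"].astype(float)
    else:
        out = df.reindex(columns=[*TAXONOMY_RANKS, "confidence"])
        out[list(TAXONOMY_RANKS)] = out[list(TAXONOMY_RANKS)].fillna("")
        out["confidence"] = out["confidence"].astype(float)
    return out


def read_cytometry(path: str | Path) -> pd.DataFrame:
    cy = pd.read_csv(path, sep="\t", index_col="sample_id")
    return cy[["cells_per_ml", "particles_per_ml"]].astype(float)


def read_votu_quant(path: str | Path) -> VotuQuant:
    """Read the long-format vOTU quantification table.

    Columns: votu_id, sample_id, length_bp, fpkm, fpkm_viral_total,
    r_viral, r_potential, and optionally mapped_reads.  The length and the
    per-sample denominators are repeated across rows and must be
    consistent.
    """
    long = pd.read_csv(path, sep="\t", dtype={"votu_id": str, "sample_id": str})
    lengths = long.groupby("votu_id")["length_bp"].agg(["min", "max"])
    if (lengths["min"] != lengths["max"]).any():
        bad = lengths.index[lengths["min"] != lengths["max"]][0]
        raise ValueError(f"inconsistent length_bp for vOTU '{bad}'")
    den = long.groupby("sample_id")[list(DENOMINATOR_COLS)].agg(["min", "max"])
    for col in DENOMINATOR_COLS:
        if (den[(col, "min")] != den[(col, "max")]).any():
            bad = den.index[den[(col, "min")] != den[(col, "max")]][0]
            raise ValueError(f"inconsistent {col} for sample '{bad}'")
    denominators = long.groupby("sample_id")[list(DENOMINATOR_COLS)].first()
    fpkm = long.pivot(index="votu_id", columns="sample_id", values="fpkm").fillna(0.0)
    fpkm.index.name = "feature_id"
    mapped = None
    if "mapped_reads" in long.columns and long["mapped_reads"].notna().any():
        mapped = (
            long.pivot(index="votu_id", columns="sample_id", values="mapped_reads")
            .fillna(0)
            .round()
            .astype(np.int64)
        )
        mapped = mapped.reindex(index=fpkm.index, columns=fpkm.columns)
    return VotuQuant(
        lengths=lengths["min"].astype(np.int64).rename("length_bp"),
        fpkm=fpkm,
        denominators=denominators.astype(float),
        mapped_reads=mapped,
    )


def read_host_predictions(path: str | Path) -> pd.DataFrame:
    hp = pd.read_csv(path, sep="\t", index_col="votu_id", dtype=str)
    hp["host_rank"] = hp["host_rank"].fillna("")
    hp["host_taxon"] = hp["host_taxon"].fillna("")
    hp["gotu"] = hp.get("gotu", pd.Series("", index=hp.index)).fillna("")
    hp["lysogenic"] = hp["lysogenic"].astype(int).astype(bool)
    return hp


def read_env_series(path: str | Path) -> EnvSeries:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = "feature_id"
    asv = df[df["kind"] == "asv"].drop(columns="kind").astype(float)
    votu = df[df["kind"] == "votu"].drop(columns="kind").astype(float)
    return EnvSeries(asv_rel=asv, votu_fpkm=votu)


def write_table(table, path: str | Path) -> None:
    """Write any pipeline table to TSV so that the matching reader
    reproduces it exactly (float columns keep 12 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(table, VotuQuant):
        _write_votu_quant(table, path)
        return
    if isinstance(table, EnvSeries):
        asv = table.asv_rel.copy()
        asv.insert(0, "kind", "asv")
        votu = table.votu_fpkm.copy()
        votu.insert(0, "kind", "votu")
        both = pd.concat([asv, votu])
        both.index.name = "feature_id"
        both.to_csv(path, sep="\t", float_format="%.12g")
        return
    if isinstance(table, pd.Series):
        table = table.to_frame()
    table.to_csv(path, sep="\t", float_format="%.12g")


def _write_votu_quant(vq: VotuQuant, path: Path) -> None:
    rows = []
    for v in vq.votus:
        for s in vq.samples:
            row = {
                "votu_id": v,
                "sample_id": s,
                "length_bp": int(vq.lengths[v]),
                "fpkm": vq.fpkm.at[v, s],
            }
            if vq.mapped_reads is not None:
                row["mapped_reads"] = int(vq.mapped_reads.at[v, s])
            for col in DENOMINATOR_COLS:
                row[col] = vq.denominators.at[s, col]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_dataset(
    feature_table_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    cytometry_path: str | Path,
    votu_quant_path: Optional[str | Path] = None,
    host_pred_path: Optional[str | Path] = None,
    config: Optional[PipelineConfig] = None,
) -> Dataset:
    """Load and cross-validate a full input bundle.

    Samples whose amplicon library is below ``config.min_reads_amplicon``
    reads, or whose virome library (viral + potential-viral reads) is below
    ``config.min_reads_virome``, are dropped from the respective table and
    logged; their metadata rows are kept.  Any missing (treatment,
    replicate, day) combination is tolerated — flasks are lost to technical
    error in real runs.
    """
    config = config or PipelineConfig()
    counts = read_feature_table(feature_table_path)
    md = read_metadata(metadata_path)
    tax = read_taxonomy(taxonomy_path)
    cyto = read_cytometry(cytometry_path)

    depths = counts.sum(axis=0)
    low = depths.index[depths < config.min_reads_amplicon]
    for s in low:
        logger.warning(
            "dropping amplicon sample '%s': %d reads < %d",
            s, int(depths[s]), config.min_reads_amplicon,
        )
    counts = counts.drop(columns=list(low))

    vq = None
    if votu_quant_path is not None:
        vq = read_votu_quant(votu_quant_path)
        virome_depth = vq.denominators["r_viral"] + vq.denominators["r_potential"]
        low_v = [s for s in vq.samples if virome_depth.get(s, 0) < config.min_reads_virome]
        for s in low_v:
            logger.warning(
                "dropping virome sample '%s': %d reads < %d",
                s, int(virome_depth[s]), config.min_reads_virome,
            )
        if low_v:
            vq = VotuQuant(
                lengths=vq.lengths,
                fpkm=vq.fpkm.drop(columns=low_v),
                denominators=vq.denominators.drop(index=low_v),
                mapped_reads=None
                if vq.mapped_reads is None
                else vq.mapped_reads.drop(columns=low_v),
            )

    hp = read_host_predictions(host_pred_path) if host_pred_path is not None else None

    ds = Dataset(
        asv_counts=counts,
        metadata=md,
        taxonomy=tax,
        cytometry=cyto,
        votu_quant=vq,
        host_predictions=hp,
    )
    ds.require_valid()
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a bundle to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": out / "feature_table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "cytometry": out / "cytometry.tsv",
    }
    write_table(ds.asv_counts, paths["feature_table"])
    write_table(ds.metadata.drop(columns="phase"), paths["metadata"])
    write_table(ds.taxonomy, paths["taxonomy"])
    write_table(ds.cytometry, paths["cytometry"])
    if ds.votu_quant is not None:
        paths["votu_quant"] = out / "votu_quant.tsv"
        write_table(ds.votu_quant, paths["votu_quant"])
    if ds.host_predictions is not None:
        paths["host_predictions"] = out / "host_predictions.tsv"
        hp = ds.host_predictions.copy()
        hp["lysogenic"] = hp["lysogenic"].astype(int)
        write_table(hp, paths["host_predictions"])
    return paths
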