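"""Domain types for the microcosm pipeline and their validation rules."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("bloomtrack")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

DENOMINATOR_COLS = ("fpkm_viral_total", "r_viral", "r_potential")


class Treatment(str, Enum):
    """Microcosm treatment arms (plus the environmental series label)."""

    CONTROL = "control"
    CIF = "CIF"
    HIF = "HIF"
    ENVIRONMENT = "environment"


class Phase(str, Enum):
    """Culture phases defined from total cell-density dynamics."""

    EARLY = "early"
    MIDDLE = "middle"
    LATE = "late"


def assign_phase(day: int) -> Phase:
    """Map an incubation day to its culture phase.

    Days 0-1 are the early phase (cells decreasing or barely increasing),
    days 2-4 the middle phase (cells increasing), and days 5-7 the late
    phase (cell densities saturated).
    """
    day = int(day)
    if day < 0 or day > 7:
        raise ValueError(f"day must be in 0..7, got {day}")
    if day <= 1:
        return Phase.EARLY
    if day <= 4:
        return Phase.MIDDLE
    return Phase.LATE


@dataclass
class VotuQuant:
    """Per-vOTU quantification plus the per-sample calibration denominators.

    ``fpkm`` holds FPKM(i) per vOTU and sample.  ``denominators`` holds,
    per sample, FPKM(viral) (the total FPKM of >1 kb viral scaffolds),
    R(viral) (reads mapped on >1 kb viral scaffolds) and R(potential v)
    (reads recruited on neither host nor viral scaffolds).  ``mapped_reads``
    is optional; when present, FPKM recomputed from it must agree with the
    supplied values.
    """

    lengths: pd.Series  # votu -> length_bp
    fpkm: pd.DataFrame  # votu x sample
    denominators: pd.DataFrame  # sample x (fpkm_viral_total, r_viral, r_potential)
    mapped_reads: Optional[pd.DataFrame] = None  # votu x sample

    @property
    def votus(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class Dataset:
    """Cross-validated bundle of all tables one microcosm run produces.

    asv_counts and votu quantification may cover different sample subsets
    (amplicon and virome libraries fail independently); metadata covers the
    union.
    """

    asv_counts: pd.DataFrame  # asv x sample, int
    metadata: pd.DataFrame  # sample -> treatment, replicate, day, phase
    taxonomy: pd.DataFrame  # asv -> ranks + confidence
    cytometry: pd.DataFrame  # sample -> cells_per_ml, particles_per_ml
    votu_quant: Optional[VotuQuant] = None
    host_predictions: Optional[pd.DataFrame] = None  # votu -> host_rank, host_taxon, gotu, lysogenic

    def validate(self) -> list[str]:
        """Cross-check the bundle; return a list of error strings (empty = valid)."""
        errors: list[str] = []
        md = self.metadata

        if md.index.has_duplicates:
            errors.append("duplicate sample ids in metadata")
        if self.asv_counts.index.has_duplicates:
            errors.append("duplicate ASV ids in feature table")
        bad_treat = set(md["treatment"]) - {t.value for t in Treatment}
        if bad_treat:
            errors.append(f"unknown treatment label(s): {sorted(bad_treat)}")
        triples = md[["treatment", "replicate", "day"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0]
            errors.append(
                "duplicate (treatment, replicate, day): "
                f"({dup['treatment']}, {dup['replicate']}, {dup['day']})"
            )

        for s in self.asv_counts.columns:
            if s not in md.index:
                errors.append(f"sample '{s}' in feature table has no metadata")
            if s not in self.cytometry.index:
                errors.append(f"sample '{s}' has no cytometry counts")
        counts = self.asv_counts.to_numpy()
        if counts.size and counts.min() < 0:
            errors.append("negative counts in feature table")
        if (self.cytometry[["cells_per_ml", "particles_per_ml"]].to_numpy() < 0).any():
            errors.append("negative cytometry counts")
        conf = self.taxonomy.get("confidence")
        if conf is not None and ((conf < 0) | (conf > 1)).any():
            errors.append("taxonomy confidence outside [0, 1]")

        vq = self.votu_quant
        if vq is not None:
            for s in vq.samples:
                if s not in md.index:
                    errors.append(f"sample '{s}' in vOTU table has no metadata")
                if s not in vq.denominators.index:
                    errors.append(f"sample '{s}' has no vOTU denominators")
            if (vq.lengths <= 0).any():
                errors.append("non-positive vOTU length")
            missing_len = set(vq.votus) - set(vq.lengths.index)
            if missing_len:
                errors.append(f"vOTUs without length: {sorted(missing_len)[:5]}")
            if (vq.fpkm.to_numpy() < 0).any():
                errors.append("negative FPKM")
            den = vq.denominators.reindex(vq.samples)
            if (den[list(DENOMINATOR_COLS)].to_numpy() < 0).any():
                errors.append("negative vOTU denominators")
            # catalogued vOTUs (>10 kb) are a subset of all >1 kb viral scaffolds
            colsum = vq.fpkm.sum(axis=0)
            tol = 1e-9 * np.maximum(1.0, den["fpkm_viral_total"].to_numpy())
            over = colsum.to_numpy() > den["fpkm_viral_total"].to_numpy() + tol
            for s in np.asarray(vq.samples)[over]:
                errors.append(
                    f"sample '{s}': sum of vOTU FPKM exceeds total viral FPKM"
                )
            if vq.mapped_reads is not None:
                from .abundance import fpkm as _fpkm  # deferred: avoids cycle

                reads = vq.mapped_reads.reindex(index=vq.votus, columns=vq.samples)
                length = vq.lengths.reindex(vq.votus).to_numpy()[:, None]
                total = den["r_viral"].to_numpy()[None, :]
                with np.errstate(divide="ignore", invalid="ignore"):
                    recomputed = _fpkm(reads.to_numpy(), length, total)
                supplied = vq.fpkm.to_numpy()
                denom = np.maximum(np.abs(supplied), 1e-300)
                rel = np.abs(recomputed - supplied) / denom
                if np.nanmax(rel, initial=0.0) > 1e-6:
                    errors.append(
                        "supplied FPKM disagrees with FPKM recomputed from "
                        "mapped reads (relative error > 1e-6)"
                    )

        if self.host_predictions is not None:
            bad_rank = set(self.host_predictions["host_rank"].dropna()) - set(
                TAXONOMY_RANKS
            ) - {""}
            if bad_rank:
                errors.append(f"host prediction rank(s) finer than genus or unknown: {sorted(bad_rank)}")

        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid dataset bundle:\n" + "\n".join(errors))
        logger.info("dataset validation: 0 errors")

    def samples_for(self, treatment: str) -> pd.Index:
        return self.metadata.index[self.metadata["treatment"] == treatment]


@dataclass
class EnvSeries:
    """Monthly environmental series: ASV relative abundance and vOTU FPKM."""

    asv_rel: pd.DataFrame  # asv x month
    votu_fpkm: pd.DataFrame  # votu x month

    @property
    def shared_timepoints(self) -> list[str]:
        return [m for m in self.asv_rel.columns if m in self.votu_fpkm.columns]


def make_metadata(
    sample_ids: list[str],
    treatments: list[str],
    replicates: list[str],
    days: list[int],
    with_phase: bool = True,
) -> pd.DataFrame:
    """Assemble a metadata frame, deriving phase from day for microcosm rows."""
    md = pd.DataFrame(
        {"treatment": treatments, "replicate": replicates, "day": days},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if with_phase:
        md["phase"] = [
            assign_phase(d).value if t != Treatment.ENVIRONMENT.value else ""
            for t, d in zip(md["treatment"], md["day"])
        ]
    return md
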