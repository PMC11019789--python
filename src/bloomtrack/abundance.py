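"""Absolute-abundance calibration for ASVs and vOTUs.

ASVs: relative amplicon abundance is rescaled by the flow-cytometry total
cell count, giving an approximate cell number per mL.  vOTUs: FPKM-based
relative abundance is calibrated by the virus-derived read fraction and
rescaled by the total viral-particle count:

    P(i) = FPKM(i)/FPKM(viral) x R(viral)/(R(viral)+R(potential v)) x P(viral)

where FPKM(viral) is the total FPKM of >1 kb viral scaffolds, R(viral) the
reads mapped on them, R(potential v) the reads recruited on neither host
nor viral scaffolds, and P(viral) the total viral-particle abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import VotuQuant


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature's read count by its sample's total read count.

    Every column of the result sums to 1.  Raises on an all-zero sample
    column, naming the sample.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample '{zero[0]}' has zero total reads")
    return counts / totals


def approximate_cell_number(
    rel_abundance: pd.DataFrame, cytometry: pd.DataFrame
) -> pd.DataFrame:
    """Multiply relative abundance (0-1) by the total prokaryotic cell count.

    Column sums equal cells/mL exactly; units are cells/mL.
    """
    missing = [s for s in rel_abundance.columns if s not in cytometry.index]
    if missing:
        raise ValueError(f"sample '{missing[0]}' has no cytometry cell count")
    cells = cytometry.loc[rel_abundance.columns, "cells_per_ml"]
    return rel_abundance * cells


def fpkm(mapped_reads, length_bp, total_mapped_reads):
    """Fragments per kilobase per million mapped reads.

    Accepts scalars or broadcastable arrays.
    """
    length_bp = np.asarray(length_bp)
    total_mapped_reads = np.asarray(total_mapped_reads)
    if (length_bp <= 0).any():
        raise ValueError("length_bp must be positive")
    if (total_mapped_reads <= 0).any():
        raise ValueError("total_mapped_reads must be positive")
    out = np.asarray(mapped_reads) / (length_bp / 1e3) / (total_mapped_reads / 1e6)
    return out if out.ndim else float(out)


def approximate_particle_number(
    fpkm_i, fpkm_viral_total, r_viral, r_potential, particles_per_ml
):
    """Approximate particle number P(i) of a vOTU, in particles/mL.

    The FPKM-based relative abundance FPKM(i)/FPKM(viral) is calibrated by
    the potential-virus-derived read fraction R(viral)/(R(viral)+R(potential v))
    and multiplied by the total viral-particle abundance.
    """
    fpkm_viral_total = np.asarray(fpkm_viral_total, dtype=float)
    r_viral = np.asarray(r_viral, dtype=float)
    r_potential = np.asarray(r_potential, dtype=float)
    if (fpkm_viral_total <= 0).any():
        raise ValueError("FPKM(viral) total must be positive")
    if (r_viral + r_potential <= 0).any():
        raise ValueError("R(viral) + R(potential v) must be positive")
    out = (
        np.asarray(fpkm_i, dtype=float)
        / fpkm_viral_total
        * (r_viral / (r_viral + r_potential))
        * np.asarray(particles_per_ml, dtype=float)
    )
    return out if out.ndim else float(out)


def votu_particle_table(vq: VotuQuant, cytometry: pd.DataFrame) -> pd.DataFrame:
    """Apply the P(i) calibration to every vOTU and sample of a bundle."""
    missing = [s for s in vq.samples if s not in cytometry.index]
    if missing:
        raise ValueError(f"sample '{missing[0]}' has no cytometry particle count")
    den = vq.denominators.loc[vq.samples]
    particles = cytometry.loc[vq.samples, "particles_per_ml"].to_numpy()
    values = approximate_particle_number(
        vq.fpkm.to_numpy(),
        den["fpkm_viral_total"].to_numpy()[None, :],
        den["r_viral"].to_numpy()[None, :],
        den["r_potential"].to_numpy()[None, :],
        particles[None, :],
    )
    return pd.DataFrame(values, index=vq.fpkm.index, columns=vq.fpkm.columns)
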