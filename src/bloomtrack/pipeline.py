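"""Orchestration of the pipeline stages on a loaded (or simulated) bundle."""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .abundance import (
    approximate_cell_number,
    relative_abundance,
    votu_particle_table,
)
from .community import anosim, bonferroni, bray_curtis, pcoa, phase_compare, rarefy
from .config import PipelineConfig
from .datatypes import Dataset, EnvSeries, Treatment
from .differential import lefse
from .pairing import candidate_pairs, significant_pairs
from .responders import (
    LYSATE_TREATMENTS,
    abundant_asvs,
    increased_votus,
    treatment_specific_asvs,
    treatment_specific_votus,
)

logger = logging.getLogger("bloomtrack")

MICROCOSM = (Treatment.CONTROL.value, Treatment.CIF.value, Treatment.HIF.value)


def calibrate_abundances(ds: Dataset) -> dict[str, pd.DataFrame]:
    """Approximate cell numbers for ASVs and particle numbers for vOTUs."""
    rel = relative_abundance(ds.asv_counts)
    out = {"asv_relative": rel, "asv_cells": approximate_cell_number(rel, ds.cytometry)}
    if ds.votu_quant is not None:
        out["votu_particles"] = votu_particle_table(ds.votu_quant, ds.cytometry)
    return out


def community_analysis(
    ds: Dataset, config: Optional[PipelineConfig] = None, seed: Optional[int] = None
) -> dict:
    """Rarefaction, Bray-Curtis, PCoA, ANOSIM contrasts and phase tests.

    The two ANOSIM contrasts follow the study design: early vs middle-late
    samples pooled over treatments, then treatment labels among middle-late
    samples; p-values for the treatment contrast pairs are Bonferroni-
    corrected downstream by the caller if more contrasts are added.
    """
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    rare = rarefy(ds.asv_counts, cfg.rarefaction_depth, seed)
    dm = bray_curtis(rare)
    ordination = pcoa(dm)
    md = ds.metadata.loc[dm.index]
    results = {"rarefied": rare, "distance": dm, "ordination": ordination}

    phase_groups = (md["phase"] == "early").map({True: "early", False: "middle-late"})
    r_phase, p_phase = anosim(dm, phase_groups, cfg.n_permutations, seed)
    ml = md.index[md["phase"] != "early"]
    r_treat, p_treat = anosim(
        dm.loc[ml, ml], md.loc[ml, "treatment"], cfg.n_permutations, seed
    )
    anosim_tab = pd.DataFrame(
        [
            {"contrast": "early_vs_middle_late", "R": r_phase, "p": p_phase},
            {"contrast": "treatment_within_middle_late", "R": r_treat, "p": p_treat},
        ]
    )
    anosim_tab["p_bonferroni"] = bonferroni(anosim_tab["p"])
    results["anosim"] = anosim_tab
    results["phase_tests"] = pd.concat(
        [
            phase_compare(ds.cytometry, ds.metadata, "cells").assign(metric="cells"),
            phase_compare(ds.cytometry, ds.metadata, "particles").assign(metric="particles"),
        ],
        ignore_index=True,
    )
    return results


def detect_responders(
    ds: Dataset,
    abundances: Optional[dict[str, pd.DataFrame]] = None,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """Abundant / treatment-specific ASVs and increased / specific vOTUs."""
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    ab = abundances or calibrate_abundances(ds)
    cells = ab["asv_cells"]
    md = ds.metadata

    abundant = {
        t: abundant_asvs(cells, md, t, cfg.top_rank, cfg.fold_threshold, cfg.fold_criterion_on)
        for t in MICROCOSM
    }
    candidates = sorted(
        set().union(*(df.index[df["abundant"]] for df in abundant.values()))
    )
    results = {"abundant": abundant}
    if candidates:
        micro_samples = [
            s for s in cells.columns if md.at[s, "treatment"] in LYSATE_TREATMENTS
            or md.at[s, "treatment"] == Treatment.CONTROL.value
        ]
        classes = md.loc[micro_samples, "treatment"]
        subclasses = md.loc[micro_samples, "replicate"]
        lefse_res = lefse(cells.loc[candidates, micro_samples], classes, subclasses, cfg, seed)
    else:
        lefse_res = pd.DataFrame(
            columns=["kw_p", "subclass_consistent", "lda_log_score", "enriched_class", "significant"]
        )
    results["asv_lefse"] = lefse_res
    results["specific_asvs"] = treatment_specific_asvs(abundant, lefse_res)

    if "votu_particles" in ab:
        increased = {
            t: increased_votus(ab["votu_particles"], md, t, cfg, seed) for t in MICROCOSM
        }
        results["votu_increased"] = increased
        results["specific_votus"] = treatment_specific_votus(increased)
    return results


def pair_hosts_and_viruses(
    ds: Dataset,
    responders: dict,
    env: Optional[EnvSeries] = None,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Candidate pairs per treatment, confirmed on the environmental series."""
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    specific_votus = responders.get("specific_votus")
    frames = []
    for t in LYSATE_TREATMENTS:
        asvs = list(responders["specific_asvs"][t].index)
        votus = (
            list(specific_votus.index[specific_votus["category"] == f"{t}-specific"])
            if specific_votus is not None
            else []
        )
        frames.append(
            candidate_pairs(asvs, votus, ds.taxonomy, ds.host_predictions, t)
        )
    pairs = pd.concat(frames, ignore_index=True)
    if env is None or pairs.empty:
        return pairs
    tested = pairs[
        pairs["asv_id"].isin(env.asv_rel.index) & pairs["votu_id"].isin(env.votu_fpkm.index)
    ]
    if tested.empty:
        logger.info("no candidate pair is observed in the environmental series")
        return pairs
    return significant_pairs(tested, env, cfg, seed)
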