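"""Filtering rules that call abundant, increased, and treatment-specific taxa.

An ASV is *abundant* in a treatment when (i) it ranks in the top 20 by
approximate cell number on at least one day after day 0 in all triplicate
flasks and (ii) its approximate cell number more than doubles relative to
day 0 at least once.  Abundant ASVs enriched in exactly one lysate
treatment by the class/subclass differential test become CIF- or
HIF-specific.  A vOTU is *increased* when the day-0 vs later differential
test flags it (direction enforced) and its approximate particle number
exceeds 100 particles/mL — the approximate mean burst size of marine
bacterial viruses, i.e. the smallest rise a single lysed host cell per mL
could explain — on at least one day.  vOTUs increased in exactly one lysate
treatment become treatment-specific.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import Treatment
from .differential import lefse

logger = logging.getLogger("bloomtrack")

LYSATE_TREATMENTS = (Treatment.CIF.value, Treatment.HIF.value)


def replicate_day_means(
    table: pd.DataFrame, metadata: pd.DataFrame, treatment: str
) -> pd.DataFrame:
    """Per-day means across available replicates (features x days).

    Lost flasks simply reduce n for that day; n per day is logged.
    """
    samples = [
        s for s in table.columns
        if s in metadata.index and metadata.at[s, "treatment"] == treatment
    ]
    days = sorted({int(metadata.at[s, "day"]) for s in samples})
    out = {}
    for d in days:
        cols = [s for s in samples if int(metadata.at[s, "day"]) == d]
        out[d] = table[cols].mean(axis=1)
        if len(cols) < 3:
            logger.info(
                "%s day %d: averaging %d replicate(s)", treatment, d, len(cols)
            )
    return pd.DataFrame(out)


def _inclusive_rank(column: pd.Series) -> pd.Series:
    """Rank within a sample, descending; ties share the best (min) rank so a
    tie at the cutoff keeps every tied feature."""
    return column.rank(ascending=False, method="min")


def abundant_asvs(
    abund: pd.DataFrame,
    metadata: pd.DataFrame,
    treatment: str,
    top_rank: int = 20,
    fold: float = 2.0,
    fold_on: str = "mean",
) -> pd.DataFrame:
    """Apply the top-rank / fold-change abundant-ASV filter for one treatment.

    Returns a frame indexed by feature with columns ``rank_pass`` (some day
    after day 0 is top-``top_rank`` in every available flask), ``fold_pass``
    (abundance more than ``fold`` x day 0 at least once; a day-0 value of
    exactly 0 passes when any later value is positive) and ``abundant``.
    ``fold_on`` selects whether the fold criterion uses replicate means
    (default) or must hold within every flask.
    """
    samples = [
        s for s in abund.columns
        if s in metadata.index and metadata.at[s, "treatment"] == treatment
    ]
    sub = abund[samples]
    days = sorted({int(metadata.at[s, "day"]) for s in samples})
    if 0 not in days:
        raise ValueError(f"treatment '{treatment}' has no day-0 sample")

    rank_pass = pd.Series(False, index=abund.index)
    for d in days:
        if d < 1:
            continue
        cols = [s for s in samples if int(metadata.at[s, "day"]) == d]
        ranks = pd.DataFrame({c: _inclusive_rank(sub[c]) for c in cols})
        rank_pass |= (ranks <= top_rank).all(axis=1)

    if fold_on == "mean":
        means = replicate_day_means(sub, metadata, treatment)
        day0 = means[0]
        later = means[[d for d in means.columns if d >= 1]]
        fold_pass = (later.gt(fold * day0, axis=0)).any(axis=1)
        fold_pass |= (day0 == 0) & later.gt(0).any(axis=1)
    elif fold_on == "flask":
        fold_pass = pd.Series(True, index=abund.index)
        replicates = sorted({metadata.at[s, "replicate"] for s in samples})
        for r in replicates:
            cols = [s for s in samples if metadata.at[s, "replicate"] == r]
            d0 = [c for c in cols if int(metadata.at[c, "day"]) == 0]
            if not d0:
                continue
            day0 = sub[d0[0]]
            later = sub[[c for c in cols if int(metadata.at[c, "day"]) >= 1]]
            ok = later.gt(fold * day0, axis=0).any(axis=1)
            ok |= (day0 == 0) & later.gt(0).any(axis=1)
            fold_pass &= ok
    else:
        raise ValueError("fold_on must be 'mean' or 'flask'")

    return pd.DataFrame(
        {
            "rank_pass": rank_pass,
            "fold_pass": fold_pass,
            "abundant": rank_pass & fold_pass,
        }
    )


def treatment_specific_asvs(
    abundant: dict[str, pd.DataFrame],
    lefse_results: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Intersect the abundant sets with the differential-enrichment calls.

    A feature is CIF-specific when it is abundant in CIF only (not HIF, not
    control) and the treatment-class differential test calls it significant
    with CIF as the enriched class; symmetrically for HIF.  Features
    abundant in both lysate treatments are excluded from both sets (they
    thrive on either fraction).
    """
    members = {t: set(df.index[df["abundant"]]) for t, df in abundant.items()}
    control = members.get(Treatment.CONTROL.value, set())
    out = {}
    for t in LYSATE_TREATMENTS:
        other = [o for o in LYSATE_TREATMENTS if o != t][0]
        rows = []
        for feat in sorted(members.get(t, set())):
            if feat in members.get(other, set()) or feat in control:
                continue
            if feat not in lefse_results.index:
                continue
            res = lefse_results.loc[feat]
            if bool(res["significant"]) and res["enriched_class"] == t:
                rows.append(
                    {
                        "feature_id": feat,
                        "treatment": t,
                        "provenance": f"abundant[{t}-only] & lefse[{t}]",
                    }
                )
        out[t] = pd.DataFrame(rows, columns=["feature_id", "treatment", "provenance"]).set_index("feature_id")
    assert not (set(out[LYSATE_TREATMENTS[0]].index) & set(out[LYSATE_TREATMENTS[1]].index))
    return out


def day0_after_classes(
    metadata: pd.DataFrame, samples, after_day: int = 1
) -> tuple[pd.Series, pd.Series]:
    """Class (day0 vs after) and subclass (flask) labels for the vOTU test.

    Samples on days strictly between 0 and ``after_day`` are excluded.
    """
    cls, sub = {}, {}
    for s in samples:
        d = int(metadata.at[s, "day"])
        if d == 0:
            cls[s] = "day0"
        elif d >= after_day:
            cls[s] = "after"
        else:
            continue
        sub[s] = metadata.at[s, "replicate"]
    return pd.Series(cls), pd.Series(sub)


def increased_votus(
    particle_table: pd.DataFrame,
    metadata: pd.DataFrame,
    treatment: str,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Call vOTUs that genuinely increased in one treatment.

    Runs the differential test with day 0 as one class and every later
    sampled day as the other (flasks as subclasses), keeps vOTUs enriched
    in the *after* class, and discards any whose replicate-mean approximate
    particle number never exceeds the burst threshold (100 particles/mL by
    default) on any day.
    """
    cfg = config or PipelineConfig()
    samples = [
        s for s in particle_table.columns
        if s in metadata.index and metadata.at[s, "treatment"] == treatment
    ]
    classes, subclasses = day0_after_classes(metadata, samples, cfg.votu_after_day)
    res = lefse(particle_table[classes.index], classes, subclasses, cfg, seed=seed)
    day_means = replicate_day_means(particle_table[samples], metadata, treatment)
    peak = day_means.max(axis=1)
    res = res.copy()
    res["peak_particles_per_ml"] = peak
    res["increased"] = (
        res["significant"]
        & (res["enriched_class"] == "after")
        & (peak > cfg.burst_threshold)
    )
    return res


def treatment_specific_votus(
    increased: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Partition increased vOTUs by the treatments they responded to.

    Returns one row per vOTU increased anywhere, with the per-treatment
    flags and a ``category``: 'CIF-specific' / 'HIF-specific' (increased in
    that lysate treatment only), 'both' (both lysate treatments, not
    control), 'all' (every treatment), or 'other' (any remaining pattern,
    e.g. control-only).
    """
    sets = {t: set(df.index[df["increased"]]) for t, df in increased.items()}
    control = sets.get(Treatment.CONTROL.value, set())
    cif = sets.get(Treatment.CIF.value, set())
    hif = sets.get(Treatment.HIF.value, set())
    rows = []
    for v in sorted(cif | hif | control):
        in_c, in_cif, in_hif = v in control, v in cif, v in hif
        if in_cif and in_hif and in_c:
            cat = "all"
        elif in_cif and in_hif:
            cat = "both"
        elif in_cif and not in_c:
            cat = "CIF-specific"
        elif in_hif and not in_c:
            cat = "HIF-specific"
        else:
            cat = "other"
        rows.append(
            {
                "feature_id": v,
                "in_control": in_c,
                "in_CIF": in_cif,
                "in_HIF": in_hif,
                "category": cat,
            }
        )
    out = pd.DataFrame(
        rows, columns=["feature_id", "in_control", "in_CIF", "in_HIF", "category"]
    ).set_index("feature_id")
    return out
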