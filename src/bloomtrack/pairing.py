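"""Host-virus candidate pairing and environmental co-occurrence confirmation.

Candidate pairs link treatment-specific vOTUs to treatment-specific ASVs
whose lineage contains the vOTU's predicted host taxon; host-unknown vOTUs
are screened against every specific ASV of the same treatment.  Candidates
are confirmed on a monthly environmental series by contemporaneous Spearman
correlation (no time delay) with a permutation p-value and
Benjamini-Hochberg q-value; a pair is significant when r > 0.6, P < 0.01
and q < 0.05.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import TAXONOMY_RANKS, EnvSeries

HOST_UNKNOWN_BASIS = "host-unknown screen"


def candidate_pairs(
    specific_asvs,
    specific_votus,
    taxonomy: pd.DataFrame,
    host_predictions: pd.DataFrame,
    treatment: str = "",
) -> pd.DataFrame:
    """Emit (ASV, vOTU) candidates from one treatment's specific sets.

    A pair is emitted when the vOTU's predicted host taxon equals the ASV's
    lineage entry at the predicted rank or at any coarser rank on the
    lineage path.  Host-unknown vOTUs are paired with every specific ASV
    (match basis "host-unknown screen").
    """
    rows = []
    for votu in specific_votus:
        if votu in host_predictions.index:
            rank = host_predictions.at[votu, "host_rank"]
            taxon = host_predictions.at[votu, "host_taxon"]
        else:
            rank, taxon = "", ""
        for asv in specific_asvs:
            if not taxon:
                rows.append(
                    {"asv_id": asv, "votu_id": votu, "treatment": treatment,
                     "match_basis": HOST_UNKNOWN_BASIS}
                )
                continue
            if asv not in taxonomy.index:
                continue
            upto = TAXONOMY_RANKS.index(rank) + 1 if rank in TAXONOMY_RANKS else len(TAXONOMY_RANKS)
            lineage = taxonomy.loc[asv, list(TAXONOMY_RANKS[:upto])]
            matches = lineage.index[lineage == taxon]
            if len(matches):
                rows.append(
                    {"asv_id": asv, "votu_id": votu, "treatment": treatment,
                     "match_basis": str(matches[0])}
                )
    return pd.DataFrame(rows, columns=["asv_id", "votu_id", "treatment", "match_basis"])


def spearman_perm(
    series_x, series_y, n_permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Spearman correlation with a two-sided permutation p-value.

    r is the Pearson correlation of mid-ranks (ties averaged).  For
    n <= 7 the p-value is exact — the fraction of all n! rank permutations
    with |r| at least as large as observed; otherwise it is a Monte-Carlo
    permutation p with the +1/+1 convention.  A constant series has no
    defined rank correlation: (nan, 1.0) is returned and the pair can never
    be significant.
    """
    x = np.asarray(list(series_x), dtype=float)
    y = np.asarray(list(series_y), dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 time points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def corr(a, b):
        return np.corrcoef(a, b)[0, 1]

    r_obs = corr(rx, ry)
    if n <= 7:
        hits = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            if abs(corr(rx, np.asarray(perm))) >= abs(r_obs) - 1e-12:
                hits += 1
        return float(r_obs), hits / total
    rng = np.random.default_rng(seed)
    # all permutations at once: with centred ranks, r is a scaled dot product
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    r_perm = (ry_c[perm_idx] @ rx_c) / denom
    hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return float(r_obs), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_pairs(
    pairs: pd.DataFrame,
    env: EnvSeries,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every candidate pair on the shared environmental time points.

    Adds r, p, q (Benjamini-Hochberg over all tested pairs jointly),
    a ``constant`` flag, and the ``significant`` call
    r > 0.6 AND p < 0.01 AND q < 0.05 (thresholds from config).
    """
    cfg = config or PipelineConfig()
    shared = env.shared_timepoints
    if len(shared) < 5:
        raise ValueError(
            f"only {len(shared)} shared time points between ASV and vOTU series"
        )
    out = pairs.copy().reset_index(drop=True)
    rs, ps, const = [], [], []
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(len(out))
    for i, row in out.iterrows():
        x = env.asv_rel.loc[row["asv_id"], shared]
        y = env.votu_fpkm.loc[row["votu_id"], shared]
        r, p = spearman_perm(
            x, y, n_permutations=cfg.n_permutations,
            seed=int(pair_seeds[i] % (2 ** 31)),
        )
        rs.append(r)
        ps.append(p)
        const.append(math.isnan(r))
    out["r"] = rs
    out["p"] = ps
    out["q"] = bh_fdr(ps) if len(ps) else []
    out["constant"] = const
    out["significant"] = (
        (out["r"] > cfg.corr_r_threshold)
        & (out["p"] < cfg.corr_p_threshold)
        & (out["q"] < cfg.corr_q_threshold)
    ).fillna(False)
    return out
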