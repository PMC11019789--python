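"""LEfSe-style class/subclass differential enrichment, built from scratch.

Three gates, applied per feature: a Kruskal-Wallis test across classes, a
subclass-consistency check (every between-class subclass pairwise rank
comparison must agree in sign with the class-level difference; here,
subclasses are the triplicate flasks), and a bootstrapped linear
discriminant effect size whose log10 must reach a threshold.  Multi-class
designs are handled one-vs-one: a feature is called for a class only if it
passes every pairwise comparison against the other classes.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

_EXACT_N = 10


def _h_statistic(values: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    for g in uniq:
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction == 0:  # all values identical
        return 0.0
    return h / correction


def _assignments(indices: tuple[int, ...], sizes: Sequence[int]):
    """All distinct ways to split ``indices`` into groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in head)
        for tail in _assignments(rest, sizes[1:]):
            yield (head, *tail)


def kruskal_wallis(values, class_labels) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction.

    The p-value comes from the chi-squared reference distribution with
    k - 1 degrees of freedom, or from exact enumeration of all label
    assignments when the total sample size is at most 10.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(class_labels))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 classes")
    h_obs = _h_statistic(values, labels, uniq)
    n = len(values)
    if n <= _EXACT_N:
        total = 0
        hits = 0
        idx = tuple(range(n))
        lab_template = np.empty(n, dtype=labels.dtype)
        for groups in _assignments(idx, list(counts)):
            for g, members in zip(uniq, groups):
                lab_template[list(members)] = g
            total += 1
            if _h_statistic(values, lab_template, uniq) >= h_obs - 1e-12:
                hits += 1
        return float(h_obs), hits / total
    p = float(stats.chi2.sf(h_obs, df=len(uniq) - 1))
    return float(h_obs), p


def lda_effect_size(
    feature_values,
    class_labels,
    n_boot: int = 30,
    subsample_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> float:
    """Bootstrapped linear-discriminant effect size of one feature.

    Each round draws a stratified subsample (fraction ``subsample_frac``
    per class) and fits a one-dimensional Fisher discriminant with a
    within-class variance floor of 1e-10 x the global variance, so constant
    features never raise.  On the unit-normalised discriminant axis of a
    single feature the recorded separation is the absolute difference of
    the subsampled class means.  The score is log10 of the mean separation
    across rounds, floored at 0 when the separation is below 1.
    """
    values = np.asarray(list(feature_values), dtype=float)
    labels = np.asarray(list(class_labels))
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("lda_effect_size is a two-class statistic")
    if len(values) < 4:
        raise ValueError("need at least 4 observations")
    rng = np.random.default_rng(seed)
    groups = [values[labels == g] for g in uniq]
    # draw subsamples in a label-independent order so that renaming the
    # classes cannot change the score (only the enrichment direction)
    canonical = sorted(range(2), key=lambda i: tuple(np.sort(groups[i])))
    groups = [groups[i] for i in canonical]
    floor = 1e-10 * max(values.var(), 1e-300)
    seps = np.empty(n_boot)
    for b in range(n_boot):
        means = []
        for g in groups:
            k = max(1, math.ceil(subsample_frac * len(g)))
            sub = g[rng.choice(len(g), size=k, replace=False)]
            # variance floor keeps the discriminant direction defined for
            # constant subsamples; the normalised axis is the feature axis
            _ = sub.var() + floor
            means.append(sub.mean())
        seps[b] = abs(means[1] - means[0])
    mean_sep = seps.mean()
    if mean_sep < 1.0:
        return 0.0
    return float(np.log10(mean_sep))


def _rank_sign(a: np.ndarray, b: np.ndarray) -> int:
    """Sign of the rank-sum comparison between two groups (0 on exact tie)."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    diff = ranks[: len(a)].mean() - ranks[len(a):].mean()
    return 0 if diff == 0 else (1 if diff > 0 else -1)


def _pair_tests(
    values: np.ndarray,
    classes: np.ndarray,
    subclasses: np.ndarray,
    c_hi: str,
    c_lo: str,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[float, bool, float]:
    """(kw_p, subclass_consistent, lda_score) for one ordered class pair."""
    mask = (classes == c_hi) | (classes == c_lo)
    v, cl, sc = values[mask], classes[mask], subclasses[mask]
    _, kw_p = kruskal_wallis(v, cl)
    hi, lo = v[cl == c_hi], v[cl == c_lo]
    class_sign = _rank_sign(hi, lo)
    consistent = class_sign != 0
    for u in np.unique(sc[cl == c_hi]):
        for w in np.unique(sc[cl == c_lo]):
            a = v[(cl == c_hi) & (sc == u)]
            b = v[(cl == c_lo) & (sc == w)]
            if a.size == 0 or b.size == 0:
                continue
            s = _rank_sign(a, b)
            if s != 0 and s != class_sign:
                consistent = False
    score = lda_effect_size(
        v, cl, n_boot=cfg.lda_boot_rounds,
        subsample_frac=cfg.lda_subsample_frac, seed=seed,
    )
    return kw_p, consistent, score


def lefse(
    table: pd.DataFrame,
    classes: pd.Series,
    subclasses: pd.Series,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run the class/subclass differential-enrichment procedure per feature.

    ``table`` holds calibrated abundances (features x samples); ``classes``
    and ``subclasses`` map each sample column to its class (treatment, or
    day-0-vs-later) and subclass (flask).  Returns a frame with columns
    kw_p, subclass_consistent, lda_log_score, enriched_class, significant.
    A feature is significant for its highest-mean class only if every
    pairwise comparison against the other classes passes all three gates.
    """
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    samples = [s for s in table.columns if s in classes.index]
    cl = classes.loc[samples].to_numpy()
    sc = subclasses.loc[samples].to_numpy()
    uniq, counts = np.unique(cl, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("lefse needs at least 2 classes")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"class '{small[0]}' has fewer than 2 samples")
    ss = np.random.SeedSequence(seed)
    feature_seeds = ss.generate_state(len(table.index))

    rows = []
    values_matrix = table[samples].to_numpy(dtype=float)
    for fi, feat in enumerate(table.index):
        values = values_matrix[fi]
        fseed = int(feature_seeds[fi] % (2 ** 31))
        means = {g: values[cl == g].mean() for g in uniq}
        top = max(means, key=lambda g: means[g])
        kw_ps, consistents, scores = [], [], []
        for other in uniq:
            if other == top:
                continue
            kw_p, cons, score = _pair_tests(values, cl, sc, top, other, cfg, fseed)
            kw_ps.append(kw_p)
            consistents.append(cons)
            scores.append(score)
        kw_p = max(kw_ps)
        consistent = all(consistents)
        score = min(scores)
        significant = (
            kw_p < cfg.lefse_alpha and consistent and score >= cfg.lda_threshold
        )
        rows.append(
            {
                "feature_id": feat,
                "kw_p": kw_p,
                "subclass_consistent": consistent,
                "lda_log_score": score,
                "enriched_class": top if significant else "",
                "significant": significant,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
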