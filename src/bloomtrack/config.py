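"""Pipeline configuration with the study's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and tuning knobs for every pipeline stage.

    Defaults follow the microcosm study design: samples rarefied to the
    lowest amplicon depth (9,450 reads), amplicon samples under 5,000 reads
    and virome samples under 10,000 reads dropped, abundant-taxon filter at
    top-20 rank with a 2-fold rise over day 0, a 100 particles/mL minimum
    (the approximate mean burst size of marine bacterial viruses) for
    calling a genuine viral increase, LEfSe defaults (alpha 0.05, LDA
    log-score 2.0), and co-occurrence thresholds r > 0.6, P < 0.01,
    q < 0.05.
    """

    rarefaction_depth: int = 9450
    min_reads_amplicon: int = 5000
    min_reads_virome: int = 10000
    top_rank: int = 20
    fold_threshold: float = 2.0
    burst_threshold: float = 100.0
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    lda_boot_rounds: int = 30
    lda_subsample_frac: float = 2.0 / 3.0
    corr_r_threshold: float = 0.6
    corr_p_threshold: float = 0.01
    corr_q_threshold: float = 0.05
    n_permutations: int = 999
    # day-0 samples form one class, every later sampled day the other;
    # set to 2 to start the "after" class at day 2 instead of day 1
    votu_after_day: int = 1
    # evaluate the 2-fold abundant-ASV criterion on replicate means
    # ("mean") or require it within every flask ("flask")
    fold_criterion_on: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            self.rarefaction_depth,
            self.min_reads_amplicon,
            self.min_reads_virome,
            self.top_rank,
            self.fold_threshold,
            self.burst_threshold,
            self.lefse_alpha,
            self.lda_threshold,
            self.lda_boot_rounds,
            self.lda_subsample_frac,
            self.corr_r_threshold,
            self.corr_p_threshold,
            self.corr_q_threshold,
            self.n_permutations,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        if self.fold_criterion_on not in ("mean", "flask"):
            raise ValueError("fold_criterion_on must be 'mean' or 'flask'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
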