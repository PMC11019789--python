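"""Synthetic microcosm and environmental-series generators with known truth.

The microcosm generator emulates the experimental design: natural-seawater
communities in triplicate flasks amended with nothing (control) or with
dissolved intracellular fractions of *Chaetoceros* sp. (CIF) or
*Heterosigma akashiwo* (HIF), sampled daily for 8 days.  A background
community of near-constant ASVs carries planted treatment responders that
grow logistically from day 1 and saturate by the end of the middle phase;
total cell densities are of order 10^6 cells/mL.  Viral particles of
planted vOTUs are released in proportion to the lysed fraction of their
host's growth increment, scaled by a burst size of ~100 particles per cell
(the approximate mean burst size of marine bacterial viruses); lysogenic
planted vOTUs simply track their host's density.  Reads are drawn
multinomially from noisy latent relative abundances, so the count tables
are compositional and overdispersed like real amplicon/virome data.

The environmental generator produces a monthly series (17 time points by
default) in which planted host-virus pairs share a latent seasonal signal
whose strength sets their expected Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    Dataset,
    EnvSeries,
    Treatment,
    VotuQuant,
    make_metadata,
)

MICROCOSM_TREATMENTS = (
    Treatment.CONTROL.value,
    Treatment.CIF.value,
    Treatment.HIF.value,
)
REPLICATES = ("I", "II", "III")

# lineage pools: responders draw from taxa the treatments are known to favour
_RESPONDER_LINEAGES = {
    Treatment.CIF.value: [
        ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae"),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Alteromonadaceae"),
    ],
    Treatment.HIF.value: [
        ("Bacteria", "Bacteroidetes", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae"),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Vibrionales", "Vibrionaceae"),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Pseudoalteromonadaceae"),
    ],
}
_BACKGROUND_LINEAGES = [
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "SAR11 clade", "Clade I"),
    ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Synechococcales", "Cyanobiaceae"),
    ("Bacteria", "Actinobacteriota", "Acidimicrobiia", "Actinomarinales", "Actinomarinaceae"),
    ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae", "Opitutales", "Puniceicoccaceae"),
    ("Archaea", "Thermoplasmatota", "Thermoplasmata", "Marine Group II", "MGIIa"),
]


@dataclass
class SimConfig:
    """Generator parameters; defaults reproduce the study conditions."""

    # community composition
    n_background_asvs: int = 60
    n_responders_cif: int = 5
    n_responders_hif: int = 8
    n_responders_both: int = 0
    n_background_votus: int = 40
    votus_per_responder: int = 2
    n_lysogenic: int = 2

    # sampling design
    days: tuple = tuple(range(8))
    virome_days: tuple = (0, 1, 3, 5, 7)
    amplicon_depth: int = 20000
    virome_depth: int = 1_000_000

    # latent cell dynamics (cells/mL)
    background_cell_density: float = 1.6e4
    responder_initial: float = 1.0e4
    responder_enrichment: float = 10.0  # carrying capacity = enrichment x initial
    growth_rate: float = 1.5
    growth_midday: float = 2.5

    # latent viral dynamics (particles/mL)
    background_votu_particles: float = 3.0e4
    planted_votu_baseline: float = 1.0e3
    burst_size: float = 100.0  # particles released per lysed host cell
    lysed_fraction: float = 0.1  # share of the host growth increment lysed
    burst_lag_days: int = 0  # 0-2 days between host growth and particle release

    # virome read annotation: share of the library that is virus-derived,
    # baseline particle share of catalogued (>10 kb) vOTUs within the
    # scaffold pool, and particle share of viruses too short/rare to
    # assemble (their reads map nowhere and become "potential viral")
    viral_read_fraction: float = 0.75
    catalog_particle_fraction: float = 0.8
    unassembled_particle_fraction: float = 0.10

    # noise
    noise_sigma: float = 0.2  # lognormal sigma on latent densities
    measurement_sigma: float = 0.05  # lognormal sigma on cytometry totals
    # per-ASV log-slope s.d. of the slow successional drift shared by all
    # treatments (bottle effect); responders override it with logistic growth
    background_drift_sigma: float = 0.4

    # environmental series
    env_n_timepoints: int = 17
    env_n_asvs: int = 8
    env_n_votus: int = 12
    env_n_pairs: int = 3
    env_strength: float = 0.9

    def __post_init__(self) -> None:
        if self.amplicon_depth <= 0 or self.virome_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        for name in ("n_background_asvs", "n_background_votus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.burst_lag_days <= 2:
            raise ValueError("burst_lag_days must be 0-2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("days", "virome_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    asv: pd.DataFrame  # responder_class, x0, carrying_capacity, rate, midday
    votu: pd.DataFrame  # host_asv, responder_class, lysogenic, burst amplitude
    env_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["asv_id", "votu_id", "strength"])
    )


def _logistic_density(
    day: np.ndarray, x0: float, cap: float, rate: float, midday: float
) -> np.ndarray:
    """Logistic growth pinned to x(0) = x0 and x(inf) = cap."""
    s = 1 / (1 + np.exp(-rate * (np.asarray(day, dtype=float) - midday)))
    s0 = 1 / (1 + np.exp(rate * midday))
    return x0 + (cap - x0) * (s - s0) / (1 - s0)


def latent_cell_density(
    truth_row: pd.Series, treatment: str, days
) -> np.ndarray:
    """Noise-free latent cell density of one ASV in one treatment."""
    days = np.asarray(days, dtype=float)
    cls = truth_row["responder_class"]
    grows = cls != "none" and (cls == "both" or cls == treatment) and treatment != Treatment.CONTROL.value
    if cls == "all":
        grows = True
    if not grows:
        return np.full(len(days), truth_row["x0"])
    return _logistic_density(
        days, truth_row["x0"], truth_row["carrying_capacity"],
        truth_row["rate"], truth_row["midday"],
    )


def _make_truth(config: SimConfig, rng: np.random.Generator) -> SimulationTruth:
    asv_rows = []
    for i in range(config.n_background_asvs):
        asv_rows.append(
            {
                "asv_id": f"ASV_bg{i:03d}",
                "responder_class": "none",
                "x0": config.background_cell_density,
                "carrying_capacity": config.background_cell_density,
                "rate": 0.0,
                "midday": 0.0,
            }
        )
    planted = (
        [(Treatment.CIF.value, i) for i in range(config.n_responders_cif)]
        + [(Treatment.HIF.value, i) for i in range(config.n_responders_hif)]
        + [("both", i) for i in range(config.n_responders_both)]
    )
    for cls, i in planted:
        asv_rows.append(
            {
                "asv_id": f"ASV_{cls}{i:02d}",
                "responder_class": cls,
                "x0": config.responder_initial,
                "carrying_capacity": config.responder_enrichment * config.responder_initial,
                "rate": config.growth_rate,
                "midday": config.growth_midday,
            }
        )
    asv = pd.DataFrame(asv_rows).set_index("asv_id")

    votu_rows = []
    for i in range(config.n_background_votus):
        votu_rows.append(
            {
                "votu_id": f"vOTU_bg{i:03d}",
                "host_asv": "",
                "responder_class": "none",
                "lysogenic": False,
                "baseline": config.background_votu_particles,
            }
        )
    responders = asv.index[asv["responder_class"] != "none"]
    for host in responders:
        for j in range(config.votus_per_responder):
            votu_rows.append(
                {
                    "votu_id": f"vOTU_{host}_{j}",
                    "host_asv": host,
                    "responder_class": asv.at[host, "responder_class"],
                    "lysogenic": False,
                    "baseline": config.planted_votu_baseline,
                }
            )
    # lysogenic vOTUs ride along with the first responders, alternating class
    for k in range(config.n_lysogenic):
        if len(responders) == 0:
            break
        host = responders[k % len(responders)]
        votu_rows.append(
            {
                "votu_id": f"vOTU_lys_{host}",
                "host_asv": host,
                "responder_class": asv.at[host, "responder_class"],
                "lysogenic": True,
                "baseline": config.planted_votu_baseline,
            }
        )
    votu = pd.DataFrame(votu_rows).set_index("votu_id")
    votu["burst_amplitude"] = np.where(
        votu["lysogenic"] | (votu["host_asv"] == ""),
        0.0,
        config.burst_size
        * config.lysed_fraction
        * (config.responder_enrichment - 1)
        * config.responder_initial,
    )
    return SimulationTruth(asv=asv, votu=votu)


def latent_particle_density(
    truth: SimulationTruth, votu_id: str, treatment: str, days, config: SimConfig
) -> np.ndarray:
    """Noise-free latent particle density of one vOTU in one treatment."""
    days = np.asarray(days, dtype=float)
    row = truth.votu.loc[votu_id]
    base = float(row["baseline"])
    host = row["host_asv"]
    if not host:
        return np.full(len(days), base)
    host_row = truth.asv.loc[host]
    lagged = np.maximum(days - config.burst_lag_days, 0.0)
    host_now = latent_cell_density(host_row, treatment, lagged)
    host_0 = float(host_row["x0"])
    if row["lysogenic"]:
        # integrated viruses track the host population, no burst
        return base * host_now / host_0
    release = config.burst_size * config.lysed_fraction * (host_now - host_0)
    return base + release


def _lognormal_noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=shape)


def _taxonomy(truth: SimulationTruth, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for asv_id, row in truth.asv.iterrows():
        cls = row["responder_class"]
        if cls in _RESPONDER_LINEAGES:
            pool = _RESPONDER_LINEAGES[cls]
        elif cls in ("both", "all"):
            pool = _RESPONDER_LINEAGES[Treatment.CIF.value]
        else:
            pool = _BACKGROUND_LINEAGES
        d, p, c, o, f = pool[rng.integers(len(pool))]
        rows.append(
            {
                "feature_id": asv_id,
                "domain": d, "phylum": p, "class": c, "order": o, "family": f,
                "genus": f"g_{asv_id}",
                "confidence": float(np.round(rng.uniform(0.8, 1.0), 4)),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def _host_predictions(
    truth: SimulationTruth, taxonomy: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    ranks = ["phylum", "class", "order", "family", "genus"]
    rows = []
    for votu_id, row in truth.votu.iterrows():
        host = row["host_asv"]
        if host and rng.random() > 0.3:  # 30% of planted vOTUs stay host-unknown
            rank = ranks[rng.integers(len(ranks))]
            taxon = taxonomy.at[host, rank]
        else:
            rank, taxon = "", ""
        rows.append(
            {
                "votu_id": votu_id,
                "host_rank": rank,
                "host_taxon": taxon,
                "gotu": f"gOTU_{rng.integers(50):02d}",
                "lysogenic": bool(row["lysogenic"]),
            }
        )
    return pd.DataFrame(rows).set_index("votu_id")


def simulate_microcosm(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[Dataset, SimulationTruth]:
    """Generate a full microcosm input bundle plus its ground truth.

    Deterministic for a fixed seed.  The bundle always passes
    ``Dataset.validate``; amplicon column sums equal the configured depth
    exactly, and the vOTU FPKM/denominator invariants hold in every sample.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    truth = _make_truth(config, rng)
    days = list(config.days)

    sample_ids, treatments, replicates, sample_days = [], [], [], []
    for t in MICROCOSM_TREATMENTS:
        for r in REPLICATES:
            for d in days:
                sample_ids.append(f"{t}-{r}-d{d}")
                treatments.append(t)
                replicates.append(r)
                sample_days.append(d)
    metadata = make_metadata(sample_ids, treatments, replicates, sample_days)

    n_asv = len(truth.asv)
    # slow successional drift, identical in every treatment and flask
    is_bg = (truth.asv["responder_class"] == "none").to_numpy()
    drift = np.where(
        is_bg, rng.normal(0, config.background_drift_sigma, n_asv), 0.0
    )
    day_arr = np.asarray(days, dtype=float)
    drift_factor = np.exp(np.outer(drift, day_arr / max(day_arr.max(), 1.0)))
    cell_latent = {}  # treatment -> (n_asv x n_days) noise-free
    for t in MICROCOSM_TREATMENTS:
        cell_latent[t] = np.stack(
            [latent_cell_density(truth.asv.loc[a], t, days) for a in truth.asv.index]
        ) * drift_factor

    counts = np.zeros((n_asv, len(sample_ids)), dtype=np.int64)
    cells_total = np.zeros(len(sample_ids))
    for j, s in enumerate(sample_ids):
        t, d = metadata.at[s, "treatment"], int(metadata.at[s, "day"])
        latent = cell_latent[t][:, days.index(d)] * _lognormal_noise(
            rng, config.noise_sigma, n_asv
        )
        cells_total[j] = latent.sum() * _lognormal_noise(rng, config.measurement_sigma, None)
        counts[:, j] = rng.multinomial(config.amplicon_depth, latent / latent.sum())
    asv_counts = pd.DataFrame(counts, index=truth.asv.index.copy(), columns=sample_ids)
    asv_counts.index.name = "feature_id"

    # ---- virome side ----
    n_votu = len(truth.votu)
    votu_lengths = pd.Series(
        rng.integers(10_001, 100_000, size=n_votu),
        index=truth.votu.index.copy(),
        name="length_bp",
    )
    virome_samples = [
        s for s in sample_ids if int(metadata.at[s, "day"]) in config.virome_days
    ]
    fpkm_tab = pd.DataFrame(0.0, index=truth.votu.index.copy(), columns=virome_samples)
    mapped_tab = pd.DataFrame(0, index=truth.votu.index.copy(), columns=virome_samples)
    den_rows = {}
    particles_total = pd.Series(0.0, index=sample_ids)

    particle_latent = {}
    for t in MICROCOSM_TREATMENTS:
        particle_latent[t] = np.stack(
            [
                latent_particle_density(truth, v, t, days, config)
                for v in truth.votu.index
            ]
        )

    # two extra latent viral pools keep the denominators self-consistent:
    # "other" = 1-10 kb scaffolds (mapped, counted in FPKM(viral) but not
    # catalogued as vOTUs) and "unassembled" = viruses whose reads map
    # nowhere (the potential-virus-derived reads).  Both are near-constant,
    # so every read fraction responds coherently when planted bursts grow.
    catalog_day0 = float(truth.votu["baseline"].sum())
    f_cat = config.catalog_particle_fraction
    other_base = (1 - f_cat) / f_cat * catalog_day0
    f_un = config.unassembled_particle_fraction
    unassembled_base = f_un / (1 - f_un) * (catalog_day0 + other_base)
    other_len, unassembled_len = 5_000.0, 5_000.0

    for j, s in enumerate(sample_ids):
        t, d = metadata.at[s, "treatment"], int(metadata.at[s, "day"])
        latent_v = particle_latent[t][:, days.index(d)] * _lognormal_noise(
            rng, config.noise_sigma, n_votu
        )
        other = other_base * _lognormal_noise(rng, config.noise_sigma, None)
        unassembled = unassembled_base * _lognormal_noise(rng, config.noise_sigma, None)
        total = latent_v.sum() + other + unassembled
        particles_total[s] = total * _lognormal_noise(rng, config.measurement_sigma, None)
        if s not in virome_samples:
            continue
        n_viral_reads = int(round(config.virome_depth * config.viral_read_fraction))
        # reads per pool are proportional to particle density x genome length
        weights = np.concatenate(
            [
                latent_v * votu_lengths.to_numpy(),
                [other * other_len, unassembled * unassembled_len],
            ]
        )
        reads = rng.multinomial(n_viral_reads, weights / weights.sum())
        votu_reads, other_reads, potential_reads = reads[:-2], reads[-2], reads[-1]
        r_viral = n_viral_reads - potential_reads
        fpkm_i = votu_reads / (votu_lengths.to_numpy() / 1e3) / (r_viral / 1e6)
        other_fpkm = other_reads / (other_len / 1e3) / (r_viral / 1e6)
        mapped_tab[s] = votu_reads
        fpkm_tab[s] = fpkm_i
        den_rows[s] = {
            "fpkm_viral_total": fpkm_i.sum() + other_fpkm,
            "r_viral": r_viral,
            "r_potential": int(potential_reads),
        }

    cytometry = pd.DataFrame(
        {"cells_per_ml": cells_total, "particles_per_ml": particles_total.to_numpy()},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    votu_quant = VotuQuant(
        lengths=votu_lengths,
        fpkm=fpkm_tab,
        denominators=pd.DataFrame.from_dict(den_rows, orient="index").rename_axis("sample_id"),
        mapped_reads=mapped_tab,
    )
    taxonomy = _taxonomy(truth, rng)
    host_pred = _host_predictions(truth, taxonomy, rng)
    ds = Dataset(
        asv_counts=asv_counts,
        metadata=metadata,
        taxonomy=taxonomy,
        cytometry=cytometry,
        votu_quant=votu_quant,
        host_predictions=host_pred,
    )
    ds.require_valid()
    return ds, truth


def simulate_environment(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[EnvSeries, SimulationTruth]:
    """Generate a monthly environmental series with planted host-virus pairs.

    Each planted (ASV, vOTU) pair shares a latent seasonal signal; the
    association strength sets the expected correlation (strength 1 gives a
    perfect monotone pair, strength 0 an independent one).  Unpaired
    features follow independent seasonal latents.
    """
    config = config or SimConfig()
    if config.env_n_timepoints < 5:
        raise ValueError("need at least 5 time points")
    if config.env_n_pairs > min(config.env_n_asvs, config.env_n_votus):
        raise ValueError("more planted pairs than features")
    rng = np.random.default_rng(seed)
    n_t = config.env_n_timepoints
    months = [f"m{i:02d}" for i in range(n_t)]
    t = np.arange(n_t)

    def seasonal() -> np.ndarray:
        # a damped annual component on top of white month-to-month variation;
        # the seasonal weight is kept low so that independent features do not
        # correlate through the shared 12-month period
        phase = rng.uniform(0, 2 * np.pi)
        z = 0.45 * np.sin(2 * np.pi * t / 12 + phase) + 0.893 * rng.normal(size=n_t)
        return (z - z.mean()) / z.std()

    a = np.sqrt(config.env_strength)
    b = np.sqrt(1 - config.env_strength)
    asv_ids = [f"envASV_{i:02d}" for i in range(config.env_n_asvs)]
    votu_ids = [f"envVOTU_{i:02d}" for i in range(config.env_n_votus)]
    asv_lat = {i: seasonal() for i in asv_ids}
    votu_lat = {i: seasonal() for i in votu_ids}
    pair_rows = []
    for k in range(config.env_n_pairs):
        z = seasonal()
        asv_lat[asv_ids[k]] = a * z + b * rng.normal(size=n_t)
        votu_lat[votu_ids[k]] = a * z + b * rng.normal(size=n_t)
        pair_rows.append(
            {"asv_id": asv_ids[k], "votu_id": votu_ids[k], "strength": config.env_strength}
        )
    # monotone maps to observation scales preserve rank correlations
    asv_rel = pd.DataFrame(
        {m: [0.01 * np.exp(0.5 * asv_lat[i][j]) for i in asv_ids] for j, m in enumerate(months)},
        index=pd.Index(asv_ids, name="feature_id"),
    )
    votu_fpkm = pd.DataFrame(
        {m: [50.0 * np.exp(0.8 * votu_lat[i][j]) for i in votu_ids] for j, m in enumerate(months)},
        index=pd.Index(votu_ids, name="feature_id"),
    )
    truth = SimulationTruth(
        asv=pd.DataFrame(index=pd.Index(asv_ids, name="asv_id")),
        votu=pd.DataFrame(index=pd.Index(votu_ids, name="votu_id")),
        env_pairs=pd.DataFrame(pair_rows),
    )
    return EnvSeries(asv_rel=asv_rel, votu_fpkm=votu_fpkm), truth
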