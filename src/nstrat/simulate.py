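"""Seeded synthetic communities with planted strategy structure.

Generates per-genome covariates (log genome size, respiration/trophic mode,
host association, ecosystem, taxonomic family), samples each strategy's
presence from a logistic model over those covariates, and realizes present
strategies by planting marker homologs emitted from the registry's profile
models, padded with background decoy proteins.  All randomness flows from a
single root seed through named substreams so partial re-runs are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit

from .markers import (
    AMINO_ACIDS,
    MarkerRegistry,
    hash_name,
    sample_background_sequence,
    uniform_background,
)
from .records import METADATA_COLUMNS, GenomeRecord, write_proteome, write_tsv
from .strategies import STRATEGIES, TRANSPORTER_FAMILIES, RuleSet

RESPIRATION_MODES = ("aerobic", "facultatively_anaerobic", "anaerobic", "phototrophic")
TROPHIC_MODES = (
    "photoautotrophic", "photoheterotrophic", "chemoautotrophic",
    "chemoorganotrophic", "mixotrophic",
)

_DEFAULT_RESPIRATION_PROBS = {
    "aerobic": 0.4, "facultatively_anaerobic": 0.2, "anaerobic": 0.3, "phototrophic": 0.1,
}
_DEFAULT_TROPHIC_PROBS = {
    "chemoorganotrophic": 0.6, "chemoautotrophic": 0.15, "photoautotrophic": 0.1,
    "photoheterotrophic": 0.1, "mixotrophic": 0.05,
}
_DEFAULT_ECOSYSTEM_PROBS = {
    "soil": 0.3, "marine": 0.2, "freshwater": 0.15, "host": 0.2, "built": 0.15,
}


def _per_strategy(value, default: float = 0.0) -> dict[str, float]:
    """Broadcast a scalar (or fill a partial dict) over the ten strategies."""
    if value is None:
        return {s: default for s in STRATEGIES}
    if isinstance(value, (int, float)):
        return {s: float(value) for s in STRATEGIES}
    unknown = set(value) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies in effect map: {sorted(unknown)}")
    return {s: float(value.get(s, default)) for s in STRATEGIES}


@dataclass
class SimConfig:
    """Configuration of the synthetic community generator.

    ``baseline_logit``, ``beta_respiration[mode]`` and ``beta_host`` accept
    either a scalar (shared across strategies) or a per-strategy map.
    ``log10_length_range`` sets the uniform sampling range of log10 genome
    length; the size covariate enters the logistic model centred at the
    range midpoint, so baselines are log-odds at reference covariates.
    """

    n_genomes: int = 100
    seed: int = 0
    baseline_logit: float | dict = 0.0
    beta_size: float = 0.0
    beta_respiration: dict = field(default_factory=dict)
    beta_host: float | dict = 0.0
    n_families: int = 20
    family_sd: float = 0.5
    decoys_per_genome: int = 10
    planted_copies: int = 1
    mutation_rate: float = 0.0
    log10_length_range: tuple[float, float] = (6.0, 7.5)
    respiration_probs: dict = field(default_factory=lambda: dict(_DEFAULT_RESPIRATION_PROBS))
    trophic_probs: dict = field(default_factory=lambda: dict(_DEFAULT_TROPHIC_PROBS))
    ecosystem_probs: dict = field(default_factory=lambda: dict(_DEFAULT_ECOSYSTEM_PROBS))
    host_prob: float = 0.25
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.family_sd < 0:
            raise ValueError("family_sd must be nonnegative")
        if self.decoys_per_genome < 0:
            raise ValueError("decoys_per_genome must be nonnegative")
        if self.planted_copies < 1:
            raise ValueError("planted_copies must be positive")
        if not 0.0 <= self.host_prob <= 1.0:
            raise ValueError("host_prob must be in [0, 1]")
        unknown = set(self.beta_respiration) - set(RESPIRATION_MODES)
        if unknown:
            raise ValueError(f"unknown respiration modes: {sorted(unknown)}")
        if set(self.respiration_probs) - set(RESPIRATION_MODES):
            raise ValueError("unknown respiration mode in respiration_probs")
        if set(self.trophic_probs) - set(TROPHIC_MODES):
            raise ValueError("unknown trophic mode in trophic_probs")

    def resolved_effects(self) -> dict:
        return {
            "baseline": _per_strategy(self.baseline_logit),
            "respiration": {
                mode: _per_strategy(self.beta_respiration.get(mode))
                for mode in RESPIRATION_MODES
            },
            "host": _per_strategy(self.beta_host),
        }


@dataclass
class SimTruth:
    """Ground truth for one simulated community."""

    metadata: pd.DataFrame
    truth: pd.DataFrame            # genome x (10 strategies + 5 families), bool
    family_ids: pd.Series
    family_effects: np.ndarray
    planted: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def strategy_matrix(self) -> pd.DataFrame:
        return self.truth[list(STRATEGIES)]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, hash_name(stream)])


def _choice(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Sample covariates and true strategy assignments (no sequences)."""
    n = config.n_genomes
    effects = config.resolved_effects()
    cov_rng = _rng(config.seed, "covariates")

    genome_ids = [f"g{i:05d}" for i in range(n)]
    lo, hi = config.log10_length_range
    log10_len = cov_rng.uniform(lo, hi, size=n)
    centre = 0.5 * (lo + hi)
    respiration = _choice(cov_rng, config.respiration_probs, n)
    trophic = _choice(cov_rng, config.trophic_probs, n)
    ecosystem = _choice(cov_rng, config.ecosystem_probs, n)
    host = cov_rng.random(n) < config.host_prob
    domain = np.where(cov_rng.random(n) < 0.95, "Bacteria", "Archaea")

    family_ids = np.arange(n) % config.n_families  # round-robin assignment
    family_effects = cov_rng.normal(0.0, config.family_sd, size=config.n_families)

    completeness = np.round(cov_rng.uniform(91.0, 99.9, size=n), 2)
    contamination = np.round(cov_rng.uniform(0.0, 4.5, size=n), 2)
    n_trna = cov_rng.integers(18, 22, size=n)

    presence = np.zeros((n, len(STRATEGIES)), dtype=bool)
    for j, s in enumerate(STRATEGIES):
        logit = (
            effects["baseline"][s]
            + config.beta_size * (log10_len - centre)
            + np.array([effects["respiration"][m][s] for m in respiration])
            + np.where(host, effects["host"][s], 0.0)
            + family_effects[family_ids]
        )
        p = expit(logit)
        presence[:, j] = cov_rng.random(n) < p

    cols = {s: presence[:, j].copy() for j, s in enumerate(STRATEGIES)}
    # Consistency closure: nitrate assimilation demands a co-occurring
    # nitrite reductase; back-fill the ferredoxin route when neither is set.
    need_nitrite = cols["nitrate_assim"] & ~(cols["fd_nitrite"] | cols["nadh_nitrite"])
    cols["fd_nitrite"] |= need_nitrite
    # Amino-acid uptake is the OR of the five transporter families.
    fam_draw = cov_rng.random((n, len(TRANSPORTER_FAMILIES))) < 0.5
    fam_pick = cov_rng.integers(0, len(TRANSPORTER_FAMILIES), size=n)
    fam_cols = {}
    for j, f in enumerate(TRANSPORTER_FAMILIES):
        chosen = fam_draw[:, j] | (fam_pick == j) & ~fam_draw.any(axis=1)
        fam_cols[f] = cols["amino_acid_uptake"] & chosen
    cols["amino_acid_uptake"] = np.logical_or.reduce(
        [fam_cols[f] for f in TRANSPORTER_FAMILIES]
    )

    genome_length = np.round(10.0 ** log10_len).astype(np.int64)
    metadata = pd.DataFrame({
        "genome_id": genome_ids,
        "domain": domain,
        "phylum": [f"p{f % 6:02d}" for f in family_ids],
        "family": [f"f{f:03d}" for f in family_ids],
        "genome_length_bp": genome_length,
        "n_cds": np.round(genome_length / 1000.0).astype(np.int64),
        "ecosystem_category": ecosystem,
        "host_associated": host.astype(int),
        "respiration_mode": respiration,
        "trophic_mode": trophic,
        "completeness": completeness,
        "contamination": contamination,
        "has_rrna": np.ones(n, dtype=int),
        "n_trna": n_trna,
    })[list(METADATA_COLUMNS)]

    truth = pd.DataFrame(
        {**{s: cols[s] for s in STRATEGIES}, **{f: fam_cols[f] for f in TRANSPORTER_FAMILIES}},
        index=pd.Index(genome_ids, name="genome_id"),
    )
    return SimTruth(
        metadata=metadata,
        truth=truth,
        family_ids=pd.Series(family_ids, index=genome_ids, name="family_id"),
        family_effects=family_effects,
    )


def simulate_community(
    config: SimConfig,
    registry: MarkerRegistry | None = None,
    rules: RuleSet | None = None,
) -> tuple[list[GenomeRecord], SimTruth]:
    """Generate genome records (proteomes + metadata) with planted markers.

    Present strategies are realized by planting every marker subunit the
    rule set demands, emitted from the corresponding profile model with
    per-residue mutation noise; ``decoys_per_genome`` background sequences
    are appended.
    """
    if registry is None:
        registry = MarkerRegistry.synthetic(calibrate=False)
    rules = rules or RuleSet()
    truth = simulate_truth(config)
    bg = uniform_background() if config.background is None else config.background

    plant_rng = _rng(config.seed, "planting")
    decoy_rng = _rng(config.seed, "decoys")
    meta_rows = truth.metadata.set_index("genome_id")
    genomes: list[GenomeRecord] = []
    for gid, truth_row in truth.truth.iterrows():
        markers_to_plant: list[str] = []
        for s in STRATEGIES:
            if not truth_row[s]:
                continue
            if s == "amino_acid_uptake":
                markers_to_plant.extend(
                    f for f in TRANSPORTER_FAMILIES if truth_row[f]
                )
            else:
                markers_to_plant.extend(rules.required_markers(s))
        proteins: dict[str, str] = {}
        planted: list[tuple[str, str]] = []
        i = 0
        for marker_id in markers_to_plant:
            profile = registry.profiles[marker_id]
            for _ in range(config.planted_copies):
                pid = f"{gid}_p{i:04d}"
                proteins[pid] = profile.sample_sequence(
                    plant_rng, mean_insertions=2.0, mutation_rate=config.mutation_rate
                )
                planted.append((pid, marker_id))
                i += 1
        for _ in range(config.decoys_per_genome):
            pid = f"{gid}_p{i:04d}"
            length = int(decoy_rng.integers(25, 61))
            proteins[pid] = sample_background_sequence(decoy_rng, length, bg)
            i += 1
        truth.planted[gid] = planted
        genomes.append(GenomeRecord(
            genome_id=gid, proteins=proteins, metadata=meta_rows.loc[gid].to_dict()
        ))
    return genomes, truth


def write_community(genomes: list[GenomeRecord], truth: SimTruth, outdir) -> None:
    """Write proteome FASTAs, ``metadata.tsv`` and the binary ``truth.tsv``."""
    from pathlib import Path

    outdir = Path(outdir)
    proteome_dir = outdir / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        write_proteome(genome, proteome_dir / f"{genome.genome_id}.faa")
    write_tsv(truth.metadata, outdir / "metadata.tsv")
    truth_out = truth.truth.astype(int).reset_index()
    write_tsv(truth_out, outdir / "truth.tsv")
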