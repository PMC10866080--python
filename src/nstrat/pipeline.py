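"""Stage orchestration: simulate -> build-profiles -> search -> call ->
prevalence -> associate, with per-stage manifests and deterministic seeding.

Each stage reads only its declared upstream artifacts and writes its
declared TSV/JSON outputs plus ``manifest_<stage>.json`` recording input and
output content hashes, the config hash and the stage seed.  Stage seeds are
derived from the root seed by stable hashing of the stage name, so re-runs
with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from .markers import MarkerRegistry, hash_name, search_proteome, write_hits_tsv, read_hits_tsv
from .prevalence import bootstrap_prevalence, estimates_to_frame
from .records import read_metadata, read_proteome, write_tsv
from .simulate import SimConfig, simulate_community, write_community
from .strategies import (
    ORGANIC_STRATEGIES,
    STRATEGIES,
    QCCriteria,
    RuleSet,
    call_strategies,
    drops_to_frame,
    profiles_to_frame,
    qc_filter_genomes,
)

logger = logging.getLogger("nstrat")

STAGES = ("simulate", "build-profiles", "search", "call", "prevalence", "associate", "all")

_SCHEMA = {
    "seed": None,
    "out_dir": None,
    "simulate": {
        "n_genomes", "baseline_logit", "beta_size", "beta_respiration", "beta_host",
        "n_families", "family_sd", "decoys_per_genome", "planted_copies",
        "mutation_rate", "log10_length_range", "respiration_probs", "trophic_probs",
        "ecosystem_probs", "host_prob",
    },
    "profiles": {
        "alignments_dir", "occupancy_threshold", "pseudocount",
        "registry_seed", "n_calibration", "threshold_margin",
    },
    "call": {"require_nird", "min_completeness", "max_contamination",
             "require_rrna", "min_trna"},
    "bootstrap": {"n_boot", "scheme", "rank", "k"},
    "models": {"family_effects", "reference_respiration"},
    "paths": {"proteome_dir", "metadata"},
}


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    def __init__(self, raw: dict, out_dir: str | Path | None = None,
                 seed: int | None = None) -> None:
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SCHEMA.items():
            if allowed is None or section not in raw:
                continue
            block = raw[section]
            if not isinstance(block, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            extra = set(block) - allowed
            if extra:
                raise ConfigError(f"unknown keys in {section!r}: {sorted(extra)}")
        self.raw = raw
        self.seed = int(seed if seed is not None else raw.get("seed", 0))
        self.out_dir = Path(out_dir or raw.get("out_dir", "nstrat_out"))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + hash_name(stage)) % (2**63)

    def config_hash(self) -> str:
        blob = json.dumps({**self.raw, "seed": self.seed}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    # -- artifact paths -----------------------------------------------------
    @property
    def alignments_dir(self) -> Path:
        return Path(self.section("profiles").get("alignments_dir")
                    or self.out_dir / "alignments")

    @property
    def proteome_dir(self) -> Path:
        return Path(self.section("paths").get("proteome_dir")
                    or self.out_dir / "proteomes")

    @property
    def metadata_path(self) -> Path:
        return Path(self.section("paths").get("metadata")
                    or self.out_dir / "metadata.tsv")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(config: PipelineConfig, stage: str,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __import__("nstrat").__version__,
        "seed": config.stage_seed(stage),
        "config_hash": config.config_hash(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = config.out_dir / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _require(path: Path, producing_stage: str) -> Path:
    if not Path(path).exists():
        raise PipelineError(
            f"missing upstream artifact {path}; run stage '{producing_stage}' first"
        )
    return Path(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = config.section("simulate")
    if "log10_length_range" in sim_kwargs:
        sim_kwargs["log10_length_range"] = tuple(sim_kwargs["log10_length_range"])
    sim_config = SimConfig(seed=config.stage_seed("simulate"), **sim_kwargs)
    prof = config.section("profiles")
    registry = MarkerRegistry.synthetic(
        seed=int(prof.get("registry_seed", 0)), calibrate=False
    )
    registry.write_alignments(config.alignments_dir)
    genomes, truth = simulate_community(sim_config, registry)
    write_community(genomes, truth, out)
    logger.info("simulated %d genomes (%d families)",
                sim_config.n_genomes, sim_config.n_families)
    outputs = [out / "metadata.tsv", out / "truth.tsv"]
    outputs += sorted((out / "proteomes").glob("*.faa"))
    outputs += sorted(config.alignments_dir.glob("*.afa"))
    _write_manifest(config, "simulate", [], outputs)
    return outputs


def stage_build_profiles(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    aln_dir = _require(config.alignments_dir, "simulate")
    prof = config.section("profiles")
    paths = {p.stem: p for p in sorted(aln_dir.glob("*.afa"))}
    if not paths:
        raise PipelineError(f"no alignments (*.afa) in {aln_dir}; run stage 'simulate' first")
    registry = MarkerRegistry.from_alignments(
        paths,
        occupancy_threshold=float(prof.get("occupancy_threshold", 0.5)),
        pseudocount=float(prof.get("pseudocount", 1.0)),
    )
    registry.calibrate_thresholds(
        n_decoys=int(prof.get("n_calibration", 150)),
        margin=float(prof.get("threshold_margin", 2.0)),
        seed=config.stage_seed("build-profiles"),
    )
    profile_path = out / "profiles.json"
    profile_path.write_text(json.dumps(registry.to_dict()) + "\n")
    thresholds = pd.DataFrame({
        "marker_id": list(registry.definitions),
        "bit_threshold": [
            round(d.bit_threshold, 6) for d in registry.definitions.values()
        ],
    })
    thr_path = out / "thresholds.tsv"
    write_tsv(thresholds, thr_path)
    _write_manifest(config, "build-profiles", sorted(aln_dir.glob("*.afa")),
                    [profile_path, thr_path])
    return [profile_path, thr_path]


def stage_search(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    profile_path = _require(out / "profiles.json", "build-profiles")
    proteome_dir = _require(config.proteome_dir, "simulate")
    registry = MarkerRegistry.from_dict(json.loads(profile_path.read_text()))
    hits = []
    fasta_paths = sorted(proteome_dir.glob("*.faa"))
    if not fasta_paths:
        raise PipelineError(f"no proteomes (*.faa) in {proteome_dir}; run stage 'simulate' first")
    for path in fasta_paths:
        genome = read_proteome(path)
        hits.extend(search_proteome(registry, genome))
    hits_path = out / "hits.tsv"
    write_hits_tsv(hits, hits_path)
    logger.info("search: %d hits across %d proteomes", len(hits), len(fasta_paths))
    _write_manifest(config, "search", [profile_path, *fasta_paths], [hits_path])
    return [hits_path]


def stage_call(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    hits_path = _require(out / "hits.tsv", "search")
    metadata_path = _require(config.metadata_path, "simulate")
    call_cfg = config.section("call")
    rules = RuleSet(require_nird=bool(call_cfg.get("require_nird", True)))
    criteria = QCCriteria(
        min_completeness=float(call_cfg.get("min_completeness", 90.0)),
        max_contamination=float(call_cfg.get("max_contamination", 5.0)),
        require_rrna=bool(call_cfg.get("require_rrna", True)),
        min_trna=int(call_cfg.get("min_trna", 18)),
    )
    metadata = read_metadata(metadata_path)
    hits = read_hits_tsv(hits_path)
    by_genome: dict[str, list] = {gid: [] for gid in metadata["genome_id"]}
    for h in hits:
        by_genome.setdefault(h.genome_id, []).append(h)
    profiles = [
        call_strategies(genome_hits, rules, genome_id=gid)
        for gid, genome_hits in by_genome.items()
    ]
    kept, dropped = qc_filter_genomes(metadata, profiles, criteria)
    for d in dropped:
        logger.info("dropped genome %s: %s", d.genome_id, ",".join(d.reasons))
    strategies_path = out / "strategies.tsv"
    dropped_path = out / "dropped.tsv"
    write_tsv(profiles_to_frame(kept), strategies_path)
    write_tsv(drops_to_frame(dropped), dropped_path)
    _write_manifest(config, "call", [hits_path, metadata_path],
                    [strategies_path, dropped_path])
    return [strategies_path, dropped_path]


def stage_prevalence(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    strategies_path = _require(out / "strategies.tsv", "call")
    boot = config.section("bootstrap")
    df = pd.read_csv(strategies_path, sep="\t").set_index("genome_id")
    matrix = df[list(STRATEGIES)].astype(bool)
    scheme = boot.get("scheme", "plain")
    taxonomy = None
    inputs = [strategies_path]
    if scheme == "taxon_balanced":
        metadata_path = _require(config.metadata_path, "simulate")
        inputs.append(metadata_path)
        meta = read_metadata(metadata_path).set_index("genome_id")
        rank = boot.get("rank", "phylum")
        taxonomy = meta.loc[matrix.index, rank]
    estimates = bootstrap_prevalence(
        matrix,
        n_boot=int(boot.get("n_boot", 1000)),
        seed=config.stage_seed("prevalence"),
        scheme=scheme,
        taxonomy=taxonomy,
        k=boot.get("k"),
    )
    prevalence_path = out / "prevalence.tsv"
    write_tsv(estimates_to_frame(estimates), prevalence_path)
    _write_manifest(config, "prevalence", inputs, [prevalence_path])
    return [prevalence_path]


def stage_associate(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    strategies_path = _require(out / "strategies.tsv", "call")
    metadata_path = _require(config.metadata_path, "simulate")
    models_cfg = config.section("models")
    reference = models_cfg.get("reference_respiration", "anaerobic")
    family_mode = models_cfg.get("family_effects", "fixed")

    df = pd.read_csv(strategies_path, sep="\t")
    meta = read_metadata(metadata_path)
    merged = df.merge(meta, on="genome_id", how="left")

    results = []

    def run(fn, *args, **kwargs):
        try:
            results.append(fn(*args, **kwargs).to_dict())
        except (assoc.FitError, ValueError) as exc:
            results.append({"model_id": getattr(fn, "__name__", "model"),
                            "error": str(exc)})

    run(assoc.fit_count_scaling, merged["strategy_count"], merged["genome_length_bp"])
    run(assoc.group_compare, merged["strategy_count"], merged["respiration_mode"])
    family = merged["family"] if family_mode == "fixed" else None
    for strategy in ("chitin_depoly", "bnf"):
        def presence_model(strategy=strategy):
            model = "logistic_with_family" if family is not None else "logistic"
            res = assoc.fit_presence_model(
                merged[strategy], merged["respiration_mode"],
                family_ids=family, model=model, reference=reference,
            )
            res.model_id = f"presence_{strategy}"
            return res
        run(presence_model)
    organic = merged[[s for s in STRATEGIES if s in ORGANIC_STRATEGIES]].sum(axis=1)
    run(assoc.fit_habitat_counts, organic, merged["ecosystem_category"], family)
    run(assoc.host_contrast, merged["inorganic_fraction"],
        merged["host_associated"].astype(bool))

    assoc_path = out / "associations.json"
    assoc_path.write_text(json.dumps(results, indent=2, default=float) + "\n")

    matrix = df.set_index("genome_id")[list(STRATEGIES)].astype(bool)
    ord_rows = []
    for method in ("pca", "logistic_pca"):
        try:
            res = assoc.ordinate(matrix, method=method, k=2)
        except ValueError as exc:
            logger.warning("ordination %s skipped: %s", method, exc)
            continue
        eco = meta.set_index("genome_id").loc[matrix.index, "ecosystem_category"]
        for gid, eco_label, row in zip(matrix.index, eco, res.scores):
            ord_rows.append({
                "method": method, "genome_id": gid,
                "axis1": round(float(row[0]), 6),
                "axis2": round(float(row[1]), 6) if res.k > 1 else 0.0,
                "ecosystem_category": eco_label,
            })
    ord_path = out / "ordination.tsv"
    write_tsv(pd.DataFrame(ord_rows), ord_path)
    _write_manifest(config, "associate", [strategies_path, metadata_path],
                    [assoc_path, ord_path])
    return [assoc_path, ord_path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build-profiles": stage_build_profiles,
    "search": stage_search,
    "call": stage_call,
    "prevalence": stage_prevalence,
    "associate": stage_associate,
}


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one pipeline stage (or ``all``); returns the produced artifacts."""
    if stage == "all":
        outputs = []
        for name in ("simulate", "build-profiles", "search", "call",
                     "prevalence", "associate"):
            outputs.extend(_STAGE_FUNCS[name](config))
        return outputs
    if stage not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage](config)
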