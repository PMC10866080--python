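"""Rule-based calling of N-acquisition strategies from marker hits.

Ten strategies are called from the 17-marker registry via monotone boolean
rules; amino-acid uptake decomposes into five transporter-family sub-flags.
Also here: the genome-level QC filter and the fixed energetic cost table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MARKER_IDS, MarkerHit

#: The ten strategies, in canonical output order.
STRATEGIES = (
    "ammonium_uptake",
    "bnf",
    "fd_nitrite",
    "nadh_nitrite",
    "nitrate_assim",
    "urea",
    "cyanate",
    "chitin_depoly",
    "hexnac_assim",
    "amino_acid_uptake",
)

#: Amino-acid transporter families (sub-flags of amino_acid_uptake).
TRANSPORTER_FAMILIES = ("APC", "AGCS", "BCCT", "LIVCS", "HAAAP")

#: Strategies targeting inorganic N (N2, ammonium, nitrite, nitrate).
#: Cyanate and urea are classed as organic N.
INORGANIC_STRATEGIES = frozenset(
    {"ammonium_uptake", "bnf", "fd_nitrite", "nadh_nitrite", "nitrate_assim"}
)
ORGANIC_STRATEGIES = frozenset(STRATEGIES) - INORGANIC_STRATEGIES

#: Minimal marker complement demanded per single-marker / multi-subunit rule.
REQUIRED_MARKERS = {
    "ammonium_uptake": ("AmtB",),
    "bnf": ("NifH", "NifD", "NifK"),
    "fd_nitrite": ("NirA",),
    "nadh_nitrite": ("NirB", "NirD"),
    "nitrate_assim": ("NasA",),  # plus a co-occurring nitrite reductase
    "urea": ("UreC",),
    "cyanate": ("CynS",),
    "chitin_depoly": ("Chitinase",),
    "hexnac_assim": ("HexNAcase",),
}


@dataclass
class StrategyProfile:
    """Per-genome boolean strategy vector plus transporter-family sub-flags."""

    genome_id: str
    presence: dict[str, bool]
    transporter_families: dict[str, bool]

    def __post_init__(self) -> None:
        missing = set(STRATEGIES) - set(self.presence)
        if missing:
            raise ValueError(f"presence vector missing strategies: {sorted(missing)}")
        if set(self.transporter_families) != set(TRANSPORTER_FAMILIES):
            raise ValueError("transporter_families must cover exactly the five families")


@dataclass
class RuleSet:
    """Monotone marker -> strategy rules.

    ``require_nird`` demands NirD alongside NirB for the NADH-dependent
    nitrite route (the stricter reading of the two-subunit marker); relax
    it to call the route on NirB alone.
    """

    require_nird: bool = True

    def evaluate(self, markers: frozenset[str] | set[str]) -> tuple[dict, dict]:
        """Evaluate the rules on a set of detected marker ids.

        Returns ``(presence, families)`` dicts.
        """
        unknown = set(markers) - set(MARKER_IDS)
        if unknown:
            raise ValueError(f"unknown marker ids: {sorted(unknown)}")
        families = {f: f in markers for f in TRANSPORTER_FAMILIES}
        p: dict[str, bool] = {}
        p["ammonium_uptake"] = "AmtB" in markers
        p["bnf"] = "NifH" in markers and "NifD" in markers and "NifK" in markers
        p["fd_nitrite"] = "NirA" in markers
        p["nadh_nitrite"] = "NirB" in markers and ("NirD" in markers or not self.require_nird)
        p["nitrate_assim"] = "NasA" in markers and (p["fd_nitrite"] or p["nadh_nitrite"])
        p["urea"] = "UreC" in markers
        p["cyanate"] = "CynS" in markers
        p["chitin_depoly"] = "Chitinase" in markers
        p["hexnac_assim"] = "HexNAcase" in markers
        p["amino_acid_uptake"] = any(families.values())
        return p, families

    def required_markers(self, strategy: str) -> tuple[str, ...]:
        if strategy == "amino_acid_uptake":
            return TRANSPORTER_FAMILIES
        return REQUIRED_MARKERS[strategy]


def call_strategies(
    hits: list[MarkerHit],
    rules: RuleSet | None = None,
    genome_id: str | None = None,
) -> StrategyProfile:
    """Convert one genome's marker hits into a :class:`StrategyProfile`."""
    rules = rules or RuleSet()
    genome_ids = {h.genome_id for h in hits}
    if len(genome_ids) > 1:
        raise ValueError(f"hits span multiple genomes: {sorted(genome_ids)}")
    if genome_id is None:
        if not hits:
            raise ValueError("genome_id required when the hit list is empty")
        genome_id = hits[0].genome_id
    elif genome_ids and genome_ids != {genome_id}:
        raise ValueError(f"hits belong to {genome_ids.pop()}, not {genome_id}")
    markers = frozenset(h.marker_id for h in hits)
    presence, families = rules.evaluate(markers)
    return StrategyProfile(genome_id=genome_id, presence=presence,
                           transporter_families=families)


def strategy_count(profile: StrategyProfile) -> int:
    """Number of present strategies among the ten (sub-flags excluded)."""
    return sum(bool(profile.presence[s]) for s in STRATEGIES)


def inorganic_fraction(profile: StrategyProfile) -> float:
    """Fraction of present strategies that target inorganic N."""
    total = strategy_count(profile)
    if total == 0:
        raise ValueError(
            f"inorganic_fraction undefined for zero-strategy genome {profile.genome_id}"
        )
    inorganic = sum(
        bool(profile.presence[s]) for s in STRATEGIES if s in INORGANIC_STRATEGIES
    )
    return inorganic / total


def profiles_to_frame(profiles: list[StrategyProfile]) -> pd.DataFrame:
    """Binary genome x (strategies + families) matrix with summary columns."""
    rows = []
    for p in profiles:
        row = {"genome_id": p.genome_id}
        row.update({s: int(p.presence[s]) for s in STRATEGIES})
        row.update({f: int(p.transporter_families[f]) for f in TRANSPORTER_FAMILIES})
        n = strategy_count(p)
        row["strategy_count"] = n
        row["inorganic_fraction"] = round(inorganic_fraction(p), 6) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QCCriteria:
    """Genome quality thresholds.

    Defaults encode the MIMAG high-quality convention: completeness
    strictly above 90, contamination strictly below 5, rRNA present,
    at least 18 tRNAs.
    """

    min_completeness: float = 90.0   # strict >
    max_contamination: float = 5.0   # strict <
    require_rrna: bool = True
    min_trna: int = 18               # >=


@dataclass
class DropRecord:
    genome_id: str
    reasons: tuple[str, ...]


def qc_filter_genomes(
    metadata: pd.DataFrame,
    profiles: list[StrategyProfile],
    criteria: QCCriteria | None = None,
) -> tuple[list[StrategyProfile], list[DropRecord]]:
    """Apply quality + zero-pathway + taxonomy filters.

    Returns (kept profiles, drop records).  Every drop carries all the
    machine-readable reason codes that applied.
    """
    criteria = criteria or QCCriteria()
    meta = metadata.set_index("genome_id")
    kept: list[StrategyProfile] = []
    dropped: list[DropRecord] = []
    for profile in profiles:
        gid = profile.genome_id
        if gid not in meta.index:
            raise ValueError(f"no metadata row for genome {gid}")
        row = meta.loc[gid]
        reasons = []
        if not float(row["completeness"]) > criteria.min_completeness:
            reasons.append("low_completeness")
        if not float(row["contamination"]) < criteria.max_contamination:
            reasons.append("high_contamination")
        if criteria.require_rrna and not bool(int(row["has_rrna"])):
            reasons.append("missing_rrna")
        if int(row["n_trna"]) < criteria.min_trna:
            reasons.append("too_few_trna")
        domain = row.get("domain")
        if domain is None or (isinstance(domain, float) and math.isnan(domain)) or str(domain) == "":
            reasons.append("missing_domain")
        if strategy_count(profile) == 0:
            reasons.append("zero_pathways")
        if reasons:
            dropped.append(DropRecord(genome_id=gid, reasons=tuple(reasons)))
        else:
            kept.append(profile)
    return kept, dropped


# ---------------------------------------------------------------------------
# Energetic cost model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyCost:
    atp_cost: float
    electron_cost: float
    cost_class: str  # low | medium | high


@dataclass(frozen=True)
class CostModel:
    costs: dict = field(default_factory=dict)

    def __getattr__(self, name: str) -> StrategyCost:
        try:
            return self.costs[name]
        except KeyError as exc:  # pragma: no cover - attribute plumbing
            raise AttributeError(name) from exc


def cost_table() -> CostModel:
    """Fixed per-strategy assimilation cost table.

    ATP and reducing-equivalent stoichiometries per N event: ammonium
    assimilation via GS-GOGAT costs 1 ATP per molecule; nitrite and nitrate
    assimilation consume 6 and 8 reducing equivalents; nitrogen fixation
    takes 16 ATP plus 8 reducing equivalents per mole of N2.  Amino-acid
    uptake is transport-coupled (PMF/SMF) with no assimilation electrons.
    Urea, cyanate, chitin and HexNAc carry high indirect (enzyme-machinery)
    costs without an asserted ATP stoichiometry.
    """
    costs = {
        "ammonium_uptake": StrategyCost(atp_cost=1.0, electron_cost=0.0, cost_class="low"),
        "amino_acid_uptake": StrategyCost(atp_cost=0.0, electron_cost=0.0, cost_class="low"),
        "fd_nitrite": StrategyCost(atp_cost=0.0, electron_cost=6.0, cost_class="medium"),
        "nadh_nitrite": StrategyCost(atp_cost=0.0, electron_cost=6.0, cost_class="medium"),
        "nitrate_assim": StrategyCost(atp_cost=0.0, electron_cost=8.0, cost_class="medium"),
        "bnf": StrategyCost(atp_cost=16.0, electron_cost=8.0, cost_class="high"),
        "urea": StrategyCost(atp_cost=0.0, electron_cost=0.0, cost_class="high"),
        "cyanate": StrategyCost(atp_cost=0.0, electron_cost=0.0, cost_class="high"),
        "chitin_depoly": StrategyCost(atp_cost=0.0, electron_cost=0.0, cost_class="high"),
        "hexnac_assim": StrategyCost(atp_cost=0.0, electron_cost=0.0, cost_class="high"),
    }
    model = CostModel(costs=costs)
    # Convenience aliases used in reports.
    costs["ammonium"] = costs["ammonium_uptake"]
    costs["nitrate"] = costs["nitrate_assim"]
    costs["nitrite"] = costs["fd_nitrite"]
    assert max(c.atp_cost for c in costs.values()) == costs["bnf"].atp_cost
    return model


def drops_to_frame(dropped: list[DropRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "genome_id": [d.genome_id for d in dropped],
        "reasons": [",".join(d.reasons) for d in dropped],
    })
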