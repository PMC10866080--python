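"""Position-specific profile models for marker proteins and homology search.

A :class:`ProfileModel` is a lightweight profile hidden Markov model built
from a marker reference alignment: match states with per-position emission
distributions, a single shared insert emission distribution, and per-position
Match/Insert/Delete transition distributions.  Queries are scored with a
local forward algorithm — free entry at any match state with uniform entry
mass, free exit after any match — returning a log2-odds bit score against a
background residue model.  This keeps the pipeline self-contained; standard
HMMER3 per-target tabular output can be read as an interop escape hatch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .records import GenomeRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: Non-standard residues scored as background-frequency emissions.
WILDCARDS = frozenset("BZXUO")
GAP_CHARS = frozenset("-.")
_LN2 = math.log(2.0)
_EULER = 0.5772156649015329

#: The 17 marker ids of the default registry: 12 pathway markers plus the
#: five amino-acid transporter families.
MARKER_IDS = (
    "AmtB", "NifH", "NifD", "NifK",
    "NirA", "NirB", "NirD", "NasA",
    "CynS", "UreC", "Chitinase", "HexNAcase",
    "APC", "AGCS", "BCCT", "LIVCS", "HAAAP",
)


class AlignmentFormatError(ValueError):
    """Raised for ragged, empty or otherwise malformed alignment files."""


class DegenerateProfileError(ValueError):
    """Raised when an alignment yields no match states."""


class CalibrationError(ValueError):
    """Raised when a null-score distribution cannot be fitted."""


class TbloutFormatError(ValueError):
    """Raised for malformed HMMER3 tblout rows."""


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """An aligned set of protein sequences over the 20-letter alphabet + gap."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentFormatError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if self.n_columns == 0:
            raise AlignmentFormatError("alignment has zero columns")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file; validates equal row lengths."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    if not ids:
        raise AlignmentFormatError(f"no sequences in {path}")
    return MultipleAlignment(ids=ids, rows=rows)


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def _encode(sequence: str) -> np.ndarray:
    """Encode residues as indices 0-19; wildcards map to index 20."""
    if not sequence:
        raise ValueError("empty sequence")
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence.upper()):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        elif ch in WILDCARDS:
            out[i] = 20
        else:
            raise ValueError(f"illegal amino-acid character {ch!r} at position {i}")
    return out


# ---------------------------------------------------------------------------
# Profile model
# ---------------------------------------------------------------------------

class ProfileModel:
    """Profile model with M match states and shared insert emissions.

    Transition arrays have length ``M - 1`` and are indexed by the source
    position ``k`` (transitions from position ``k`` toward ``k + 1``).  The
    final match state has exit only.
    """

    def __init__(
        self,
        marker_id: str,
        match_emissions: np.ndarray,
        insert_emissions: np.ndarray,
        t_mm: np.ndarray,
        t_mi: np.ndarray,
        t_md: np.ndarray,
        t_im: np.ndarray,
        t_ii: np.ndarray,
        t_dm: np.ndarray,
        t_dd: np.ndarray,
        background: np.ndarray,
        occupancy_threshold: float = 0.5,
        pseudocount: float = 1.0,
    ) -> None:
        self.marker_id = marker_id
        self.match_emissions = np.asarray(match_emissions, dtype=float)
        self.insert_emissions = np.asarray(insert_emissions, dtype=float)
        self.t_mm = np.asarray(t_mm, dtype=float)
        self.t_mi = np.asarray(t_mi, dtype=float)
        self.t_md = np.asarray(t_md, dtype=float)
        self.t_im = np.asarray(t_im, dtype=float)
        self.t_ii = np.asarray(t_ii, dtype=float)
        self.t_dm = np.asarray(t_dm, dtype=float)
        self.t_dd = np.asarray(t_dd, dtype=float)
        self.background = np.asarray(background, dtype=float)
        self.occupancy_threshold = occupancy_threshold
        self.pseudocount = pseudocount
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    # -- scoring caches -----------------------------------------------------
    def _log_odds_match(self) -> np.ndarray:
        """(M, 21) natural-log odds; column 20 (wildcard) is zero."""
        if "lom" not in self._cache:
            lom = np.zeros((self.n_match, 21))
            lom[:, :20] = np.log(self.match_emissions) - np.log(self.background)
            self._cache["lom"] = lom
        return self._cache["lom"]

    def _log_odds_insert(self) -> np.ndarray:
        if "loi" not in self._cache:
            loi = np.zeros(21)
            loi[:20] = np.log(self.insert_emissions) - np.log(self.background)
            self._cache["loi"] = loi
        return self._cache["loi"]

    def _log_trans(self, name: str) -> np.ndarray:
        key = f"l_{name}"
        if key not in self._cache:
            with np.errstate(divide="ignore"):
                self._cache[key] = np.log(getattr(self, name))
        return self._cache[key]

    # -- generation ---------------------------------------------------------
    def consensus(self) -> str:
        """Highest-probability residue at each match state."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_emissions, axis=1))

    def sample_sequence(
        self,
        rng: np.random.Generator,
        mean_insertions: float = 2.0,
        mutation_rate: float = 0.0,
    ) -> str:
        """Emit a sequence along the match path with Poisson-count insertions
        at random inter-match slots, then apply per-residue mutation noise."""
        residues = [
            AMINO_ACIDS[rng.choice(20, p=self.match_emissions[k])]
            for k in range(self.n_match)
        ]
        n_ins = rng.poisson(mean_insertions)
        for _ in range(n_ins):
            pos = int(rng.integers(0, len(residues) + 1))
            residues.insert(pos, AMINO_ACIDS[rng.choice(20, p=self.insert_emissions)])
        if mutation_rate > 0.0:
            mask = rng.random(len(residues)) < mutation_rate
            for i in np.flatnonzero(mask):
                residues[i] = AMINO_ACIDS[rng.integers(0, 20)]
        return "".join(residues)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "t_mm": self.t_mm.tolist(),
            "t_mi": self.t_mi.tolist(),
            "t_md": self.t_md.tolist(),
            "t_im": self.t_im.tolist(),
            "t_ii": self.t_ii.tolist(),
            "t_dm": self.t_dm.tolist(),
            "t_dd": self.t_dd.tolist(),
            "background": self.background.tolist(),
            "occupancy_threshold": self.occupancy_threshold,
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileModel":
        return cls(**{k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()})


def build_profile(
    msa: MultipleAlignment,
    occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Estimate a :class:`ProfileModel` from an alignment.

    Columns whose gap fraction is strictly below ``occupancy_threshold``
    become match states.  Match emissions are
    ``(count + pseudocount * background) / (contributing_rows + pseudocount)``;
    wildcard residues contribute a background-distributed fractional count.
    Transitions are estimated from the observed gap patterns with Laplace
    (add-one) smoothing; insert emissions equal the background.
    """
    if not 0.0 < occupancy_threshold <= 1.0:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    if pseudocount <= 0.0:
        raise ValueError("pseudocount must be positive")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    n_rows, n_cols = msa.n_rows, msa.n_columns

    cols = np.array([[row[c] for row in msa.rows] for c in range(n_cols)])
    gap_frac = np.array([np.mean([ch in GAP_CHARS for ch in col]) for col in cols])
    match_cols = [c for c in range(n_cols) if gap_frac[c] < occupancy_threshold]
    M = len(match_cols)
    if M == 0:
        raise DegenerateProfileError("no alignment column qualifies as a match state")

    # Emissions.
    em = np.empty((M, 20))
    for k, c in enumerate(match_cols):
        counts = np.zeros(20)
        contributing = 0
        for ch in cols[c]:
            if ch in GAP_CHARS:
                continue
            contributing += 1
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1.0
            elif ch in WILDCARDS:
                counts += bg
            else:
                raise AlignmentFormatError(f"illegal residue {ch!r} in alignment column {c}")
        em[k] = (counts + pseudocount * bg) / (contributing + pseudocount)

    # Transitions from per-row state paths over match columns.
    c_mm = np.ones(max(M - 1, 0)); c_mi = np.ones_like(c_mm); c_md = np.ones_like(c_mm)
    c_im = np.ones_like(c_mm); c_ii = np.ones_like(c_mm)
    c_dm = np.ones_like(c_mm); c_dd = np.ones_like(c_mm)
    match_set = set(match_cols)
    for row in msa.rows:
        states = ["M" if row[c] not in GAP_CHARS else "D" for c in match_cols]
        for k in range(M - 1):
            lo, hi = match_cols[k], match_cols[k + 1]
            n_ins = sum(
                1 for c in range(lo + 1, hi)
                if c not in match_set and row[c] not in GAP_CHARS
            )
            s0, s1 = states[k], states[k + 1]
            if s0 == "M":
                if n_ins == 0:
                    (c_mm if s1 == "M" else c_md)[k] += 1.0
                else:
                    c_mi[k] += 1.0
                    c_ii[k] += n_ins - 1
                    if s1 == "M":
                        c_im[k] += 1.0
                    # I -> D transitions are not modelled; such a path
                    # contributes only its M->I / I->I counts.
            else:
                (c_dm if s1 == "M" else c_dd)[k] += 1.0

    tm_tot = c_mm + c_mi + c_md
    ti_tot = c_im + c_ii
    td_tot = c_dm + c_dd
    return ProfileModel(
        marker_id="",
        match_emissions=em,
        insert_emissions=bg.copy(),
        t_mm=c_mm / tm_tot, t_mi=c_mi / tm_tot, t_md=c_md / tm_tot,
        t_im=c_im / ti_tot, t_ii=c_ii / ti_tot,
        t_dm=c_dm / td_tot, t_dd=c_dd / td_tot,
        background=bg,
        occupancy_threshold=occupancy_threshold,
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_sequence(profile: ProfileModel, sequence: str) -> float:
    """Local forward bit score of ``sequence`` against ``profile``.

    Sums over all local alignments: entry at any match state with uniform
    mass ``1/M``, free exit after any match; flanking residues are emitted
    by the background and therefore contribute odds 1.  Returns
    ``log2(P(sequence | profile) / P(sequence | background))``.
    """
    idx = _encode(sequence)
    M = profile.n_match
    lom = profile._log_odds_match()
    loi = profile._log_odds_insert()
    l_mm = profile._log_trans("t_mm"); l_mi = profile._log_trans("t_mi")
    l_md = profile._log_trans("t_md"); l_im = profile._log_trans("t_im")
    l_ii = profile._log_trans("t_ii"); l_dm = profile._log_trans("t_dm")
    l_dd = profile._log_trans("t_dd")

    NEG = -np.inf
    l_entry = -math.log(M)
    lm = np.full(M, NEG)            # in match k, having emitted i residues
    li = np.full(max(M - 1, 0), NEG)  # in insert after match k
    ld = np.full(M, NEG)            # in delete k
    # Prefix sums of delete-chain transitions: S[k] = sum_{l<k} log t_dd[l].
    S = np.concatenate([[0.0], np.cumsum(l_dd)]) if M > 1 else np.zeros(1)
    total = NEG

    for x in idx:
        r = lom[:, x]
        cont = np.full(M, l_entry)
        if M > 1:
            prev = np.logaddexp(
                np.logaddexp(lm[:-1] + l_mm, li + l_im),
                ld[:-1] + l_dm,
            )
            cont[1:] = np.logaddexp(cont[1:], prev)
        lm_new = r + cont
        if M > 1:
            li = loi[x] + np.logaddexp(lm[:-1] + l_mi, li + l_ii)
            # Delete chains consume no residues: scan within the row.
            g = lm_new[:-1] + l_md - S[1:M]
            acc = np.logaddexp.accumulate(g)
            ld = np.full(M, NEG)
            ld[1:] = S[1:M] + acc
        lm = lm_new
        row_total = np.logaddexp.reduce(lm)
        total = np.logaddexp(total, row_total)

    return float(total / _LN2)


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

@dataclass
class NullCalibration:
    """Gumbel fit to background scores, used to convert bit scores to E-values."""

    marker_id: str
    gumbel_mu: float
    gumbel_lambda: float
    n_samples: int
    length_distribution: str
    seed: int

    def __post_init__(self) -> None:
        if self.gumbel_lambda <= 0:
            raise CalibrationError("gumbel_lambda must be positive")

    def evalue(self, score: float, n_targets: int = 1) -> float:
        return float(n_targets * math.exp(-self.gumbel_lambda * (score - self.gumbel_mu)))


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi / (sd * sqrt(6)),
    mu = mean - euler_gamma / lambda."""
    scores = np.asarray(scores, dtype=float)
    sd = float(np.std(scores, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise CalibrationError("zero variance in null scores")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(np.mean(scores)) - _EULER / lam
    return mu, lam


def sample_background_sequence(
    rng: np.random.Generator, length: int, background: np.ndarray | None = None
) -> str:
    bg = uniform_background() if background is None else background
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=bg))


def _length_sampler(lengths, M: int):
    if lengths is None:
        return (lambda rng: M), f"constant({M})"
    if isinstance(lengths, int):
        return (lambda rng: lengths), f"constant({lengths})"
    if isinstance(lengths, tuple) and len(lengths) == 2:
        lo, hi = lengths
        return (lambda rng: int(rng.integers(lo, hi + 1))), f"uniform({lo},{hi})"
    if callable(lengths):
        return lengths, "callable"
    raise ValueError("lengths must be None, int, (lo, hi) or callable")


def calibrate_null(
    profile: ProfileModel,
    n_samples: int = 200,
    lengths=None,
    seed: int = 0,
) -> NullCalibration:
    """Score background-sampled sequences and fit a Gumbel null by moments."""
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    sampler, descriptor = _length_sampler(lengths, profile.n_match)
    rng = np.random.default_rng(seed)
    scores = np.array([
        score_sequence(profile, sample_background_sequence(rng, sampler(rng), profile.background))
        for _ in range(n_samples)
    ])
    mu, lam = fit_gumbel(scores)
    return NullCalibration(
        marker_id=profile.marker_id,
        gumbel_mu=mu,
        gumbel_lambda=lam,
        n_samples=n_samples,
        length_distribution=descriptor,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Registry and search
# ---------------------------------------------------------------------------

@dataclass
class MarkerDefinition:
    marker_id: str
    alignment_path: str | None = None
    bit_threshold: float | None = None
    description: str = ""


@dataclass(order=True)
class MarkerHit:
    """A scored match of one protein to one marker model."""

    genome_id: str
    protein_id: str
    marker_id: str
    bit_score: float
    e_value: float | None = None
    source: str = "native"

    def __post_init__(self) -> None:
        if not np.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("e_value must be nonnegative")


class MarkerRegistry:
    """A set of marker definitions with their profile models and thresholds."""

    def __init__(self) -> None:
        self.definitions: dict[str, MarkerDefinition] = {}
        self.profiles: dict[str, ProfileModel] = {}
        self.alignments: dict[str, MultipleAlignment] = {}
        self.calibrations: dict[str, NullCalibration] = {}

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(self.definitions)

    def add(self, definition: MarkerDefinition, profile: ProfileModel,
            alignment: MultipleAlignment | None = None) -> None:
        if definition.marker_id in self.definitions:
            raise ValueError(f"duplicate marker_id {definition.marker_id}")
        profile.marker_id = definition.marker_id
        self.definitions[definition.marker_id] = definition
        self.profiles[definition.marker_id] = profile
        if alignment is not None:
            self.alignments[definition.marker_id] = alignment

    @classmethod
    def from_alignments(
        cls,
        alignment_paths: dict[str, str | Path],
        occupancy_threshold: float = 0.5,
        pseudocount: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "MarkerRegistry":
        reg = cls()
        for marker_id, path in alignment_paths.items():
            msa = read_alignment(path)
            profile = build_profile(msa, occupancy_threshold, pseudocount, background)
            reg.add(MarkerDefinition(marker_id=marker_id, alignment_path=str(path)),
                    profile, alignment=msa)
        return reg

    @classmethod
    def synthetic(
        cls,
        seed: int = 0,
        n_rows: int = 8,
        n_columns: int = 30,
        substitution_rate: float = 0.1,
        calibrate: bool = True,
        n_decoys: int = 200,
        margin: float = 8.0,
        separation_cap: float = 9.0,
    ) -> "MarkerRegistry":
        """Build a registry of well-separated synthetic reference alignments,
        one per marker in :data:`MARKER_IDS` (for testing and simulation).

        Separation is enforced at synthesis: any consensus whose cross-score
        against another marker's profile reaches ``separation_cap`` bits is
        resampled, so chance cross-marker homology stays far below the
        calibrated thresholds.
        """
        rng = np.random.default_rng([seed, 0x6D6B])
        reg = cls()
        built: list[tuple[str, ProfileModel, str]] = []  # (marker, profile, consensus)
        for marker_id in MARKER_IDS:
            for _attempt in range(100):
                consensus = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n_columns)]
                rows = []
                for r in range(n_rows):
                    row = list(consensus)
                    mask = rng.random(n_columns) < substitution_rate
                    for i in np.flatnonzero(mask):
                        row[i] = AMINO_ACIDS[rng.integers(0, 20)]
                    # A couple of gapped cells on a minority of rows exercise
                    # delete transitions without dropping any match column.
                    if r < 2:
                        for i in rng.integers(0, n_columns, size=2):
                            row[i] = "-"
                    rows.append("".join(row))
                msa = MultipleAlignment(
                    ids=[f"{marker_id}_ref{r}" for r in range(n_rows)], rows=rows
                )
                profile = build_profile(msa)
                cons = "".join(c for c in consensus)
                separated = all(
                    score_sequence(other_profile, cons) < separation_cap
                    and score_sequence(profile, other_cons) < separation_cap
                    for _, other_profile, other_cons in built
                )
                if separated:
                    break
            else:  # pragma: no cover - would need adversarial parameters
                raise RuntimeError(f"could not separate marker {marker_id}")
            built.append((marker_id, profile, cons))
            reg.add(MarkerDefinition(marker_id=marker_id, description="synthetic reference"),
                    profile, alignment=msa)
        if calibrate:
            reg.calibrate_thresholds(n_decoys=n_decoys, margin=margin, seed=seed)
        return reg

    def calibrate_thresholds(
        self, n_decoys: int = 200, margin: float = 8.0, seed: int = 0
    ) -> None:
        """Set each marker's bit threshold to max decoy score + ``margin`` bits
        and fit the Gumbel null from the same decoy scores.  Decoy lengths
        span the profile length plus a typical insertion load so the null is
        length-matched to planted queries."""
        for marker_id, profile in self.profiles.items():
            rng = np.random.default_rng([seed, abs(hash_name(marker_id))])
            M = profile.n_match
            scores = np.array([
                score_sequence(
                    profile,
                    sample_background_sequence(
                        rng, int(rng.integers(M, M + 9)), profile.background
                    ),
                )
                for _ in range(n_decoys)
            ])
            self.definitions[marker_id].bit_threshold = float(scores.max()) + margin
            try:
                mu, lam = fit_gumbel(scores)
            except CalibrationError:
                continue
            self.calibrations[marker_id] = NullCalibration(
                marker_id=marker_id, gumbel_mu=mu, gumbel_lambda=lam,
                n_samples=n_decoys, length_distribution=f"constant({profile.n_match})",
                seed=seed,
            )

    def write_alignments(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for marker_id, msa in self.alignments.items():
            p = outdir / f"{marker_id}.afa"
            write_alignment(msa, p)
            paths[marker_id] = p
        return paths

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "markers": [
                {
                    "definition": {
                        "marker_id": d.marker_id,
                        "alignment_path": d.alignment_path,
                        "bit_threshold": d.bit_threshold,
                        "description": d.description,
                    },
                    "profile": self.profiles[m].to_dict(),
                    "calibration": (
                        vars(self.calibrations[m]) if m in self.calibrations else None
                    ),
                }
                for m, d in self.definitions.items()
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerRegistry":
        reg = cls()
        for entry in d["markers"]:
            definition = MarkerDefinition(**entry["definition"])
            reg.add(definition, ProfileModel.from_dict(entry["profile"]))
            if entry.get("calibration"):
                reg.calibrations[definition.marker_id] = NullCalibration(**entry["calibration"])
        return reg


def hash_name(name: str) -> int:
    """Stable 63-bit hash of a string (process-independent)."""
    import hashlib

    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big") >> 1


def search_proteome(registry: MarkerRegistry, genome: GenomeRecord) -> list[MarkerHit]:
    """Score every protein against every registry marker; emit hits at or
    above each marker's bit threshold, sorted by (marker, -score, protein)."""
    for marker_id, definition in registry.definitions.items():
        if definition.bit_threshold is None:
            raise ValueError(f"marker {marker_id} has no bit_threshold; calibrate first")
    n_targets = max(len(genome.proteins), 1)
    hits: list[MarkerHit] = []
    for marker_id, profile in registry.profiles.items():
        threshold = registry.definitions[marker_id].bit_threshold
        calibration = registry.calibrations.get(marker_id)
        for protein_id, seq in genome.proteins.items():
            score = score_sequence(profile, seq)
            if score >= threshold:
                ev = calibration.evalue(score, n_targets) if calibration else None
                hits.append(MarkerHit(
                    genome_id=genome.genome_id, protein_id=protein_id,
                    marker_id=marker_id, bit_score=score, e_value=ev,
                ))
    hits.sort(key=lambda h: (h.marker_id, -h.bit_score, h.protein_id))
    return hits


# ---------------------------------------------------------------------------
# HMMER3 tblout interop
# ---------------------------------------------------------------------------

def read_hmmer_tblout(path: str | Path, known_markers: set[str] | None = None) -> list[MarkerHit]:
    """Parse HMMER3 per-target tabular output (tblout dialect).

    Column 1 is the target name (``genome|protein`` headers are split),
    column 3 the query (marker) name, column 5 the full-sequence E-value and
    column 6 the full-sequence bit score.  Rows with fewer than 18 fields
    raise :class:`TbloutFormatError` with the offending line number.
    """
    hits: list[MarkerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 18:
                raise TbloutFormatError(
                    f"{path}:{lineno}: expected >= 18 whitespace-separated fields, got {len(fields)}"
                )
            target, query = fields[0], fields[2]
            e_value, score = float(fields[4]), float(fields[5])
            if known_markers is not None and query not in known_markers:
                warnings.warn(f"{path}:{lineno}: unknown query name {query!r}")
            if "|" in target:
                genome_id, protein_id = target.split("|", 1)
            else:
                genome_id, protein_id = "", target
            hits.append(MarkerHit(
                genome_id=genome_id, protein_id=protein_id, marker_id=query,
                bit_score=score, e_value=e_value, source="hmmer_tblout",
            ))
    return hits


def write_hmmer_tblout(hits: list[MarkerHit], path: str | Path) -> None:
    """Write hits in the tblout dialect (for round-trip tests and interop)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession  query name accession "
                 "E-value score bias (remaining columns unused)\n")
        for h in hits:
            target = f"{h.genome_id}|{h.protein_id}" if h.genome_id else h.protein_id
            ev = h.e_value if h.e_value is not None else 0.0
            row = [target, "-", h.marker_id, "-", f"{ev:.6g}", f"{h.bit_score:.6f}", "0.0"]
            row += ["-"] * 11
            fh.write(" ".join(row) + "\n")


def hits_to_frame(hits: list[MarkerHit]):
    import pandas as pd

    return pd.DataFrame({
        "genome_id": [h.genome_id for h in hits],
        "protein_id": [h.protein_id for h in hits],
        "marker_id": [h.marker_id for h in hits],
        "bit_score": [f"{h.bit_score:.6f}" for h in hits],
        "e_value": ["" if h.e_value is None else f"{h.e_value:.6e}" for h in hits],
        "source": [h.source for h in hits],
    })


def write_hits_tsv(hits: list[MarkerHit], path: str | Path) -> None:
    from .records import write_tsv

    write_tsv(hits_to_frame(hits), path)


def read_hits_tsv(path: str | Path) -> list[MarkerHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "protein_id": str})
    hits = []
    for row in df.itertuples(index=False):
        ev = None if (not isinstance(row.e_value, str) and pd.isna(row.e_value)) else float(row.e_value)
        hits.append(MarkerHit(
            genome_id=row.genome_id, protein_id=row.protein_id,
            marker_id=row.marker_id, bit_score=float(row.bit_score),
            e_value=ev, source=row.source,
        ))
    return hits
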