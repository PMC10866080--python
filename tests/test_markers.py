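import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import enumerate_forward_score, random_profile
from nstrat.markers import (
    AlignmentFormatError,
    CalibrationError,
    DegenerateProfileError,
    MarkerHit,
    MultipleAlignment,
    NullCalibration,
    TbloutFormatError,
    build_profile,
    calibrate_null,
    fit_gumbel,
    read_alignment,
    read_hmmer_tblout,
    sample_background_sequence,
    score_sequence,
    search_proteome,
    write_alignment,
    write_hmmer_tblout,
)
from nstrat.records import GenomeRecord

EULER = 0.5772156649015329


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

class TestReadAlignment:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text(">a\nAC-\n>b\nAG-\n")
        msa = read_alignment(p)
        assert msa.n_rows == 2
        assert msa.n_columns == 3

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text(">a\nACD\n>b\nACDE\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p)

    def test_single_row_rejected(self, tmp_path):
        p = tmp_path / "a.afa"
        p.write_text(">a\nACD\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACDEF-"), size=12)) for _ in range(5)]
        msa = MultipleAlignment(ids=[f"s{i}" for i in range(5)], rows=rows)
        p = tmp_path / "rt.afa"
        write_alignment(msa, p)
        back = read_alignment(p)
        assert back.rows == msa.rows
        assert back.ids == msa.ids


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_frequency_limit(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AC", "AC"])
        prof = build_profile(msa, pseudocount=1e-9)
        assert prof.n_match == 2
        assert prof.match_emissions[0][0] == pytest.approx(1.0, abs=1e-8)  # A
        assert prof.match_emissions[1][1] == pytest.approx(1.0, abs=1e-8)  # C

    def test_gap_fraction_boundary_is_strict(self):
        # First column has gap fraction exactly 0.5 -> not a match state.
        msa = MultipleAlignment(
            ids=list("abcd"), rows=["AA", "AA", "-C", "-C"]
        )
        prof = build_profile(msa, occupancy_threshold=0.5)
        assert prof.n_match == 1

    def test_pseudocount_arithmetic(self):
        # Column {A, A, C}: P(A) = (2 + 1*0.05) / (3 + 1) = 0.5125.
        msa = MultipleAlignment(ids=list("abc"), rows=["A", "A", "C"])
        prof = build_profile(msa, pseudocount=1.0)
        assert prof.match_emissions[0][0] == pytest.approx(0.5125)
        assert prof.match_emissions[0][1] == pytest.approx((1 + 0.05) / 4)

    def test_all_gap_columns_degenerate(self):
        msa = MultipleAlignment(ids=list("ab"), rows=["--", "--"])
        with pytest.raises(DegenerateProfileError):
            build_profile(msa)

    @given(
        n_rows=st.integers(2, 6),
        n_cols=st.integers(1, 8),
        seed=st.integers(0, 10_000),
        occupancy=st.floats(0.1, 1.0),
        pseudocount=st.floats(0.01, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_distributions_normalized(self, n_rows, n_cols, seed, occupancy, pseudocount):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("ACDEFGHIKL-"), size=n_cols))
            for _ in range(n_rows)
        ]
        msa = MultipleAlignment(ids=[f"s{i}" for i in range(n_rows)], rows=rows)
        try:
            prof = build_profile(msa, occupancy_threshold=occupancy,
                                 pseudocount=pseudocount)
        except DegenerateProfileError:
            return
        assert np.allclose(prof.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(prof.match_emissions > 0)
        assert np.allclose(prof.t_mm + prof.t_mi + prof.t_md, 1.0, atol=1e-9)
        assert np.allclose(prof.t_im + prof.t_ii, 1.0, atol=1e-9)
        assert np.allclose(prof.t_dm + prof.t_dd, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Forward scoring
# ---------------------------------------------------------------------------

class TestScoreSequence:
    def test_background_match_single_residue_scores_zero(self):
        rng = np.random.default_rng(0)
        prof = random_profile(rng, 1)
        prof.match_emissions = prof.background.reshape(1, 20).copy()
        prof._cache.clear()
        for residue in "AWKV":
            assert score_sequence(prof, residue) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for case in range(80):
            M = int(rng.integers(1, 4))
            L = int(rng.integers(1, 5))
            prof = random_profile(rng, M)
            seq = "".join(rng.choice(letters, size=L))
            expected = enumerate_forward_score(prof, seq)
            assert score_sequence(prof, seq) == pytest.approx(expected, abs=1e-9)

    def test_planted_sequence_separates_from_background(self, uncalibrated_registry):
        prof = uncalibrated_registry.profiles["AmtB"]
        rng = np.random.default_rng(11)
        planted = prof.sample_sequence(rng, mean_insertions=0.0)
        planted_score = score_sequence(prof, planted)
        decoy_scores = [
            score_sequence(prof, sample_background_sequence(rng, len(planted)))
            for _ in range(100)
        ]
        assert planted_score > max(decoy_scores)

    def test_empty_sequence_rejected(self, uncalibrated_registry):
        with pytest.raises(ValueError):
            score_sequence(uncalibrated_registry.profiles["AmtB"], "")

    def test_illegal_character_rejected(self, uncalibrated_registry):
        with pytest.raises(ValueError):
            score_sequence(uncalibrated_registry.profiles["AmtB"], "ACD1EF")

    def test_wildcard_residues_allowed(self, uncalibrated_registry):
        prof = uncalibrated_registry.profiles["AmtB"]
        s = score_sequence(prof, "ACDXEF")
        assert np.isfinite(s)


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_constant_scores_error(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(200, 3.5))

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(123)
        scores = rng.gumbel(loc=0.0, scale=1.0, size=10_000)
        mu, lam = fit_gumbel(scores)
        assert mu == pytest.approx(0.0, abs=0.05)
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_evalue_closed_form(self):
        cal = NullCalibration(
            marker_id="x", gumbel_mu=5.0, gumbel_lambda=1.0,
            n_samples=100, length_distribution="constant(30)", seed=0,
        )
        # At score = mu the stated formula gives N_targets exactly.
        assert cal.evalue(5.0, 1) == pytest.approx(1.0)
        # One Euler-gamma/lambda below mu it gives exp(gamma) ~ 1.78.
        assert cal.evalue(5.0 - EULER, 1) == pytest.approx(math.exp(EULER), rel=1e-9)
        assert cal.evalue(7.0, 100) == pytest.approx(100 * math.exp(-2.0))

    def test_calibrate_null_runs_on_profile(self, uncalibrated_registry):
        prof = uncalibrated_registry.profiles["NifH"]
        cal = calibrate_null(prof, n_samples=150, seed=4)
        assert cal.gumbel_lambda > 0
        assert cal.n_samples == 150

    def test_minimum_sample_size(self, uncalibrated_registry):
        with pytest.raises(ValueError):
            calibrate_null(uncalibrated_registry.profiles["NifH"], n_samples=50)


# ---------------------------------------------------------------------------
# Proteome search
# ---------------------------------------------------------------------------

class TestSearchProteome:
    def test_decoy_only_proteome_yields_no_hits(self, registry):
        rng = np.random.default_rng(77)
        genome = GenomeRecord(genome_id="d0", proteins={
            f"p{i}": sample_background_sequence(rng, int(rng.integers(25, 61)))
            for i in range(50)
        })
        assert search_proteome(registry, genome) == []

    def test_consensus_retrieval_is_specific(self, registry):
        consensus = registry.profiles["NifH"].consensus()
        genome = GenomeRecord(genome_id="g0", proteins={"p0": consensus})
        hits = search_proteome(registry, genome)
        assert {h.marker_id for h in hits} == {"NifH"}

    def test_search_is_deterministic(self, registry):
        rng = np.random.default_rng(5)
        genome = GenomeRecord(genome_id="g1", proteins={
            "p0": registry.profiles["UreC"].sample_sequence(rng),
            "p1": sample_background_sequence(rng, 40),
        })
        first = search_proteome(registry, genome)
        second = search_proteome(registry, genome)
        assert first == second

    def test_specificity_on_background_decoys(self, registry):
        # False-positive rate <= 1% per marker on 1000 decoys.
        rng = np.random.default_rng(3)
        decoys = [sample_background_sequence(rng, 35) for _ in range(1000)]
        for marker_id in ("AmtB", "NifH", "Chitinase"):
            prof = registry.profiles[marker_id]
            thr = registry.definitions[marker_id].bit_threshold
            fp = sum(score_sequence(prof, d) >= thr for d in decoys)
            assert fp / 1000 <= 0.01

    def test_sensitivity_noiseless_and_mutated(self, registry):
        rng = np.random.default_rng(9)
        for rate, floor in ((0.0, 1.0), (0.1, 0.9)):
            recovered = 0
            for _ in range(100):
                marker_id = str(rng.choice(list(registry.profiles)))
                prof = registry.profiles[marker_id]
                seq = prof.sample_sequence(rng, mutation_rate=rate)
                if score_sequence(prof, seq) >= registry.definitions[marker_id].bit_threshold:
                    recovered += 1
            assert recovered / 100 >= floor

    def test_uncalibrated_registry_rejected(self, uncalibrated_registry):
        genome = GenomeRecord(genome_id="g", proteins={"p": "ACDEF"})
        with pytest.raises(ValueError, match="bit_threshold"):
            search_proteome(uncalibrated_registry, genome)


# ---------------------------------------------------------------------------
# HMMER tblout interop
# ---------------------------------------------------------------------------

class TestTblout:
    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "empty.tbl"
        p.write_text("# comment\n#\n# another\n")
        assert read_hmmer_tblout(p) == []

    def test_echo_single_row(self, tmp_path):
        fields = ["g1|p1", "-", "NifH", "-", "1e-10", "55.2", "0.1"] + ["-"] * 11
        p = tmp_path / "one.tbl"
        p.write_text("# header\n" + " ".join(fields) + "\n")
        (hit,) = read_hmmer_tblout(p)
        assert hit.genome_id == "g1"
        assert hit.protein_id == "p1"
        assert hit.marker_id == "NifH"
        assert hit.bit_score == pytest.approx(55.2)
        assert hit.e_value == pytest.approx(1e-10)
        assert hit.source == "hmmer_tblout"

    def test_short_row_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tbl"
        p.write_text("# ok\ntoo few fields here\n")
        with pytest.raises(TbloutFormatError, match=":2:"):
            read_hmmer_tblout(p)

    def test_unknown_query_flagged(self, tmp_path):
        fields = ["g1|p1", "-", "NotAMarker", "-", "1e-5", "20.0", "0.0"] + ["-"] * 11
        p = tmp_path / "u.tbl"
        p.write_text(" ".join(fields) + "\n")
        with pytest.warns(UserWarning, match="unknown query"):
            read_hmmer_tblout(p, known_markers={"NifH"})

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        hits = [
            MarkerHit(
                genome_id=f"g{i % 4}", protein_id=f"p{i:03d}",
                marker_id="UreC" if i % 2 else "CynS",
                bit_score=round(float(rng.uniform(10, 90)), 6),
                e_value=round(float(10.0 ** -rng.uniform(2, 12)), 18),
                source="hmmer_tblout",
            )
            for i in range(20)
        ]
        p = tmp_path / "rt.tbl"
        write_hmmer_tblout(hits, p)
        back = read_hmmer_tblout(p)
        assert len(back) == 20
        for a, b in zip(hits, back):
            assert (a.genome_id, a.protein_id, a.marker_id) == (b.genome_id, b.protein_id, b.marker_id)
            assert b.bit_score == pytest.approx(a.bit_score, abs=1e-6)
            assert b.e_value == pytest.approx(a.e_value, rel=1e-5)
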