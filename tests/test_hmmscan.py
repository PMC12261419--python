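"""HMMER3 parsing and local Viterbi scoring against closed forms and oracles."""

import math

import numpy as np
import pytest

from taxocycle.fixtures import make_toy_hmm, random_profile, random_sequence
from taxocycle.hmmscan import (
    HmmFormatError,
    ProfileHMM,
    ScoringError,
    brute_force_score,
    call_hits,
    parse_hmm_file,
    present_profiles,
    viterbi_score,
    write_hmm_file,
)

LOG2_20 = math.log2(20.0)


class TestParsing:
    def test_single_model_round_trip(self, tmp_path):
        hmm = make_toy_hmm("MKV", sharpness=0.9, cutoff_bits=10.0)
        path = write_hmm_file([hmm], tmp_path / "toy.hmm")
        (parsed,) = parse_hmm_file(path)
        assert parsed.name == hmm.name and parsed.length == 3
        assert parsed.cutoff_bits == 10.0
        np.testing.assert_allclose(parsed.match_emissions, hmm.match_emissions, atol=1e-9)
        np.testing.assert_allclose(parsed.insert_emissions, hmm.insert_emissions, atol=1e-9)
        np.testing.assert_allclose(parsed.transitions, hmm.transitions, atol=1e-9)
        np.testing.assert_allclose(parsed.background, hmm.background, atol=1e-9)

    def test_concatenated_models_preserve_order(self, tmp_path):
        models = [make_toy_hmm("MKV", name="first"), make_toy_hmm("ACDEF", name="second")]
        path = write_hmm_file(models, tmp_path / "two.hmm")
        parsed = parse_hmm_file(path)
        assert [m.name for m in parsed] == ["first", "second"]
        assert [m.length for m in parsed] == [3, 5]

    def test_stored_zero_is_prob_one_and_star_is_zero(self, tmp_path):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        path = write_hmm_file([hmm], tmp_path / "toy.hmm")
        text = path.read_text()
        assert "*" in text  # zero-probability branches
        (parsed,) = parse_hmm_file(path)
        # deterministic emissions: stored 0.0 nats -> probability exactly 1
        assert parsed.match_emissions.max() == 1.0
        assert parsed.match_emissions.min() == 0.0

    def test_missing_leng_is_format_error(self, tmp_path):
        hmm = make_toy_hmm("MKV")
        path = write_hmm_file([hmm], tmp_path / "toy.hmm")
        broken = "\n".join(
            l for l in path.read_text().splitlines() if not l.startswith("LENG")
        )
        (tmp_path / "broken.hmm").write_text(broken)
        with pytest.raises(HmmFormatError, match="LENG"):
            parse_hmm_file(tmp_path / "broken.hmm")

    def test_missing_end_marker_is_format_error(self, tmp_path):
        hmm = make_toy_hmm("MKV")
        path = write_hmm_file([hmm], tmp_path / "toy.hmm")
        (tmp_path / "broken.hmm").write_text(path.read_text().replace("//", ""))
        with pytest.raises(HmmFormatError, match="end marker"):
            parse_hmm_file(tmp_path / "broken.hmm")

    def test_wrong_emission_arity_reports_line(self, tmp_path):
        hmm = make_toy_hmm("MKV")
        path = write_hmm_file([hmm], tmp_path / "toy.hmm")
        lines = path.read_text().splitlines()
        node1 = next(i for i, l in enumerate(lines) if l.split()[:1] == ["1"])
        lines[node1] = " ".join(lines[node1].split()[:10])
        (tmp_path / "broken.hmm").write_text("\n".join(lines))
        with pytest.raises(HmmFormatError, match="arity|node"):
            parse_hmm_file(tmp_path / "broken.hmm")

    def test_pyhmmer_reads_our_files(self, tmp_path):
        """Independent format oracle: the reference HMMER parser."""
        pyhmmer = pytest.importorskip("pyhmmer")
        models = [make_toy_hmm("MKVLA", cutoff_bits=20.0), make_toy_hmm("WYW", sharpness=0.8)]
        path = write_hmm_file(models, tmp_path / "pair.hmm")
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            parsed = list(fh)
        names = [h.name if isinstance(h.name, str) else h.name.decode() for h in parsed]
        assert names == [m.name for m in models]
        assert [h.M for h in parsed] == [5, 3]
        assert parsed[0].cutoffs.gathering == (20.0, 20.0)


class TestViterbiClosedForms:
    def test_consensus_scores_sum_of_log_odds(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        score, span = viterbi_score(hmm, "MKV")
        assert score == pytest.approx(3 * LOG2_20, abs=1e-9)
        assert span == (1, 3)

    def test_sharpness_scales_per_state_odds(self):
        hmm = make_toy_hmm("MKV", sharpness=0.9)
        score, _ = viterbi_score(hmm, "MKV")
        assert score == pytest.approx(3 * math.log2(0.9 * 20), abs=1e-9)

    def test_embedded_motif_found_with_span(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        score, span = viterbi_score(hmm, "AAAMKVCC")
        assert score == pytest.approx(3 * LOG2_20, abs=1e-9)
        assert span == (4, 6)

    def test_never_emitted_residues_give_neg_inf(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        score, span = viterbi_score(hmm, "WWW")
        assert score == float("-inf") and span is None

    def test_single_ambiguity_residue_scores_zero(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        score, span = viterbi_score(hmm, "X")
        assert score == 0.0 and span == (1, 1)

    def test_stop_codon_star_skipped(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)
        score, _ = viterbi_score(hmm, "MKV*")
        assert score == pytest.approx(3 * LOG2_20, abs=1e-9)

    def test_single_state_single_residue(self):
        p = random_profile(3, length=1)
        aa = "W"
        v, _ = viterbi_score(p, aa)
        i = "ACDEFGHIKLMNPQRSTVWY".index(aa)
        assert v == pytest.approx(
            math.log2(p.match_emissions[0, i] / p.background[i]), abs=1e-12
        )

    def test_empty_sequence_errors(self):
        hmm = make_toy_hmm("MKV")
        with pytest.raises(ScoringError):
            viterbi_score(hmm, "")
        with pytest.raises(ScoringError):
            viterbi_score(hmm, "***")

    def test_non_alphabet_character_errors(self):
        hmm = make_toy_hmm("MKV")
        with pytest.raises(ScoringError, match="'J'"):
            viterbi_score(hmm, "MJV")


class TestOracleEquivalence:
    def test_random_profiles_match_brute_force_exactly(self):
        rng = np.random.default_rng(1)
        for case in range(60):
            profile = random_profile(case, length=int(rng.integers(1, 5)))
            seq = random_sequence(rng, int(rng.integers(1, 7)))
            v, _ = viterbi_score(profile, seq)
            b = brute_force_score(profile, seq)
            assert v == b, f"case {case}: {v} != {b}"

    def test_match_only_fast_path_matches_brute_force_exactly(self):
        rng = np.random.default_rng(2)
        for case in range(40):
            cons = random_sequence(rng, int(rng.integers(3, 5)))
            profile = make_toy_hmm(cons, sharpness=float(rng.uniform(0.6, 1.0)))
            seq = random_sequence(rng, int(rng.integers(1, 7)))
            v, _ = viterbi_score(profile, seq)
            b = brute_force_score(profile, seq)
            assert v == b

    def test_brute_force_refuses_large_inputs(self):
        with pytest.raises(ScoringError):
            brute_force_score(random_profile(0, length=1), "A" * 7)
        big = make_toy_hmm("ACDEF")
        with pytest.raises(ScoringError):
            brute_force_score(big, "ACDEF")


class TestScoringProperties:
    def test_extension_never_decreases_local_score(self):
        rng = np.random.default_rng(3)
        for case in range(30):
            profile = random_profile(100 + case, length=3)
            seq = random_sequence(rng, 4)
            base, _ = viterbi_score(profile, seq)
            for suffix in ("A", "WY"):
                longer, _ = viterbi_score(profile, seq + suffix)
                assert longer >= base

    def test_scaling_emissions_and_background_preserves_scores(self):
        rng = np.random.default_rng(4)
        profile = random_profile(7, length=3)
        factor = rng.uniform(0.5, 2.0, size=20)
        scaled = ProfileHMM(
            name="scaled",
            length=profile.length,
            match_emissions=profile.match_emissions * factor,
            insert_emissions=profile.insert_emissions * factor,
            transitions=profile.transitions,
            background=profile.background * factor,
        )
        for _ in range(20):
            seq = random_sequence(rng, 6)
            assert viterbi_score(scaled, seq)[0] == pytest.approx(
                viterbi_score(profile, seq)[0], abs=1e-9
            )

    def test_profile_order_does_not_change_scores(self):
        rng = np.random.default_rng(5)
        profiles = [make_toy_hmm("MKVLA", cutoff_bits=20.0), make_toy_hmm("WYWYW", cutoff_bits=20.0)]
        proteome = [(f"s{i}", random_sequence(rng, 25)) for i in range(5)]
        fwd = call_hits(profiles, proteome)
        rev = call_hits(profiles[::-1], proteome)
        key = lambda h: (h.sequence_id, h.profile_name)
        assert sorted(fwd, key=key) == sorted(rev, key=key)


class TestCallHits:
    def test_cutoff_comparison(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0)  # consensus scores ~12.966
        hits10 = call_hits([hmm], [("s", "MKV")], cutoffs={hmm.name: 10.0})
        hits15 = call_hits([hmm], [("s", "MKV")], cutoffs={hmm.name: 15.0})
        assert hits10[0].passed and not hits15[0].passed

    def test_cutoff_priority_table_then_ga_then_default(self):
        hmm = make_toy_hmm("MKV", sharpness=1.0, cutoff_bits=5.0)
        (h_table,) = call_hits([hmm], [("s", "MKV")], cutoffs={hmm.name: 99.0})
        assert not h_table.passed  # explicit table overrides GA
        (h_ga,) = call_hits([hmm], [("s", "MKV")])
        assert h_ga.passed  # GA 5 < 12.966
        bare = make_toy_hmm("MKV", sharpness=1.0)
        (h_default,) = call_hits([bare], [("s", "MKV")], default_cutoff=40.0)
        assert not h_default.passed

    def test_planted_motif_is_only_pass_among_decoys(self):
        from taxocycle.markers import default_profiles

        profiles = [p for p in default_profiles() if p.name in ("mcrA", "dsrA")]
        mcra = next(p for p in profiles if p.name == "mcrA")
        planted = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[int(np.argmax(row))] for row in mcra.match_emissions
        )
        rng = np.random.default_rng(6)
        from taxocycle.fixtures import _decoy

        proteome = [("planted", planted)] + [
            (f"decoy_{i}", _decoy(rng, profiles)) for i in range(50)
        ]
        hits = call_hits(profiles, proteome)
        passing = [(h.sequence_id, h.profile_name) for h in hits if h.passed]
        assert passing == [("planted", "mcrA")]
        assert present_profiles(hits) == {"mcrA"}

    def test_empty_proteome_errors(self):
        with pytest.raises(ScoringError):
            call_hits([make_toy_hmm("MKV")], [])
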