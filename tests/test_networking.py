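"""Modified cosine and network construction."""
import numpy as np
import pytest

from photonet import networking
from photonet.exceptions import ParameterError, ValidationError
from photonet.networking import build_network, match_peaks, modified_cosine
from photonet.types import FragmentSpectrum

from .oracles import exhaustive_modified_cosine, random_related_pair


def spec(fid, prec, peaks):
    mz, inten = zip(*peaks)
    return FragmentSpectrum(fid, prec, 1.0, np.array(mz), np.array(inten))


class TestMatchPeaks:
    def test_identical_spectra_give_direct_candidates(self):
        a = spec("a", 300.0, [(100.0, 1.0), (150.0, 2.0)])
        b = spec("b", 300.0, [(100.0, 1.0), (150.0, 2.0)])
        pairs = match_peaks(a, b, 0.02)
        direct = [p for p in pairs if not p.shifted]
        assert len(direct) == 2

    def test_precursor_shifted_candidate(self):
        # precursors 300/314; a peak at 150 matches b's 164 via the +14 shift
        a = spec("a", 300.0, [(150.0, 1.0)])
        b = spec("b", 314.0, [(164.0, 1.0)])
        pairs = match_peaks(a, b, 0.02)
        assert len(pairs) == 1 and pairs[0].shifted

    def test_disjoint_peaks_no_shift_empty(self):
        a = spec("a", 300.0, [(100.0, 1.0)])
        b = spec("b", 300.0, [(200.0, 1.0)])
        assert match_peaks(a, b, 0.02) == []

    def test_nonpositive_tolerance_rejected(self):
        a = spec("a", 300.0, [(100.0, 1.0)])
        with pytest.raises(ParameterError):
            match_peaks(a, a, 0.0)


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        a = spec("a", 300.0, [(100.0, 5.0), (150.0, 1.0), (200.0, 3.0)])
        score, n = modified_cosine(a, a)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_analog_pair_with_direct_and_shifted_match(self):
        # one conserved fragment + one shifted by the +14 precursor delta,
        # identical relative intensities: perfect correlation
        a = spec("a", 300.0, [(100.0, 1.0), (150.0, 0.25)])
        b = spec("b", 314.0, [(100.0, 1.0), (164.0, 0.25)])
        score, n = modified_cosine(a, b, 0.02)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert n == 2

    def test_no_candidates_scores_zero(self):
        a = spec("a", 300.0, [(100.0, 1.0)])
        b = spec("b", 300.0, [(250.0, 1.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_both_empty_spectra_score_zero_without_error(self):
        a = FragmentSpectrum("a", 300.0, 1.0, np.array([]), np.array([]))
        b = FragmentSpectrum("b", 310.0, 1.0, np.array([]), np.array([]))
        assert modified_cosine(a, b) == (0.0, 0)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_related_pair(rng)
            s_ab, n_ab = modified_cosine(a, b)
            s_ba, n_ba = modified_cosine(b, a)
            assert s_ab == pytest.approx(s_ba, abs=1e-9)
            assert n_ab == n_ba
            assert 0.0 <= s_ab <= 1.0

    def test_matches_exhaustive_assignment_oracle(self, rng):
        """On small spectra the score equals brute-force enumeration."""
        for _ in range(200):
            a, b = random_related_pair(rng)
            score, _ = modified_cosine(a, b)
            oracle_score, _ = exhaustive_modified_cosine(a, b, 0.02)
            assert score == pytest.approx(oracle_score, abs=1e-9)

    def test_agrees_with_matchms_reference(self, rng):
        """Independent cross-check against the matchms ModifiedCosine scorer.

        matchms scores raw intensity products, so the spectra are fed in
        square-root scale to match our convention; matchms resolves
        conflicting candidates greedily, so our optimal assignment may only
        ever score equal or higher, and equals it in conflict-free cases.
        """
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        scorer = ModifiedCosine(tolerance=0.02)
        n_equal = 0
        for _ in range(60):
            a, b = random_related_pair(rng)
            ref = scorer.pair(
                matchms.Spectrum(
                    mz=a.mz, intensities=np.sqrt(a.intensities),
                    metadata={"precursor_mz": a.precursor_mz},
                    metadata_harmonization=False,
                ),
                matchms.Spectrum(
                    mz=b.mz, intensities=np.sqrt(b.intensities),
                    metadata={"precursor_mz": b.precursor_mz},
                    metadata_harmonization=False,
                ),
            )
            ours, _ = modified_cosine(a, b, 0.02)
            assert ours >= float(ref["score"]) - 1e-9
            n_equal += ours == pytest.approx(float(ref["score"]), abs=1e-9)
        assert n_equal >= 30  # most random pairs are conflict-free


class TestBuildNetwork:
    def test_single_spectrum_is_singleton(self):
        a = spec("a", 300.0, [(100.0, 1.0)])
        net = build_network([a])
        assert net.n_nodes == 1 and net.n_edges == 0
        assert net.singletons == {"a"}

    def test_duplicate_feature_ids_rejected(self):
        a = spec("x", 300.0, [(100.0, 1.0)])
        b = spec("x", 301.0, [(100.0, 1.0)])
        with pytest.raises(ValidationError):
            build_network([a, b])

    def test_mutual_top_k_rank_rule_on_triangle(self):
        """Triangle A-B 0.9, B-C 0.8, A-C 0.7 with top_k=1: only A-B survives."""
        base = [(100.0 + 10 * i, 1.0) for i in range(6)]
        a = spec("A", 300.0, base)
        b = spec("B", 300.0, [(m, i * (1 + 0.4 * (m > 130))) for m, i in base])
        c = spec("C", 300.0, [(m, i * (1 + 1.2 * (m > 130))) for m, i in base])
        scores = {
            ("A", "B"): modified_cosine(a, b)[0],
            ("B", "C"): modified_cosine(b, c)[0],
            ("A", "C"): modified_cosine(a, c)[0],
        }
        # sanity: the planted ordering holds and all pass the 0.7 threshold
        assert scores["A", "B"] > scores["B", "C"] > scores["A", "C"] >= 0.7
        net = build_network([a, b, c], top_k=1, score_threshold=0.7, min_matched=6)
        kept = {frozenset((e.feature_a, e.feature_b)) for e in net.edges}
        assert kept == {frozenset(("A", "B"))}

    def test_component_size_cap_enforced(self, rng):
        # a clique of 12 near-identical spectra, capped at component size 5
        peaks = [(100.0 + 15 * i, 10.0) for i in range(8)]
        spectra = [
            spec(f"s{i:02d}", 400.0, [(m, v * float(rng.uniform(0.95, 1.05))) for m, v in peaks])
            for i in range(12)
        ]
        net = build_network(spectra, max_component_size=5, score_threshold=0.7)
        sizes = {}
        for node, cid in net.components.items():
            sizes[cid] = sizes.get(cid, 0) + 1
        assert max(sizes.values()) <= 5
        for e in net.edges:
            assert e.score >= 0.7

    def test_generated_families_recovered_as_components(self, spectra, truth):
        """Adjusted Rand index between components and planted families ≥ 0.9."""
        sklearn = pytest.importorskip("sklearn.metrics")
        net = build_network(spectra)
        fam = truth.family_of
        ids = sorted(net.components)
        fam_labels = [fam[i] if fam[i] != "single" else f"single_{i}" for i in ids]
        comp_labels = [net.components[i] for i in ids]
        ari = sklearn.adjusted_rand_score(fam_labels, comp_labels)
        assert ari >= 0.9

    def test_five_analog_family_forms_one_component(self, rng):
        from photonet import synthetic_data as sd

        cfg = sd.GeneratorConfig(seed=3, n_families=2, family_size_min=5,
                                 family_size_max=5, n_background=0,
                                 specific_feature_plan={"rubrophyllus": 5,
                                                        "xanthophyllus": 5},
                                 inactive_specific_plan={})
        spectra, plans = sd.generate_spectra(cfg)
        fam0 = [s for s, p in zip(spectra, plans) if p.family == "fam00"]
        assert len(fam0) == 5
        net = build_network(fam0)
        assert net.n_components == 1
        assert len(net.singletons) == 0
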