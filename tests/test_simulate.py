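"""Synthetic-data generators: determinism, round trips, recovery."""

import numpy as np
import pytest

from permutome.alignment import ProbeSequence, percent_identity
from permutome.catalogues import PATHWAYS
from permutome.fattyacids import UndefinedRatioError, ol_ratio, percent_unsaturated
from permutome.permutation import permutation_count
from permutome.silencing import (
    DownregulationState,
    TreatmentStateVector,
    classify_treatment,
)
from permutome.simulate import (
    SimulationConfig,
    hexamer_composition_table,
    mutate_to_identity,
    random_probe,
    random_state_vectors,
    simulate_bands,
    simulate_fatty_acids,
)

NOT = DownregulationState.NOT_DOWNREGULATED
PARTIAL = DownregulationState.PARTIAL
FULL = DownregulationState.FULL

PROTECTED = frozenset({"arachin_biosynthesis", "fatty_acid_desaturase"})


def recover(truth, cfg):
    """Classify simulated bands back into states with matching protection."""
    observations = simulate_bands(truth, cfg)
    recovered = {}
    for t in {o.treatment for o in observations}:
        rows = [o for o in observations if o.treatment == t]
        recovered[t] = classify_treatment(rows, PROTECTED, cfg.silencing)
    return recovered


def accuracy(truth, recovered):
    hits = total = 0
    for t, vector in truth.items():
        for pw, state in vector.states.items():
            hits += recovered[t].states[pw] is state
            total += 1
    return hits / total


class TestMutateToIdentity:
    def test_target_100_returns_template(self):
        template = random_probe(60, seed=1)
        assert mutate_to_identity(template, 100.0, seed=2) == template

    def test_length_100_target_77(self):
        template = random_probe(100, seed=3)
        mutant = mutate_to_identity(template, 77.0, seed=4)
        assert percent_identity(template, mutant) == pytest.approx(77.0, abs=1.0)

    def test_distinct_seeds_same_identity_different_sequences(self):
        template = random_probe(100, seed=5)
        m1 = mutate_to_identity(template, 80.0, seed=10)
        m2 = mutate_to_identity(template, 80.0, seed=11)
        assert m1.bases != m2.bases
        assert percent_identity(template, m1) == pytest.approx(
            percent_identity(template, m2), abs=1.0
        )

    def test_unattainable_target_on_short_sequence(self):
        with pytest.raises(ValueError, match="not attainable"):
            mutate_to_identity(ProbeSequence("x", "", "ACGT"), 85.0, seed=0)

    def test_ambiguous_positions_not_substituted(self):
        template = ProbeSequence("x", "", "N" * 30 + "ACGT")
        with pytest.raises(ValueError, match="substitutable"):
            mutate_to_identity(template, 50.0, seed=0)


class TestSimulateBands:
    def test_noise_free_round_trip_is_exact(self):
        cfg = SimulationConfig(seed=42, noise_cv=0.0)
        truth = random_state_vectors(PROTECTED, cfg)
        assert accuracy(truth, recover(truth, cfg)) == 1.0

    def test_noise_free_permutation_counts_preserved(self):
        cfg = SimulationConfig(seed=43, noise_cv=0.0)
        truth = random_state_vectors(PROTECTED, cfg)
        recovered = recover(truth, cfg)
        for t in truth:
            assert permutation_count(recovered[t]) == permutation_count(truth[t])

    def test_identical_config_identical_output(self):
        truth = random_state_vectors(PROTECTED, SimulationConfig(seed=7))
        a = simulate_bands(truth, SimulationConfig(seed=7, noise_cv=0.2))
        b = simulate_bands(truth, SimulationConfig(seed=7, noise_cv=0.2))
        assert a == b

    def test_recovery_accuracy_non_increasing_in_noise(self):
        accuracies = []
        for cv in (0.0, 0.8, 2.5):
            acc = []
            for rep in range(40):
                cfg = SimulationConfig(seed=1000 + rep, noise_cv=cv)
                truth = random_state_vectors(PROTECTED, cfg)
                acc.append(accuracy(truth, recover(truth, cfg)))
            accuracies.append(np.mean(acc))
        assert accuracies[0] >= accuracies[1] >= accuracies[2]

    def test_missing_state_rejected(self):
        truth = {("PK", pw): NOT for pw in PATHWAYS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            simulate_bands(truth, SimulationConfig())

    def test_flat_state_map_accepted(self):
        truth = {("PK", pw): PARTIAL for pw in PATHWAYS}
        observations = simulate_bands(truth, SimulationConfig(noise_cv=0.0))
        assert len(observations) == len(PATHWAYS)
        assert all(o.treatment == "PK" for o in observations)


class TestRandomStateVectors:
    def test_consistent_with_protection(self):
        truth = random_state_vectors(PROTECTED, SimulationConfig(seed=3))
        for vector in truth.values():
            for pw, state in vector.states.items():
                if state is PARTIAL:
                    assert pw in PROTECTED
                if state is FULL:
                    assert pw not in PROTECTED


class TestSimulateFattyAcids:
    def test_identity_case_reproduces_wild_ol(self, table2_profiles):
        p = simulate_fatty_acids(1.0, wild_profile=table2_profiles["control"])
        assert ol_ratio(p).rounded == 1.35

    def test_zero_residual_hits_undefined_ratio_path(self, table2_profiles):
        p = simulate_fatty_acids(0.0, wild_profile=table2_profiles["control"])
        with pytest.raises(UndefinedRatioError):
            ol_ratio(p)

    def test_conserves_pooled_c18_and_unsaturation(self, table2_profiles):
        wild = table2_profiles["control"]
        pool = wild.value("C18:1") + wild.value("C18:2")
        for residual in np.linspace(0.0, 1.0, 6):
            p = simulate_fatty_acids(residual, wild_profile=wild)
            assert p.value("C18:1") + p.value("C18:2") == pytest.approx(pool)
            assert percent_unsaturated(p) == pytest.approx(
                percent_unsaturated(wild), abs=0.1
            )

    def test_ol_strictly_decreasing_in_residual(self, table2_profiles):
        wild = table2_profiles["control"]
        grid = np.arange(0.1, 1.01, 0.1)
        ratios = [
            ol_ratio(simulate_fatty_acids(r, wild_profile=wild)).value
            for r in grid
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestHexamerCompositions:
    def test_three_subunit_types_give_28_classes(self):
        table = hexamer_composition_table(3)
        assert len(table) == 28
        assert table["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_subunit_type(self):
        table = hexamer_composition_table(1)
        assert len(table) == 1
        assert table["probability"].iloc[0] == pytest.approx(1.0)

    def test_uniform_frequencies_favor_even_split(self):
        table = hexamer_composition_table(3, [1 / 3, 1 / 3, 1 / 3])
        assert tuple(table["counts"].iloc[0]) == (2, 2, 2)

    def test_probabilities_sum_to_one_for_skewed_frequencies(self):
        table = hexamer_composition_table(3, [0.7, 0.2, 0.1])
        assert table["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            hexamer_composition_table(3, [0.5, 0.5, 0.5])
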