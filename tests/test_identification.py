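import math

import numpy as np
import pytest

import barcodekit as bk

from conftest import matrix_from_pairs, random_matrix


SPECIES_2X2 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


def _m2x2(intra=0.01, inter=0.10):
    return matrix_from_pairs(
        ["a1", "a2", "b1", "b2"],
        {
            ("a1", "a2"): intra,
            ("b1", "b2"): intra,
            ("a1", "b1"): inter,
            ("a1", "b2"): inter,
            ("a2", "b1"): inter,
            ("a2", "b2"): inter,
        },
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles: explicit per-row scans over neighbours
# ---------------------------------------------------------------------------

def brute_nn(m, species):
    out = {}
    for i, lab in enumerate(m.labels):
        row = [(m.values[i, j], m.labels[j]) for j in range(len(m)) if j != i]
        row = [(d, l) for d, l in row if not math.isnan(d)]
        if not row:
            continue
        dmin = min(d for d, _ in row)
        tied = [l for d, l in row if d == dmin]
        out[lab] = "true" if any(species[l] == species[lab] for l in tied) else "false"
    return out


def brute_bcm(m, species, t):
    out = {}
    for i, lab in enumerate(m.labels):
        row = [(m.values[i, j], m.labels[j]) for j in range(len(m)) if j != i]
        row = [(d, l) for d, l in row if not math.isnan(d)]
        if not row:
            continue
        dmin = min(d for d, _ in row)
        if dmin > t:
            out[lab] = "no_id"
            continue
        tied = [l for d, l in row if d == dmin]
        con = any(species[l] == species[lab] for l in tied)
        het = any(species[l] != species[lab] for l in tied)
        out[lab] = "ambiguous" if (con and het) else ("correct" if con else "incorrect")
    return out


def brute_thresh(m, species, t):
    out = {}
    for i, lab in enumerate(m.labels):
        row = [(m.values[i, j], m.labels[j]) for j in range(len(m)) if j != i]
        row = [(d, l) for d, l in row if not math.isnan(d)]
        if not row:
            continue
        within = [l for d, l in row if d <= t]
        if not within:
            out[lab] = "no_id"
            continue
        con = any(species[l] == species[lab] for l in within)
        het = any(species[l] != species[lab] for l in within)
        out[lab] = "ambiguous" if (con and het) else ("correct" if con else "incorrect")
    return out


def _verdicts(result):
    return {o.id: o.verdict for o in result.outcomes}


class TestNearNeighbour:
    def test_clean_library_all_true(self):
        res = bk.near_neighbour(_m2x2(), SPECIES_2X2)
        assert res.summary["true"] == 100.0

    def test_singleton_is_necessarily_false(self):
        m = matrix_from_pairs(
            ["a1", "a2", "c1"],
            {("a1", "a2"): 0.01, ("a1", "c1"): 0.1, ("a2", "c1"): 0.1},
        )
        res = bk.near_neighbour(m, {"a1": "A", "a2": "A", "c1": "C"})
        assert _verdicts(res)["c1"] == "false"
        assert res.n_singletons == 1

    def test_tie_counts_as_true_if_any_conspecific(self):
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.05, ("a1", "b1"): 0.05, ("a2", "b1"): 0.2},
        )
        res = bk.near_neighbour(m, {"a1": "A", "a2": "A", "b1": "B"})
        assert _verdicts(res)["a1"] == "true"


class TestBestCloseMatch:
    def test_nearest_conspecific_within_threshold(self):
        res = bk.best_close_match(_m2x2(intra=0.004, inter=0.1), SPECIES_2X2, 0.0144)
        assert res.summary["correct"] == 100.0

    def test_everything_beyond_threshold_is_no_id(self):
        res = bk.best_close_match(_m2x2(intra=0.05, inter=0.1), SPECIES_2X2, 0.0144)
        assert res.summary["no_id"] == 100.0

    def test_mixed_tie_is_ambiguous(self):
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.005, ("a1", "b1"): 0.005, ("a2", "b1"): 0.2},
        )
        res = bk.best_close_match(m, {"a1": "A", "a2": "A", "b1": "B"}, 0.01)
        assert _verdicts(res)["a1"] == "ambiguous"

    def test_reduces_to_near_neighbour_at_infinite_threshold(self, panel20):
        """With no distance cutoff and no ties, BCM correct/incorrect must
        mirror NN true/false."""
        _, lib, m = panel20
        species = lib.species_of()
        nn = _verdicts(bk.near_neighbour(m, species))
        bcm = _verdicts(bk.best_close_match(m, species, float("inf")))
        mapping = {"correct": "true", "incorrect": "false"}
        for rid, verdict in bcm.items():
            if verdict in mapping:
                assert nn[rid] == mapping[verdict]


class TestThresholdId:
    def test_mixed_neighbours_within_cutoff_ambiguous(self):
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.002, ("a1", "b1"): 0.008, ("a2", "b1"): 0.2},
        )
        res = bk.threshold_id(m, {"a1": "A", "a2": "A", "b1": "B"}, 0.01)
        assert _verdicts(res)["a1"] == "ambiguous"

    def test_only_conspecifics_within_cutoff_correct(self):
        res = bk.threshold_id(_m2x2(intra=0.002, inter=0.1), SPECIES_2X2, 0.01)
        assert res.summary["correct"] == 100.0

    def test_no_id_count_monotone_in_threshold(self, panel20):
        _, lib, m = panel20
        species = lib.species_of()
        counts = []
        for t in (0.0005, 0.002, 0.01, 0.05, 0.2):
            res = bk.threshold_id(m, species, t)
            counts.append(sum(1 for o in res.outcomes if o.verdict == "no_id"))
        assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("seed", range(10))
def test_estimators_agree_with_brute_force(seed):
    """All three estimators against exhaustive per-row scans, on random
    matrices with ties and occasional MISSING entries."""
    rng = np.random.default_rng(seed)
    m, species = random_matrix(rng, n=20, missing_prob=0.05 if seed % 2 else 0.0)
    t = float(rng.uniform(0.01, 0.15))
    assert _verdicts(bk.near_neighbour(m, species)) == brute_nn(m, species)
    assert _verdicts(bk.best_close_match(m, species, t)) == brute_bcm(m, species, t)
    assert _verdicts(bk.threshold_id(m, species, t)) == brute_thresh(m, species, t)


class TestOptimizeThreshold:
    def test_clean_separation_picks_smallest_zero_error_point(self):
        m = _m2x2(intra=0.004, inter=0.05)
        grid = [0.001, 0.003, 0.005, 0.01, 0.02, 0.06]
        t, profile = bk.optimize_threshold(m, SPECIES_2X2, grid=grid)
        assert t == 0.005  # smallest grid point above max intra
        zero_region = profile[profile["cumulative_error"] == 0]["threshold"]
        assert 0.005 in set(zero_region)

    def test_profile_matches_per_record_brute_force(self, panel20):
        """False negatives (furthest conspecific beyond t) and false
        positives (nearest heterospecific within t) counted row by row."""
        _, lib, m = panel20
        species = lib.species_of()
        grid = [0.001, 0.005, 0.02, 0.1]
        _, profile = bk.optimize_threshold(m, species, grid=grid)
        for _, row in profile.iterrows():
            t = row["threshold"]
            fn = fp = 0
            for i, lab in enumerate(m.labels):
                con = [
                    m.values[i, j]
                    for j in range(len(m))
                    if j != i and species[m.labels[j]] == species[lab]
                ]
                het = [
                    m.values[i, j]
                    for j in range(len(m))
                    if j != i and species[m.labels[j]] != species[lab]
                ]
                if con and max(con) > t:
                    fn += 1
                if het and min(het) <= t:
                    fp += 1
            assert row["false_negative"] == fn
            assert row["false_positive"] == fp
            assert row["cumulative_error"] == fn + fp

    def test_single_point_grid_returns_it(self):
        t, _ = bk.optimize_threshold(_m2x2(), SPECIES_2X2, grid=[0.0123])
        assert t == 0.0123

    def test_empty_grid_rejected(self):
        with pytest.raises(bk.BarcodekitError, match="empty grid"):
            bk.optimize_threshold(_m2x2(), SPECIES_2X2, grid=[])

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_threshold_inside_the_gap(self, seed):
        """On well-separated synthetic libraries the optimum lies between
        realized max-intra and min-inter."""
        cfg = bk.SyntheticConfig(
            n_species=20,
            individuals_per_species=3,
            seq_length=600,
            inter_target=0.10,
            intra_target=0.003,
            seed=100 + seed,
        )
        lib, _ = bk.generate_library(cfg)
        m = bk.build_distance_matrix(lib)
        intra, inter = bk.partition_distances(m, lib.species_of())
        t, _ = bk.optimize_threshold(m, lib.species_of())
        assert intra.max() < t < inter.min()


class TestEfficacyTable:
    def test_perfect_library_all_hundred(self, panel20):
        _, lib, m = panel20
        table = bk.efficacy_table(lib, m, bcm_threshold=0.02, bold_threshold=0.02)
        for method, want in [
            ("near_neighbour", "true"),
            ("best_close_match", "correct"),
            ("threshold_id", "correct"),
        ]:
            row = table[(table["method"] == method) & (table["verdict"] == want)]
            assert row["pct"].iloc[0] == 100.0

    def test_percentages_sum_to_hundred_per_method(self, panel20):
        _, lib, m = panel20
        table = bk.efficacy_table(lib, m, bcm_threshold=0.005)
        sums = table.groupby("method")["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_mislabeled_record_costs_exactly_one_share(self):
        """Relabelling a record whose conspecifics do not depend on it as
        their nearest neighbour lowers NN true% by exactly its own share."""
        m = matrix_from_pairs(
            ["a1", "a2", "a3", "b1", "b2"],
            {
                ("a1", "a2"): 0.01,
                ("a1", "a3"): 0.02,
                ("a2", "a3"): 0.005,  # a2 and a3 are each other's nearest
                ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.1,
                ("a1", "b2"): 0.1,
                ("a2", "b1"): 0.1,
                ("a2", "b2"): 0.1,
                ("a3", "b1"): 0.1,
                ("a3", "b2"): 0.1,
            },
        )
        species = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        baseline = bk.near_neighbour(m, species).summary["true"]
        assert baseline == 100.0
        mislabeled = dict(species, a1="Imposter")
        perturbed = bk.near_neighbour(m, mislabeled).summary["true"]
        assert baseline - perturbed == pytest.approx(100.0 / 5)
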