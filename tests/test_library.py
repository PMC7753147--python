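"""Library generators, WT normalization, and array/TRIC correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricscreen import datasets
from tricscreen.library import (
    AMINO_ACIDS,
    correlate_array_tric,
    make_overlapping_library,
    make_positional_scan,
    normalize_to_wt,
    simulate_array,
)


class TestOverlappingLibrary:
    def test_single_window(self):
        lib = make_overlapping_library("A" * 15)
        assert len(lib) == 1

    def test_window_count_for_long_parent(self):
        seq = "".join(AMINO_ACIDS[i % 20] for i in range(100))
        lib = make_overlapping_library(seq)
        assert len(lib) == 86  # L - 15 + 1

    def test_benchmark_window_reproduced_from_loop(self):
        loop, start = datasets.synthetic_glyr_beta_loop()
        lib = make_overlapping_library(loop, parent_id="loop", parent_start=start)
        row = lib.entries.set_index("peptide_id").loc["loop_414_428"]
        assert row["sequence"] == datasets.GLYR_BETA_WT_PEPTIDE
        assert (row["start"], row["end"]) == (414, 428)

    def test_short_parent_rejected(self):
        with pytest.raises(ValueError):
            make_overlapping_library("ACDEF")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(15, 60),
        length=st.integers(5, 15),
        start=st.integers(1, 500),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_coordinate_roundtrip(self, n, length, start, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        lib = make_overlapping_library(seq, length=length, parent_start=start)
        for _, row in lib.entries.iterrows():
            assert lib.window_sequence(row["start"], row["end"]) == row["sequence"]


class TestPositionalScan:
    def test_full_scan_combinatorics(self):
        lib = make_positional_scan(datasets.GLYR_BETA_WT_PEPTIDE, parent_start=414)
        assert len(lib) == 300
        assert int(lib.entries["is_wt"].sum()) == 15

    def test_motif_restricted_scan(self):
        m0 = datasets.GLYR_BETA_MOTIF_START
        lib = make_positional_scan(
            datasets.GLYR_BETA_WT_PEPTIDE, parent_start=414, positions=range(m0, m0 + 5)
        )
        assert len(lib) == 100

    def test_point_substitution_sequence(self):
        lib = make_positional_scan(
            datasets.GLYR_BETA_WT_PEPTIDE, parent_id="wt", parent_start=414,
            positions=[420],
        )
        row = lib.entries.set_index("peptide_id").loc["wt_420A"]
        assert row["sequence"] == "DLRSNDASIVGSLPR"
        assert not row["is_wt"]

    def test_generators_are_pure(self):
        a = make_positional_scan("ACDEF", parent_start=10)
        b = make_positional_scan("ACDEF", parent_start=10)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            make_positional_scan("ACDEX")
        with pytest.raises(ValueError):
            make_positional_scan("ACDEF", alphabet="AZ")


@pytest.fixture(scope="module")
def motif_scan():
    m0 = datasets.GLYR_BETA_MOTIF_START
    return make_positional_scan(
        datasets.GLYR_BETA_WT_PEPTIDE, parent_id="wt", parent_start=414,
        positions=range(m0, m0 + 5),
    )


class TestNormalizeToWt:
    def test_uniform_intensities_give_unit_matrix(self, motif_scan):
        rows = [
            {"array_id": a, "peptide_id": pid, "role": "spot", "intensity": 500.0}
            for a in ("array1", "array2")
            for pid in motif_scan.entries["peptide_id"]
        ]
        mat = normalize_to_wt(pd.DataFrame(rows), motif_scan, subtract_background=False)
        np.testing.assert_allclose(mat.grid.to_numpy(), 1.0)

    def test_identical_replicates_zero_sd(self, motif_scan):
        ki_map = {pid: 1e-6 for pid in motif_scan.entries["peptide_id"]}
        spots = simulate_array(motif_scan, ki_map, n_arrays=3, noise_cv=0.0)
        mat = normalize_to_wt(spots, motif_scan)
        np.testing.assert_allclose(mat.sd.to_numpy(), 0.0)
        np.testing.assert_allclose(mat.n.to_numpy(), 3)

    def test_scale_invariance_per_array(self, motif_scan):
        ki_map = {pid: 10 ** (-6 - (hash(pid) % 7) / 3) for pid in
                  motif_scan.entries["peptide_id"]}
        spots = simulate_array(motif_scan, ki_map, n_arrays=2, noise_cv=0.02, seed=4)
        scaled = spots.copy()
        one = scaled["array_id"] == "array1"
        scaled.loc[one, "intensity"] *= 37.5
        a = normalize_to_wt(spots, motif_scan)
        b = normalize_to_wt(scaled, motif_scan)
        pd.testing.assert_frame_equal(a.grid, b.grid)

    def test_mutation_sensitive_position_is_matrix_minimum(self, motif_scan):
        # position 420 substitutions lose binding strongly; 424 is tolerant
        ki_map = {}
        for _, r in motif_scan.entries.iterrows():
            if r["is_wt"]:
                ki_map[r["peptide_id"]] = 1e-6
            elif r["sub_pos"] == 420:
                ki_map[r["peptide_id"]] = 1e-3
            else:
                ki_map[r["peptide_id"]] = 2e-6
        spots = simulate_array(motif_scan, ki_map, n_arrays=3, noise_cv=0.0)
        mat = normalize_to_wt(spots, motif_scan)
        row_means = mat.grid.mean(axis=1)
        assert row_means.idxmin() == 420


class TestCorrelateArrayTric:
    def test_monotone_intensities_give_unit_coefficient(self, motif_scan):
        ki_map = {pid: 10 ** (-7 + 0.02 * i) for i, pid in
                  enumerate(motif_scan.entries["peptide_id"])}
        spots = simulate_array(motif_scan, ki_map, n_arrays=2, noise_cv=0.0)
        mat = normalize_to_wt(spots, motif_scan)
        comp = correlate_array_tric(mat, ki_map)
        assert comp.coefficient == pytest.approx(1.0)
        assert comp.n_pairs == 100

    def test_shuffled_intensities_decorrelate(self, motif_scan):
        pids = list(motif_scan.entries["peptide_id"])
        ki = {pid: 10 ** (-7 + 0.02 * i) for i, pid in enumerate(pids)}
        spots = simulate_array(motif_scan, ki, n_arrays=1, noise_cv=0.0)
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = dict(zip(pids, rng.permutation([ki[p] for p in pids])))
            mat = normalize_to_wt(spots, motif_scan)
            coefs.append(abs(correlate_array_tric(mat, shuffled).coefficient))
        assert np.quantile(coefs, 0.95) < 0.25

    def test_censored_ranked_below_finite(self, motif_scan):
        pids = list(motif_scan.entries["peptide_id"])[:10]
        sub = motif_scan.entries[motif_scan.entries["peptide_id"].isin(pids)]
        lib = type(motif_scan)(sub.reset_index(drop=True), motif_scan.parent_id,
                               motif_scan.parent_sequence, motif_scan.parent_start)
        ki_map = {pid: 10 ** (-7 + 0.1 * i) for i, pid in enumerate(pids)}
        # weakest three become censored non-binders; array still sees them weakest
        for pid in pids[-3:]:
            ki_map[pid] = None
        spots_ki = {p: (10 ** (-7 + 0.1 * i) if ki_map[p] is not None else 1e-2)
                    for i, p in enumerate(pids)}
        spots = simulate_array(lib, spots_ki, n_arrays=1, noise_cv=0.0)
        mat = normalize_to_wt(spots, lib)
        comp = correlate_array_tric(mat, ki_map, policy="censored_lowest")
        assert comp.coefficient > 0.9
        excl = correlate_array_tric(mat, ki_map, policy="exclude")
        assert excl.n_pairs == 7

    def test_too_few_pairs_rejected(self, motif_scan):
        with pytest.raises(ValueError):
            correlate_array_tric(
                normalize_to_wt(
                    simulate_array(motif_scan,
                                   {p: 1e-6 for p in motif_scan.entries["peptide_id"]},
                                   n_arrays=1, noise_cv=0.0),
                    motif_scan,
                ),
                {"wt_420A": 1e-6, "wt_420C": 2e-6},
            )
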