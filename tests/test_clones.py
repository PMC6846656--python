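"""Clone-level processivity statistics: covariance, distance correlation,
correlation-length fit, clusters and per-clone distribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aidmds import simulate
from aidmds.clones import (CloneMutationMatrix, cluster_fraction,
                           correlation_length_from_matrix, distance_correlation,
                           fit_correlation_length, mutation_covariance,
                           mutations_per_clone, singly_mutated_fraction)


def brute_force_covariance(matrix, coords):
    """Direct loop evaluation of c(i,j) = <dh_i dh_j> / (s_i s_j) and C(d)."""
    h = np.asarray(matrix, dtype=float)
    n, m = h.shape
    mean = [sum(h[k][i] for k in range(n)) / n for i in range(m)]
    c = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            cov = sum((h[k][i] - mean[i]) * (h[k][j] - mean[j]) for k in range(n)) / n
            si = (sum((h[k][i] - mean[i]) ** 2 for k in range(n)) / n) ** 0.5
            sj = (sum((h[k][j] - mean[j]) ** 2 for k in range(n)) / n) ** 0.5
            if si * sj > 0:
                c[i, j] = cov / (si * sj)
    cd = {}
    for i in range(m):
        for j in range(i + 1, m):
            d = abs(coords[j] - coords[i])
            if np.isfinite(c[i, j]):
                cd.setdefault(d, []).append(c[i, j])
    return c, {d: np.mean(v) for d, v in cd.items()}


class TestMutationCovariance:
    def test_hand_computed_example(self):
        # clones {1,2} and {2,3}: site 2 never varies -> excluded;
        # sites 1 and 3 are perfectly anti-correlated
        m = CloneMutationMatrix(strand="NTS", coords=[1, 2, 3],
                                matrix=[[1, 1, 0], [0, 1, 1]])
        c = mutation_covariance(m)
        assert np.isnan(c[0, 1]) and np.isnan(c[1, 2])
        assert c[0, 2] == pytest.approx(-1.0)
        assert np.isnan(c).all() is not True

    def test_perfectly_comutated_pair_is_plus_one(self):
        m = CloneMutationMatrix(strand="NTS", coords=[1, 5],
                                matrix=[[1, 1], [0, 0], [1, 1], [1, 1]])
        c = mutation_covariance(m, scope="all")
        assert c[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        m = CloneMutationMatrix(strand="NTS", coords=np.arange(8),
                                matrix=rng.integers(0, 2, size=(30, 8)))
        c = mutation_covariance(m, scope="all")
        finite = np.isfinite(c)
        assert np.array_equal(finite, finite.T)
        assert np.allclose(c[finite], c.T[finite])
        assert np.nanmax(np.abs(c)) <= 1 + 1e-12

    def test_oracle_equivalence_small_matrices(self):
        """c(i,j) and C(d) equal direct brute-force evaluation on random
        matrices up to 6 clones x 8 sites."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n, m = rng.integers(2, 7), rng.integers(2, 9)
            coords = np.sort(rng.choice(np.arange(1, 40), size=m, replace=False))
            mat = rng.integers(0, 2, size=(n, m))
            cm = CloneMutationMatrix(strand="NTS", coords=coords, matrix=mat)
            c = mutation_covariance(cm, scope="all")
            bc, bcd = brute_force_covariance(mat, coords)
            assert np.allclose(c, bc, equal_nan=True)
            cd = distance_correlation(c, coords)
            got = dict(zip(cd["d"], cd["C"]))
            assert set(got) == set(bcd)
            for d in bcd:
                assert got[d] == pytest.approx(bcd[d])

    def test_column_shuffled_matrix_uncorrelated(self):
        """Independently permuting each column destroys the correlation:
        mean off-diagonal c within 3 SE of zero and the aggregated C(d)
        confidence interval covers zero."""
        model = simulate.DeaminationModel(p_hot=0.5, p_other=0.3, p_cold=0.1,
                                          burst_rate=1.0, tract_mean=10, strand_mode="NTS")
        ref = simulate.generate_reference(seed=7)
        truth = simulate.simulate_clone_mutations(ref, model, 3000, seed=13).truth_table()
        coords = [ref.duplex_coord("NTS", p) for p in ref.c_positions("NTS")]
        mat = CloneMutationMatrix.from_calls(truth, coords, "NTS").restrict(2).matrix
        rng = np.random.default_rng(14)
        shuffled = np.column_stack([rng.permutation(col) for col in np.asarray(mat).T])
        cm = CloneMutationMatrix(strand="NTS", coords=coords, matrix=shuffled)
        c = mutation_covariance(cm, scope="all")
        vals = c[np.isfinite(c) & ~np.eye(len(coords), dtype=bool)]
        se = vals.std(ddof=1) / np.sqrt(len(vals) / 2)  # each pair appears twice
        assert abs(vals.mean()) <= 3 * se
        cd = distance_correlation(c, coords)
        mean_c = np.average(cd["C"], weights=cd["n_pairs"])
        se_c = np.sqrt(np.cov(cd["C"], aweights=cd["n_pairs"]) / len(cd))
        assert abs(mean_c) <= 3 * se_c

    def test_too_few_clones_rejected(self):
        m = CloneMutationMatrix(strand="NTS", coords=[1, 2], matrix=[[1, 1]])
        with pytest.raises(ValueError):
            mutation_covariance(m, scope="all")


class TestDistanceCorrelation:
    def test_single_defined_pair(self):
        c = np.full((2, 2), np.nan)
        c[0, 1] = c[1, 0] = -1.0
        cd = distance_correlation(c, [1, 3])
        assert cd.to_dict("records") == [{"d": 2, "C": -1.0, "n_pairs": 1}]

    def test_all_zero_covariance(self):
        c = np.zeros((4, 4))
        np.fill_diagonal(c, np.nan)
        cd = distance_correlation(c, [1, 2, 3, 4])
        assert (cd["C"] == 0).all()

    def test_tract_simulation_decreasing_in_distance(self):
        ref = simulate.generate_reference(seed=7)
        model = simulate.DeaminationModel(p_hot=0.5, p_other=0.3, p_cold=0.1,
                                          burst_rate=1.0, tract_mean=10, strand_mode="NTS")
        truth = simulate.simulate_clone_mutations(ref, model, 5000, seed=15).truth_table()
        coords = [ref.duplex_coord("NTS", p) for p in ref.c_positions("NTS")]
        mat = CloneMutationMatrix.from_calls(truth, coords, "NTS")
        c = mutation_covariance(mat)
        cd = distance_correlation(c, coords, d_max=20)
        short = cd[cd["d"] <= 5]["C"].mean()
        long = cd[cd["d"] >= 15]["C"].mean()
        assert short > long


class TestExponentialFit:
    @pytest.mark.parametrize("L_true", [15.0, 14.0])
    def test_exact_closure(self, L_true):
        d = np.arange(1, 41)
        cd = pd.DataFrame({"d": d, "C": np.exp(-d / L_true), "n_pairs": 1})
        fit = fit_correlation_length(cd)
        assert fit.L == pytest.approx(L_true, abs=1e-6)
        assert fit.residual < 1e-9

    def test_free_amplitude_variant(self):
        d = np.arange(1, 41)
        cd = pd.DataFrame({"d": d, "C": 0.5 * np.exp(-d / 12.0), "n_pairs": 1})
        fit = fit_correlation_length(cd, free_amplitude=True)
        assert fit.L == pytest.approx(12.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-6)

    def test_all_nonpositive_refused(self):
        cd = pd.DataFrame({"d": [1, 2, 3], "C": [-0.1, 0.0, -0.2], "n_pairs": 1})
        with pytest.raises(ValueError, match="refused"):
            fit_correlation_length(cd)

    def test_monotone_tract_knob(self):
        """Longer engagement tracts never systematically shorten the
        fitted correlation length (rank comparison over seeds)."""
        ref = simulate.generate_reference(seed=7)
        fitted = {}
        for tract in (4.0, 20.0):
            Ls = []
            for seed in (41, 42, 43):
                model = simulate.DeaminationModel(p_hot=0.5, p_other=0.3, p_cold=0.1,
                                                  burst_rate=1.2, tract_mean=tract,
                                                  strand_mode="NTS")
                truth = simulate.simulate_clone_mutations(ref, model, 4000, seed=seed).truth_table()
                coords = [ref.duplex_coord("NTS", p) for p in ref.c_positions("NTS")]
                mat = CloneMutationMatrix.from_calls(truth, coords, "NTS")
                fit, _ = correlation_length_from_matrix(mat)
                Ls.append(fit.L)
            fitted[tract] = np.median(Ls)
        assert fitted[20.0] > fitted[4.0]


class TestPerCloneStatistics:
    def test_all_single_mutation_clones(self):
        m = CloneMutationMatrix(strand="NTS", coords=[1, 2, 3],
                                matrix=np.eye(3, dtype=int))
        assert singly_mutated_fraction(m) == 1.0

    def test_empty_matrix_flagged(self):
        m = CloneMutationMatrix(strand="NTS", coords=[1, 2],
                                matrix=np.zeros((3, 2), dtype=int))
        assert mutations_per_clone(m).empty
        with pytest.raises(ValueError):
            singly_mutated_fraction(m)

    def test_geometric_planted_histogram(self):
        """Per-clone counts planted from a geometric law are recovered
        within multinomial 3-SD."""
        rng = np.random.default_rng(19)
        n = 4000
        p = 0.5
        counts = np.minimum(rng.geometric(p, size=n), 8)
        mat = np.zeros((n, 10), dtype=int)
        for i, k in enumerate(counts):
            mat[i, rng.choice(10, size=k, replace=False)] = 1
        # choice() can repeat a site draw? replace=False ensures exactly k
        cm = CloneMutationMatrix(strand="NTS", coords=np.arange(10) * 3, matrix=mat)
        hist = mutations_per_clone(cm).set_index("n_mutations")
        for k in (1, 2, 3):
            expect = p * (1 - p) ** (k - 1)
            got = hist.loc[k, "fraction"]
            sd = np.sqrt(expect * (1 - expect) / n)
            assert abs(got - expect) <= 3 * sd

    @pytest.mark.parametrize("pair,window,within", [
        ((10, 19), 10, True),    # span of 10 nt fits the window
        ((10, 20), 10, False),   # span of 11 nt does not
    ])
    def test_cluster_window_boundary(self, pair, window, within):
        coords = sorted(set(pair) | {100, 150})
        row = [1 if c in pair else 0 for c in coords]
        m = CloneMutationMatrix(strand="NTS", coords=coords, matrix=[row, row])
        assert (cluster_fraction(m, window=window) == 1.0) == within

    def test_tract_model_exceeds_independent_null(self):
        """Clustering within a 10-nt window under the tract model beats
        the column-permutation null."""
        ref = simulate.generate_reference(seed=7)
        model = simulate.DeaminationModel(p_hot=0.5, p_other=0.3, p_cold=0.1,
                                          burst_rate=1.0, tract_mean=10, strand_mode="NTS")
        truth = simulate.simulate_clone_mutations(ref, model, 4000, seed=23).truth_table()
        coords = [ref.duplex_coord("NTS", p) for p in ref.c_positions("NTS")]
        mat = CloneMutationMatrix.from_calls(truth, coords, "NTS")
        observed = cluster_fraction(mat, window=10)
        rng = np.random.default_rng(24)
        nulls = []
        for _ in range(20):
            shuffled = np.column_stack([rng.permutation(col) for col in mat.matrix.T])
            cm = CloneMutationMatrix(strand="NTS", coords=coords, matrix=shuffled)
            nulls.append(cluster_fraction(cm, window=10))
        assert observed > np.percentile(nulls, 97.5)
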