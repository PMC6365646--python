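import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fitcaller import synthdata
from fitcaller.bcio import CountTable
from fitcaller.errors import DegenerateInputError, InvalidParameterError, PairingError
from fitcaller.fitness import (
    FitnessParams,
    compute_fitness_matrix,
    gene_fitness,
    kde_mode,
    normalize_mode,
    strain_fitness,
    strain_variance,
)

from helpers import brute_force_kde_mode


def table_from_counts(t0, after, extra_t0=None):
    """CountTable with one Time0 (or two) and one experiment."""
    n = len(t0)
    barcodes = []
    for i in range(n):
        digits, x = [], i
        for _ in range(20):
            digits.append("ACGT"[x % 4])
            x //= 4
        barcodes.append("".join(digits))
    cols = {"T0": t0, "expA": after}
    samples = [
        {"sample": "T0", "condition": "Time0", "t0set": "T0A", "is_time0": True},
        {"sample": "expA", "condition": "glc", "t0set": "T0A", "is_time0": False},
    ]
    if extra_t0 is not None:
        cols["T0b"] = extra_t0
        samples.insert(1, {"sample": "T0b", "condition": "Time0", "t0set": "T0A", "is_time0": True})
    return CountTable(counts=pd.DataFrame(cols, index=barcodes), samples=pd.DataFrame(samples))


class TestFitnessParams:
    def test_defaults(self):
        p = FitnessParams()
        assert p.pseudocount == 0.5
        assert p.central_window == (0.1, 0.9)
        assert p.min_t0_reads == 3

    @pytest.mark.parametrize("kwargs", [
        {"pseudocount": 0.0},
        {"central_window": (0.9, 0.1)},
        {"central_window": (-0.1, 0.9)},
        {"mode_grid_step": 0.0},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            FitnessParams(**kwargs)


class TestStrainFitness:
    def test_identity_case_zero(self):
        # 8 of 1,000 reads in both samples: ratio of ratios is 1, f = 0
        table = table_from_counts([8, 992], [8, 992])
        sf = strain_fitness(table, "expA")
        assert sf["fitness"].iloc[0] == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        # n_a=4, n_0=16, equal totals, psi=0.5: f = log2(4.5/16.5)
        table = table_from_counts([16, 984], [4, 996])
        sf = strain_fitness(table, "expA")
        assert sf["fitness"].iloc[0] == pytest.approx(math.log2(4.5 / 16.5))
        assert sf["fitness"].iloc[0] == pytest.approx(-1.874, abs=5e-4)

    def test_scale_invariance_under_doubling(self):
        # the pseudocount perturbs f by ~0.25/(n ln2) per term under count
        # doubling, so the 0.01 bound needs n >~ 80 on both sides
        rng = np.random.default_rng(3)
        t0 = rng.integers(80, 400, size=50).tolist()
        after = rng.integers(80, 400, size=50).tolist()
        f1 = strain_fitness(table_from_counts(t0, after), "expA")["fitness"]
        f2 = strain_fitness(
            table_from_counts([2 * x for x in t0], [2 * x for x in after]), "expA"
        )["fitness"]
        assert (f1 - f2).abs().max() < 0.01

    def test_time0_samples_are_summed(self):
        table = table_from_counts([8, 492], [4, 996], extra_t0=[8, 492])
        sf = strain_fitness(table, "expA")
        assert sf["n_t0"].iloc[0] == 16
        assert sf["fitness"].iloc[0] == pytest.approx(math.log2(4.5 / 1000) - math.log2(16.5 / 1000))

    def test_insufficient_t0_reads_excluded(self):
        table = table_from_counts([2, 998], [50, 950])
        sf = strain_fitness(table, "expA")
        assert not sf["sufficient"].iloc[0]
        assert np.isnan(sf["fitness"].iloc[0])
        assert sf["sufficient"].iloc[1]

    def test_experiment_must_not_be_time0(self, two_sample_table):
        with pytest.raises(PairingError):
            strain_fitness(two_sample_table, "T0")

    def test_zero_total_sample(self):
        table = table_from_counts([10, 10], [0, 0])
        with pytest.raises(DegenerateInputError):
            strain_fitness(table, "expA")

    def test_monotone_in_n_after(self):
        base = strain_fitness(table_from_counts([50, 950], [20, 980]), "expA")
        more = strain_fitness(table_from_counts([50, 950], [25, 975]), "expA")
        assert more["fitness"].iloc[0] > base["fitness"].iloc[0]


def pool_rows(specs):
    """specs: list of (barcode_i, locus_tag, fraction)."""
    rows = []
    for i, (locus, fraction) in enumerate(specs):
        digits, x = [], i
        for _ in range(20):
            digits.append("ACGT"[x % 4])
            x //= 4
        rows.append(
            {"barcode": "".join(digits), "scaffold": "scaffold1", "strand": "+",
             "position": 100 + i, "locus_tag": locus,
             "fraction": fraction if locus else np.nan}
        )
    return pd.DataFrame(rows)


class TestGeneFitness:
    def test_single_central_strain_identity(self):
        table = table_from_counts([16, 984], [4, 996])
        sf = strain_fitness(table, "expA")
        pool = pool_rows([("gX", 0.5), (None, None)])
        gf = gene_fitness(sf, pool)
        assert gf.loc["gX", "fitness_raw"] == pytest.approx(sf["fitness"].iloc[0])
        assert gf.loc["gX", "n_strains"] == 1
        assert np.isnan(gf.loc["gX", "var_emp"])

    def test_equal_counts_give_arithmetic_mean(self):
        table = table_from_counts([20, 20, 960], [10, 10, 980])
        sf = strain_fitness(table, "expA")
        pool = pool_rows([("gX", 0.3), ("gX", 0.6), (None, None)])
        gf = gene_fitness(sf, pool)
        assert gf.loc["gX", "fitness_raw"] == pytest.approx(sf["fitness"].iloc[:2].mean())
        assert gf.loc["gX", "n_strains"] == 2

    def test_peripheral_strain_excluded(self):
        table = table_from_counts([20, 20, 960], [10, 100, 890])
        sf = strain_fitness(table, "expA")
        pool = pool_rows([("gX", 0.05), ("gX", 0.50), (None, None)])
        gf = gene_fitness(sf, pool)
        # only the 0.50 strain contributes
        assert gf.loc["gX", "n_strains"] == 1
        assert gf.loc["gX", "fitness_raw"] == pytest.approx(sf["fitness"].iloc[1])

    def test_window_boundaries_inclusive(self):
        table = table_from_counts([20, 20, 960], [10, 10, 980])
        sf = strain_fitness(table, "expA")
        pool = pool_rows([("gX", 0.1), ("gX", 0.9), (None, None)])
        gf = gene_fitness(sf, pool)
        assert gf.loc["gX", "n_strains"] == 2

    def test_insufficient_and_intergenic_never_contribute(self):
        # mutation test: wildly perturbing excluded strains leaves f_g fixed
        t0 = [20, 20, 2, 50, 900]
        after = [10, 10, 400, 77, 503]
        pool = pool_rows([
            ("gX", 0.5), ("gX", 0.3),   # usable
            ("gX", 0.5),                # insufficient t0 (2 reads)
            (None, None),               # intergenic
            ("gY", 0.95),               # peripheral
        ])
        sf = strain_fitness(table_from_counts(t0, after), "expA")
        gf = gene_fitness(sf, pool)
        # perturb the excluded strains' counts hugely, keep totals fixed by
        # compensating on the intergenic strain
        t0b = [20, 20, 2, 50, 900]
        afterb = [10, 10, 4, 473, 503]
        sfb = strain_fitness(table_from_counts(t0b, afterb), "expA")
        gfb = gene_fitness(sfb, pool)
        assert gf.loc["gX", "fitness_raw"] == pytest.approx(gfb.loc["gX", "fitness_raw"])
        assert "gY" not in gf.index

    def test_weights_are_inverse_variance(self):
        table = table_from_counts([100, 10, 890], [50, 5, 945])
        sf = strain_fitness(table, "expA")
        pool = pool_rows([("gX", 0.4), ("gX", 0.6), (None, None)])
        gf = gene_fitness(sf, pool)
        v = strain_variance(sf["n_after"].to_numpy()[:2], sf["n_t0"].to_numpy()[:2])
        w = 1.0 / v
        expected = (w * sf["fitness"].to_numpy()[:2]).sum() / w.sum()
        assert gf.loc["gX", "fitness_raw"] == pytest.approx(expected)
        assert gf.loc["gX", "var_counts"] == pytest.approx(1.0 / w.sum())


class TestNormalizeMode:
    def test_already_centered_unchanged(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 0.2, size=2000)
        shifted, shift = normalize_mode(v)
        assert abs(shift) <= 0.05  # mode of a centered sample is near 0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 0.3, size=1000)
        _, s1 = normalize_mode(v)
        _, s2 = normalize_mode(v + 0.7)
        assert abs((s2 - s1) - 0.7) <= 0.01 + 1e-9  # within one grid step

    def test_mixture_recovery_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 4000
        planted = rng.random(n) < 0.05
        v = np.where(planted, rng.normal(-3, 0.2, n), rng.normal(0, 0.2, n))
        shifted, shift = normalize_mode(v)
        assert shift == pytest.approx(brute_force_kde_mode(v), abs=0.011)
        assert abs(kde_mode(shifted)) <= 0.02
        assert abs(shifted[planted].mean() + 3) <= 0.15

    def test_too_few_values_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            shifted, shift = normalize_mode([1.0, 2.0, 3.0])
        assert shift == 0.0

    def test_nan_passthrough(self):
        v = np.array([np.nan] + list(np.random.default_rng(8).normal(0, 0.1, 50)))
        shifted, _ = normalize_mode(v)
        assert np.isnan(shifted[0])
        assert np.isfinite(shifted[1:]).all()


@pytest.fixture(scope="module")
def dataset(default_genome, default_pool):
    pool, baseline = default_pool
    tags = default_genome.locus_tags
    effects = {"dxr": [(lt, -2.0) for lt in tags[:10]] + [(tags[12], 2.0)]}
    truth = synthdata.plant_effects(default_genome, effects, baseline=baseline)
    samples = pd.DataFrame(
        [
            {"sample": "T0_1", "condition": "Time0", "t0set": "T0A", "is_time0": True},
            {"sample": "T0_2", "condition": "Time0", "t0set": "T0A", "is_time0": True},
            {"sample": "dxr_1", "condition": "dxr", "t0set": "T0A", "is_time0": False},
            {"sample": "glc_1", "condition": "glc", "t0set": "T0A", "is_time0": False},
        ]
    )
    counts = synthdata.build_count_table(pool, truth, samples, 1_500_000, seed=51)
    fm = compute_fitness_matrix(counts, pool, locus_tags=default_genome.locus_tags)
    return default_genome, pool, truth, fm


class TestComputeFitnessMatrix:

    def test_shape_and_absent_flagging(self, dataset):
        genome, pool, truth, fm = dataset
        assert list(fm.fitness.columns) == ["dxr_1", "glc_1"]
        assert len(fm.fitness) == len(genome.genes)
        uncovered = fm.n_strains["dxr_1"] == 0
        assert fm.fitness.loc[uncovered, "dxr_1"].isna().all()
        covered = fm.n_strains["dxr_1"] > 0
        assert fm.fitness.loc[covered, "dxr_1"].notna().all()

    def test_mode_is_zero_after_normalization(self, dataset):
        *_, fm = dataset
        for exp in fm.fitness.columns:
            v = fm.fitness[exp].dropna().to_numpy()
            assert abs(kde_mode(v)) <= 0.01 + 1e-9  # within one grid step

    def test_planted_effects_recovered(self, dataset):
        genome, pool, truth, fm = dataset
        planted = [lt for (lt, c) in truth.effects if c == "dxr"]
        for lt in planted:
            e = truth.effect(lt, "dxr")
            if fm.n_strains.loc[lt, "dxr_1"] >= 2:
                assert fm.fitness.loc[lt, "dxr_1"] == pytest.approx(e, abs=0.5)
            assert fm.fitness.loc[lt, "glc_1"] == pytest.approx(0.0, abs=0.5)

    def test_median_strain_coverage_in_sanity_band(self, dataset):
        *_, fm = dataset
        n = fm.n_strains["dxr_1"]
        median = n[n > 0].median()
        assert 3 <= median <= 8

    def test_detrimental_gene_positive_fitness(self, dataset):
        genome, pool, truth, fm = dataset
        up = [lt for (lt, c), e in truth.effects.items() if e > 0][0]
        assert fm.fitness.loc[up, "dxr_1"] > 1.0


@given(st.integers(5, 60), st.integers(5, 60), st.integers(3, 60))
@settings(max_examples=30, deadline=None)
def test_strain_fitness_monotonicity_property(n_a, n_a2, n_0):
    if n_a2 <= n_a:
        n_a, n_a2 = n_a2, n_a + 1
    filler = 2000
    f1 = strain_fitness(table_from_counts([n_0, filler], [n_a, filler + (n_a2 - n_a)]), "expA")
    f2 = strain_fitness(table_from_counts([n_0, filler], [n_a2, filler]), "expA")
    assert f2["fitness"].iloc[0] > f1["fitness"].iloc[0]
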