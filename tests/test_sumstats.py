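import numpy as np
import pandas as pd
import pytest

from parapop.genio import MISSING, GenotypeDataset
from parapop.sumstats import (
    amova,
    diversity_table,
    expected_heterozygosity,
    fixation_index,
    geography_regression,
    observed_heterozygosity,
    pairwise_fst,
    private_alleles,
)
from conftest import random_dataset


def _ds(genos, pops, species=None, loci=None):
    genos = np.asarray(genos, dtype=np.int32)
    pops = np.array(pops, dtype=object)
    ids = [f"i{k}" for k in range(len(genos))]
    loci = loci or [f"L{j}" for j in range(genos.shape[1])]
    species = species or {p: "S" for p in set(pops)}
    return GenotypeDataset(genos, ids, loci, pops, species_of_pop=species)


# ---------------------------------------------------------------------------
# heterozygosity and F
# ---------------------------------------------------------------------------

def test_observed_heterozygosity_basics():
    ds = _ds([[[10, 10]], [[12, 12]]], ["p", "p"])
    per_locus, mean, _ = observed_heterozygosity(ds)
    assert per_locus.iloc[0] == 0.0

    ds2 = _ds([[[10, 12]], [[12, 12]]], ["p", "p"])
    per_locus, mean, _ = observed_heterozygosity(ds2)
    assert per_locus.iloc[0] == 0.5


def test_expected_heterozygosity_basics():
    mono = _ds([[[10, 10]], [[10, 10]]], ["p", "p"])
    per_locus, _, _ = expected_heterozygosity(mono)
    assert per_locus.iloc[0] == 0.0

    half = _ds([[[10, 10]], [[12, 12]]], ["p", "p"])
    per_locus, _, _ = expected_heterozygosity(half)
    assert per_locus.iloc[0] == pytest.approx(0.5)


def test_fixation_index():
    f, _, _ = fixation_index(pd.Series([0.3]), pd.Series([0.3]))
    assert f.iloc[0] == pytest.approx(0.0)
    f, _, _ = fixation_index(pd.Series([0.0]), pd.Series([0.4]))
    assert f.iloc[0] == pytest.approx(1.0)
    f, _, _ = fixation_index(pd.Series([0.169]), pd.Series([0.341]))
    assert f.iloc[0] == pytest.approx(1 - 0.169 / 0.341)
    assert f.iloc[0] == pytest.approx(0.5044, abs=5e-5)
    # He = 0 loci are excluded from the mean
    f, mean, _ = fixation_index(pd.Series([0.0, 0.2]), pd.Series([0.0, 0.4]))
    assert np.isnan(f.iloc[0]) and mean == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------

def test_private_alleles_disjoint_and_identical():
    ds = _ds([[[10, 12]], [[14, 14]]], ["a", "b"],
             species={"a": "X", "b": "Y"})
    res = private_alleles(ds, by="species")
    assert res["counts"] == {"X": 2, "Y": 1}

    same = _ds([[[10, 12]], [[10, 12]]], ["a", "b"], species={"a": "X", "b": "Y"})
    res = private_alleles(same, by="species")
    assert res["counts"] == {"X": 0, "Y": 0}


def test_private_alleles_single_group_errors():
    ds = _ds([[[10, 12]]], ["a"], species={"a": "X"})
    with pytest.raises(ValueError, match=">= 2 groups"):
        private_alleles(ds, by="species")


def test_private_allele_population_frequency():
    # species X private allele 10 at frequency 3/4 in pop a
    ds = _ds([[[10, 10]], [[10, 12]], [[12, 12]]], ["a", "a", "b"],
             species={"a": "X", "b": "Y"})
    res = private_alleles(ds, by="species")
    assert res["pop_private_freq"]["a"] == pytest.approx(3 / 4)
    # allele 12 is shared, so pop b carries no species-private copies
    assert res["pop_private_freq"]["b"] == 0.0


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def test_amova_fixed_differences_phi_st_one():
    genos = [[[10, 10]]] * 5 + [[[12, 12]]] * 5
    ds = _ds(genos, ["a"] * 5 + ["b"] * 5)
    res = amova(ds, "pop", n_permutations=99, rng=0)
    assert res.phi["Phi_ST"] == pytest.approx(1.0)
    assert res.p_values["Phi_ST"] < 0.05


def test_amova_identical_populations_phi_near_zero():
    rng = np.random.default_rng(0)
    genos = rng.choice([10, 12, 14], size=(120, 2, 2)).astype(np.int32)
    ds = _ds(genos, ["a"] * 60 + ["b"] * 60)
    res = amova(ds, "pop", n_permutations=99, rng=1)
    assert abs(res.phi["Phi_ST"]) < 0.03
    assert res.p_values["Phi_ST"] > 0.05


def test_amova_three_level_fixed_species_differences():
    # two species fixed for different alleles; pops within species identical
    genos = [[[10, 10]]] * 8 + [[[12, 12]]] * 8
    pops = ["a1"] * 4 + ["a2"] * 4 + ["b1"] * 4 + ["b2"] * 4
    ds = _ds(genos, pops, species={"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"})
    res = amova(ds, "species/pop", n_permutations=0)
    assert res.phi["Phi_CT"] == pytest.approx(1.0)
    assert res.phi["Phi_ST"] == pytest.approx(1.0)
    # variance percentages sum to 100
    assert res.table.loc[res.table.source != "Total", "pct"].sum() == pytest.approx(100)


def test_amova_df_identities(toy_dataset):
    res = amova(toy_dataset, "species/pop", n_permutations=0)
    n_copies = int((toy_dataset.alleles[:, :, 0] != MISSING).sum()) * 2
    df = res.table.set_index("source")["df"]
    assert df["Among species"] == (2 - 1) * toy_dataset.n_loci  # G-1 per locus
    # each locus contributes (G-1) + (P-G) + (M_l - P); totals must match copies
    assert df.sum() - df["Total"] == df["Total"]
    assert df["Total"] == n_copies - toy_dataset.n_loci


def test_amova_ss_total_invariant_under_relabeling(toy_dataset):
    """Permuting individuals among populations leaves SS_total unchanged."""
    res = amova(toy_dataset, "species/pop", n_permutations=0)
    rng = np.random.default_rng(3)
    shuffled = toy_dataset.subset(rng.permutation(toy_dataset.n_individuals))
    res2 = amova(shuffled, "species/pop", n_permutations=0)
    ss = res.table.set_index("source")["SS"]
    ss2 = res2.table.set_index("source")["SS"]
    assert ss["Total"] == pytest.approx(ss2["Total"], rel=1e-12)


# ---------------------------------------------------------------------------
# naive double-loop oracle (spec: <= 10 individuals, agreement to 1e-12)
# ---------------------------------------------------------------------------

def _oracle_ho_he(ds, locus):
    het = n = 0
    copies = []
    for i in range(ds.n_individuals):
        a1, a2 = ds.alleles[i, locus]
        if a1 == MISSING:
            continue
        n += 1
        het += a1 != a2
        copies += [a1, a2]
    ho = het / n
    freqs = {}
    for c in copies:
        freqs[c] = freqs.get(c, 0) + 1
    he = 1 - sum((v / len(copies)) ** 2 for v in freqs.values())
    return ho, he


def _oracle_amova_2level(ds):
    """Direct pairwise-distance AMOVA over allele copies, one locus at a time."""
    sig_a = sig_c = 0.0
    pops = ds.populations
    for l in range(ds.n_loci):
        copies, pop_of_copy = [], []
        for i in range(ds.n_individuals):
            a1, a2 = ds.alleles[i, l]
            if a1 == MISSING:
                continue
            copies += [a1, a2]
            pop_of_copy += [ds.pop_of_individual[i]] * 2
        M = len(copies)
        P = len(set(pop_of_copy))

        def ss_group(sel):
            tot = 0.0
            for x in range(len(sel)):
                for y in range(x + 1, len(sel)):
                    tot += copies[sel[x]] != copies[sel[y]]
            return tot / len(sel)

        ss_tot = ss_group(list(range(M)))
        ss_wp = 0.0
        sizes = []
        for p in pops:
            sel = [k for k in range(M) if pop_of_copy[k] == p]
            if sel:
                ss_wp += ss_group(sel)
                sizes.append(len(sel))
        ss_ap = ss_tot - ss_wp
        sc = ss_wp / (M - P)
        n0 = (M - sum(s**2 for s in sizes) / M) / (P - 1)
        sa = (ss_ap / (P - 1) - sc) / n0
        sig_a += sa
        sig_c += sc
    return sig_a / (sig_a + sig_c)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sumstats_match_naive_oracle(seed):
    ds = random_dataset(seed, n_pops=2, n_per_pop=5, n_loci=3, missing_rate=0.15)
    # restrict allele diversity so distances are informative
    ds.alleles[ds.alleles != MISSING] = 10 + 2 * (ds.alleles[ds.alleles != MISSING] % 4)
    ho, _, _ = observed_heterozygosity(ds)
    he, _, _ = expected_heterozygosity(ds)
    for l in range(ds.n_loci):
        o_ho, o_he = _oracle_ho_he(ds, l)
        assert ho.iloc[l] == pytest.approx(o_ho, abs=1e-12)
        assert he.iloc[l] == pytest.approx(o_he, abs=1e-12)
    res = amova(ds, "pop", n_permutations=0)
    assert res.phi["Phi_ST"] == pytest.approx(_oracle_amova_2level(ds), abs=1e-12)


# ---------------------------------------------------------------------------
# pairwise F_ST
# ---------------------------------------------------------------------------

def test_pairwise_fst_identical_and_fixed():
    rng = np.random.default_rng(1)
    genos = rng.choice([10, 12], size=(100, 2, 2)).astype(np.int32)
    ds = _ds(genos, ["a"] * 50 + ["b"] * 50)
    res = pairwise_fst(ds)
    assert res.matrix.loc["a", "b"] < 0.03
    assert res.matrix.loc["a", "a"] == 0.0

    fixed = _ds([[[10, 10]]] * 4 + [[[12, 12]]] * 4, ["a"] * 4 + ["b"] * 4)
    res = pairwise_fst(fixed)
    assert res.matrix.loc["a", "b"] == pytest.approx(1.0)


def test_pairwise_fst_random_split_centered_near_zero():
    rng = np.random.default_rng(2)
    genos = rng.choice([10, 12, 14, 16], size=(300, 3, 2)).astype(np.int32)
    labels = np.array(["a"] * 150 + ["b"] * 150, dtype=object)
    ds = _ds(genos, labels)
    res = pairwise_fst(ds)
    assert res.matrix.loc["a", "b"] < 0.02


def test_pairwise_fst_small_population_skipped(toy_dataset):
    ds = toy_dataset.subset(np.arange(6))  # B1 keeps a single individual
    with pytest.warns(UserWarning, match="skipped"):
        res = pairwise_fst(ds)
    assert "B1" not in res.matrix.index


def test_pairwise_fst_between_species_test(mini_study):
    ds, _ = mini_study
    res = pairwise_fst(ds)
    assert set(res.within_species_mean) == set(ds.species)
    assert res.between_species_test is not None
    assert 0 <= res.between_species_test["p"] <= 1


# ---------------------------------------------------------------------------
# geography regressions
# ---------------------------------------------------------------------------

def _geo(n, alt):
    return pd.DataFrame({"latitude": np.linspace(22, 25, n),
                         "longitude": np.linspace(120, 122, n),
                         "altitude": alt}, index=[f"p{i}" for i in range(n)])


def test_regression_perfect_line():
    alt = np.array([100.0, 200, 300, 400, 500])
    y = pd.Series(2.0 * alt, index=[f"p{i}" for i in range(5)])
    res = geography_regression(y, _geo(5, alt), predictors=("altitude",))
    assert res.loc["altitude", "slope"] == pytest.approx(2.0)
    assert res.loc["altitude", "p"] == pytest.approx(0.0, abs=1e-12)


def test_regression_constant_response():
    alt = np.array([100.0, 200, 300, 400, 500])
    y = pd.Series(np.ones(5), index=[f"p{i}" for i in range(5)])
    res = geography_regression(y, _geo(5, alt), predictors=("altitude",))
    assert res.loc["altitude", "slope"] == 0.0
    assert res.loc["altitude", "t"] == 0.0


def test_regression_matches_closed_form_ols():
    x = np.array([1.0, 2, 3, 4, 5])
    y_vals = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
    y = pd.Series(y_vals, index=[f"p{i}" for i in range(5)])
    res = geography_regression(y, _geo(5, x), predictors=("altitude",))
    # closed-form OLS oracle
    b = ((x - x.mean()) * (y_vals - y_vals.mean())).sum() / ((x - x.mean()) ** 2).sum()
    a = y_vals.mean() - b * x.mean()
    resid = y_vals - (a + b * x)
    se = np.sqrt(resid @ resid / 3 / ((x - x.mean()) ** 2).sum())
    from scipy.stats import t as t_dist

    t_stat = b / se
    p = 2 * t_dist.sf(abs(t_stat), 3)
    assert res.loc["altitude", "slope"] == pytest.approx(b, abs=1e-10)
    assert res.loc["altitude", "t"] == pytest.approx(t_stat, abs=1e-10)
    assert res.loc["altitude", "p"] == pytest.approx(p, abs=1e-10)


def test_regression_zero_variance_predictor_errors():
    y = pd.Series(np.arange(4.0), index=[f"p{i}" for i in range(4)])
    geo = _geo(4, np.full(4, 1000.0))
    with pytest.raises(ValueError, match="zero variance"):
        geography_regression(y, geo, predictors=("altitude",))


# ---------------------------------------------------------------------------
# diversity table
# ---------------------------------------------------------------------------

def test_diversity_table_shapes_and_invariants(mini_study):
    ds, _ = mini_study
    div = diversity_table(ds)
    s = div.summary
    assert set(s.index) == set(ds.species)
    assert ((s["Ho_mean"] >= 0) & (s["Ho_mean"] <= 1)).all()
    assert ((s["He_mean"] >= 0) & (s["He_mean"] < 1)).all()
    # F consistent with Ho/He per locus where defined
    per = div.per_locus.dropna(subset=["F"])
    ok = per["He"] > 0
    assert np.allclose(per.loc[ok, "F"], 1 - per.loc[ok, "Ho"] / per.loc[ok, "He"])
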