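"""Diversity and differentiation statistics for codominant SSR data.

Conventions follow the common desktop toolchain for microsatellite studies:
expected heterozygosity is the uncorrected 1 - sum(p^2) (not Nei's unbiased
form); AMOVA uses allele-identity distances between allele copies
(F_ST-type), with variance components computed per locus from allele-count
tables and summed over loci; negative variance components and negative
pairwise F_ST estimates are truncated at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genio import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-locus helpers
# ---------------------------------------------------------------------------

def _scope_indices(dataset: GenotypeDataset, scope) -> np.ndarray:
    """Resolve a scope (None, species label, boolean mask, or index array)."""
    if scope is None:
        return np.arange(dataset.n_individuals)
    if isinstance(scope, str):
        mask = dataset.mask_for_species(scope)
        if not mask.any():
            raise ValueError(f"no individuals in species {scope!r}")
        return np.flatnonzero(mask)
    arr = np.asarray(scope)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return arr


def _polymorphic_loci(dataset: GenotypeDataset) -> np.ndarray:
    """Loci with >= 2 distinct alleles anywhere in the dataset."""
    out = []
    for l in range(dataset.n_loci):
        vals = dataset.alleles[:, l, :]
        vals = np.unique(vals[vals != MISSING])
        out.append(len(vals) >= 2)
    return np.array(out, dtype=bool)


def allele_frequencies(dataset: GenotypeDataset, locus: int, scope=None) -> pd.Series:
    """Allele relative frequencies at one locus, pooled over the scope."""
    idx = _scope_indices(dataset, scope)
    vals = dataset.alleles[idx, locus, :].ravel()
    vals = vals[vals != MISSING]
    if vals.size == 0:
        return pd.Series(dtype=float)
    uniq, counts = np.unique(vals, return_counts=True)
    return pd.Series(counts / counts.sum(), index=uniq)


def observed_heterozygosity(dataset: GenotypeDataset, scope=None, loci=None):
    """Per-locus observed heterozygosity and its mean +/- SE over loci.

    Ho at a locus is the fraction of heterozygous individuals among those
    with a non-missing genotype.  Loci with no data in scope are excluded
    from the mean (and logged).  Returns ``(per_locus, mean, se)``.
    """
    idx = _scope_indices(dataset, scope)
    a = dataset.alleles[idx]
    present = a[:, :, 0] != MISSING
    het = (a[:, :, 0] != a[:, :, 1]) & present
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n > 0, het.sum(axis=0) / np.maximum(n, 1), np.nan)
    per_locus = pd.Series(ho, index=dataset.locus_names, name="Ho")
    return per_locus, *_mean_se(per_locus, dataset, loci)


def expected_heterozygosity(dataset: GenotypeDataset, scope=None, loci=None):
    """Per-locus expected heterozygosity He = 1 - sum(p_i^2) and mean +/- SE.

    Allele frequencies are pooled over the whole scope (the uncorrected
    GenAlEx-style estimator).
    """
    idx = _scope_indices(dataset, scope)
    he = np.empty(dataset.n_loci)
    for l in range(dataset.n_loci):
        p = allele_frequencies(dataset, l, idx)
        he[l] = np.nan if p.empty else 1.0 - float((p.values**2).sum())
    per_locus = pd.Series(he, index=dataset.locus_names, name="He")
    return per_locus, *_mean_se(per_locus, dataset, loci)


def _mean_se(per_locus: pd.Series, dataset: GenotypeDataset, loci=None):
    if loci is None:
        keep = _polymorphic_loci(dataset)
    else:
        keep = np.asarray(loci)
        if keep.dtype != bool:
            m = np.zeros(dataset.n_loci, dtype=bool)
            m[keep] = True
            keep = m
    vals = per_locus.values[keep]
    good = ~np.isnan(vals)
    if not good.all():
        logger.warning("%d loci with no data excluded from the mean", (~good).sum())
    vals = vals[good]
    if vals.size == 0:
        return np.nan, np.nan
    se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return float(vals.mean()), float(se)


def fixation_index(ho: pd.Series, he: pd.Series):
    """Per-locus fixation index F = 1 - Ho/He and its mean +/- SE.

    Loci with He = 0 (or missing) are undefined and excluded from the mean.
    """
    ho_v, he_v = np.asarray(ho, float), np.asarray(he, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(he_v > 0, 1.0 - ho_v / he_v, np.nan)
    per_locus = pd.Series(f, index=ho.index if hasattr(ho, "index") else None, name="F")
    vals = per_locus.values[~np.isnan(per_locus.values)]
    if vals.size == 0:
        return per_locus, np.nan, np.nan
    se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return per_locus, float(vals.mean()), float(se)


# ---------------------------------------------------------------------------
# diversity table and private alleles
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-species diversity summary (per-locus values plus means over loci)."""

    per_locus: pd.DataFrame  # columns: species, locus, Ho, He, F, n_alleles
    summary: pd.DataFrame  # index species; columns incl. Ho_mean, He_mean, ...


def diversity_table(dataset: GenotypeDataset) -> DiversityTable:
    if not dataset.species_of_pop:
        raise ValueError("dataset has no species assignments (attach metadata first)")
    rows = []
    summaries = []
    priv = private_alleles(dataset, by="species")
    for sp in dataset.species:
        idx = _scope_indices(dataset, sp)
        ho, ho_m, ho_se = observed_heterozygosity(dataset, sp)
        he, he_m, he_se = expected_heterozygosity(dataset, sp)
        f, f_m, f_se = fixation_index(ho, he)
        n_alleles = []
        for l in range(dataset.n_loci):
            vals = dataset.alleles[idx, l, :]
            n_alleles.append(len(np.unique(vals[vals != MISSING])))
        for l, name in enumerate(dataset.locus_names):
            rows.append(
                dict(species=sp, locus=name, Ho=ho.iloc[l], He=he.iloc[l],
                     F=f.iloc[l], n_alleles=n_alleles[l])
            )
        summaries.append(
            dict(species=sp, sample_size=len(idx), n_alleles=int(np.sum(n_alleles)),
                 private_alleles=priv["counts"][sp],
                 Ho_mean=ho_m, Ho_se=ho_se, He_mean=he_m, He_se=he_se,
                 F_mean=f_m, F_se=f_se)
        )
    return DiversityTable(
        per_locus=pd.DataFrame(rows),
        summary=pd.DataFrame(summaries).set_index("species"),
    )


def private_alleles(dataset: GenotypeDataset, by: str = "species",
                    freq_definition: str = "copy_frequency") -> dict:
    """Private-allele accounting.

    An allele is private to a group if it is observed in that group and in no
    other.  Returns a dict with:

    ``counts``
        total number of private alleles per group (summed over loci);
    ``alleles``
        per group, per locus, the sorted private allele values;
    ``pop_private_freq``
        per population, the frequency of alleles private to the population's
        group.  With ``freq_definition="copy_frequency"`` (default) this is
        the summed within-population relative frequency of private-allele
        copies; ``"allele_count_fraction"`` instead divides the number of
        distinct private alleles seen in the population by its total number
        of distinct alleles.
    """
    if by == "species":
        if not dataset.species_of_pop:
            raise ValueError("species grouping requires species assignments")
        group_of_ind = dataset.species_of_individual()
    elif by == "population":
        group_of_ind = dataset.pop_of_individual
    else:
        raise ValueError(f"unknown grouping {by!r}")
    groups = list(dict.fromkeys(group_of_ind))
    if len(groups) < 2:
        raise ValueError("private alleles need >= 2 groups")

    counts = {g: 0 for g in groups}
    alleles: dict[str, dict[str, list[int]]] = {g: {} for g in groups}
    private_sets: list[dict[str, set]] = []
    for l, name in enumerate(dataset.locus_names):
        seen = {}
        for g in groups:
            vals = dataset.alleles[group_of_ind == g, l, :]
            seen[g] = set(vals[vals != MISSING].tolist())
        priv_l = {}
        for g in groups:
            others = set().union(*(seen[h] for h in groups if h != g))
            priv = seen[g] - others
            priv_l[g] = priv
            if priv:
                counts[g] += len(priv)
                alleles[g][name] = sorted(priv)
        private_sets.append(priv_l)

    pop_freq = {}
    for pop in dataset.populations:
        g = (dataset.species_of_pop.get(pop) if by == "species" else pop)
        idx = dataset.individuals_of_pop(pop)
        priv_copies = 0
        total_copies = 0
        priv_distinct: set = set()
        all_distinct: set = set()
        for l in range(dataset.n_loci):
            vals = dataset.alleles[idx, l, :]
            vals = vals[vals != MISSING]
            total_copies += vals.size
            priv = private_sets[l].get(g, set())
            priv_copies += int(np.isin(vals, sorted(priv)).sum()) if priv else 0
            all_distinct.update((l, v) for v in np.unique(vals).tolist())
            priv_distinct.update((l, v) for v in np.unique(vals).tolist() if v in priv)
        if freq_definition == "copy_frequency":
            pop_freq[pop] = priv_copies / total_copies if total_copies else np.nan
        elif freq_definition == "allele_count_fraction":
            pop_freq[pop] = len(priv_distinct) / len(all_distinct) if all_distinct else np.nan
        else:
            raise ValueError(f"unknown freq_definition {freq_definition!r}")
    return {"counts": counts, "alleles": alleles,
            "pop_private_freq": pd.Series(pop_freq, name="private_freq")}


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """AMOVA table, Phi statistics and permutation p-values."""

    table: pd.DataFrame  # rows: sources of variation; df, SS, variance, pct
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


def _copy_arrays(dataset: GenotypeDataset, idx: np.ndarray):
    """Per locus: (owner individual positions, compact allele indices, n_alleles)."""
    out = []
    for l in range(dataset.n_loci):
        vals = dataset.alleles[idx, l, :]  # (n, 2)
        flat = vals.ravel()
        owner = np.repeat(np.arange(len(idx)), 2)
        keep = flat != MISSING
        flat, owner = flat[keep], owner[keep]
        uniq, inv = np.unique(flat, return_inverse=True)
        out.append((owner, inv.astype(np.int64), len(uniq)))
    return out


def _pairs(x):
    return x * (x - 1) / 2.0


def _ss_from_counts(counts: np.ndarray):
    """SS within each row-group from an allele-count table (rows = groups)."""
    m = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(m > 0, (_pairs(m) - _pairs(counts).sum(axis=1)) / np.maximum(m, 1), 0.0)
    return ss, m


def _components_2level(copydata, pop_code: np.ndarray, n_pops: int):
    """Summed-over-loci variance components for a populations/individuals design."""
    sig_a = sig_c = 0.0
    ss_ap = ss_wp = 0.0
    df_ap = df_wp = 0
    for owner, allele, n_all in copydata:
        if n_all == 0:
            continue
        pc = pop_code[owner]
        counts = np.zeros((n_pops, n_all))
        np.add.at(counts, (pc, allele), 1.0)
        ss_p, m_p = _ss_from_counts(counts)
        tot_counts = counts.sum(axis=0, keepdims=True)
        ss_t, m_t = _ss_from_counts(tot_counts)
        present = m_p > 0
        P = int(present.sum())
        M = float(m_t[0])
        if P < 2 or M <= P:
            continue
        l_ss_wp = float(ss_p.sum())
        l_ss_ap = float(ss_t[0] - l_ss_wp)
        l_df_wp = M - P
        l_df_ap = P - 1
        sc = l_ss_wp / l_df_wp
        n0 = (M - float((m_p**2).sum()) / M) / l_df_ap
        sa = (l_ss_ap / l_df_ap - sc) / n0
        sig_c += sc
        sig_a += sa
        ss_wp += l_ss_wp
        ss_ap += l_ss_ap
        df_wp += l_df_wp
        df_ap += l_df_ap
    return sig_a, sig_c, ss_ap, ss_wp, df_ap, df_wp


def _components_3level(copydata, pop_code: np.ndarray, n_pops: int,
                       sp_of_pop: np.ndarray, n_sp: int):
    """Summed-over-loci components for a species/populations/individuals design."""
    tables = []
    for owner, allele, n_all in copydata:
        if n_all == 0:
            continue
        pc = pop_code[owner]
        counts = np.zeros((n_pops, n_all))
        np.add.at(counts, (pc, allele), 1.0)
        tables.append(counts)
    return _components_3level_tables(tables, sp_of_pop, n_sp)


def _components_3level_tables(tables, sp_of_pop: np.ndarray, n_sp: int):
    """3-level components from per-locus population allele-count tables."""
    sig_a = sig_b = sig_c = 0.0
    ss = np.zeros(3)  # among-species, among-pop-within, within-pop
    df = np.zeros(3)
    for counts in tables:
        ss_p, m_p = _ss_from_counts(counts)
        sp_counts = np.zeros((n_sp, counts.shape[1]))
        for s in range(n_sp):
            sp_counts[s] = counts[sp_of_pop == s].sum(axis=0)
        ss_g, m_g = _ss_from_counts(sp_counts)
        tot = counts.sum(axis=0, keepdims=True)
        ss_t, m_t = _ss_from_counts(tot)

        present_p = m_p > 0
        present_g = m_g > 0
        P = int(present_p.sum())
        G = int(present_g.sum())
        M = float(m_t[0])
        if G < 2 or P <= G or M <= P:
            continue
        l_ss_wp = float(ss_p.sum())
        l_ss_wg = float(ss_g.sum())
        l_ss_ap = l_ss_wg - l_ss_wp
        l_ss_ag = float(ss_t[0]) - l_ss_wg
        l_df = np.array([G - 1.0, P - G, M - P])

        # unequal-size coefficients of the nested random-effects model
        A = float(sum((m_p[sp_of_pop == s] ** 2).sum() / m_g[s]
                      for s in range(n_sp) if m_g[s] > 0))
        B = float((m_p**2).sum() / M)
        Cg = float((m_g**2).sum() / M)
        n_c = (M - A) / (P - G)
        n_p = (A - B) / (G - 1)
        n_pp = (M - Cg) / (G - 1)

        sc = l_ss_wp / l_df[2]
        sb = (l_ss_ap / l_df[1] - sc) / n_c
        sa = (l_ss_ag / l_df[0] - sc - n_p * sb) / n_pp
        sig_a += sa
        sig_b += sb
        sig_c += sc
        ss += [l_ss_ag, l_ss_ap, l_ss_wp]
        df += l_df
    return sig_a, sig_b, sig_c, ss, df


def amova(dataset: GenotypeDataset, hierarchy: str = "species/pop",
          n_permutations: int = 9999, rng=None) -> AmovaResult:
    """AMOVA on allele-identity distances between allele copies.

    ``hierarchy="species/pop"`` fits the 3-level species/populations/
    individuals design and reports Phi_CT (among species), Phi_SC (among
    populations within species) and Phi_ST (among populations overall);
    ``hierarchy="pop"`` fits the 2-level design (Phi_ST only).

    Permutation scheme: Phi_ST permutes individuals among populations;
    Phi_SC permutes individuals among populations within species; Phi_CT
    permutes whole populations among species.  p = (#{perm >= obs}+1)/(N+1).
    """
    rng = np.random.default_rng(rng)
    idx = np.arange(dataset.n_individuals)
    pops = dataset.populations
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_code = np.array([pop_index[p] for p in dataset.pop_of_individual])
    copydata = _copy_arrays(dataset, idx)

    if hierarchy == "pop":
        sig_a, sig_c, ss_ap, ss_wp, df_ap, df_wp = _components_2level(
            copydata, pop_code, len(pops))
        tot = sig_a + sig_c
        phi_st = sig_a / tot if tot > 0 else np.nan
        phi = {"Phi_ST": phi_st}
        obs = {"Phi_ST": phi_st}
        perm_ge = {"Phi_ST": 0}
        for _ in range(n_permutations):
            perm = rng.permutation(pop_code)
            a, c, *_ = _components_2level(copydata, perm, len(pops))
            if (a / (a + c) if (a + c) > 0 else np.nan) >= obs["Phi_ST"]:
                perm_ge["Phi_ST"] += 1
        pvals = {k: (v + 1) / (n_permutations + 1) for k, v in perm_ge.items()} \
            if n_permutations else {}
        table = pd.DataFrame(
            [
                ("Among populations", df_ap, ss_ap, sig_a, 100 * sig_a / tot if tot else np.nan),
                ("Within populations", df_wp, ss_wp, sig_c, 100 * sig_c / tot if tot else np.nan),
                ("Total", df_ap + df_wp, ss_ap + ss_wp, tot, 100.0),
            ],
            columns=["source", "df", "SS", "variance", "pct"],
        )
        return AmovaResult(table, phi, pvals, n_permutations)

    if hierarchy != "species/pop":
        raise ValueError(f"unknown hierarchy {hierarchy!r}")
    if not dataset.species_of_pop:
        raise ValueError("3-level AMOVA requires species assignments")
    species = dataset.species
    if len(species) < 2:
        raise ValueError("3-level AMOVA requires >= 2 species")
    sp_index = {s: i for i, s in enumerate(species)}
    sp_of_pop = np.array([sp_index[dataset.species_of_pop[p]] for p in pops])

    sig_a, sig_b, sig_c, ss, df = _components_3level(
        copydata, pop_code, len(pops), sp_of_pop, len(species))
    sig_a_t = max(sig_a, 0.0)
    sig_b_t = max(sig_b, 0.0)
    if sig_a < 0 or sig_b < 0:
        logger.info("negative variance component truncated to 0")
    tot = sig_a_t + sig_b_t + sig_c
    phi = {
        "Phi_CT": sig_a_t / tot if tot > 0 else np.nan,
        "Phi_SC": sig_b_t / (sig_b_t + sig_c) if (sig_b_t + sig_c) > 0 else np.nan,
        "Phi_ST": (sig_a_t + sig_b_t) / tot if tot > 0 else np.nan,
    }

    pvals: dict[str, float] = {}
    if n_permutations:
        ge = {"Phi_CT": 0, "Phi_SC": 0, "Phi_ST": 0}
        sp_of_ind = sp_of_pop[pop_code]
        for _ in range(n_permutations):
            # Phi_ST: individuals among all populations
            perm_st = rng.permutation(pop_code)
            a, b, c, *_ = _components_3level(copydata, perm_st, len(pops),
                                             sp_of_pop, len(species))
            t = max(a, 0) + max(b, 0) + c
            if t > 0 and (max(a, 0) + max(b, 0)) / t >= phi["Phi_ST"]:
                ge["Phi_ST"] += 1
            # Phi_SC: individuals among populations within species
            perm_sc = pop_code.copy()
            for s in range(len(species)):
                sel = np.flatnonzero(sp_of_ind == s)
                perm_sc[sel] = perm_sc[rng.permutation(sel)]
            a, b, c, *_ = _components_3level(copydata, perm_sc, len(pops),
                                             sp_of_pop, len(species))
            if (max(b, 0) + c) > 0 and max(b, 0) / (max(b, 0) + c) >= phi["Phi_SC"]:
                ge["Phi_SC"] += 1
            # Phi_CT: whole populations among species
            perm_ct = rng.permutation(sp_of_pop)
            a, b, c, *_ = _components_3level(copydata, pop_code, len(pops),
                                             perm_ct, len(species))
            t = max(a, 0) + max(b, 0) + c
            if t > 0 and max(a, 0) / t >= phi["Phi_CT"]:
                ge["Phi_CT"] += 1
        pvals = {k: (v + 1) / (n_permutations + 1) for k, v in ge.items()}

    tot_ss = ss.sum()
    table = pd.DataFrame(
        [
            ("Among species", df[0], ss[0], sig_a_t, 100 * sig_a_t / tot if tot else np.nan),
            ("Among populations within species", df[1], ss[1], sig_b_t,
             100 * sig_b_t / tot if tot else np.nan),
            ("Within populations", df[2], ss[2], sig_c, 100 * sig_c / tot if tot else np.nan),
            ("Total", df.sum(), tot_ss, tot, 100.0),
        ],
        columns=["source", "df", "SS", "variance", "pct"],
    )
    return AmovaResult(table, phi, pvals, n_permutations)


# ---------------------------------------------------------------------------
# pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Pairwise population F_ST with within-species means."""

    matrix: pd.DataFrame
    within_species_mean: dict[str, float]
    between_species_test: dict | None = None  # U, p for the two within-species sets


def _pop_count_tables(dataset: GenotypeDataset):
    """Per locus, allele-count table (n_pops x n_alleles) over all populations."""
    pops = dataset.populations
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_code = np.array([pop_index[p] for p in dataset.pop_of_individual])
    tables = []
    for l in range(dataset.n_loci):
        vals = dataset.alleles[:, l, :]
        flat = vals.ravel()
        owner = np.repeat(pop_code, 2)
        keep = flat != MISSING
        flat, owner = flat[keep], owner[keep]
        uniq, inv = np.unique(flat, return_inverse=True)
        counts = np.zeros((len(pops), len(uniq)))
        np.add.at(counts, (owner, inv), 1.0)
        tables.append(counts)
    return pops, tables


def _fst_from_tables(tables, i: int, j: int) -> float:
    """2-level AMOVA F_ST between populations i and j from count tables."""
    sig_a = sig_c = 0.0
    for counts in tables:
        pair = counts[[i, j]]
        m = pair.sum(axis=1)
        if (m > 0).sum() < 2:
            continue
        ss_p, m_p = _ss_from_counts(pair)
        ss_t, m_t = _ss_from_counts(pair.sum(axis=0, keepdims=True))
        M = float(m_t[0])
        P = 2
        if M <= P:
            continue
        ss_wp = float(ss_p.sum())
        ss_ap = float(ss_t[0]) - ss_wp
        sc = ss_wp / (M - P)
        n0 = (M - float((m_p**2).sum()) / M)
        sa = (ss_ap - sc) / n0
        sig_a += sa
        sig_c += sc
    if sig_a <= 0:
        return 0.0
    tot = sig_a + sig_c
    return sig_a / tot if tot > 0 else 0.0


def pairwise_fst(dataset: GenotypeDataset, min_pop_size: int = 2) -> FstMatrix:
    """Pairwise F_ST among all populations (AMOVA allele-identity distances).

    Negative estimates are truncated at 0.  Populations with fewer than
    *min_pop_size* individuals are skipped with a warning.  When species
    assignments are present, within-species means and a Mann-Whitney U
    comparison of the two within-species sets of pairwise values are
    reported.
    """
    pops, tables = _pop_count_tables(dataset)
    sizes = {p: len(dataset.individuals_of_pop(p)) for p in pops}
    usable = [p for p in pops if sizes[p] >= min_pop_size]
    skipped = [p for p in pops if p not in usable]
    if skipped:
        warnings.warn(f"populations skipped (n < {min_pop_size}): {skipped}")
    if len(usable) < 2:
        raise ValueError("pairwise F_ST needs >= 2 usable populations")
    mat = pd.DataFrame(0.0, index=usable, columns=usable)
    pop_pos = {p: i for i, p in enumerate(pops)}
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            f = _fst_from_tables(tables, pop_pos[usable[a]], pop_pos[usable[b]])
            f = min(max(f, 0.0), 1.0)
            mat.iloc[a, b] = mat.iloc[b, a] = f

    within_means: dict[str, float] = {}
    test = None
    if dataset.species_of_pop:
        values_by_sp: dict[str, list[float]] = {}
        for a in range(len(usable)):
            for b in range(a + 1, len(usable)):
                sa = dataset.species_of_pop.get(usable[a])
                sb = dataset.species_of_pop.get(usable[b])
                if sa == sb and sa is not None:
                    values_by_sp.setdefault(sa, []).append(mat.iloc[a, b])
        within_means = {s: float(np.mean(v)) for s, v in values_by_sp.items()}
        if len(values_by_sp) == 2:
            from .demography import mann_whitney_u

            (s1, v1), (s2, v2) = values_by_sp.items()
            u, p = mann_whitney_u(v1, v2)
            test = {"species": (s1, s2), "U": u, "p": p}
    return FstMatrix(mat, within_means, test)


# ---------------------------------------------------------------------------
# geography regressions
# ---------------------------------------------------------------------------

def geography_regression(y: pd.Series, geography: pd.DataFrame,
                         predictors=("altitude", "longitude", "latitude")) -> pd.DataFrame:
    """OLS of a per-population response on one geographic predictor at a time.

    Returns one row per predictor with slope, intercept, t statistic of the
    slope, two-sided p-value, and n.  Requires >= 3 populations; a
    zero-variance predictor raises ``ValueError``.
    """
    joined = pd.concat([y.rename("y"), geography], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("geography regression needs >= 3 populations")
    rows = []
    for pred in predictors:
        x = joined[pred].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {pred!r} has zero variance")
        yv = joined["y"].to_numpy(float)
        X = sm.add_constant(x)
        fit = sm.OLS(yv, X).fit()
        slope, t, p = fit.params[1], fit.tvalues[1], fit.pvalues[1]
        if fit.ssr <= 1e-12 * max(1.0, float((yv**2).sum())):
            # exact fit: t undefined from a zero residual variance
            if abs(slope) < 1e-12:
                slope, t, p = 0.0, 0.0, 1.0
            else:
                t, p = np.inf, 0.0
        rows.append(
            dict(predictor=pred, slope=slope, intercept=fit.params[0],
                 t=t, p=p, n=int(fit.nobs))
        )
    return pd.DataFrame(rows).set_index("predictor")
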