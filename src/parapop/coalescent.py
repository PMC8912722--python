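"""Two-deme structured coalescent with stepwise microsatellite mutation.

Simulates gene genealogies for two species under four divergence scenarios
that differ only in when interspecific gene flow is active:

``SI``  strict isolation — no gene flow after divergence;
``AM``  ancient migration — gene flow only in the early window (t2, t1);
``SC``  secondary contact — gene flow only in the recent window (0, t2);
``CM``  continuous migration — gene flow throughout (0, t1).

Time runs backward in generations.  Epochs: (0, t2) with recent sizes,
(t2, t1) with early sizes, (t1, inf) a single ancestral deme.  Migration
rates are backward lineage-movement rates matching the forward direction of
gene flow: ``m1`` is forward flow from species A (cau) into species B (mor),
so backward a lineage sampled in B jumps to A at rate m1.  Mutations are
dropped on branches as a Poisson process of rate ``mu`` per lineage per
generation; each mutation steps the repeat count by +/-1 with equal
probability (strict stepwise model).  Final allele states below the floor
are reflected at it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .genio import MISSING, GenotypeDataset

MODELS = ("SI", "AM", "SC", "CM")

#: migration activity per model in epoch 0 (recent, (0,t2)) and epoch 1 ((t2,t1))
_MIG_WINDOWS = {"SI": (False, False), "AM": (False, True),
                "SC": (True, False), "CM": (True, True)}


@dataclass
class ScenarioSpec:
    """One divergence scenario plus its demographic parameters.

    Sizes are diploid effective sizes (individuals); times are generations
    before present; ``m1``/``m2`` are per-generation migration rates (forward
    A->B and B->A respectively); ``mu`` is the per-locus per-generation
    stepwise mutation rate.  Sample sizes ``n_cau``/``n_mor`` are diploid
    individuals per deme.
    """

    model: str
    ne_anc: float
    ne_cau_t1: float
    ne_mor_t1: float
    ne_cau_t2: float
    ne_mor_t2: float
    m1: float
    m2: float
    t1: float
    t2: float
    mu: float = 5e-4
    n_loci: int = 17
    n_cau: int = 20
    n_mor: int = 20
    ancestral_state: int = 20
    state_floor: int = 2
    deme_names: tuple = ("cau", "mor")

    PARAM_NAMES = ("ne_anc", "ne_cau_t1", "ne_mor_t1", "ne_cau_t2", "ne_mor_t2",
                   "m1", "m2", "t1", "t2")

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        for nm in ("ne_anc", "ne_cau_t1", "ne_mor_t1", "ne_cau_t2", "ne_mor_t2"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if not (0 <= self.t2 <= self.t1):
            raise ValueError("need 0 <= t2 <= t1")
        for nm in ("m1", "m2"):
            if not (0 <= getattr(self, nm) < 1):
                raise ValueError(f"{nm} must be in [0, 1)")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    def params(self) -> dict[str, float]:
        return {nm: float(getattr(self, nm)) for nm in self.PARAM_NAMES}

    def with_params(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


@dataclass
class SimulatedSample:
    """Haploid allele states for one simulated dataset.

    ``states`` has shape (n_lineages, n_loci); ``deme`` gives the sampling
    deme (0 = first species) of each lineage; ``tree_heights`` records the
    per-locus time to the most recent common ancestor (diagnostics).
    """

    states: np.ndarray
    deme: np.ndarray
    tree_heights: np.ndarray
    deme_names: tuple = ("cau", "mor")
    locus_names: list = field(default_factory=list)

    def to_genotype_dataset(self) -> GenotypeDataset:
        """Pair haploid lineages sequentially into diploid individuals per deme."""
        loci = self.locus_names or [f"L{j + 1}" for j in range(self.states.shape[1])]
        rows, ids, pops = [], [], []
        for d, name in enumerate(self.deme_names):
            sel = np.flatnonzero(self.deme == d)
            if len(sel) % 2:
                raise ValueError("odd haploid sample size in deme " + name)
            for k in range(0, len(sel), 2):
                rows.append(np.stack([self.states[sel[k]], self.states[sel[k + 1]]], axis=-1))
                ids.append(f"{name}_{k // 2 + 1}")
                pops.append(name)
        ds = GenotypeDataset(
            np.array(rows, dtype=np.int32), ids, loci, np.array(pops, dtype=object),
            species_of_pop={name: name for name in self.deme_names},
        )
        return ds


@njit(cache=True)
def _sim_locus_core(seed, n0, n1, ne0_e0, ne1_e0, ne0_e1, ne1_e1, ne_anc,
                    m_back0, m_back1, mig_e0, mig_e1, t1, t2, mu,
                    ancestral, floor):
    """Gillespie realization of one locus; returns (tip states, tmrca).

    m_back0/m_back1: backward jump rates for lineages currently in deme 0/1.
    """
    np.random.seed(seed)
    n = n0 + n1
    deme = np.empty(n, np.int64)
    for i in range(n):
        deme[i] = 0 if i < n0 else 1
    alive = np.ones(n, np.bool_)
    lin_of_tip = np.arange(n)
    offset = np.zeros(n, np.int64)
    k = n
    t = 0.0
    epoch = 0
    while k > 1:
        if epoch == 0:
            ne_a, ne_b = ne0_e0, ne1_e0
            mig = mig_e0
            t_end = t2
        elif epoch == 1:
            ne_a, ne_b = ne0_e1, ne1_e1
            mig = mig_e1
            t_end = t1
        else:
            ne_a, ne_b = ne_anc, ne_anc
            mig = False
            t_end = 1e300

        k0 = 0
        for i in range(n):
            if alive[i] and deme[i] == 0:
                k0 += 1
        k1 = k - k0
        rate_c0 = k0 * (k0 - 1) / 2.0 / (2.0 * ne_a)
        rate_c1 = k1 * (k1 - 1) / 2.0 / (2.0 * ne_b)
        rate_m = (k0 * m_back0 + k1 * m_back1) if mig else 0.0
        rate_mut = mu * k
        total = rate_c0 + rate_c1 + rate_m + rate_mut
        if total <= 0.0:
            t = t_end
            epoch += 1
            if epoch == 2:
                for i in range(n):
                    if alive[i]:
                        deme[i] = 0
            continue
        dt = np.random.exponential(1.0 / total)
        if t + dt >= t_end:
            t = t_end
            epoch += 1
            if epoch == 2:
                for i in range(n):
                    if alive[i]:
                        deme[i] = 0
            continue
        t += dt
        u = np.random.random() * total
        if u < rate_c0 + rate_c1:
            d = 0 if u < rate_c0 else 1
            # choose two distinct alive lineages in deme d
            kd = k0 if d == 0 else k1
            i1 = np.random.randint(kd)
            i2 = np.random.randint(kd - 1)
            if i2 >= i1:
                i2 += 1
            a = -1
            b = -1
            c = 0
            for i in range(n):
                if alive[i] and deme[i] == d:
                    if c == i1:
                        a = i
                    if c == i2:
                        b = i
                    c += 1
            # merge b into a
            for tip in range(n):
                if lin_of_tip[tip] == b:
                    lin_of_tip[tip] = a
            alive[b] = False
            k -= 1
        elif u < rate_c0 + rate_c1 + rate_m:
            r = u - rate_c0 - rate_c1
            for i in range(n):
                if alive[i]:
                    ri = m_back0 if deme[i] == 0 else m_back1
                    r -= ri
                    if r <= 0.0:
                        deme[i] = 1 - deme[i]
                        break
        else:
            j = np.random.randint(k)
            c = 0
            lin = -1
            for i in range(n):
                if alive[i]:
                    if c == j:
                        lin = i
                        break
                    c += 1
            step = 1 if np.random.random() < 0.5 else -1
            for tip in range(n):
                if lin_of_tip[tip] == lin:
                    offset[tip] += step
    states = np.empty(n, np.int64)
    for i in range(n):
        s = ancestral + offset[i]
        if s < floor:
            s = floor + (floor - s)
        states[i] = s
    return states, t


def simulate_locus(spec: ScenarioSpec, rng) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate one locus; returns (haploid states, deme labels, tmrca)."""
    spec.validate()
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    mig_e0, mig_e1 = _MIG_WINDOWS[spec.model]
    n0, n1 = 2 * spec.n_cau, 2 * spec.n_mor
    states, tmrca = _sim_locus_core(
        seed, n0, n1,
        float(spec.ne_cau_t2), float(spec.ne_mor_t2),
        float(spec.ne_cau_t1), float(spec.ne_mor_t1), float(spec.ne_anc),
        float(spec.m2), float(spec.m1),  # backward: deme0 jumps at m2, deme1 at m1
        mig_e0, mig_e1, float(spec.t1), float(spec.t2), float(spec.mu),
        int(spec.ancestral_state), int(spec.state_floor),
    )
    deme = np.concatenate([np.zeros(n0, dtype=np.int64), np.ones(n1, dtype=np.int64)])
    return states, deme, tmrca


def simulate_dataset(spec: ScenarioSpec, rng) -> SimulatedSample:
    """Simulate ``spec.n_loci`` independent loci for one dataset."""
    spec.validate()
    rng = np.random.default_rng(rng)
    n = 2 * (spec.n_cau + spec.n_mor)
    states = np.empty((n, spec.n_loci), dtype=np.int64)
    heights = np.empty(spec.n_loci)
    deme = None
    for l in range(spec.n_loci):
        s, deme, h = simulate_locus(spec, rng)
        states[:, l] = s
        heights[l] = h
    return SimulatedSample(states, deme, heights, deme_names=spec.deme_names)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

SUMMARY_STAT_NAMES = [
    "he_a", "ho_a", "nall_a", "sizevar_a", "mratio_a",
    "he_b", "ho_b", "nall_b", "sizevar_b", "mratio_b",
    "fst", "delta_mu2", "shared_alleles", "priv_a", "priv_b",
]


def _geno_arrays(obj):
    """Normalize input to (alleles (n, L, 2), species codes per individual)."""
    if isinstance(obj, SimulatedSample):
        ds = obj
        n_lin, L = ds.states.shape
        groups = []
        genos = []
        for d in (0, 1):
            sel = np.flatnonzero(ds.deme == d)
            if len(sel) % 2:
                raise ValueError("odd haploid sample size")
            g = np.stack([ds.states[sel[0::2]], ds.states[sel[1::2]]], axis=-1)
            genos.append(g)
            groups.append(np.full(len(sel) // 2, d))
        return np.concatenate(genos), np.concatenate(groups)
    if isinstance(obj, GenotypeDataset):
        sp = obj.species
        if len(sp) != 2:
            raise ValueError("summary statistics require exactly 2 species")
        code = np.array([0 if s == sp[0] else 1 for s in obj.species_of_individual()])
        return obj.alleles, code
    raise TypeError(f"cannot summarize {type(obj)!r}")


def summarize(obj) -> np.ndarray:
    """Fixed-order summary-statistic vector for a two-species dataset.

    Per species: mean expected and observed heterozygosity, mean allele
    count, mean allele-size variance and mean M-ratio (number of alleles /
    allele-size span + 1) over loci.  Joint: between-species F_ST (2-level
    AMOVA on allele identity), mean squared difference of mean allele size
    (delta-mu squared), proportion of shared alleles, and per-species
    private-allele counts scaled by sample size.  Monomorphic loci
    contribute He = 0; a fully monomorphic dataset yields F_ST = 0.
    """
    from .sumstats import _fst_from_tables

    alleles, code = _geno_arrays(obj)
    L = alleles.shape[1]
    per_sp = np.zeros((2, 5, L))  # he, ho, nall, sizevar, mratio
    dmu2 = np.zeros(L)
    shared = np.zeros(L)
    union = np.zeros(L)
    priv = np.zeros((2, L))
    tables = []
    n_ind = [max(int((code == g).sum()), 1) for g in (0, 1)]
    for l in range(L):
        sets = []
        means = []
        counts_rows = []
        for g in (0, 1):
            sub = alleles[code == g, l, :]
            pres = sub[:, 0] != MISSING
            vals = sub[pres].ravel()
            vals = vals[vals != MISSING]
            if vals.size == 0:
                sets.append(set())
                means.append(np.nan)
                counts_rows.append(np.zeros(0))
                continue
            uniq, cnt = np.unique(vals, return_counts=True)
            p = cnt / cnt.sum()
            per_sp[g, 0, l] = 1.0 - float((p**2).sum())
            if pres.any():
                per_sp[g, 1, l] = float(((sub[pres, 0] != sub[pres, 1]).mean()))
            per_sp[g, 2, l] = len(uniq)
            per_sp[g, 3, l] = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
            per_sp[g, 4, l] = len(uniq) / (uniq.max() - uniq.min() + 1.0)
            sets.append(set(uniq.tolist()))
            means.append(float(vals.mean()))
            counts_rows.append((uniq, cnt))
        if sets[0] or sets[1]:
            inter = sets[0] & sets[1]
            un = sets[0] | sets[1]
            shared[l] = len(inter)
            union[l] = len(un)
            priv[0, l] = len(sets[0] - sets[1])
            priv[1, l] = len(sets[1] - sets[0])
        if not (np.isnan(means[0]) or np.isnan(means[1])):
            dmu2[l] = (means[0] - means[1]) ** 2
        # build 2 x n_alleles count table for F_ST
        all_vals = sorted(sets[0] | sets[1])
        idx = {v: i for i, v in enumerate(all_vals)}
        tab = np.zeros((2, max(len(all_vals), 1)))
        for g in (0, 1):
            if isinstance(counts_rows[g], tuple):
                uniq, cnt = counts_rows[g]
                for v, c in zip(uniq, cnt):
                    tab[g, idx[v]] = c
        tables.append(tab)

    fst = _fst_from_tables(tables, 0, 1)
    fst = min(max(fst, 0.0), 1.0)
    out = np.concatenate([
        per_sp[0].mean(axis=1),
        per_sp[1].mean(axis=1),
        [fst, dmu2.mean(),
         shared.sum() / union.sum() if union.sum() > 0 else 0.0,
         priv[0].sum() / n_ind[0], priv[1].sum() / n_ind[1]],
    ])
    return out


def summarize_series(obj):
    """Summary vector as a pandas Series keyed by :data:`SUMMARY_STAT_NAMES`."""
    import pandas as pd

    return pd.Series(summarize(obj), index=SUMMARY_STAT_NAMES)
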