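"""Seeded synthetic fixture datasets with the statistical structure of a
two-species SSR study.

The generator is a frequency-model sampler, not a coalescent run: species
allele-frequency profiles are drawn with a Balding-Nichols-style Dirichlet
scatter calibrated against a target between-species divergence (Phi_CT) and
a within-species population differentiation (F_ST); part of each species's
allele pool is private to it, with the private-allele weight increasing
along the altitude gradient for the first species only.  Designated
individuals are drawn as mixtures of the two species pools with known true
ancestry (introgressed, hybrid or misassigned classes), recorded in a truth
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import ScenarioSpec, simulate_dataset, summarize_series
from .genio import MISSING, GenotypeDataset


@dataclass
class StudyTemplate:
    """Shape and targets of a generated study.

    The default mirrors the scale of an intensely sampled two-maple SSR
    survey: two species, 20 + 19 populations, about 380 + 285 individuals,
    17 loci, strong between-species divergence (Phi_CT ~ 0.48), moderate
    within-species structure, a minority of introgressed individuals, and
    altitude-enriched private alleles in the first species.
    """

    species_names: tuple = ("cau", "mor")
    pops_per_species: tuple = (20, 19)
    individuals_per_pop: tuple = (19, 15)
    n_loci: int = 17
    target_phi_ct: float = 0.478
    target_fst: float = 0.14
    introgressed_frac: tuple = (0.0243, 0.0534)
    hybrid_frac: tuple = (0.0, 0.0035)
    misassigned_frac: tuple = (0.0, 0.0175)
    shared_alleles_per_locus: int = 5
    private_alleles_per_locus: tuple = (3, 2)
    private_weight_range: tuple = (0.05, 0.30)  # species A, low -> high altitude
    private_weight_b: float = 0.12
    altitude_range: tuple = ((300.0, 2800.0), (1400.0, 2700.0))
    missing_rate: float = 0.02

    def validate(self) -> None:
        for fr in (*self.introgressed_frac, *self.hybrid_frac, *self.misassigned_frac,
                   self.missing_rate):
            if not (0 <= fr <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if not (0 <= self.target_phi_ct < 1) or not (0 <= self.target_fst < 1):
            raise ValueError("divergence targets must be in [0, 1)")


def mini_template(**overrides) -> StudyTemplate:
    """Small template for fast test suites (2 x 3 populations x 10 individuals)."""
    base = dict(pops_per_species=(3, 3), individuals_per_pop=(10, 10), n_loci=8,
                introgressed_frac=(0.1, 0.1), hybrid_frac=(0.0, 0.0),
                misassigned_frac=(0.0, 0.0), missing_rate=0.0)
    base.update(overrides)
    return StudyTemplate(**base)


@dataclass
class FrequencyModel:
    """Drawn allele-frequency profiles backing a synthetic study."""

    template: StudyTemplate
    allele_values: list[np.ndarray]  # per locus, integer sizes
    species_profiles: list[np.ndarray]  # per locus, (2, J)
    pop_profiles: list[np.ndarray]  # per locus, (n_pops, J)
    pop_names: list[str]
    species_of_pop: dict[str, str]
    geography: pd.DataFrame
    implied_phi_ct: float = np.nan
    implied_fst: float = np.nan


def _bn_profile(u: np.ndarray, base: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols draw via fixed uniforms (common random numbers).

    Equivalent to Dirichlet(base * (1-f)/f) with the gamma variates obtained
    through the quantile function at the frozen uniforms *u*, so the profile
    moves smoothly and monotonically as the differentiation level f changes.
    """
    from scipy.stats import gamma as gamma_dist

    f = min(max(f, 1e-4), 0.99)
    conc = np.maximum(base, 1e-9) * (1.0 - f) / f
    g = gamma_dist.ppf(u, conc)
    g = np.where(np.isfinite(g), g, 0.0)
    s = g.sum()
    if s <= 0:  # extreme differentiation: collapse onto the heaviest allele
        out = np.zeros_like(base)
        out[np.argmax(u * base)] = 1.0
        return out
    return g / s


def _draw_materials(template: StudyTemplate, rng_seed: int):
    """Draw all random ingredients once, independent of the scatter levels.

    Profiles are later formed by pushing frozen uniforms through the
    Balding-Nichols quantile map, so the implied divergence is a smooth
    monotone function of the differentiation parameters and can be
    calibrated by bisection.
    """
    t = template
    rng = np.random.default_rng(rng_seed)
    nA, nB = t.pops_per_species
    n_pops = nA + nB
    pop_names = [f"A{i + 1:02d}" for i in range(nA)] + [f"B{i + 1:02d}" for i in range(nB)]
    species_of_pop = {p: (t.species_names[0] if p.startswith("A") else t.species_names[1])
                      for p in pop_names}
    alts = np.concatenate([
        np.linspace(*t.altitude_range[0], nA),
        np.linspace(*t.altitude_range[1], nB),
    ])
    geography = pd.DataFrame({
        "latitude": rng.uniform(21.9, 25.3, n_pops).round(3),
        "longitude": rng.uniform(120.0, 122.0, n_pops).round(3),
        "altitude": alts.round(0),
    }, index=pd.Index(pop_names, name="population"))

    pa, pb = t.private_alleles_per_locus
    n_sh = t.shared_alleles_per_locus
    J = n_sh + pa + pb
    loci = []
    for l in range(t.n_loci):
        sizes = (100 + 10 * l + 2 * np.arange(J)).astype(int)
        base = rng.dirichlet(np.ones(n_sh))
        u_species = rng.uniform(0.02, 0.98, size=(2, n_sh))
        u_pop = rng.uniform(0.02, 0.98, size=(n_pops, J))
        priv = [rng.dirichlet(np.ones(pa)) if pa else np.zeros(0),
                rng.dirichlet(np.ones(pb)) if pb else np.zeros(0)]
        loci.append(dict(sizes=sizes, base=base, u_species=u_species,
                         u_pop=u_pop, priv=priv))
    return dict(loci=loci, pop_names=pop_names, species_of_pop=species_of_pop,
                geography=geography)


def _implied_stats(template: StudyTemplate, pop_profiles) -> tuple[float, float]:
    """Large-sample AMOVA Phi_CT and mean within-species pairwise F_ST implied
    by drawn population profiles.

    Uses expected allele-count tables (profile x planned copy number) pushed
    through the same variance-component estimator the measurement uses, so
    calibration and measurement agree up to sampling noise.
    """
    from .sumstats import _components_3level_tables, _fst_from_tables

    nA, nB = template.pops_per_species
    sizes = np.array([2 * template.individuals_per_pop[0]] * nA
                     + [2 * template.individuals_per_pop[1]] * nB, float)
    tables = [pops * sizes[:, None] for pops in pop_profiles]
    sp_of_pop = np.array([0] * nA + [1] * nB)
    sa, sb, sc, _, _ = _components_3level_tables(tables, sp_of_pop, 2)
    tot = max(sa, 0.0) + max(sb, 0.0) + sc
    phi_ct = max(sa, 0.0) / tot if tot > 0 else 0.0
    fst_means = []
    for start, count in ((0, nA), (nA, nB)):
        vals = [_fst_from_tables(tables, i, j)
                for i in range(start, start + count)
                for j in range(i + 1, start + count)]
        if vals:
            fst_means.append(float(np.mean(vals)))
    fst = float(np.mean(fst_means)) if fst_means else 0.0
    return phi_ct, fst


def _build(template: StudyTemplate, materials: dict, f_ct: float, f_st: float):
    """Compose species and population profiles from pre-drawn materials.

    ``f_ct`` is the Balding-Nichols differentiation of each species's
    shared-allele core around the common base (between-species divergence);
    ``f_st`` that of each population around its species profile.  Both act
    smoothly and monotonically through the frozen-uniform quantile map.
    """
    t = template
    nA, nB = t.pops_per_species
    pa, pb = t.private_alleles_per_locus
    n_sh = t.shared_alleles_per_locus
    J = n_sh + pa + pb
    shared = slice(0, n_sh)
    priv_sl = [slice(n_sh, n_sh + pa), slice(n_sh + pa, J)]
    w_lo, w_hi = t.private_weight_range
    alt_rank_a = np.arange(nA) / max(nA - 1, 1)
    pop_names = materials["pop_names"]

    allele_values, sp_profiles, pop_profiles = [], [], []
    for mat in materials["loci"]:
        allele_values.append(mat["sizes"])
        sp = np.zeros((2, J))
        supports = []
        for s in (0, 1):
            core = _bn_profile(mat["u_species"][s], mat["base"], f_ct)
            w = t.private_weight_b if s == 1 else (w_lo + w_hi) / 2.0
            n_priv = pa if s == 0 else pb
            if n_priv:
                sp[s, shared] = core * (1 - w)
                sp[s, priv_sl[s]] = w * mat["priv"][s]
            else:
                sp[s, shared] = core
            sup = np.zeros(J, dtype=bool)
            sup[shared] = True
            sup[priv_sl[s]] = n_priv > 0
            supports.append(sup)
        sp_profiles.append(sp)

        pops = np.zeros((nA + nB, J))
        for pi in range(nA + nB):
            s = 0 if pi < nA else 1
            sup = supports[s]
            prof = np.zeros(J)
            prof[sup] = _bn_profile(mat["u_pop"][pi, sup], sp[s, sup], f_st)
            if s == 0 and pa:
                # re-tilt the private block along the altitude gradient
                w_p = w_lo + (w_hi - w_lo) * alt_rank_a[pi]
                priv_mass = prof[priv_sl[0]].sum()
                other = prof.sum() - priv_mass
                if priv_mass > 1e-9 and other > 1e-9:
                    prof[priv_sl[0]] *= w_p / priv_mass
                    prof[shared] *= (1 - w_p) / other
                elif other > 1e-9:
                    # private block collapsed numerically: rebuild it from the
                    # species-level private profile at the target weight
                    prof[priv_sl[0]] = w_p * mat["priv"][0]
                    prof[shared] *= (1 - w_p) / other
            pops[pi] = prof / prof.sum()
        pop_profiles.append(pops)
    return allele_values, sp_profiles, pop_profiles, pop_names, \
        materials["species_of_pop"], materials["geography"]


def generate_frequency_model(template: StudyTemplate, rng) -> FrequencyModel:
    """Draw allele-frequency profiles calibrated to the template's targets.

    Calibration iterates on the Dirichlet scatter parameters until the
    divergence implied by the drawn profiles (a ratio of heterozygosity
    deficits summed over loci) is within 0.01 of the targets; unattainable
    targets raise ``ValueError`` reporting the best attained value.
    """
    template.validate()
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    materials = _draw_materials(template, seed)

    lo, hi = 0.0, 1.0

    def implied(f_ct, f_st):
        return _implied_stats(template, _build(template, materials, f_ct, f_st)[2])

    def bisect(eval_f, target, n_iter=18):
        # monotone root find on the mixing weight
        a, b = lo, hi
        if eval_f(a) >= target:
            return a
        if eval_f(b) <= target:
            return b
        for _ in range(n_iter):
            mid = (a + b) / 2
            val = eval_f(mid)
            if abs(val - target) <= 0.002:
                return mid
            if val < target:
                a = mid
            else:
                b = mid
        return (a + b) / 2

    f_ct = template.target_phi_ct
    f_st = template.target_fst
    for _ in range(2):
        if template.target_phi_ct > 0:
            f_ct = bisect(lambda f: implied(f, f_st)[0], template.target_phi_ct)
        if template.target_fst > 0:
            f_st = bisect(lambda f: implied(f_ct, f)[1], template.target_fst)
    built = _build(template, materials, f_ct, f_st)
    implied_ct, implied_st = _implied_stats(template, built[2])
    if abs(implied_ct - template.target_phi_ct) > 0.05:
        raise ValueError(
            f"target Phi_CT {template.target_phi_ct} unattainable; "
            f"best attained {implied_ct:.3f}")
    allele_values, sp_profiles, pop_profiles, pop_names, species_of_pop, geography = built
    if template.target_phi_ct == 0:
        sp_profiles = [np.repeat(sp.mean(axis=0, keepdims=True), 2, axis=0)
                       for sp in sp_profiles]
        implied_ct = 0.0
    if template.target_fst == 0:
        pop_profiles = [
            np.stack([sp_profiles[l][0 if p.startswith("A") else 1]
                      for p in pop_names])
            for l in range(template.n_loci)
        ]
        implied_st = 0.0
    return FrequencyModel(template, allele_values, sp_profiles, pop_profiles,
                          pop_names, species_of_pop, geography,
                          implied_ct, implied_st)


_CLASS_Q = {  # true ancestry of the other species's cluster, by class
    "pure": (0.0, 0.0),
    "introgressed": (0.08, 0.45),
    "hybrid": (0.52, 0.88),
    "misassigned": (0.92, 0.995),
}


def generate_dataset(template: StudyTemplate, rng,
                     model: FrequencyModel | None = None):
    """Draw a diploid genotype dataset plus its truth table.

    Returns ``(GenotypeDataset, truth)`` where ``truth`` records each
    individual's population, species, class, true ancestry of the other
    species's pool, and population altitude.  Designated introgressed /
    hybrid / misassigned individuals draw each allele copy from the other
    species's profile with probability equal to their true ancestry.
    """
    rng = np.random.default_rng(rng)
    if model is None:
        model = generate_frequency_model(template, rng)
    t = template
    nA, nB = t.pops_per_species
    pop_sizes = [t.individuals_per_pop[0]] * nA + [t.individuals_per_pop[1]] * nB
    pop_species_idx = [0] * nA + [1] * nB

    # assign classes per species
    classes_per_ind: list[str] = []
    pops_per_ind: list[int] = []
    for s in (0, 1):
        pops_s = [i for i, si in enumerate(pop_species_idx) if si == s]
        n_s = sum(pop_sizes[i] for i in pops_s)
        n_intro = int(round(t.introgressed_frac[s] * n_s))
        n_hyb = int(round(t.hybrid_frac[s] * n_s))
        n_mis = int(round(t.misassigned_frac[s] * n_s))
        labels = (["introgressed"] * n_intro + ["hybrid"] * n_hyb
                  + ["misassigned"] * n_mis + ["pure"] * (n_s - n_intro - n_hyb - n_mis))
        labels = list(rng.permutation(labels))
        for p in pops_s:
            for _ in range(pop_sizes[p]):
                classes_per_ind.append(labels.pop())
                pops_per_ind.append(p)

    n_ind = len(classes_per_ind)
    q_true = np.zeros(n_ind)
    for i, c in enumerate(classes_per_ind):
        lo, hi = _CLASS_Q[c]
        q_true[i] = rng.uniform(lo, hi) if hi > lo else 0.0

    alleles = np.empty((n_ind, t.n_loci, 2), dtype=np.int32)
    for l in range(t.n_loci):
        vals = model.allele_values[l]
        pops = model.pop_profiles[l]
        sp = model.species_profiles[l]
        for i in range(n_ind):
            p = pops_per_ind[i]
            s = pop_species_idx[p]
            own = pops[p]
            other = sp[1 - s]
            for c in (0, 1):
                prof = other if rng.random() < q_true[i] else own
                alleles[i, l, c] = vals[rng.choice(len(vals), p=prof)]
    if t.missing_rate > 0:
        miss = rng.random((n_ind, t.n_loci)) < t.missing_rate
        alleles[miss] = MISSING

    ids = []
    pop_labels = []
    counters: dict[int, int] = {}
    for i in range(n_ind):
        p = pops_per_ind[i]
        counters[p] = counters.get(p, 0) + 1
        ids.append(f"{model.pop_names[p]}_{counters[p]:03d}")
        pop_labels.append(model.pop_names[p])
    ds = GenotypeDataset(alleles, ids, [f"L{l + 1}" for l in range(t.n_loci)],
                         np.array(pop_labels, dtype=object),
                         species_of_pop=dict(model.species_of_pop),
                         geography=model.geography.copy())
    ds.validate()
    truth = pd.DataFrame({
        "individual": ids,
        "population": pop_labels,
        "species": [t.species_names[pop_species_idx[p]] for p in pops_per_ind],
        "class": classes_per_ind,
        "true_q_other": q_true,
        "altitude": [model.geography.loc[model.pop_names[p], "altitude"]
                     for p in pops_per_ind],
    })
    return ds, truth


def generate_observed_stats(scenario_spec: ScenarioSpec, rng):
    """Pseudo-observed summary statistics: one simulated dataset, summarized."""
    sample = simulate_dataset(scenario_spec, np.random.default_rng(rng))
    return summarize_series(sample)
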