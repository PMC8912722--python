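"""Bayesian admixture clustering and introgression classification.

A STRUCTURE-style admixture model: each allele copy carries a latent cluster
assignment Z; cluster allele frequencies P have independent Dirichlet(lambda)
priors per cluster and locus; individual ancestry vectors Q have a
Dirichlet(alpha) prior with alpha fixed at 1/K (uniform on the simplex).
The Gibbs sampler alternates Z | P,Q -> P | Z -> Q | Z and reports posterior
means of Q and P over the post-burn-in sweeps.  Missing alleles are skipped
in the likelihood.

Cluster number selection uses the second-order rate of change of the model
log-likelihood across K (the Evanno delta-K statistic); replicate runs are
aligned into a common labelling before averaging; introgression calls apply
ordered thresholds on the ancestry proportion of the other species's
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset


@dataclass
class AdmixtureRun:
    """One Gibbs chain: posterior means and the log-likelihood trace."""

    K: int
    Q: np.ndarray  # (n_individuals, K) posterior mean ancestry
    P: np.ndarray  # (K, n_loci, max_alleles) posterior mean frequencies
    allele_values: list[np.ndarray]  # per-locus allele sizes backing P's columns
    loglik_trace: np.ndarray
    seed: int
    chain_len: int
    burn_in: int
    individual_ids: list[str]

    def ln_prob_data(self) -> float:
        """STRUCTURE-style estimate of ln P(X | K): mean minus half the
        variance of the post-burn-in log-likelihood trace."""
        tail = self.loglik_trace[self.burn_in:]
        return float(tail.mean() - tail.var() / 2.0)


def _allele_indices(dataset: GenotypeDataset):
    """Compact per-locus allele indices; returns (A (n, L, 2), values per locus)."""
    n, L = dataset.n_individuals, dataset.n_loci
    A = np.full((n, L, 2), -1, dtype=np.int64)
    values = []
    for l in range(L):
        vals = dataset.alleles[:, l, :]
        flat = vals.ravel()
        keep = flat != MISSING
        uniq = np.unique(flat[keep])
        values.append(uniq)
        if uniq.size:
            lookup = {v: i for i, v in enumerate(uniq.tolist())}
            idx = np.array([lookup.get(v, -1) for v in flat.tolist()], dtype=np.int64)
            A[:, l, :] = idx.reshape(n, 2)
    return A, values


def gibbs_admixture(dataset: GenotypeDataset, K: int, chain_len: int = 50_000,
                    burn_in: float = 0.2, seed: int = 0,
                    alpha: float | None = None, lam: float = 1.0) -> AdmixtureRun:
    """Run the admixture-model Gibbs sampler.

    ``burn_in`` may be a fraction of ``chain_len`` (values < 1) or an
    absolute sweep count.  ``alpha`` defaults to 1/K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    burn = int(burn_in * chain_len) if burn_in < 1 else int(burn_in)
    if chain_len <= burn:
        raise ValueError("chain_len must exceed burn_in")
    if alpha is None:
        alpha = 1.0 / K
    rng = np.random.default_rng(seed)
    A, values = _allele_indices(dataset)
    n, L, _ = A.shape
    Jmax = max((v.size for v in values), default=1) or 1
    valid = np.zeros((L, Jmax), dtype=bool)
    for l, v in enumerate(values):
        valid[l, : v.size] = True
    mask = A >= 0  # (n, L, 2) non-missing copies
    A_safe = np.where(mask, A, 0)
    l_idx = np.broadcast_to(np.arange(L)[None, :, None], A.shape)

    total_diversity = int(sum(v.size for v in values))
    if K > total_diversity:
        import warnings

        warnings.warn(f"K={K} exceeds total allele diversity {total_diversity}")

    # initialize
    P = rng.dirichlet(np.ones(Jmax), size=(K, L))
    P = P * valid[None]
    P = P / P.sum(axis=2, keepdims=True)
    Q = np.full((n, K), 1.0 / K)

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    ll_trace = np.empty(chain_len)
    kept = 0
    for sweep in range(chain_len):
        # P[k] gathered at each copy's allele: lik (K, n, L, 2)
        lik = P[:, l_idx, A_safe]
        probs = Q.T[:, :, None, None] * lik
        tot = probs.sum(axis=0)
        tot = np.where(tot > 0, tot, 1.0)
        probs /= tot
        u = rng.random((n, L, 2))
        cum = np.cumsum(probs, axis=0)
        Z = (u[None] > cum).sum(axis=0)  # (n, L, 2) in 0..K-1
        Z = np.minimum(Z, K - 1)

        # log-likelihood of the data under current (P, Q)
        mix = (Q.T[:, :, None, None] * lik).sum(axis=0)
        ll_trace[sweep] = float(np.log(np.maximum(mix[mask], 1e-300)).sum())

        # P update: Dirichlet(lam + counts) per cluster and locus
        counts = np.zeros((K, L, Jmax))
        zf, lf, af = Z[mask], l_idx[mask], A_safe[mask]
        np.add.at(counts, (zf, lf, af), 1.0)
        shape = np.where(valid[None], lam + counts, 0.0)
        G = rng.standard_gamma(shape)
        denom = G.sum(axis=2, keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        P = G / denom

        # Q update: Dirichlet(alpha + per-individual cluster counts)
        qcounts = np.zeros((n, K))
        ind_idx = np.broadcast_to(np.arange(n)[:, None, None], A.shape)
        np.add.at(qcounts, (ind_idx[mask], zf), 1.0)
        Gq = rng.standard_gamma(alpha + qcounts)
        Q = Gq / Gq.sum(axis=1, keepdims=True)

        if sweep >= burn:
            Q_sum += Q
            P_sum += P
            kept += 1

    Q_mean = Q_sum / kept
    if K == 1:
        Q_mean = np.ones((n, 1))
    return AdmixtureRun(K, Q_mean, P_sum / kept, values, ll_trace, seed,
                        chain_len, burn, list(dataset.individual_ids))


# ---------------------------------------------------------------------------
# replicate alignment and K selection
# ---------------------------------------------------------------------------

def align_replicates(runs: list[AdmixtureRun]) -> list[AdmixtureRun]:
    """Permute cluster labels of each run to best match the first run.

    The permutation maximizes the summed correlation between matched Q
    columns (solved as an assignment problem).  Returns new runs; the first
    is returned unchanged.
    """
    from scipy.optimize import linear_sum_assignment

    if not runs:
        return []
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must have equal K")
    ref = runs[0].Q
    out = [runs[0]]
    for r in runs[1:]:
        C = np.zeros((K, K))
        for j in range(K):
            for k in range(K):
                a, b = ref[:, j], r.Q[:, k]
                if a.std() == 0 or b.std() == 0:
                    C[j, k] = -float(np.abs(a - b).mean())
                else:
                    C[j, k] = float(np.corrcoef(a, b)[0, 1])
        _, perm = linear_sum_assignment(-C)
        out.append(AdmixtureRun(K, r.Q[:, perm], r.P[perm], r.allele_values,
                                r.loglik_trace, r.seed, r.chain_len, r.burn_in,
                                r.individual_ids))
    return out


def evanno_delta_k(ln_prob_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table: per-K mean and SD of ln P(X|K) and delta-K.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K)),
    defined only for interior K with consecutive neighbours; SD = 0 leaves
    delta-K undefined (NaN) at that K.
    """
    ks = sorted(ln_prob_by_k)
    if len(ks) < 3:
        raise ValueError("delta-K needs >= 3 consecutive K values")
    mean = {k: float(np.mean(ln_prob_by_k[k])) for k in ks}
    sd = {k: float(np.std(ln_prob_by_k[k], ddof=1)) if len(ln_prob_by_k[k]) > 1 else 0.0
          for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if (k - 1) in mean and (k + 1) in mean and sd[k] > 0:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append(dict(K=k, mean_ln_prob=mean[k], sd_ln_prob=sd[k],
                         n_replicates=len(ln_prob_by_k[k]), delta_k=dk))
    return pd.DataFrame(rows).set_index("K")


# ---------------------------------------------------------------------------
# introgression classification
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = (0.05, 0.50, 0.90)


def cluster_of_species(Q: np.ndarray, species_of_individual: np.ndarray) -> dict[str, int]:
    """Map each species to the cluster with the highest mean ancestry among
    its individuals (K = 2)."""
    species = list(dict.fromkeys(species_of_individual))
    mapping = {}
    for s in species:
        mapping[s] = int(np.argmax(Q[species_of_individual == s].mean(axis=0)))
    return mapping


def classify_introgression(Q: np.ndarray, host_species: np.ndarray,
                           species_cluster: dict[str, int] | None = None,
                           thresholds=DEFAULT_THRESHOLDS,
                           individual_ids=None) -> pd.DataFrame:
    """Rule-based introgression calls from a K = 2 aligned ancestry matrix.

    ``q_other`` is the ancestry proportion of the other species's cluster.
    Classes (with default thresholds t = (0.05, 0.50, 0.90)):
    pure (q_other <= t0), introgressed (t0 < q_other <= t1),
    hybrid (t1 < q_other <= t2), misassigned (q_other > t2).
    """
    Q = np.asarray(Q, float)
    if Q.shape[1] != 2:
        raise ValueError("introgression classification is defined for K=2 only")
    t0, t1, t2 = thresholds
    if not (0 < t0 < t1 < t2 < 1):
        raise ValueError("thresholds must be ordered in (0, 1)")
    host_species = np.asarray(host_species, dtype=object)
    if species_cluster is None:
        species_cluster = cluster_of_species(Q, host_species)
    if len(set(species_cluster.values())) != 2:
        raise ValueError("the two species map to the same cluster; "
                         "data are not separable at K=2")
    q_other = np.array([Q[i, 1 - species_cluster[host_species[i]]]
                        for i in range(len(Q))])
    cls = np.where(q_other <= t0, "pure",
                   np.where(q_other <= t1, "introgressed",
                            np.where(q_other <= t2, "hybrid", "misassigned")))
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(len(Q))]
    return pd.DataFrame(dict(individual=individual_ids, host_species=host_species,
                             q_other=q_other, call=cls))


def introgression_geography(calls: pd.DataFrame, dataset: GenotypeDataset,
                            classes=("introgressed",)) -> dict:
    """Geographic ranges of called individuals per species.

    Returns per species the (min, max) of altitude, longitude and latitude
    over individuals whose call is in *classes*, plus per-population counts.
    Empty ranges (no calls) are reported as ``None``, not an error.
    """
    if dataset.geography is None:
        raise ValueError("dataset has no geography (attach metadata first)")
    geo = dataset.geography
    pop = dataset.pop_of_individual
    sel = calls["call"].isin(classes).to_numpy()
    out: dict = {"ranges": {}, "counts_per_population": {}}
    for s in dict.fromkeys(calls["host_species"]):
        mask = sel & (calls["host_species"] == s).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            out["ranges"][s] = None
            continue
        sub_pops = pop[idx]
        rng_ = {}
        for col in ("altitude", "longitude", "latitude"):
            vals = geo.loc[list(sub_pops), col].to_numpy(float)
            rng_[col] = (float(vals.min()), float(vals.max()))
        out["ranges"][s] = rng_
        counts = pd.Series(sub_pops).value_counts().to_dict()
        out["counts_per_population"].update({str(k): int(v) for k, v in counts.items()})
    return out
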