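"""Per-SV Weir-Cockerham F_ST, permutation outlier scan, and dosage PCA.

The Weir-Cockerham estimator partitions allele-frequency variance into
among-population (a), among-individual-within-population (b) and
within-individual (c) components; theta = a / (a + b + c). For r groups
with sizes n_i, alt-allele frequencies p_i and observed heterozygote
proportions h_i:

    nbar = sum(n_i) / r
    n_c  = (r*nbar - sum(n_i^2)/(r*nbar)) / (r - 1)
    pbar = sum(n_i * p_i) / (r * nbar)
    s2   = sum(n_i * (p_i - pbar)^2) / ((r - 1) * nbar)
    hbar = sum(n_i * h_i) / (r * nbar)
    a = (nbar/n_c) * (s2 - (pbar*(1-pbar) - s2*(r-1)/r - hbar/4) / (nbar-1))
    b = (nbar/(nbar-1)) * (pbar*(1-pbar) - s2*(r-1)/r - hbar*(2*nbar-1)/(4*nbar))
    c = hbar / 2

Significance of each per-SV theta is assessed by permuting individuals
into two groups of the original sizes and recomputing theta; the per-SV P
is the fraction of permuted values strictly greater than the observed one
(so 10 exceedances out of 200 permutations gives P = 0.05). A single
genome-wide cutoff is the q-quantile (default 99.7%) of the pooled
permutation null; an outlier must have P < alpha AND theta above the
cutoff. SVs without an alternative allele in the union of the two groups
are excluded as monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from svpop.errors import ConfigurationError
from svpop.svset import GenotypeMatrix


def _group_stats(G: np.ndarray, mask: np.ndarray):
    """Per-SV (n, p, h) for one group given genotype codes (-1/0/1/2)."""
    sub = G[:, mask]
    obs = sub >= 0
    n = obs.sum(axis=1).astype(float)
    alt = np.where(obs, sub, 0).sum(axis=1).astype(float)
    het = (sub == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        h = het / n
    return n, p, h


def _wc_theta_from_stats(n1, p1, h1, n2, p2, h2):
    """Vectorized two-group Weir-Cockerham theta from per-group statistics.

    Returns (theta, abc_sum) with NaN where a+b+c == 0 (monomorphic).
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta, denom


def wc_fst(genotypes: np.ndarray, groups: np.ndarray) -> tuple[float, bool]:
    """Weir-Cockerham theta for one SV between two groups.

    ``genotypes`` are dosage codes (0/1/2, -1 missing); ``groups`` is a
    boolean array (True = group 1). Returns ``(theta, excluded)`` where
    ``excluded`` marks a monomorphic/undefined site (theta is NaN there).
    Missing genotypes are removed pairwise. Raises if either group has
    fewer than 2 non-missing genotypes.
    """
    genotypes = np.asarray(genotypes)
    groups = np.asarray(groups, dtype=bool)
    if genotypes.shape != groups.shape:
        raise ConfigurationError("genotypes and groups must align")
    G = genotypes[None, :]
    n1, p1, h1 = _group_stats(G, groups)
    n2, p2, h2 = _group_stats(G, ~groups)
    if n1[0] < 2 or n2[0] < 2:
        raise ConfigurationError(
            "each group needs >=2 non-missing genotypes"
        )
    theta, denom = _wc_theta_from_stats(n1, p1, h1, n2, p2, h2)
    excluded = bool(denom[0] == 0)
    return (float(theta[0]) if not excluded else float("nan")), excluded


@dataclass
class PermutationNull:
    """Permutation null for an F_ST scan.

    ``assignments`` holds, per permutation, the sample indices assigned to
    group 1; ``null_thetas`` is (n_sv, n_perm); ``global_cutoff`` is the
    q-quantile of the pooled finite null values.
    """

    n_perm: int
    seed: int
    q: float
    assignments: np.ndarray
    null_thetas: np.ndarray
    global_cutoff: float

    @property
    def pooled(self) -> np.ndarray:
        vals = self.null_thetas.ravel()
        return vals[np.isfinite(vals)]


def permutation_pvalue(
    theta_obs: float, null_thetas: np.ndarray, strict: bool = True
) -> float:
    """Fraction of permuted theta values exceeding the observed one.

    ``strict=True`` (default) counts strict exceedances (ties are
    non-exceedances); ``strict=False`` counts >=.
    """
    null_thetas = np.asarray(null_thetas, dtype=float)
    finite = np.isfinite(null_thetas)
    if strict:
        n_exceed = int((null_thetas[finite] > theta_obs).sum())
    else:
        n_exceed = int((null_thetas[finite] >= theta_obs).sum())
    return n_exceed / null_thetas.size


def fst_outlier_scan(
    matrix: GenotypeMatrix,
    labels,
    n_perm: int = 200,
    q: float = 0.997,
    alpha: float = 0.01,
    seed: int = 0,
    strict: bool = True,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Per-SV theta, permutation P, and outlier flags for a two-group contrast.

    ``labels`` is a length-n_samples sequence with exactly two distinct
    values (e.g. 'farmed'/'wild'). Monomorphic SVs (no alternative allele
    across the union of groups) are excluded from P values, the pooled null
    and the cutoff, and flagged in the output. Deterministic given ``seed``.

    Returns a results frame (sv_id, theta, n_exceed, p_perm, passes_cutoff,
    is_outlier, excluded_monomorphic) and the :class:`PermutationNull`.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ConfigurationError(f"need exactly 2 group labels, got {list(uniq)}")
    mask_obs = labels == uniq[0]
    n1 = int(mask_obs.sum())
    G = matrix.codes

    def theta_for(mask: np.ndarray) -> np.ndarray:
        s1 = _group_stats(G, mask)
        s2 = _group_stats(G, ~mask)
        th, _ = _wc_theta_from_stats(*s1, *s2)
        return th

    theta_obs = theta_for(mask_obs)
    # monomorphic across the union: no alt allele or fixed alt everywhere
    obs = G >= 0
    alt = np.where(obs, G, 0).sum(axis=1)
    total = 2 * obs.sum(axis=1)
    monomorphic = (alt == 0) | (alt == total) | ~np.isfinite(theta_obs)

    rng = np.random.default_rng(seed)
    n_samples = matrix.n_samples
    assignments = np.empty((n_perm, n1), dtype=int)
    null = np.full((matrix.n_sv, n_perm), np.nan)
    for k in range(n_perm):
        perm = rng.permutation(n_samples)
        g1 = perm[:n1]
        assignments[k] = g1
        mask = np.zeros(n_samples, dtype=bool)
        mask[g1] = True
        null[:, k] = theta_for(mask)
    null[monomorphic, :] = np.nan

    pooled = null[np.isfinite(null)]
    cutoff = float(np.quantile(pooled, q)) if pooled.size else float("nan")

    cmp = null > theta_obs[:, None] if strict else null >= theta_obs[:, None]
    n_exceed = np.where(np.isfinite(null), cmp, False).sum(axis=1)
    p_perm = n_exceed / n_perm
    passes = theta_obs > cutoff
    outlier = (p_perm < alpha) & passes & ~monomorphic
    res = pd.DataFrame(
        {
            "sv_id": matrix.sv_ids,
            "theta": theta_obs,
            "n_exceed": n_exceed,
            "p_perm": np.where(monomorphic, np.nan, p_perm),
            "passes_cutoff": passes & ~monomorphic,
            "is_outlier": outlier,
            "excluded_monomorphic": monomorphic,
        }
    )
    return res, PermutationNull(n_perm, seed, q, assignments, null, cutoff)


def pca_dosage(dosage: pd.DataFrame, n_components: int = 10):
    """PCA of the centered sample x SV dosage matrix.

    ``dosage`` is an SV x sample frame (output of
    :func:`svpop.svset.recode_dosage`); constant SVs are dropped with a
    warning. Returns (scores frame indexed by sample, explained-variance
    fractions).
    """
    import warnings

    from sklearn.decomposition import PCA

    if dosage.shape[0] < 2 or dosage.shape[1] < 2:
        raise ConfigurationError("PCA needs >=2 SVs and >=2 samples")
    X = dosage.to_numpy(float).T  # samples x SVs
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"pca_dosage: dropped {int(const.sum())} constant SV column(s)",
            stacklevel=2,
        )
        X = X[:, ~const]
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        scores,
        index=dosage.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return frame, pca.explained_variance_ratio_
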