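"""Sequence summary statistics and AMOVA-based population structure.

All statistics operate on `seqevo.Alignment` objects and are applied
identically to observed and simulated data.  Columns containing a gap or
ambiguity code in *any* sequence are excluded alignment-wide before any
statistic is computed.

Haplotype diversity follows Nei's unbiased estimator
``h = n (1 - sum p_i^2) / (n - 1)``; nucleotide diversity is the mean
pairwise proportion of differing sites; phi_ST is the Excoffier-style
AMOVA fixation index computed from squared pairwise haplotype distances
(number of differing sites), with significance from permutation of
individual population labels (plain-proportion p, mirroring Arlequin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import InvalidParameterError
from .seqevo import Alignment


class UndefinedStatisticError(ValueError):
    """Statistic undefined for this input (e.g. fewer than two sequences)."""


@dataclass(frozen=True)
class PopulationMap:
    """Maps sequence labels to population codes (and populations to regions)."""

    assignments: dict[str, str]
    regions: dict[str, str] | None = None

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def labels_for(self, population: str) -> list[str]:
        return [l for l, p in self.assignments.items() if p == population]

    def check_alignment(self, aln: Alignment) -> None:
        missing = [l for l in aln.labels if l not in self.assignments]
        if missing:
            raise InvalidParameterError(
                f"alignment labels missing from population map: {missing}"
            )


def clean_matrix(aln: Alignment) -> np.ndarray:
    """Alignment matrix restricted to columns free of gaps/ambiguities."""
    keep = np.all(aln.data <= 3, axis=0)
    return aln.data[:, keep]


def _variable_columns(mat: np.ndarray) -> np.ndarray:
    if mat.shape[0] == 0:
        return mat
    return mat[:, np.any(mat != mat[0], axis=0)]


def haplotype_counts(aln: Alignment) -> np.ndarray:
    """Sizes of sequence identity classes, largest first."""
    if aln.n_sequences == 0:
        raise UndefinedStatisticError("empty alignment")
    var = _variable_columns(clean_matrix(aln))
    if var.shape[1] == 0:
        return np.array([aln.n_sequences])
    _, counts = np.unique(var, axis=0, return_counts=True)
    return np.sort(counts)[::-1]


def haplotype_diversity(counts: np.ndarray) -> float:
    """Nei's unbiased haplotype diversity from identity-class sizes."""
    counts = np.asarray(counts)
    n = int(counts.sum())
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def nucleotide_diversity(aln: Alignment) -> float:
    """Mean pairwise proportion of differing sites (pi per site)."""
    if aln.n_sequences < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    mat = clean_matrix(aln)
    L = mat.shape[1]
    if L == 0:
        raise UndefinedStatisticError("no usable columns in alignment")
    var = _variable_columns(mat)
    n = aln.n_sequences
    if var.shape[1] == 0:
        return 0.0
    # per-column allele counts: differing pairs at a column = C(n,2) - sum C(n_a,2)
    state_counts = np.stack([(var == s).sum(axis=0) for s in range(4)])
    same_pairs = (state_counts * (state_counts - 1) // 2).sum(axis=0)
    n_pairs = n * (n - 1) / 2
    diff_pairs = n_pairs - same_pairs
    return float(diff_pairs.sum()) / n_pairs / L


def segregating_sites(aln: Alignment) -> int:
    """Number of columns with two or more observed states."""
    if aln.n_sequences < 2:
        raise UndefinedStatisticError("segregating sites needs n >= 2")
    return int(_variable_columns(clean_matrix(aln)).shape[1])


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """Individual-by-individual matrix of differing-site counts."""
    mat = _variable_columns(clean_matrix(aln))
    n = aln.n_sequences
    if mat.shape[1] == 0:
        return np.zeros((n, n))
    haps, inverse = np.unique(mat, axis=0, return_inverse=True)
    dh = np.count_nonzero(
        haps[:, None, :] != haps[None, :, :], axis=2
    ).astype(float)
    return dh[np.ix_(inverse, inverse)]


@dataclass(frozen=True)
class AmovaResult:
    phi_st: float
    p_value: float
    sigma2_among: float
    sigma2_within: float
    phi_st_clamped: float
    n_permutations: int


def _phi_from_distances(
    d: np.ndarray, assign: np.ndarray, pop_ids: np.ndarray
) -> tuple[float, float, float]:
    n = len(assign)
    P = len(pop_ids)
    ssd_total = float(np.sum(np.triu(d, 1))) / n
    ssd_within = 0.0
    sum_np2 = 0.0
    for p in pop_ids:
        idx = np.flatnonzero(assign == p)
        n_p = len(idx)
        sum_np2 += n_p * n_p
        if n_p > 1:
            sub = d[np.ix_(idx, idx)]
            ssd_within += float(np.sum(np.triu(sub, 1))) / n_p
    ssd_among = ssd_total - ssd_within
    df_among = P - 1
    df_within = n - P
    if df_within <= 0:
        raise UndefinedStatisticError("AMOVA needs more individuals than pops")
    sigma_w = ssd_within / df_within
    n_bar = (n - sum_np2 / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else 0.0
    return phi, sigma_a, sigma_w


def amova_phist(
    aln: Alignment,
    pops: PopulationMap,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """AMOVA phi_ST with a permutation test on population labels.

    Negative variance components are reported as computed; a clamped
    phi_ST restricted to [-1, 1] is provided alongside.
    """
    pops.check_alignment(aln)
    assign = np.array([pops.assignments[l] for l in aln.labels])
    pop_ids = np.unique(assign)
    if len(pop_ids) < 2:
        raise UndefinedStatisticError("AMOVA needs at least two populations")
    d = pairwise_difference_matrix(aln)
    phi, sig_a, sig_w = _phi_from_distances(d, assign, pop_ids)
    if rng is None:
        rng = np.random.default_rng()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(assign)
        phi_p, _, _ = _phi_from_distances(d, perm, pop_ids)
        if phi_p >= phi:
            hits += 1
    p = hits / n_perm if n_perm > 0 else float("nan")
    return AmovaResult(
        phi_st=phi,
        p_value=p,
        sigma2_among=sig_a,
        sigma2_within=sig_w,
        phi_st_clamped=float(np.clip(phi, -1.0, 1.0)),
        n_permutations=n_perm,
    )


def pairwise_phist(
    aln: Alignment,
    pops: PopulationMap,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    linearized: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """phi_ST (optionally linearized as phi/(1-phi)) and p per population pair."""
    pops.check_alignment(aln)
    if rng is None:
        rng = np.random.default_rng()
    assign = {l: pops.assignments[l] for l in aln.labels}
    codes = sorted(set(assign.values()))
    P = len(codes)
    phi_m = np.zeros((P, P))
    p_m = np.zeros((P, P))
    idx_by_pop = {
        c: [i for i, l in enumerate(aln.labels) if assign[l] == c]
        for c in codes
    }
    for a in range(P):
        for b in range(a + 1, P):
            rows = idx_by_pop[codes[a]] + idx_by_pop[codes[b]]
            sub = Alignment(
                data=aln.data[rows],
                labels=tuple(aln.labels[i] for i in rows),
                partition=aln.partition,
            )
            res = amova_phist(sub, pops, n_perm=n_perm, rng=rng)
            val = res.phi_st
            if linearized:
                val = val / (1.0 - val) if val < 1.0 else np.inf
            phi_m[a, b] = phi_m[b, a] = val
            p_m[a, b] = p_m[b, a] = res.p_value
    return (
        pd.DataFrame(phi_m, index=codes, columns=codes),
        pd.DataFrame(p_m, index=codes, columns=codes),
    )


def population_stats_table(
    aln: Alignment,
    pops: PopulationMap,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-population and overall N, k, h, pi (with optional site-bootstrap SDs)."""
    pops.check_alignment(aln)
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    groups = {c: pops.labels_for(c) for c in pops.populations()}
    groups["Overall"] = list(aln.labels)
    label_idx = {l: i for i, l in enumerate(aln.labels)}
    for code, labels in groups.items():
        idx = [label_idx[l] for l in labels if l in label_idx]
        if not idx:
            continue
        sub = Alignment(
            data=aln.data[idx],
            labels=tuple(aln.labels[i] for i in idx),
            partition=aln.partition,
        )
        counts = haplotype_counts(sub)
        k = len(counts)
        if sub.n_sequences >= 2:
            h = haplotype_diversity(counts)
            pi = nucleotide_diversity(sub)
        else:
            h = np.nan
            pi = np.nan
        h_sd = pi_sd = np.nan
        if n_bootstrap > 0 and sub.n_sequences >= 2:
            hs, pis = [], []
            L = sub.length
            for _ in range(n_bootstrap):
                cols = rng.integers(0, L, size=L)
                b = Alignment(
                    data=sub.data[:, cols], labels=sub.labels,
                    partition=sub.partition,
                )
                hs.append(haplotype_diversity(haplotype_counts(b)))
                pis.append(nucleotide_diversity(b))
            h_sd = float(np.std(hs, ddof=1))
            pi_sd = float(np.std(pis, ddof=1))
        rows.append(
            {"population": code, "N": sub.n_sequences, "k": k, "h": h,
             "h_sd": h_sd, "pi": pi, "pi_sd": pi_sd}
        )
    return pd.DataFrame(rows).set_index("population")
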