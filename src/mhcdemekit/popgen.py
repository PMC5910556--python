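"""Deme- and region-level population-genetic statistics.

Heterozygosities (Nei's unbiased expected form), effective allele number,
an exact/Monte-Carlo conditional Hardy-Weinberg test, Weir-Cockerham
F_ST, Queller-Goodnight pairwise relatedness, hypergeometric rarefaction
of allele richness with bootstrap intervals, shared vs region-specific
allele classification, Fisher's exact 2x2 contingency test, sample-size
correlation and mtDNA haplotype-sharing summaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity_stats(genotypes: list):
    """(h_obs, h_exp, n_eff) for one deme x locus.

    ``genotypes`` is a list of 2-tuples of allele labels. h_exp uses Nei's
    unbiased correction 2n/(2n-1) * (1 - sum p_i^2); n_eff = 1 / sum p_i^2.
    """
    n = len(genotypes)
    if n == 0:
        raise ValueError("no genotypes")
    h_obs = sum(1 for a, b in genotypes if a != b) / n
    counts: dict = {}
    for a, b in genotypes:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    p = np.array(list(counts.values()), dtype=float) / (2 * n)
    sum_p2 = float(np.sum(p ** 2))
    h_exp = (2 * n / (2 * n - 1)) * (1 - sum_p2)
    return h_obs, h_exp, 1.0 / sum_p2


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (conditional on allele counts)
# ---------------------------------------------------------------------------

def _log_table_prob(f: np.ndarray, n: int, allele_counts: np.ndarray) -> float:
    # P(table | allele counts) = n! prod(n_i!) 2^h / ((2n)! prod(f_ij!))
    h = int(np.sum(f) - np.trace(f))
    return (gammaln(n + 1) + np.sum(gammaln(allele_counts + 1))
            + h * np.log(2.0) - gammaln(2 * n + 1)
            - float(np.sum(gammaln(f + 1))))


def _enumerate_tables(allele_counts: np.ndarray, limit: int):
    """All genotype-count tables with the given allele counts, or None when
    a cheap upper bound says the space exceeds ``limit``."""
    k = len(allele_counts)
    c = allele_counts.astype(np.int64)
    bound = 1.0
    for i in range(k):
        for j in range(i, k):
            bound *= (min(c[i], c[j]) + 1)
            if bound > limit:
                return None
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    tables: list[np.ndarray] = []
    f = np.zeros((k, k), dtype=np.int64)

    def rec(ci: int, remaining: np.ndarray):
        if ci == len(cells):
            if np.all(remaining == 0):
                tables.append(f.copy())
            return
        i, j = cells[ci]
        max_v = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for v in range(int(max_v) + 1):
            f[i, j] = v
            r = remaining.copy()
            if i == j:
                r[i] -= 2 * v
            else:
                r[i] -= v
                r[j] -= v
            # once every cell of row i is fixed, allele i must be used up
            if j == k - 1 and r[i] != 0:
                continue
            rec(ci + 1, r)
        f[i, j] = 0

    rec(0, c.copy())
    return tables


def hwe_exact_test(genotype_counts: dict, mc_reps: int = 100_000,
                   seed: int = 0, enumeration_limit: int = 100_000) -> float:
    """Exact conditional Hardy-Weinberg test for multi-allelic data.

    ``genotype_counts`` maps unordered genotype (a, b) -> count. The test
    conditions on allele counts; p is the probability mass of tables no
    more probable than the observed one. Full enumeration is used when the
    configuration space is small, otherwise Monte-Carlo permutation of gene
    copies (``mc_reps`` shuffles, seeded) with the add-one correction.
    A monomorphic sample returns 1.0.
    """
    alleles = sorted({a for g in genotype_counts for a in g})
    k = len(alleles)
    if k <= 1:
        return 1.0
    idx = {a: i for i, a in enumerate(alleles)}
    f_obs = np.zeros((k, k), dtype=np.int64)
    for (a, b), c in genotype_counts.items():
        i, j = sorted((idx[a], idx[b]))
        f_obs[i, j] += c
    n = int(np.sum(f_obs))
    allele_counts = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i, k):
            allele_counts[i] += f_obs[i, j]
            allele_counts[j] += f_obs[i, j]
    lp_obs = _log_table_prob(f_obs, n, allele_counts)

    tables = _enumerate_tables(allele_counts, enumeration_limit)
    if tables is not None:
        lps = np.array([_log_table_prob(t, n, allele_counts) for t in tables])
        total = np.exp(lps - lps.max())
        mass = total[lps <= lp_obs + 1e-9].sum() / total.sum()
        return float(mass)

    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(k), allele_counts)
    hits = 0
    gl = gammaln(np.arange(2 * n + 2))   # lookup table for factorials
    const = (gammaln(n + 1) + np.sum(gammaln(allele_counts + 1))
             - gammaln(2 * n + 1))
    for _ in range(mc_reps):
        rng.shuffle(copies)
        pairs = copies.reshape(n, 2)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        codes = lo * k + hi
        fc = np.bincount(codes, minlength=k * k)
        het = int(np.sum(fc)) - int(np.sum(fc[np.arange(k) * k + np.arange(k)]))
        lp = const + het * np.log(2.0) - float(np.sum(gl[fc + 1]))
        if lp <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (mc_reps + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(deme_genotypes: list):
    """Per-allele Weir-Cockerham variance components a, b, c summed over
    alleles, for one locus across r demes."""
    r = len(deme_genotypes)
    ns = np.array([len(g) for g in deme_genotypes], dtype=float)
    if np.any(ns == 0) or r < 2:
        return 0.0, 0.0, 0.0
    alleles = sorted({a for g in deme_genotypes for pair in g for a in pair})
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p = np.array([sum((a == al) + (b == al) for a, b in g) / (2 * len(g))
                      for g in deme_genotypes])
        het = np.array([sum((a == al) != (b == al) for a, b in g) / len(g)
                        for g in deme_genotypes])
        pbar = float(np.sum(ns * p) / (r * nbar))
        s2 = float(np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(ns * het) / (r * nbar))
        a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar / 4) / (nbar - 1))
        b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4 * nbar))
        c_c = hbar / 2
        A += a_c
        B += b_c
        C += c_c
    return A, B, C


def fst_weir_cockerham(deme_genotypes: dict):
    """Pairwise Weir-Cockerham theta matrix over demes, multilocus.

    ``deme_genotypes`` maps deme -> {locus: [(a, b), ...]}. Components are
    summed over alleles and loci before the ratio (ratio-of-sums averaging);
    small negative estimates are reported as computed. Returns a DataFrame
    with the pairwise theta matrix; overall mean via ``.values``.
    """
    demes = sorted(deme_genotypes)
    if len(demes) < 2:
        raise ValueError("need >= 2 demes")
    theta = pd.DataFrame(np.nan, index=demes, columns=demes, dtype=float)
    for i, d1 in enumerate(demes):
        theta.loc[d1, d1] = 0.0
        for d2 in demes[i + 1:]:
            loci = sorted(set(deme_genotypes[d1]) & set(deme_genotypes[d2]))
            A = B = C = 0.0
            for locus in loci:
                a, b, c = _wc_components([deme_genotypes[d1][locus],
                                          deme_genotypes[d2][locus]])
                A += a
                B += b
                C += c
            denom = A + B + C
            val = A / denom if denom != 0 else np.nan
            theta.loc[d1, d2] = theta.loc[d2, d1] = val
    return theta


def mean_pairwise_fst(theta: pd.DataFrame) -> float:
    vals = theta.values[np.triu_indices(len(theta), 1)]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness
# ---------------------------------------------------------------------------

def relatedness_qg(gx: dict, gy: dict, freqs: dict) -> float:
    """Symmetrized Queller-Goodnight relatedness of two multilocus genotypes.

    ``gx``/``gy`` map locus -> (allele, allele); ``freqs`` maps locus ->
    {allele: frequency} from the pooled reference sample. Monomorphic loci
    are skipped.
    """
    def one_way(ga, gb):
        num = den = 0.0
        for locus, (a, b) in ga.items():
            if locus not in gb or locus not in freqs:
                continue
            f = freqs[locus]
            if len(f) < 2:
                continue
            c, d = gb[locus]
            pa, pb = f.get(a, 0.0), f.get(b, 0.0)
            num += 0.5 * ((a == c) + (a == d) + (b == c) + (b == d)) - pa - pb
            den += 1 + (a == b) - pa - pb
        return num, den

    n1, d1 = one_way(gx, gy)
    n2, d2 = one_way(gy, gx)
    if d1 + d2 == 0:
        return float("nan")
    return (n1 + n2) / (d1 + d2)


def average_relatedness(genotypes: dict, freqs: dict) -> float:
    """Mean Queller-Goodnight relatedness over all unordered pairs of a deme.

    ``genotypes`` maps individual -> {locus: (a, b)}.
    """
    inds = sorted(genotypes)
    vals = [relatedness_qg(genotypes[i], genotypes[j], freqs)
            for k, i in enumerate(inds) for j in inds[k + 1:]]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def pooled_frequencies(genotypes: dict) -> dict:
    """Allele frequencies per locus pooled over all individuals."""
    counts: dict = {}
    for g in genotypes.values():
        for locus, (a, b) in g.items():
            d = counts.setdefault(locus, {})
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
    return {locus: {a: c / sum(d.values()) for a, c in d.items()}
            for locus, d in counts.items()}


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_expected(copy_counts, n: int, bootstrap: int = 0,
                         seed: int = 0):
    """Expected number of distinct alleles in a random subsample of n copies.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] with N_i the copy count of
    allele i. With ``bootstrap`` > 0, a (2.5, 97.5)% interval from
    resampling the N copies with replacement is returned as well.
    """
    counts = np.asarray(list(copy_counts), dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside 1..{N}")

    def expected(cnts, ntot):
        with np.errstate(invalid="ignore"):
            log_keep = (gammaln(ntot - cnts + 1) - gammaln(ntot - cnts - n + 1)
                        - gammaln(ntot + 1) + gammaln(ntot - n + 1))
        miss = np.where(ntot - cnts >= n, np.exp(log_keep), 0.0)
        return float(np.sum(1.0 - miss))

    e = expected(counts, N)
    if bootstrap <= 0:
        return e
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    stats_ = np.empty(bootstrap)
    for b in range(bootstrap):
        res = rng.choice(pool, size=N, replace=True)
        cnts = np.bincount(res, minlength=len(counts))
        stats_[b] = expected(cnts[cnts > 0], N)
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return e, (float(lo), float(hi))


def rarefaction_curve(copy_counts, n_points: Optional[int] = None) -> pd.DataFrame:
    counts = [c for c in copy_counts if c > 0]
    N = int(sum(counts))
    ns = range(1, N + 1) if n_points is None else \
        np.unique(np.linspace(1, N, n_points).astype(int))
    rows = [(int(n), rarefaction_expected(counts, int(n))) for n in ns]
    return pd.DataFrame(rows, columns=["n", "expected_alleles"])


def final_third_slope(curve: pd.DataFrame) -> float:
    """Mean slope (alleles per sampled copy) over the final third of a
    rarefaction curve — the saturation measure."""
    n = curve["n"].to_numpy(dtype=float)
    e = curve["expected_alleles"].to_numpy(dtype=float)
    cut = n >= n.max() - (n.max() - n.min()) / 3.0
    if cut.sum() < 2:
        return 0.0
    res = stats.linregress(n[cut], e[cut])
    return float(res.slope)


# ---------------------------------------------------------------------------
# sharing classification and misc tests
# ---------------------------------------------------------------------------

@dataclass
class SharingReport:
    classes: dict                    # allele -> shared | region_specific
    demes_of: dict                   # allele -> sorted list of demes
    per_deme: pd.DataFrame           # deme rows with class counts
    single_deme: set                 # region-specific alleles in one deme


def classify_allele_sharing(observations: list,
                            survey_alleles: Optional[set] = None,
                            musculus_alleles: Optional[set] = None) -> SharingReport:
    """Shared vs region-specific classification of allele observations.

    ``observations`` is a list of (allele, deme, region) for every allele
    copy (or carrier) observed. An allele seen in >= 2 regions is shared,
    otherwise region-specific; region-specific alleles confined to a single
    deme are additionally flagged. Optional catalogs annotate presence in
    the species-wide survey / in musculus-labelled populations.
    """
    regions_of: dict = {}
    demes_of: dict = {}
    counts: dict = {}
    for allele, deme, region in observations:
        regions_of.setdefault(allele, set()).add(region)
        demes_of.setdefault(allele, set()).add(deme)
        counts[(allele, deme)] = counts.get((allele, deme), 0) + 1
    classes = {a: ("shared" if len(r) >= 2 else "region_specific")
               for a, r in regions_of.items()}
    single = {a for a, c in classes.items()
              if c == "region_specific" and len(demes_of[a]) == 1}
    demes = sorted({d for _a, d, _r in observations})
    rows = []
    for d in demes:
        row = {"deme": d,
               "n_shared": sum(1 for a in classes
                               if classes[a] == "shared" and d in demes_of[a]),
               "n_region_specific": sum(
                   1 for a in classes
                   if classes[a] == "region_specific" and d in demes_of[a])}
        if survey_alleles is not None:
            row["n_in_survey"] = sum(1 for a in classes
                                     if d in demes_of[a] and a in survey_alleles)
        if musculus_alleles is not None:
            row["n_in_musculus"] = sum(1 for a in classes
                                       if d in demes_of[a] and a in musculus_alleles)
        rows.append(row)
    return SharingReport(classes, {a: sorted(v) for a, v in demes_of.items()},
                         pd.DataFrame(rows), single)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 count table (method of small
    p-values)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def sample_size_correlation(n_per_deme, alleles_per_deme) -> float:
    """OLS R^2 of per-deme allele count on per-deme sample size."""
    x = np.asarray(n_per_deme, dtype=float)
    y = np.asarray(alleles_per_deme, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 demes")
    if np.var(x) == 0:
        raise ValueError("zero variance in sample sizes")
    if np.var(y) == 0:
        return 0.0
    r = stats.linregress(x, y)
    return float(r.rvalue ** 2)


def dloop_sharing(haplotypes: dict) -> dict:
    """mtDNA haplotype sharing summaries.

    ``haplotypes`` maps individual -> (haplotype, deme, region). Returns
    per-deme modal-haplotype fraction and counts of haplotypes shared
    across demes / across regions.
    """
    by_deme: dict = {}
    demes_of: dict = {}
    regions_of: dict = {}
    for _ind, (h, deme, region) in haplotypes.items():
        by_deme.setdefault(deme, []).append(h)
        demes_of.setdefault(h, set()).add(deme)
        regions_of.setdefault(h, set()).add(region)
    modal = {d: max(np.unique(hs, return_counts=True)[1]) / len(hs)
             for d, hs in by_deme.items()}
    return {
        "modal_fraction": {d: float(v) for d, v in modal.items()},
        "haplotypes_shared_across_demes": sum(
            1 for h, ds in demes_of.items() if len(ds) >= 2),
        "haplotypes_shared_across_regions": sum(
            1 for h, rs in regions_of.items() if len(rs) >= 2),
        "n_haplotypes": len(demes_of),
    }


def deme_summary(deme: str, genotypes: dict, freqs: dict, locus: str,
                 hwe_reps: int = 10_000, seed: int = 0):
    """One row of the per-deme summary table for one locus."""
    glist = [genotypes[i][locus] for i in sorted(genotypes)
             if locus in genotypes[i]]
    h_obs, h_exp, n_eff = heterozygosity_stats(glist)
    counts: dict = {}
    for a, b in glist:
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
    p = hwe_exact_test(counts, mc_reps=hwe_reps, seed=seed)
    rel = average_relatedness(
        {i: {locus: g[locus]} for i, g in genotypes.items() if locus in g},
        freqs)
    return {"deme": deme, "locus": locus, "n": len(glist), "h_obs": h_obs,
            "h_exp": h_exp, "n_eff_alleles": n_eff, "hwe_p": p,
            "relatedness_mean": rel}
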