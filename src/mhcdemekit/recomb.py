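"""Recombination and gene-conversion detection among aligned alleles.

Implements the Hudson-Kaplan four-gamete minimum number of recombination
events (Rm), a GENECONV-style search for gene-conversion fragments (runs of
matching polymorphic sites between a sequence pair — inner — or uniquely
differing in one sequence — outer) with a site-order permutation null and
Bonferroni correction, Kimura two-parameter distances, Nei-Gojobori dN/dS
with Jukes-Cantor correction, per-codon variability profiles against an
antigen-binding-site annotation, and the point-mutation waiting-time
expectation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class SiteMatrix:
    """Aligned equal-length sequences with their polymorphic site positions."""

    ids: list
    sequences: list

    def __post_init__(self):
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("sequences must be aligned to equal length")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must align")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def polymorphic_sites(self) -> list:
        sites = []
        for pos in range(self.length):
            if len({s[pos] for s in self.sequences}) >= 2:
                sites.append(pos)
        return sites

    def column(self, pos: int) -> list:
        return [s[pos] for s in self.sequences]


@dataclass
class GeneConversionFragment:
    kind: str                        # inner | outer
    seq1: str
    seq2: Optional[str]              # None for outer fragments
    begin: int                       # alignment positions (0-based, inclusive)
    end: int
    length: int                      # base pairs spanned
    score: int                       # run length in polymorphic sites
    sim_p: float
    corrected_p: float


@dataclass
class RecombinationReport:
    rm: int
    intervals: list
    fragments: list = field(default_factory=list)
    dn_ds: Optional[pd.DataFrame] = None
    k2p: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# four-gamete / Hudson-Kaplan Rm
# ---------------------------------------------------------------------------

def _four_gametes(col1: list, col2: list) -> bool:
    """All four gametes over any base pair at two sites."""
    gametes = set(zip(col1, col2))
    b1 = sorted({g[0] for g in gametes})
    b2 = sorted({g[1] for g in gametes})
    for i, x1 in enumerate(b1):
        for y1 in b1[i + 1:]:
            for j, x2 in enumerate(b2):
                for y2 in b2[j + 1:]:
                    if {(x1, x2), (x1, y2), (y1, x2), (y1, y2)} <= gametes:
                        return True
    return False


def incompatible_pairs(matrix: SiteMatrix) -> list:
    """Ordered polymorphic-site index pairs exhibiting all four gametes."""
    sites = matrix.polymorphic_sites
    cols = {p: matrix.column(p) for p in sites}
    out = []
    for i, p1 in enumerate(sites):
        for p2 in sites[i + 1:]:
            if _four_gametes(cols[p1], cols[p2]):
                out.append((p1, p2))
    return out


def four_gamete_rm(matrix: SiteMatrix):
    """Hudson-Kaplan minimum number of recombination events.

    Incompatible site pairs define open intervals that must each contain a
    recombination event; Rm is the size of a maximal set of pairwise
    disjoint intervals (intervals sharing only an endpoint do not overlap).
    Returns (rm, intervals).
    """
    if len(matrix.sequences) < 2:
        return 0, []
    pairs = incompatible_pairs(matrix)
    if not pairs:
        return 0, []
    # discard intervals that contain another interval, then greedy scan
    keep = [iv for iv in pairs
            if not any(o != iv and iv[0] <= o[0] and o[1] <= iv[1]
                       for o in pairs)]
    keep.sort(key=lambda iv: iv[1])
    chosen: list = []
    last_end = -1
    for a, b in keep:
        if a >= last_end:
            chosen.append((a, b))
            last_end = b
    return len(chosen), chosen


def rm_bruteforce(matrix: SiteMatrix) -> int:
    """Exhaustive maximum number of pairwise disjoint incompatible intervals
    (oracle for :func:`four_gamete_rm`)."""
    pairs = incompatible_pairs(matrix)

    def best(avail: list) -> int:
        if not avail:
            return 0
        top = 0
        for i, iv in enumerate(avail):
            rest = [o for o in avail[i + 1:] if o[0] >= iv[1] or o[1] <= iv[0]]
            top = max(top, 1 + best(rest))
        return top

    return best(pairs)


# ---------------------------------------------------------------------------
# GENECONV-style gene-conversion fragments
# ---------------------------------------------------------------------------

def _max_run_rows(mat: np.ndarray) -> np.ndarray:
    """Maximal run of True per row of a boolean matrix."""
    run = np.zeros(mat.shape[0], dtype=np.int64)
    best = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(mat.shape[1]):
        run = (run + 1) * mat[:, j]
        best = np.maximum(best, run)
    return best


def _runs_of(vec: np.ndarray) -> list:
    """(start_index, length) of maximal True runs in a boolean vector."""
    out = []
    start = None
    for i, v in enumerate(vec):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(vec) - start))
    return out


def _null_max_run(m: int, S: int, perm_idx: np.ndarray) -> np.ndarray:
    """Null distribution of the maximal run for a vector with ``m`` True
    among ``S`` sites, under shared site-order permutations."""
    base = np.zeros(S, dtype=bool)
    base[:m] = True
    return _max_run_rows(base[perm_idx])


def geneconv_fragments(matrix: SiteMatrix, kind: str = "both",
                       n_permutations: int = 10_000, seed: int = 0,
                       min_score: int = 2) -> list:
    """Candidate gene-conversion fragments with permutation p-values.

    On the polymorphic sites: an inner fragment is a maximal run of
    consecutive sites at which a sequence pair is identical; an outer
    fragment is a maximal run at which one sequence differs from every
    other sequence. Each pair (or sequence) contributes its best-scoring
    run; ``sim_p`` is the fraction of site-order permutations of that
    pair's match vector whose maximal run reaches the observed score
    (conditioning on the number of matching sites), with the add-one
    correction; ``corrected_p`` applies a Bonferroni factor equal to the
    number of pairs/sequences tested, capped at 1.
    """
    if kind not in ("inner", "outer", "both"):
        raise ValueError("kind must be inner, outer or both")
    sites = matrix.polymorphic_sites
    if not sites:
        return []
    S = len(sites)
    nseq = len(matrix.sequences)
    arr = np.array([[s[p] for p in sites] for s in matrix.sequences])
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, S)), axis=1)
    null_cache: dict[int, np.ndarray] = {}

    def sim_p_for(vec: np.ndarray, score: int) -> float:
        m = int(vec.sum())
        if m not in null_cache:
            null_cache[m] = _null_max_run(m, S, perm_idx)
        null = null_cache[m]
        return (int(np.sum(null >= score)) + 1) / (n_permutations + 1)

    fragments: list[GeneConversionFragment] = []
    # family-wise Bonferroni factor: every pair (inner) and sequence (outer)
    # tested in this call
    n_tested = 0
    if kind in ("inner", "both") and nseq >= 3:
        n_tested += nseq * (nseq - 1) // 2
    if kind in ("outer", "both") and nseq >= 2:
        n_tested += nseq

    if kind in ("inner", "both") and nseq >= 3:
        for i in range(nseq):
            for j in range(i + 1, nseq):
                match = arr[i] == arr[j]
                if match.all() or not match.any():
                    continue
                runs = _runs_of(match)
                start, length = max(runs, key=lambda r: r[1])
                if length < min_score:
                    continue
                p = sim_p_for(match, length)
                begin, endpos = sites[start], sites[start + length - 1]
                fragments.append(GeneConversionFragment(
                    "inner", matrix.ids[i], matrix.ids[j], begin, endpos,
                    endpos - begin + 1, length, p,
                    min(1.0, p * n_tested)))

    if kind in ("outer", "both") and nseq >= 2:
        for i in range(nseq):
            others = np.delete(arr, i, axis=0)
            unique = np.all(others != arr[i][None, :], axis=0)
            if not unique.any() or unique.all():
                continue
            runs = _runs_of(unique)
            start, length = max(runs, key=lambda r: r[1])
            if length < min_score:
                continue
            p = sim_p_for(unique, length)
            begin, endpos = sites[start], sites[start + length - 1]
            fragments.append(GeneConversionFragment(
                "outer", matrix.ids[i], None, begin, endpos,
                endpos - begin + 1, length, p, min(1.0, p * n_tested)))

    fragments.sort(key=lambda f: (f.sim_p, f.begin))
    return fragments


# ---------------------------------------------------------------------------
# distances and dN/dS
# ---------------------------------------------------------------------------

def kimura2p(seq1: str, seq2: str):
    """Kimura two-parameter distance; (distance, saturated_flag)."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be of equal length")
    pairs = [(a, b) for a, b in zip(seq1, seq2)
             if a in "ACGT" and b in "ACGT"]
    if not pairs:
        raise ValueError("no comparable positions")
    n = len(pairs)
    ts = sum(1 for a, b in pairs if (a, b) in TRANSITIONS)
    tv = sum(1 for a, b in pairs if a != b and (a, b) not in TRANSITIONS)
    P, Q = ts / n, tv / n
    x = 1 - 2 * P - Q
    y = 1 - 2 * Q
    if x <= 0 or y <= 0:
        return float("inf"), True
    return -0.5 * np.log(x) - 0.25 * np.log(y), False


def k2p_matrix(ids: list, seqs: list) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d, _sat = kimura2p(seqs[i], seqs[j])
            out.iloc[i, j] = out.iloc[j, i] = d
    return out


def _codon_syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3): at each position the
    fraction of the 3 possible changes that are synonymous; changes to stop
    codons count as non-synonymous."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if str(Seq(alt).translate()) == aa:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str):
    """Average synonymous/non-synonymous difference counts over all
    shortest mutational pathways between two codons, skipping pathways
    through stop codons."""
    from itertools import permutations
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = c1
        syn = nsyn = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if str(Seq(nxt).translate()) == "*":
                valid = False
                break
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if valid:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        # all pathways hit a stop: fall back to counting every change as
        # non-synonymous
        return 0.0, float(len(diff))
    return syn_tot / n_paths, nsyn_tot / n_paths


def dnds(seq1: str, seq2: str):
    """Nei-Gojobori dN and dS with Jukes-Cantor correction.

    Sequences must be codon-aligned (length a multiple of 3). Returns
    (dN, dS, ratio); the ratio is None (undefined) when dS = 0. Sequences
    with internal stop codons raise ValueError.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("need codon-aligned sequences of equal length")
    codons1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]
    for cs in (codons1, codons2):
        if any(str(Seq(c).translate()) == "*" for c in cs[:-1]):
            raise ValueError("internal stop codon")
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s1, s2 = _codon_syn_sites(c1), _codon_syn_sites(c2)
        S += (s1 + s2) / 2
        N += 3 - (s1 + s2) / 2
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return float("inf")
        return -0.75 * np.log(1 - 4 * p / 3)

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jc(pS), jc(pN)
    ratio = dN / dS if dS > 0 else None
    return dN, dS, ratio


def site_variability_profile(matrix: SiteMatrix, abs_codons: list,
                             frame: int = 0):
    """Per-codon count of distinct residues plus ABS enrichment summary.

    ``abs_codons`` lists 0-based codon indices annotated as antigen-binding
    sites. Returns (profile, summary) where profile maps codon index ->
    number of distinct amino acids and summary reports the fraction of
    variable codons inside vs outside the ABS list and their ratio.
    """
    if frame is None:
        raise ValueError("reading frame not configured")
    n_codons = (matrix.length - frame) // 3
    profile: dict[int, int] = {}
    for c in range(n_codons):
        lo = frame + 3 * c
        residues = {str(Seq(s[lo:lo + 3]).translate())
                    for s in matrix.sequences}
        profile[c] = len(residues)
    abs_set = {c for c in abs_codons if c in profile}
    inside = [c for c in profile if c in abs_set]
    outside = [c for c in profile if c not in abs_set]
    frac_in = (sum(profile[c] > 1 for c in inside) / len(inside)
               if inside else 0.0)
    frac_out = (sum(profile[c] > 1 for c in outside) / len(outside)
                if outside else 0.0)
    ratio = frac_in / frac_out if frac_out > 0 else float("inf")
    summary = {"frac_variable_abs": frac_in,
               "frac_variable_non_abs": frac_out,
               "enrichment_ratio": ratio}
    return profile, summary


# ---------------------------------------------------------------------------
# mutation waiting time
# ---------------------------------------------------------------------------

@dataclass
class MutationExpectation:
    mu: float
    L: int
    n_chrom: int

    @property
    def waiting_generations(self) -> float:
        return 1.0 / (self.mu * self.L * self.n_chrom)


def expected_mutation_waiting_time(mu: float, L: int,
                                   n_chrom: int) -> MutationExpectation:
    """Expected generations between new point mutations in a window of L bp
    across ``n_chrom`` chromosomes: 1 / (mu * L * n_chrom)."""
    if mu <= 0 or L <= 0 or n_chrom <= 0:
        raise ValueError("all arguments must be positive")
    return MutationExpectation(mu, L, n_chrom)
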