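"""Deme (sample-set-2) workflow: diploid genotype calling per individual.

Direct-sequencing consensi (IUPAC-coded, from double peaks) are phased by
catalog subtraction: every known allele consistent with the consensus
implies a complement allele, and a unique pair phases the individual.
Independently, Illumina-style reads (only individuals with > 5000 reads)
are clustered with a UPGMA tree cut into one or two read clusters, whose
majority consensi are the short-read alleles. The two routes are then
consolidated: agreement gives support "both"; a direct-only allele can be
rescued by finding it verbatim among the raw short reads; individuals with
no short-read verification and no known allele extractable from the direct
sequence are excluded as unphasable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seq import IUPAC2_REV, IUPAC_MULTI, decode, encode
from .core import AlleleCatalog, DirectRead, GenotypeCall
from .synthdata import IlluminaReadSet

TRIM_WINDOWS = {"H2-Aa": (0, 208), "H2-Eb": (0, 231)}


def detect_het_sites(direct: DirectRead):
    """Positions with two-base IUPAC codes and their base pairs.

    Returns (het_sites, unusable) where ``het_sites`` maps position ->
    (base, base) and ``unusable`` lists positions with >= 3-base ambiguity
    codes.
    """
    het: dict[int, tuple] = {}
    unusable: list[int] = []
    for pos, ch in enumerate(direct.sequence):
        if ch in IUPAC2_REV:
            het[pos] = IUPAC2_REV[ch]
        elif ch in IUPAC_MULTI:
            unusable.append(pos)
    return het, unusable


@dataclass
class PhasingResult:
    status: str                      # phased | homozygous | ambiguous | unphased
    pairs: list = field(default_factory=list)   # [(seq_a, seq_b), ...]

    @property
    def alleles(self) -> Optional[tuple]:
        return self.pairs[0] if self.status in ("phased", "homozygous") else None


def _consistent(allele: str, direct_seq: str, het: dict) -> bool:
    if len(allele) != len(direct_seq):
        return False
    for pos, ch in enumerate(direct_seq):
        a = allele[pos]
        if pos in het:
            if a not in het[pos]:
                return False
        elif ch in "ACGT" and a != ch:
            return False
        # >=3-base ambiguity positions constrain nothing
    return True


def subtract_complement(allele: str, direct_seq: str, het: dict) -> str:
    """The complement haplotype: at each het site take the other base."""
    out = list(allele)
    for pos, (b1, b2) in het.items():
        out[pos] = b2 if allele[pos] == b1 else b1
    return "".join(out)


def phase_against_catalog(direct: DirectRead, catalog: AlleleCatalog):
    """Enumerate catalog-consistent allele pairs for an IUPAC consensus.

    Every catalog allele consistent with the consensus yields the pair
    (allele, complement-by-subtraction). A unique pair phases the
    individual; zero het sites give a homozygous pair; several distinct
    pairs are ambiguous unless a consistent major/minor peak orientation
    singles one out; no consistent known allele with >= 2 het sites is
    unphased.
    """
    het, unusable = detect_het_sites(direct)
    if unusable:
        return PhasingResult("unphased")
    if not het:
        return PhasingResult("homozygous", [(direct.sequence, direct.sequence)])
    if len(het) == 1:
        # a single double peak phases trivially
        pos = next(iter(het))
        b1, b2 = het[pos]
        s = list(direct.sequence)
        s[pos] = b1
        a = "".join(s)
        s[pos] = b2
        return PhasingResult("phased", [(a, "".join(s))])

    pairs: list[tuple] = []
    seen: set = set()
    for entry in catalog.by_locus(direct.locus):
        if not _consistent(entry.sequence, direct.sequence, het):
            continue
        comp = subtract_complement(entry.sequence, direct.sequence, het)
        key = frozenset((entry.sequence, comp))
        if key not in seen:
            seen.add(key)
            pairs.append((entry.sequence, comp))
    if not pairs:
        return PhasingResult("unphased")
    if len(pairs) == 1:
        return PhasingResult("phased", pairs)
    if direct.peaks:
        # peak-ratio tiebreak: keep pairs in which one haplotype carries the
        # major base at every het site
        majors = {pos: mb for pos, (mb, _r) in direct.peaks.items()}
        kept = []
        for a, b in pairs:
            for hap, other in ((a, b), (b, a)):
                if all(hap[pos] == mb for pos, mb in majors.items()):
                    kept.append((hap, other))
                    break
        if len(kept) == 1:
            return PhasingResult("phased", kept)
        if kept:
            return PhasingResult("ambiguous", kept)
    return PhasingResult("ambiguous", pairs)


# ---------------------------------------------------------------------------
# short-read (Illumina-style) calling
# ---------------------------------------------------------------------------

@dataclass
class ShortReadCall:
    alleles: list                    # 1 or 2 consensus sequences
    cluster_sizes: list
    n_reads: int


def _as_matrix(reads, reference: Optional[str] = None):
    if isinstance(reads, IlluminaReadSet):
        return reads.matrix
    if isinstance(reads, np.ndarray):
        return reads
    seqs = [r.sequence if hasattr(r, "sequence") else str(r) for r in reads]
    if reference is not None:
        seqs = [s for s in seqs if len(s) == len(reference)]
    elif seqs:
        want = len(seqs[0])
        seqs = [s for s in seqs if len(s) == want]
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.stack([encode(s) for s in seqs])


def _consensus(mat: np.ndarray) -> str:
    cols = np.apply_along_axis(np.bincount, 0, mat, minlength=5)
    return decode(np.argmax(cols[:4], axis=0))


def shortread_call(reads, min_reads: int = 5000, max_sample: int = 500,
                   separation_factor: float = 3.0, minor_fraction: float = 0.02,
                   seed: int = 0, reference: Optional[str] = None):
    """UPGMA 1-vs-2 cluster decision and per-cluster consensus.

    Individuals with <= ``min_reads`` reads are not called. Reads (matrix,
    IlluminaReadSet or sequence list; unalignable lengths discarded) are
    subsampled to ``max_sample``, all-pairs Hamming distances feed a UPGMA
    tree whose root is cut in two; two alleles are reported when the
    between-cluster mean distance exceeds ``separation_factor`` times the
    within-cluster mean and the minor cluster holds >= ``minor_fraction``
    of the reads (after nearest-consensus reassignment of all reads).
    Deterministic given ``seed``.
    """
    mat = _as_matrix(reads, reference)
    if mat.shape[0] <= min_reads:
        return None
    if mat.size == 0:
        return None
    rng = np.random.default_rng(seed)
    if mat.shape[0] > max_sample:
        idx = rng.choice(mat.shape[0], size=max_sample, replace=False)
        sub = mat[idx]
    else:
        sub = mat
    n = sub.shape[0]
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    condensed = squareform(diff, checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=2, criterion="maxclust")
    g1, g2 = sub[labels == 1], sub[labels == 2]

    def mean_within(g):
        if g.shape[0] < 2:
            return 0.0
        d = (g[:, None, :] != g[None, :, :]).sum(axis=2)
        return float(d[np.triu_indices(g.shape[0], 1)].mean())

    two = False
    if g1.shape[0] and g2.shape[0]:
        between = float((g1[:, None, :] != g2[None, :, :]).sum(axis=2).mean())
        within = (mean_within(g1) + mean_within(g2)) / 2.0
        two = between > separation_factor * within
    if two:
        c1, c2 = encode(_consensus(g1)), encode(_consensus(g2))
        d1 = (mat != c1[None, :]).sum(axis=1)
        d2 = (mat != c2[None, :]).sum(axis=1)
        assign = d2 < d1
        n2 = int(assign.sum())
        frac_minor = min(n2, mat.shape[0] - n2) / mat.shape[0]
        if frac_minor >= minor_fraction and 0 < n2 < mat.shape[0]:
            cons1 = _consensus(mat[~assign])
            cons2 = _consensus(mat[assign])
            if cons1 != cons2:
                sizes = sorted([mat.shape[0] - n2, n2], reverse=True)
                alleles = [cons1, cons2] if n2 <= mat.shape[0] - n2 else [cons2, cons1]
                return ShortReadCall(alleles, sizes, mat.shape[0])
    return ShortReadCall([_consensus(mat)], [mat.shape[0]], mat.shape[0])


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def count_exact_reads(allele: str, reads) -> int:
    """Number of raw short reads identical to ``allele``."""
    if isinstance(reads, IlluminaReadSet):
        return reads.count_exact(allele)
    mat = _as_matrix(reads)
    enc = encode(allele)
    if mat.size == 0 or mat.shape[1] != len(enc):
        return 0
    return int(np.sum(np.all(mat == enc[None, :], axis=1)))


def consolidate_calls(individual: str, locus: str,
                      direct_result: Optional[PhasingResult],
                      shortread_result: Optional[ShortReadCall],
                      raw_short_reads=None,
                      catalog: Optional[AlleleCatalog] = None,
                      rescue_min_reads: int = 10) -> GenotypeCall:
    """Merge direct-sequencing and short-read calls into one GenotypeCall.

    Alleles present in both routes get support "both". A direct-only allele
    found verbatim in >= ``rescue_min_reads`` raw short reads is promoted
    to "both" (rescue of a poorly amplified allele); otherwise it keeps
    "direct_only". Short-read-only alleles keep "shortread_only". With no
    usable short reads and no known catalog allele in the direct phasing,
    the individual is excluded ("unphasable"); full disagreement without
    rescue is excluded ("conflict").
    """
    direct_pair = direct_result.alleles if direct_result else None
    short = list(shortread_result.alleles) if shortread_result else None
    if direct_pair is None and short is None:
        return GenotypeCall(individual, locus, excluded=True, reason="unphasable")

    if direct_pair is None:
        if len(short) == 1:
            alleles = (short[0], short[0])
        else:
            alleles = tuple(short[:2])
        return GenotypeCall(individual, locus, alleles,
                            {a: "shortread_only" for a in set(alleles)})

    direct_set = set(direct_pair)
    if short is None:
        known = bool(catalog) and any(
            catalog.lookup(locus, a) is not None for a in direct_set)
        if not known:
            return GenotypeCall(individual, locus, excluded=True,
                                reason="unphasable")
        support = {}
        for a in direct_set:
            n = count_exact_reads(a, raw_short_reads) if raw_short_reads is not None else 0
            support[a] = "both" if n >= rescue_min_reads else "direct_only"
        return GenotypeCall(individual, locus, tuple(direct_pair), support)

    short_set = set(short)
    support: dict[str, str] = {}
    for a in direct_set:
        if a in short_set:
            support[a] = "both"
        elif raw_short_reads is not None and \
                count_exact_reads(a, raw_short_reads) >= rescue_min_reads:
            support[a] = "both"          # rescued: poorly amplified allele
        else:
            support[a] = "direct_only"

    if not any(v == "both" for v in support.values()):
        return GenotypeCall(individual, locus, excluded=True, reason="conflict")

    if len(direct_set) == 2:
        # heterozygous direct call wins; extra short-read alleles dropped
        return GenotypeCall(individual, locus, tuple(direct_pair), support)
    # direct looked homozygous; a second short-read cluster reveals the
    # poorly amplified allele
    a = direct_pair[0]
    others = [b for b in short if b != a]
    if others:
        support[others[0]] = "shortread_only"
        return GenotypeCall(individual, locus, (a, others[0]),
                            {k: v for k, v in support.items()
                             if k in (a, others[0])})
    return GenotypeCall(individual, locus, (a, a), {a: support[a]})


def trim_to_common_length(alleles: list, locus: str,
                          windows: Optional[dict] = None):
    """Trim alleles to the locus comparison window (208 bp H2-Aa, 231 bp
    H2-Eb); post-trim duplicates are merged and logged.

    Returns (trimmed_unique, merge_log, excluded) — ``excluded`` lists
    alleles shorter than the window.
    """
    windows = windows or TRIM_WINDOWS
    if locus not in windows:
        raise ValueError(f"no trim window configured for locus {locus}")
    start, length = windows[locus]
    out: list[str] = []
    merge_log: list[tuple] = []
    excluded: list[str] = []
    seen: dict[str, int] = {}
    for a in alleles:
        if len(a) < start + length:
            excluded.append(a)
            continue
        t = a[start:start + length]
        if t in seen:
            merge_log.append((a, t))
        else:
            seen[t] = len(out)
            out.append(t)
    return out, merge_log, excluded


# ---------------------------------------------------------------------------
# per-dataset driver
# ---------------------------------------------------------------------------

def run_deme_typing(direct_reads: dict, illumina: dict,
                    catalog: AlleleCatalog, min_reads: int = 5000,
                    max_sample: int = 500, separation_factor: float = 3.0,
                    minor_fraction: float = 0.02, rescue_min_reads: int = 10,
                    seed: int = 0) -> list:
    """Call genotypes for every (individual, locus) with both data routes.

    ``direct_reads`` maps (individual, locus) -> DirectRead; ``illumina``
    maps the same keys to read sets (may miss keys).
    """
    import zlib
    calls = []
    for key in sorted(set(direct_reads) | set(illumina)):
        ind, locus = key
        direct = direct_reads.get(key)
        reads = illumina.get(key)
        phased = phase_against_catalog(direct, catalog) if direct else None
        sub_seed = zlib.crc32(f"{seed}:{ind}:{locus}".encode()) % (2 ** 31)
        src = shortread_call(reads, min_reads, max_sample, separation_factor,
                             minor_fraction, seed=sub_seed) \
            if reads is not None else None
        calls.append(consolidate_calls(ind, locus, phased, src, reads,
                                       catalog, rescue_min_reads))
    return calls
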