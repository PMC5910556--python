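"""Survey (sample-set-1) workflow: 454-style read processing and allele validation.

Reads are quality-filtered, demultiplexed by exact 10-bp MID tags, trimmed
of primers and intron margins, assigned to a locus by best identity against
reference sequences, corrected for platform-typical homopolymer indels
against an aligned reference, and condensed into candidate alleles. A
candidate is validated when the identical sequence occurs in at least two
independent amplifications with different primer pairs within one
individual, or in two different individuals, and at least two unedited raw
reads confirm it. Validated alleles are classified as known/new and
normal/silent/non-functional.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp, translate
from .core import AlleleCatalog, CandidateAllele, CatalogEntry, SequencingRead


# ---------------------------------------------------------------------------
# read filtering and trimming
# ---------------------------------------------------------------------------

def quality_filter(reads: list, min_avg_q: float = 25.0,
                   min_len: int = 200) -> list:
    """Retain reads with mean quality > ``min_avg_q`` (strict), length >
    ``min_len`` (strict) and no 'N' bases; order preserved."""
    return [r for r in reads
            if len(r.sequence) > min_len
            and r.mean_quality > min_avg_q
            and "N" not in r.sequence]


@dataclass
class TrimmedRead:
    individual: str
    locus: str
    primer_pair: str
    amplification: str
    sequence: str
    qualities: np.ndarray
    orientation: str


def demultiplex_and_trim(read: SequencingRead, mids: dict, primers: dict,
                         intron_margins: Optional[dict] = None):
    """Assign a read to its individual by exact MID match and trim to exon.

    ``mids`` maps 10-bp MID tag -> individual; ``primers`` maps
    (locus, primer_pair) -> (forward, reverse) primer sequences;
    ``intron_margins`` maps locus -> (left, right) bases to drop next to the
    primers. Orientation is detected by MID match on the read or its
    reverse complement. Returns a :class:`TrimmedRead` or ``(None, reason)``
    for the unassigned bin. Matching is exact: a 1-mismatch MID is
    unassigned.
    """
    if not mids or not primers:
        raise ValueError("MID and primer tables must be non-empty")
    intron_margins = intron_margins or {}
    mid_len = len(next(iter(mids)))
    seq, quals, orientation = read.sequence, read.qualities, "forward"
    if seq[:mid_len] not in mids:
        seq, quals = revcomp(seq), read.qualities[::-1]
        orientation = "reverse"
        if seq[:mid_len] not in mids:
            return None, "no_mid_match"
    individual = mids[seq[:mid_len]]
    rest = seq[mid_len:]
    for (locus, pp), (fwd, rev) in primers.items():
        if not rest.startswith(fwd):
            continue
        tail = revcomp(rev)
        idx = rest.rfind(tail)
        if idx <= len(fwd):
            return None, "no_primer_suffix"
        left, right = intron_margins.get(locus, (0, 0))
        lo = len(fwd) + left
        hi = idx - right
        if hi <= lo:
            return None, "empty_after_trim"
        exon = rest[lo:hi]
        q = np.asarray(quals[mid_len + lo: mid_len + hi])
        return TrimmedRead(individual, locus, pp, f"{locus}:{pp}", exon, q,
                           orientation), None
    return None, "no_primer_match"


def assign_locus(sequence: str, references: dict, identity_margin: float = 0.02,
                 identity_floor: float = 0.8):
    """Locus of the best-identity reference, with a paralog-ambiguity flag.

    ``references`` maps locus -> list of reference sequences. Returns
    (locus, ambiguous) — ``(None, False)`` when the best identity is below
    ``identity_floor``; ``ambiguous`` is set when the best and second-best
    loci are closer than ``identity_margin`` in identity.
    """
    if not references or not any(references.values()):
        raise ValueError("reference catalog needs >= 1 sequence per locus")
    best: dict[str, float] = {}
    for locus, refs in references.items():
        for ref in refs:
            d = edlib.align(sequence, ref, mode="NW", task="distance")["editDistance"]
            ident = 1.0 - d / max(len(sequence), len(ref))
            if ident > best.get(locus, -1.0):
                best[locus] = ident
    ranked = sorted(best.items(), key=lambda kv: -kv[1])
    top_locus, top_ident = ranked[0]
    if top_ident < identity_floor:
        return None, False
    ambiguous = len(ranked) > 1 and (top_ident - ranked[1][1]) < identity_margin
    return top_locus, ambiguous


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    out = np.empty(len(seq), dtype=np.int32)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def _make_aligner():
    # gaps are far costlier than mismatches: the reference may be tens of
    # substitutions away from the read's allele, and clusters of divergent
    # sites must never be realized as compensating indel pairs
    from Bio.Align import PairwiseAligner
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 0.0
    a.mismatch_score = -1.0
    a.open_gap_score = -4.5
    a.extend_gap_score = -4.5
    return a


_ALIGNER = _make_aligner()


def correct_homopolymer_errors(sequence: str, reference: str):
    """Close/expand single-base gaps inside reference homopolymer runs.

    The read is globally aligned to the reference; a 1-bp insertion or
    deletion whose base falls in a reference homopolymer run of length >= 3
    is reverted to the reference run length. Substitutions are never
    altered. Returns (corrected_sequence, edit_log, full_length_ok) —
    ``full_length_ok`` is False when gaps that the rule does not cover
    remain (such reads are dropped from full-length allele support).
    """
    if len(sequence) == len(reference):
        # gapless by construction: substitutions only, nothing to correct
        return sequence, [], True
    aln = _ALIGNER.align(reference, sequence)[0]
    t_blocks, q_blocks = aln.aligned
    runs = _run_lengths(reference)
    out: list[str] = []
    edits: list[tuple] = []
    ok = True
    tpos = qpos = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        tgap = ts - tpos
        qgap = qs - qpos
        if tgap and qgap:
            out.append(sequence[qpos:qs])   # unalignable stretch: keep as-is
            ok = False
        elif qgap:                          # extra base(s) in read
            base = sequence[qpos]
            near_run = (
                (ts < len(reference) and reference[ts] == base and runs[ts] >= 3)
                or (tpos > 0 and reference[tpos - 1] == base
                    and runs[tpos - 1] >= 3)
                or (tpos < len(reference) and reference[tpos] == base
                    and runs[tpos] >= 3))
            if qgap == 1 and near_run:
                edits.append(("del_inserted", qpos, base))
            else:
                out.append(sequence[qpos:qs])
                ok = False
        elif tgap:                          # base(s) missing from read
            base = reference[tpos]
            if tgap == 1 and runs[tpos] >= 3:
                out.append(base)
                edits.append(("restore_deleted", qpos, base))
            else:
                ok = False
        out.append(sequence[qs:qe])
        tpos, qpos = te, qe
    # trailing gaps
    if qpos < len(sequence):
        out.append(sequence[qpos:])
        ok = False
    if tpos < len(reference):
        if len(reference) - tpos == 1 and runs[tpos] >= 3:
            out.append(reference[tpos])
            edits.append(("restore_deleted", qpos, reference[tpos]))
        else:
            ok = False
    return "".join(out), edits, ok


# ---------------------------------------------------------------------------
# candidate building and validation
# ---------------------------------------------------------------------------

def build_candidates(trimmed_reads: list, references: dict,
                     identity_margin: float = 0.02,
                     identity_floor: float = 0.8):
    """Group corrected full-length reads into candidate alleles.

    Reads are locus-assigned, homopolymer-corrected against their closest
    reference, and grouped by identical corrected sequence. Raw-read counts
    record how many unedited trimmed reads match each candidate exactly.
    Returns (candidates, skipped) where skipped maps reason -> count.
    """
    skipped: dict[str, int] = {}
    raw_counts: dict[tuple, int] = {}
    raw_by_ind: dict[tuple, dict] = {}
    cands: dict[tuple, CandidateAllele] = {}
    ref_len = {loc: len(refs[0]) for loc, refs in references.items() if refs}
    for tr in trimmed_reads:
        key_raw = (tr.locus if tr.locus else "", tr.sequence)
        locus, ambiguous = assign_locus(tr.sequence, references,
                                        identity_margin, identity_floor)
        if locus is None:
            skipped["unassigned_locus"] = skipped.get("unassigned_locus", 0) + 1
            continue
        if ambiguous:
            skipped["ambiguous_locus"] = skipped.get("ambiguous_locus", 0) + 1
            continue
        refs = references[locus]
        dists = [edlib.align(tr.sequence, ref, mode="NW",
                             task="distance")["editDistance"] for ref in refs]
        ref = refs[int(np.argmin(dists))]
        corrected, _edits, ok = correct_homopolymer_errors(tr.sequence, ref)
        raw_key = (locus, tr.sequence)
        raw_counts[raw_key] = raw_counts.get(raw_key, 0) + 1
        d = raw_by_ind.setdefault(raw_key, {})
        d[tr.individual] = d.get(tr.individual, 0) + 1
        if not ok or len(corrected) != ref_len.get(locus, len(ref)):
            skipped["not_full_length"] = skipped.get("not_full_length", 0) + 1
            continue
        if "N" in corrected:
            skipped["ambiguity_in_read"] = skipped.get("ambiguity_in_read", 0) + 1
            continue
        key = (locus, corrected)
        c = cands.get(key)
        if c is None:
            c = cands[key] = CandidateAllele(corrected, locus)
        c.support.add((tr.individual, tr.primer_pair, tr.amplification))
        c.read_count += 1
        c.reads_by_individual[tr.individual] = (
            c.reads_by_individual.get(tr.individual, 0) + 1)
    for (locus, seq), c in cands.items():
        c.raw_read_count = raw_counts.get((locus, seq), 0)
        c.raw_by_individual = dict(raw_by_ind.get((locus, seq), {}))
    return list(cands.values()), skipped


def is_single_switch_hybrid(seq: str, parent_a: str, parent_b: str) -> bool:
    """True when ``seq`` equals a single-crossover hybrid of the two parents
    (and is not identical to either parent)."""
    if len(seq) != len(parent_a) or len(seq) != len(parent_b):
        return False
    if seq == parent_a or seq == parent_b:
        return False
    n = len(seq)
    for a, b in ((parent_a, parent_b), (parent_b, parent_a)):
        pre = 0
        while pre < n and seq[pre] == a[pre]:
            pre += 1
        suf = 0
        while suf < n and seq[n - 1 - suf] == b[n - 1 - suf]:
            suf += 1
        if pre + suf >= n:
            return True
    return False


def _passes_support(c: CandidateAllele) -> bool:
    pps = c.primer_pairs_by_individual
    within = any(len(v) >= 2 for v in pps.values())
    across = len(pps) >= 2
    return within or across


def validate_alleles(candidates: list, min_raw_reads: int = 2,
                     chimera_screen: bool = True):
    """Apply the reliability rules; returns (accepted, rejected).

    A candidate is accepted iff it occurs in >= 2 amplifications with
    distinct primer pairs within one individual OR in >= 2 distinct
    individuals, AND >= ``min_raw_reads`` unedited raw reads match it
    exactly. With ``chimera_screen`` on, support from an individual is
    discarded when that individual already carries two better-supported
    validated alleles whose single-crossover hybrid the candidate is —
    in a diploid a PCR chimera always co-occurs with both of its parents,
    while a true recombinant allele cannot. ``rejected`` carries the failed
    criterion per candidate.
    """
    def base_ok(c):
        return _passes_support(c) and c.raw_read_count >= min_raw_reads

    if chimera_screen:
        by_ind: dict[tuple, list] = {}
        for c in candidates:
            for ind in c.reads_by_individual:
                by_ind.setdefault((ind, c.locus), []).append(c)
        for (ind, _locus), cs in by_ind.items():
            # in a diploid, a chimera co-occurs with both of its parents and
            # the dominant allele always out-amplifies it: take the top
            # candidate as one parent and flag any candidate that some other
            # supported candidate completes as a single-crossover hybrid
            ranked = sorted(
                cs, key=lambda c: (-c.reads_by_individual.get(ind, 0),
                                   -c.read_count, c.sequence))
            if len(ranked) < 2:
                continue
            g1 = ranked[0]
            partners = [x for x in ranked[1:]
                        if x.reads_by_individual.get(ind, 0) >= 2]
            for c in ranked[1:]:
                if any(x is not c and is_single_switch_hybrid(
                        c.sequence, g1.sequence, x.sequence)
                       for x in partners):
                    c.support = {t for t in c.support if t[0] != ind}
                    c.read_count -= c.reads_by_individual.pop(ind, 0)
                    c.raw_read_count -= c.raw_by_individual.pop(ind, 0)

    accepted, rejected = [], []
    for c in candidates:
        if not c.support:
            rejected.append((c, "chimera_screen"))
        elif not _passes_support(c):
            rejected.append((c, "independence"))
        elif c.raw_read_count < min_raw_reads:
            rejected.append((c, "raw_read_support"))
        else:
            accepted.append(c)
    return accepted, rejected


# ---------------------------------------------------------------------------
# classification and survey summaries
# ---------------------------------------------------------------------------

def classify_allele(sequence: str, locus: str, known: AlleleCatalog,
                    frame: Optional[int] = 0,
                    reference_length: Optional[int] = None):
    """Status (known/new) and functional class of a validated allele.

    non_functional: premature stop codon, or a length change that is not a
    multiple of 3 relative to the reference window (frame shift). silent:
    encodes a protein identical to a different catalog allele of the locus.
    """
    if frame is None:
        raise ValueError(f"reading frame not configured for locus {locus}")
    entry = known.lookup(locus, sequence)
    status = "known" if entry is not None else "new"
    if reference_length is not None and (len(sequence) - reference_length) % 3 != 0:
        return status, "non_functional"
    prot = translate(sequence, frame)
    if "*" in prot:
        return status, "non_functional"
    for other in known.by_locus(locus):
        if other.sequence != sequence and translate(other.sequence, frame) == prot:
            return status, "silent"
    return status, "normal"


def catalog_from_candidates(accepted: list, known: AlleleCatalog,
                            frames: Optional[dict] = None,
                            populations: Optional[dict] = None) -> AlleleCatalog:
    """Build the validated-allele catalog (ids ``LOCUS-NNN``) from accepted
    candidates, classifying each against the known catalog.

    ``populations`` maps individual -> population label, used to record the
    populations each allele was observed in.
    """
    frames = frames or {}
    catalog = AlleleCatalog()
    for c in sorted(accepted, key=lambda c: (c.locus, -c.read_count, c.sequence)):
        status, fclass = classify_allele(
            c.sequence, c.locus, known, frames.get(c.locus, 0))
        pops = set()
        if populations:
            pops = {populations.get(i, "?") for i in c.individuals}
        catalog.new_entry(c.locus, c.sequence, status=status,
                          functional_class=fclass, populations=pops)
    return catalog


def summarize_survey(catalog: AlleleCatalog, genotypes: dict,
                     populations: dict, subspecies: Optional[dict] = None):
    """Survey tables: per-locus totals and fractions, per-population counts
    and private alleles, cross-subspecies sharing, multi-allele flags.

    ``genotypes`` maps individual -> {locus: set of allele ids observed};
    individuals with more than two alleles at a locus are flagged and that
    individual x locus is excluded from genotype-level totals.
    """
    subspecies = subspecies or {}
    flags = [(ind, locus, len(aids))
             for ind, by_locus in genotypes.items()
             for locus, aids in by_locus.items() if len(aids) > 2]
    flagged = {(ind, locus) for ind, locus, _ in flags}

    rows = []
    loci = sorted({e.locus for e in catalog})
    for locus in loci:
        entries = catalog.by_locus(locus)
        n = len(entries)
        rows.append({
            "locus": locus, "total": n,
            "frac_new": sum(e.status == "new" for e in entries) / n if n else 0.0,
            "frac_silent": sum(e.functional_class == "silent" for e in entries) / n if n else 0.0,
            "frac_non_functional": sum(e.functional_class == "non_functional"
                                       for e in entries) / n if n else 0.0})
    per_locus = pd.DataFrame(rows)

    pop_of = populations
    obs: dict[tuple, set] = {}   # (locus, allele_id) -> populations observed
    for ind, by_locus in genotypes.items():
        for locus, aids in by_locus.items():
            if (ind, locus) in flagged:
                continue
            for aid in aids:
                obs.setdefault((locus, aid), set()).add(pop_of.get(ind, "?"))
    rows = []
    all_pops = sorted(set(pop_of.values()))
    for locus in loci:
        for pop in all_pops:
            present = {aid for (loc, aid), ps in obs.items()
                       if loc == locus and pop in ps}
            private = {aid for aid in present
                       if obs[(locus, aid)] == {pop}}
            rows.append({"locus": locus, "population": pop,
                         "n_alleles": len(present), "n_private": len(private)})
    per_population = pd.DataFrame(rows)

    rows = []
    for locus in loci:
        shared = 0
        for (loc, aid), ps in obs.items():
            if loc != locus:
                continue
            subs = {subspecies.get(p, p) for p in ps}
            if len(subs) >= 2:
                shared += 1
        rows.append({"locus": locus, "shared_across_subspecies": shared})
    cross = pd.DataFrame(rows)

    return {"per_locus": per_locus, "per_population": per_population,
            "cross_subspecies": cross,
            "multi_allele_flags": pd.DataFrame(
                flags, columns=["individual", "locus", "n_alleles"])}


# ---------------------------------------------------------------------------
# convenience: full survey calling from raw reads
# ---------------------------------------------------------------------------

@dataclass
class SurveyCallResult:
    catalog: AlleleCatalog
    accepted: list
    rejected: list
    genotypes: dict
    stats: dict = field(default_factory=dict)


def run_survey_calling(reads: list, mids: dict, primers: dict,
                       references: dict, known: Optional[AlleleCatalog] = None,
                       intron_margins: Optional[dict] = None,
                       min_avg_q: float = 25.0, min_len: int = 200,
                       min_raw_reads: int = 2, identity_margin: float = 0.02,
                       chimera_screen: bool = True,
                       populations: Optional[dict] = None) -> SurveyCallResult:
    """Raw reads -> validated, classified allele catalog (filter ledger in
    ``stats``)."""
    known = known or AlleleCatalog()
    stats = {"reads_in": len(reads)}
    passed = quality_filter(reads, min_avg_q, min_len)
    stats["reads_quality_pass"] = len(passed)
    trimmed = []
    unassigned: dict[str, int] = {}
    for r in passed:
        tr, reason = demultiplex_and_trim(r, mids, primers, intron_margins)
        if tr is None:
            unassigned[reason] = unassigned.get(reason, 0) + 1
        else:
            trimmed.append(tr)
    stats["reads_trimmed"] = len(trimmed)
    stats["unassigned"] = unassigned
    candidates, skipped = build_candidates(trimmed, references, identity_margin)
    stats["candidates"] = len(candidates)
    stats["skipped"] = skipped
    accepted, rejected = validate_alleles(candidates, min_raw_reads,
                                          chimera_screen)
    stats["accepted"] = len(accepted)
    stats["rejected"] = len(rejected)
    catalog = catalog_from_candidates(accepted, known, populations=populations)
    genotypes: dict[str, dict] = {}
    for c in accepted:
        entry = catalog.lookup(c.locus, c.sequence)
        for ind in c.individuals:
            genotypes.setdefault(ind, {}).setdefault(c.locus, set()).add(
                entry.allele_id)
    return SurveyCallResult(catalog, accepted, rejected, genotypes, stats)
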