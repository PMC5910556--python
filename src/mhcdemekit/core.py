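"""Shared domain types for the amplicon-genotyping and deme-analysis stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SequencingRead:
    """One sequencing read with platform tag and amplification provenance.

    ``platform`` is ``"long-amplicon"`` (454-style) or ``"short-read"``
    (Illumina-style). Provenance identifies the template molecule pool the
    read came from: individual, primer pair and independent amplification.
    """

    id: str
    sequence: str
    qualities: np.ndarray
    platform: str
    individual: str
    primer_pair: str
    amplification: str

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must equal sequence length")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if len(self.qualities) else 0.0


@dataclass
class CandidateAllele:
    """A trimmed exon sequence with the provenance triples supporting it."""

    sequence: str
    locus: str
    support: set = field(default_factory=set)  # (individual, primer_pair, amplification)
    raw_read_count: int = 0
    read_count: int = 0  # corrected reads matching, all provenance
    reads_by_individual: dict = field(default_factory=dict)
    raw_by_individual: dict = field(default_factory=dict)

    @property
    def individuals(self) -> set:
        return {t[0] for t in self.support}

    @property
    def primer_pairs_by_individual(self) -> dict:
        out: dict[str, set] = {}
        for ind, pp, _amp in self.support:
            out.setdefault(ind, set()).add(pp)
        return out


@dataclass
class CatalogEntry:
    allele_id: str
    locus: str
    sequence: str
    status: str = "new"            # known | new
    functional_class: str = "normal"  # normal | silent | non_functional
    populations: set = field(default_factory=set)


class AlleleCatalog:
    """Per-locus registry of validated allele sequences.

    (locus, sequence) pairs are unique; entries are retrievable by id or
    by sequence.
    """

    def __init__(self, entries: Optional[list[CatalogEntry]] = None):
        self.entries: list[CatalogEntry] = []
        self._by_seq: dict[tuple[str, str], CatalogEntry] = {}
        self._by_id: dict[str, CatalogEntry] = {}
        for e in entries or []:
            self.add(e)

    def add(self, entry: CatalogEntry) -> CatalogEntry:
        key = (entry.locus, entry.sequence)
        if key in self._by_seq:
            return self._by_seq[key]
        self.entries.append(entry)
        self._by_seq[key] = entry
        self._by_id[entry.allele_id] = entry
        return entry

    def new_entry(self, locus: str, sequence: str, **kw) -> CatalogEntry:
        key = (locus, sequence)
        if key in self._by_seq:
            return self._by_seq[key]
        n = sum(1 for e in self.entries if e.locus == locus) + 1
        return self.add(CatalogEntry(f"{locus}-{n:03d}", locus, sequence, **kw))

    def lookup(self, locus: str, sequence: str) -> Optional[CatalogEntry]:
        return self._by_seq.get((locus, sequence))

    def get(self, allele_id: str) -> Optional[CatalogEntry]:
        return self._by_id.get(allele_id)

    def by_locus(self, locus: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.locus == locus]

    def sequences(self, locus: str) -> list[str]:
        return [e.sequence for e in self.by_locus(locus)]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, locus_seq: tuple[str, str]):
        return locus_seq in self._by_seq


@dataclass
class DirectRead:
    """Unphased diploid direct-sequencing consensus, IUPAC-coded.

    ``peaks`` maps heterozygous 0-based positions to ``(major_base, ratio)``
    — the taller chromatogram peak and the major:minor peak-height ratio.
    """

    individual: str
    locus: str
    sequence: str
    peaks: dict = field(default_factory=dict)


@dataclass
class GenotypeCall:
    """Diploid call for one individual at one locus.

    ``support`` maps each called allele sequence to one of
    ``both`` / ``direct_only`` / ``shortread_only``.
    """

    individual: str
    locus: str
    alleles: tuple = ()
    support: dict = field(default_factory=dict)
    excluded: bool = False
    reason: str = ""

    @property
    def support_tier(self) -> str:
        """Weakest per-allele support tier of an included call."""
        if self.excluded or not self.alleles:
            return "none"
        tiers = {self.support.get(a, "none") for a in set(self.alleles)}
        for t in ("none", "direct_only", "shortread_only"):
            if t in tiers:
                return t
        return "both"
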