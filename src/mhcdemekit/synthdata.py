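"""Synthetic metapopulation and amplicon-sequencing simulator.

Generates the full study design in silico: demes of related individuals
(extended family groups founded by a few mating pairs), a pool of widely
shared ancestral MHC alleles plus rare region-specific recombinant alleles,
PCR chimera artifacts, platform-specific sequencing errors, unequal allele
amplification, and matrilineally structured neutral markers (microsatellites
and an mtDNA haplotype). Every downstream stage can therefore be tested
against exact ground truth.

Random streams are per-purpose (pedigree, alleles, errors, chimeras, ...),
spawned from the master seed, so changing one rate does not perturb
unrelated draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._seq import (
    BASES,
    decode,
    encode,
    has_internal_stop,
    random_coding_seq,
    random_seq,
    revcomp,
)
from .core import DirectRead, SequencingRead


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic metapopulation + sequencing experiment.

    Counts are >= 1, probabilities lie in [0, 1] and exon windows are the
    study's trimmed lengths (H2-Aa 208 bp, H2-Eb 231 bp) by default.
    Identical config + seed reproduces every output byte-identically.
    """

    n_regions: int = 2
    demes_per_region: int = 5
    individuals_per_deme: tuple = (6, 14)
    n_ancestral_alleles: int = 12
    loci: dict = field(default_factory=lambda: {"H2-Aa": 208, "H2-Eb": 231})
    mutations_per_allele: tuple = (5, 9)
    regional_freq_concentration: float = 3.0
    recombinant_rate: float = 0.6
    recombinants_per_deme: tuple = (1, 2)
    conversion_tract_length: tuple = (20, 100)
    migration_rate: float = 0.03
    # --- 454-style survey sequencing ---
    chimera_rate: float = 0.1
    homopolymer_indel_rate: float = 0.02
    substitution_error_rate: float = 0.0001
    n_emission_rate: float = 0.02         # bad-quality base becomes 'N'
    low_quality_read_rate: float = 0.05
    truncation_rate: float = 0.03
    amplification_bias_range: tuple = (1.0, 5.0)
    reads_per_individual: tuple = (80, 120)
    n_primer_pairs: int = 4
    # --- Sanger surrogate + Illumina-style sequencing ---
    illumina_reads_per_individual: tuple = (5200, 7000)
    illumina_error_rate: float = 0.001
    dropout_bias: float = 9.0             # minor allele hidden in direct read
    # --- neutral markers ---
    microsat_loci: int = 10
    microsat_mutation_rate: float = 0.005
    n_msat_founder_alleles: int = 6
    n_mtdna_haplotypes: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "recombinant_rate", "migration_rate", "chimera_rate",
            "homopolymer_indel_rate", "substitution_error_rate",
            "n_emission_rate", "low_quality_read_rate", "truncation_rate",
            "illumina_error_rate", "microsat_mutation_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        for name in (
            "n_regions", "demes_per_region", "n_ancestral_alleles",
            "microsat_loci", "n_primer_pairs", "n_mtdna_haplotypes",
            "n_msat_founder_alleles",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.loci:
            raise ConfigurationError("at least one locus required")
        for locus, length in self.loci.items():
            if length < 208:
                raise ConfigurationError(
                    f"locus {locus}: window {length} < 208 bp")
        if self.n_ancestral_alleles < 2:
            raise ConfigurationError("allele pool needs >= 2 ancestral alleles")
        if self.individuals_per_deme[0] < 2:
            raise ConfigurationError("demes need >= 2 individuals")

    def rng_streams(self) -> dict:
        names = ("alleles", "pedigree", "recombinants", "migration",
                 "markers", "chimeras", "errors", "illumina", "design")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TrueAllele:
    id: str
    locus: str
    sequence: str
    class_label: str                 # shared | region_specific
    origin_region: Optional[str] = None
    origin_deme: Optional[str] = None
    donors: Optional[tuple] = None
    event: Optional[str] = None      # crossover | conversion
    breakpoints: Optional[tuple] = None


@dataclass
class Individual:
    id: str
    deme: str
    region: str
    sex: str
    mother: Optional[str] = None
    father: Optional[str] = None
    natal_deme: str = ""
    genotypes: dict = field(default_factory=dict)   # locus -> (allele_id, allele_id)
    microsats: dict = field(default_factory=dict)   # msat locus -> (int, int)
    mtdna: str = ""


@dataclass
class MetapopTruth:
    """Ground truth of a simulated metapopulation."""

    config: SimConfig
    alleles: dict                      # locus -> {allele_id: TrueAllele}
    individuals: list
    events: list = field(default_factory=list)

    def allele_seq(self, locus: str, allele_id: str) -> str:
        return self.alleles[locus][allele_id].sequence

    def genotype_seqs(self, ind: Individual, locus: str) -> tuple:
        a, b = ind.genotypes[locus]
        return self.allele_seq(locus, a), self.allele_seq(locus, b)

    def by_deme(self) -> dict:
        out: dict[str, list] = {}
        for ind in self.individuals:
            out.setdefault(ind.deme, []).append(ind)
        return out

    def carriers(self, locus: str, allele_id: str) -> list:
        return [i for i in self.individuals if allele_id in i.genotypes[locus]]


# ---------------------------------------------------------------------------
# allele-level primitives
# ---------------------------------------------------------------------------

def generate_recombinant_allele(donor1: str, donor2: str, breakpoint: int) -> str:
    """Single-crossover product ``donor1[:breakpoint] + donor2[breakpoint:]``."""
    if len(donor1) != len(donor2):
        raise ValueError("donor sequences must be of equal length")
    if not 0 <= breakpoint <= len(donor1):
        raise ValueError("breakpoint out of bounds")
    return donor1[:breakpoint] + donor2[breakpoint:]


def apply_conversion_tract(recipient: str, donor: str, start: int, length: int) -> str:
    """Replace ``recipient[start:start+length]`` with the donor's tract."""
    if len(recipient) != len(donor):
        raise ValueError("sequences must be of equal length")
    if start < 0 or length < 0 or start + length > len(recipient):
        raise ValueError("conversion tract exceeds sequence bounds")
    return recipient[:start] + donor[start:start + length] + recipient[start + length:]


def _ancestral_pool(config: SimConfig, rng: np.random.Generator) -> dict:
    """Ancestral allele pool per locus, generated along a genealogy.

    Each new allele derives from a randomly chosen existing allele by
    mutating a handful of previously unmutated positions (infinite-sites
    style), so the ancestral pool itself is tree-compatible and carries no
    four-gamete signal — recombination signal downstream comes from the
    recombinant alleles the demes create.
    """
    pool: dict[str, dict[str, TrueAllele]] = {}
    lo_m, hi_m = config.mutations_per_allele
    for locus, length in config.loci.items():
        base = random_coding_seq(length, rng)
        site_order = list(rng.permutation(length))
        cursor = 0
        seen = {base}
        seqs = [base]
        alleles: dict[str, TrueAllele] = {}
        aid = f"{locus}*anc01"
        alleles[aid] = TrueAllele(aid, locus, base, "shared")
        k = 1
        attempts = 0
        while k < config.n_ancestral_alleles:
            attempts += 1
            if attempts > 500 * config.n_ancestral_alleles:
                raise ConfigurationError(
                    f"cannot generate {config.n_ancestral_alleles} distinct "
                    f"stop-free alleles for locus {locus}")
            parent = seqs[int(rng.integers(len(seqs)))]
            n_mut = int(rng.integers(lo_m, hi_m + 1))
            s = list(parent)
            for _ in range(n_mut):
                if cursor >= len(site_order):   # finite exon: reuse positions
                    site_order = list(rng.permutation(length))
                    cursor = 0
                pos = site_order[cursor]
                cursor += 1
                s[pos] = rng.choice([b for b in BASES if b != s[pos]])
            seq = "".join(s)
            if seq in seen or has_internal_stop(seq):
                continue
            seen.add(seq)
            seqs.append(seq)
            k += 1
            aid = f"{locus}*anc{k:02d}"
            alleles[aid] = TrueAllele(aid, locus, seq, "shared")
        pool[locus] = alleles
    return pool


# ---------------------------------------------------------------------------
# metapopulation pedigree
# ---------------------------------------------------------------------------

def simulate_metapopulation(config: SimConfig) -> MetapopTruth:
    """Draw a metapopulation of extended family groups with ground truth.

    Each deme is founded by 1-3 mating pairs plus one to two generations of
    offspring, yielding elevated within-deme relatedness. Shared alleles are
    drawn from a species-wide ancestral pool; with probability
    ``recombinant_rate`` a deme receives novel recombinant (crossover or
    gene-conversion) alleles confined, bar migration, to that deme.
    """
    config.validate()
    streams = config.rng_streams()
    rng_all = streams["alleles"]
    rng_ped = streams["pedigree"]
    rng_rec = streams["recombinants"]
    rng_mig = streams["migration"]

    alleles = _ancestral_pool(config, rng_all)
    all_seqs = {loc: {a.sequence for a in d.values()} for loc, d in alleles.items()}
    events: list[dict] = []
    individuals: list[Individual] = []

    lo, hi = config.individuals_per_deme
    for r in range(config.n_regions):
        region = f"R{r + 1}"
        # skewed regional allele frequencies: a few common, many rare
        region_freqs = {}
        for locus in config.loci:
            ids = sorted(a for a, v in alleles[locus].items()
                         if v.class_label == "shared")
            alpha = np.full(len(ids), config.regional_freq_concentration)
            region_freqs[locus] = (ids, rng_ped.dirichlet(alpha))
        for d in range(config.demes_per_region):
            deme = f"{region}D{d + 1}"
            n_target = int(rng_ped.integers(lo, hi + 1))
            n_pairs = int(rng_ped.integers(1, 4))
            n_founders = min(2 * n_pairs, n_target)
            n_pairs = max(1, n_founders // 2)

            founders: list[Individual] = []
            for p in range(n_pairs):
                for sex in ("F", "M"):
                    iid = f"{deme}-I{len(founders) + 1:02d}"
                    ind = Individual(iid, deme, region, sex, natal_deme=deme)
                    for locus in config.loci:
                        ids, freqs = region_freqs[locus]
                        ind.genotypes[locus] = tuple(
                            rng_ped.choice(ids, size=2, replace=True, p=freqs))
                    founders.append(ind)

            # region-specific recombinant alleles; placed into random deme
            # members after breeding so they stay at low copy number
            pending_recombinants: list[tuple] = []
            if rng_rec.random() < config.recombinant_rate:
                k = int(rng_rec.integers(config.recombinants_per_deme[0],
                                         config.recombinants_per_deme[1] + 1))
                for _ in range(k):
                    locus = str(rng_rec.choice(list(config.loci)))
                    length = config.loci[locus]
                    donor_ids = list(rng_rec.choice(
                        [a for a in alleles[locus]
                         if alleles[locus][a].class_label == "shared"],
                        size=2, replace=False))
                    d1 = alleles[locus][donor_ids[0]].sequence
                    d2 = alleles[locus][donor_ids[1]].sequence
                    seq = None
                    event = None
                    bkp = None
                    for _try in range(30):
                        if rng_rec.random() < 0.5:
                            event = "crossover"
                            b = int(rng_rec.integers(15, length - 15))
                            cand = generate_recombinant_allele(d1, d2, b)
                            bkp = (b,)
                        else:
                            event = "conversion"
                            tlo, thi = config.conversion_tract_length
                            tlen = int(rng_rec.integers(tlo, thi + 1))
                            start = int(rng_rec.integers(0, length - tlen + 1))
                            cand = apply_conversion_tract(d1, d2, start, tlen)
                            bkp = (start, start + tlen)
                        if cand not in all_seqs[locus] and not has_internal_stop(cand):
                            seq = cand
                            break
                    if seq is None:
                        continue
                    n_rec = sum(1 for a in alleles[locus].values()
                                if a.class_label == "region_specific")
                    aid = f"{locus}*rec{n_rec + 1:02d}"
                    alleles[locus][aid] = TrueAllele(
                        aid, locus, seq, "region_specific", origin_region=region,
                        origin_deme=deme, donors=tuple(donor_ids), event=event,
                        breakpoints=bkp)
                    all_seqs[locus].add(seq)
                    events.append({"type": event, "locus": locus, "allele": aid,
                                   "deme": deme, "donors": tuple(donor_ids),
                                   "breakpoints": bkp})
                    pending_recombinants.append((locus, aid))

            members = list(founders)
            pairs = [(founders[2 * p], founders[2 * p + 1])
                     for p in range(n_pairs)]
            gen1: list[Individual] = []
            while len(members) < n_target:
                # second generation once enough gen-1 animals of both sexes exist
                g1f = [i for i in gen1 if i.sex == "F"]
                g1m = [i for i in gen1 if i.sex == "M"]
                if g1f and g1m and len(gen1) >= 4 and rng_ped.random() < 0.3:
                    mother = g1f[int(rng_ped.integers(len(g1f)))]
                    father = g1m[int(rng_ped.integers(len(g1m)))]
                else:
                    mother, father = pairs[int(rng_ped.integers(len(pairs)))]
                iid = f"{deme}-I{len(members) + 1:02d}"
                child = Individual(
                    iid, deme, region, "F" if rng_ped.random() < 0.5 else "M",
                    mother=mother.id, father=father.id, natal_deme=deme)
                for locus in config.loci:
                    ma = mother.genotypes[locus][int(rng_ped.integers(2))]
                    pa = father.genotypes[locus][int(rng_ped.integers(2))]
                    child.genotypes[locus] = (ma, pa)
                members.append(child)
                if child.mother == mother.id and mother in founders:
                    gen1.append(child)
            for locus, aid in pending_recombinants:
                n_copies = 1 if rng_rec.random() < 0.7 else 2
                hosts = rng_rec.choice(len(members),
                                       size=min(n_copies, len(members)),
                                       replace=False)
                for h in np.atleast_1d(hosts):
                    host = members[int(h)]
                    g = list(host.genotypes[locus])
                    g[int(rng_rec.integers(2))] = aid
                    host.genotypes[locus] = tuple(g)
            individuals.extend(members)

    simulate_neutral_markers(config, individuals, streams["markers"])

    # migration: relabel a few animals into another deme (mostly within region)
    demes = sorted({i.deme for i in individuals})
    for ind in individuals:
        if rng_mig.random() < config.migration_rate:
            same_region = [d for d in demes
                           if d.startswith(ind.region) and d != ind.deme]
            other = [d for d in demes if not d.startswith(ind.region)]
            if same_region and (not other or rng_mig.random() < 0.8):
                target = str(rng_mig.choice(same_region))
            elif other:
                target = str(rng_mig.choice(other))
            else:
                continue
            ind.deme = target
            ind.region = target.split("D")[0]

    return MetapopTruth(config, alleles, individuals, events)


def simulate_neutral_markers(config: SimConfig, individuals: list,
                             rng: np.random.Generator) -> None:
    """Microsatellites (stepwise mutation along the pedigree) and mtDNA.

    Founders draw microsatellite alleles from a regional founder pool and
    founding females draw an mtDNA haplotype from a regional haplotype pool;
    offspring inherit Mendelianly (with stepwise microsatellite mutation)
    and matrilineally. Operates on individuals in pedigree order (parents
    precede offspring).
    """
    regions = sorted({i.natal_deme.split("D")[0] for i in individuals})
    msat_pools = {}
    mt_pools = {}
    for region in regions:
        msat_pools[region] = {
            m: list(100 + 2 * rng.integers(0, 40, size=config.n_msat_founder_alleles))
            for m in range(config.microsat_loci)}
        mt_pools[region] = [f"{region}-H{h + 1}" for h in range(config.n_mtdna_haplotypes)]

    by_id = {i.id: i for i in individuals}
    for ind in individuals:
        region = ind.natal_deme.split("D")[0]
        if ind.mother is None:  # founder
            for m in range(config.microsat_loci):
                pool = msat_pools[region][m]
                ind.microsats[m] = (int(rng.choice(pool)), int(rng.choice(pool)))
            ind.mtdna = str(rng.choice(mt_pools[region]))
        else:
            mother = by_id[ind.mother]
            father = by_id[ind.father]
            for m in range(config.microsat_loci):
                a = mother.microsats[m][int(rng.integers(2))]
                b = father.microsats[m][int(rng.integers(2))]
                if rng.random() < config.microsat_mutation_rate:
                    a += 2 if rng.random() < 0.5 else -2
                if rng.random() < config.microsat_mutation_rate:
                    b += 2 if rng.random() < 0.5 else -2
                ind.microsats[m] = (int(a), int(b))
            ind.mtdna = mother.mtdna


# ---------------------------------------------------------------------------
# PCR and sequencing
# ---------------------------------------------------------------------------

@dataclass
class Template:
    sequence: str
    source: str                      # allele1 | allele2 | chimera
    switch_point: Optional[int] = None
    orientation: Optional[str] = None  # chimera prefix donor: '12' or '21'


def simulate_pcr_amplicons(genotype: tuple, chimera_rate: float, bias: float,
                           n_templates: int, rng: np.random.Generator) -> list:
    """Template molecules of one amplification.

    Templates are drawn from the two alleles at ratio ``bias``:1; a
    ``chimera_rate`` fraction are single-switch-point chimeras (an
    incompletely extended strand re-priming on the other allele), with the
    switch point uniform over the amplicon. Chimeric templates are labelled
    in the returned metadata even when sequence-identical to a parent
    (homozygotes).
    """
    a1, a2 = genotype
    if len(a1) != len(a2):
        raise ValueError("genotype alleles must have equal trimmed length")
    p1 = bias / (1.0 + bias)
    out: list[Template] = []
    for _ in range(n_templates):
        if rng.random() < chimera_rate:
            sp = int(rng.integers(1, len(a1)))
            if rng.random() < p1:
                seq, orient = a1[:sp] + a2[sp:], "12"
            else:
                seq, orient = a2[:sp] + a1[sp:], "21"
            out.append(Template(seq, "chimera", sp, orient))
        else:
            if rng.random() < p1:
                out.append(Template(a1, "allele1"))
            else:
                out.append(Template(a2, "allele2"))
    return out


DEFAULT_QUALITY_MODEL = {"q_good": 38, "q_bad": 12, "p_bad": 0.02,
                         "p_bad_lowq": 0.7}


def _draw_qualities(n: int, rng: np.random.Generator, low_quality: bool,
                    model: dict) -> np.ndarray:
    p_bad = model["p_bad_lowq"] if low_quality else model["p_bad"]
    bad = rng.random(n) < p_bad
    q = np.where(bad, model["q_bad"], model["q_good"]).astype(np.int16)
    return q


def apply_454_errors(sequence: str, homopolymer_indel_rate: float,
                     substitution_error_rate: float,
                     rng: np.random.Generator,
                     n_emission_rate: float = 0.0,
                     low_quality: bool = False,
                     quality_model: dict = DEFAULT_QUALITY_MODEL):
    """One 454-style read of a template: homopolymer indels per run of
    length >= 3, per-base substitutions, and per-base two-state qualities
    (bad-quality bases may be emitted as 'N'). Returns (seq, qualities,
    n_indels, n_subs)."""
    s = list(sequence)
    n_subs = 0
    if substitution_error_rate > 0:
        for pos in np.nonzero(rng.random(len(s)) < substitution_error_rate)[0]:
            s[pos] = rng.choice([b for b in BASES if b != s[pos]])
            n_subs += 1
    # homopolymer runs are found on the template so coordinates are stable;
    # indels applied right-to-left
    runs = []
    i = 0
    while i < len(sequence):
        j = i
        while j < len(sequence) and sequence[j] == sequence[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, j - i, sequence[i]))
        i = j
    n_indels = 0
    for start, length, base in reversed(runs):
        if rng.random() < homopolymer_indel_rate:
            n_indels += 1
            if rng.random() < 0.5:
                s.insert(start, base)
            else:
                del s[start]
    quals = _draw_qualities(len(s), rng, low_quality, quality_model)
    if n_emission_rate > 0:
        bad = quals == quality_model["q_bad"]
        to_n = bad & (rng.random(len(s)) < n_emission_rate)
        for pos in np.nonzero(to_n)[0]:
            s[pos] = "N"
    return "".join(s), quals, n_indels, n_subs


def simulate_reads_454(templates: list, homopolymer_indel_rate: float,
                       substitution_error_rate: float,
                       rng: np.random.Generator,
                       quality_model: dict = DEFAULT_QUALITY_MODEL,
                       individual: str = "NA", primer_pair: str = "pp1",
                       amplification: str = "amp1") -> list:
    """454-style reads, one per template, with provenance attached."""
    if not templates:
        raise ValueError("templates must be non-empty")
    reads = []
    for k, t in enumerate(templates):
        seq = t.sequence if isinstance(t, Template) else t
        s, q, _ni, _ns = apply_454_errors(
            seq, homopolymer_indel_rate, substitution_error_rate, rng,
            quality_model=quality_model)
        reads.append(SequencingRead(
            f"{individual}|{primer_pair}|{amplification}#{k}", s, q,
            "long-amplicon", individual, primer_pair, amplification))
    return reads


@dataclass
class IlluminaReadSet:
    """Short reads of one individual x locus as an encoded base matrix."""

    individual: str
    locus: str
    matrix: np.ndarray               # (n_reads, window) uint8
    true_sources: np.ndarray         # 0/1 template allele index per read

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def sequences(self) -> list:
        return [decode(row) for row in self.matrix]

    def count_exact(self, sequence: str) -> int:
        """Number of reads identical to ``sequence``."""
        enc = encode(sequence)
        if self.matrix.shape[1] != len(enc):
            return 0
        return int(np.sum(np.all(self.matrix == enc[None, :], axis=1)))


def simulate_direct_and_illumina(genotype: tuple, bias: float,
                                 illumina_error_rate: float, n_reads: int,
                                 rng: np.random.Generator,
                                 dropout_bias: float = 9.0,
                                 individual: str = "NA", locus: str = "NA"):
    """Direct-sequencing surrogate plus Illumina-style short reads.

    The direct read is the position-wise IUPAC consensus of the two alleles
    with per-site peak metadata (major base = the better-amplified allele's
    base, ratio = ``bias``). At ``bias >= dropout_bias`` the minor allele
    drops out of the consensus entirely, emulating poor amplification of one
    allele; the short-read pool still contains minor-allele reads at
    frequency 1/(1+bias).
    """
    a1, a2 = genotype
    if len(a1) != len(a2):
        raise ValueError("genotype alleles must have equal trimmed length")
    from ._seq import IUPAC2
    peaks = {}
    if bias >= dropout_bias:
        consensus = a1  # a1 is the major allele by convention
    else:
        chars = []
        for pos, (x, y) in enumerate(zip(a1, a2)):
            if x == y:
                chars.append(x)
            else:
                chars.append(IUPAC2[frozenset((x, y))])
                peaks[pos] = (x, bias)
        consensus = "".join(chars)
    direct = DirectRead(individual, locus, consensus, peaks)

    p1 = bias / (1.0 + bias)
    sources = (rng.random(n_reads) >= p1).astype(np.int8)  # 0 -> a1, 1 -> a2
    enc = np.stack([encode(a1), encode(a2)])
    mat = enc[sources]
    if illumina_error_rate > 0:
        err = rng.random(mat.shape) < illumina_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        mat[err] = (mat[err] + shift) % 4
    return direct, IlluminaReadSet(individual, locus, mat, sources)


# ---------------------------------------------------------------------------
# full survey dataset (raw 454 reads with MIDs/primers) and deme dataset
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# alignment generators for the gene-conversion detection benchmark
# ---------------------------------------------------------------------------

def simulate_haplogroup_alignment(rng: np.random.Generator, n_seqs: int = 8,
                                  length: int = 300, n_group_sites: int = 50,
                                  private_mutations: int = 2):
    """Two divergent haplogroups of alleles (infinite-sites style).

    The two group ancestors differ at ``n_group_sites`` positions; each
    sequence adds a few private mutations at fresh positions. Returns
    (ids, sequences, group_labels, group_site_positions).
    """
    base = random_seq(length, rng)
    positions = list(rng.permutation(length))
    group_sites = sorted(positions[:n_group_sites])
    cursor = n_group_sites
    anc2 = list(base)
    for pos in group_sites:
        anc2[pos] = rng.choice([b for b in BASES if b != base[pos]])
    ancestors = [base, "".join(anc2)]
    ids, seqs, groups = [], [], []
    for i in range(n_seqs):
        g = i % 2
        s = list(ancestors[g])
        for _ in range(private_mutations):
            if cursor >= len(positions):
                break
            pos = positions[cursor]
            cursor += 1
            s[pos] = rng.choice([b for b in BASES if b != s[pos]])
        ids.append(f"g{g + 1}-{i // 2 + 1}")
        seqs.append("".join(s))
        groups.append(g)
    return ids, seqs, groups, group_sites


def implant_conversion_tract(seqs: list, groups: list, group_sites: list,
                             tract_sites: int, rng: np.random.Generator):
    """Copy a donor tract spanning ``tract_sites`` group-difference sites
    from a group-2 donor into a group-1 recipient.

    Returns (new_seqs, recipient_index, donor_index, (start, end)) with the
    tract bounds in alignment coordinates (inclusive).
    """
    recipients = [i for i, g in enumerate(groups) if g == 0]
    donors = [i for i, g in enumerate(groups) if g == 1]
    rec = int(rng.choice(recipients))
    don = int(rng.choice(donors))
    first = int(rng.integers(0, len(group_sites) - tract_sites + 1))
    start = group_sites[first]
    end = group_sites[first + tract_sites - 1]
    converted = apply_conversion_tract(seqs[rec], seqs[don], start,
                                       end - start + 1)
    out = list(seqs)
    out[rec] = converted
    return out, rec, don, (start, end)


def simulate_independent_sites_alignment(rng: np.random.Generator,
                                         n_seqs: int = 20, length: int = 300,
                                         n_poly: int = 60):
    """Null alignment with independent polymorphic sites (two equifrequent
    bases drawn independently per sequence per site)."""
    base = random_seq(length, rng)
    positions = sorted(rng.choice(length, size=n_poly, replace=False))
    seqs = [list(base) for _ in range(n_seqs)]
    for pos in positions:
        b1 = base[pos]
        b2 = rng.choice([b for b in BASES if b != b1])
        draws = rng.random(n_seqs) < 0.5
        for i in range(n_seqs):
            seqs[i][pos] = b2 if draws[i] else b1
    ids = [f"s{i + 1}" for i in range(n_seqs)]
    return ids, ["".join(s) for s in seqs]


@dataclass
class SurveyDesign:
    mids: dict                        # individual -> 10-bp MID
    primers: dict                     # (locus, primer_pair) -> (fwd, rev)
    intron_margins: dict              # locus -> (left, right)

    def mid_table(self) -> dict:
        return {mid: ind for ind, mid in self.mids.items()}


def _unique_tags(n: int, length: int, rng: np.random.Generator) -> list:
    tags: list[str] = []
    seen = set()
    while len(tags) < n:
        t = "".join(rng.choice(list(BASES), size=length))
        if t not in seen:
            seen.add(t)
            tags.append(t)
    return tags


def make_survey_design(truth: MetapopTruth, rng: np.random.Generator) -> SurveyDesign:
    inds = [i.id for i in truth.individuals]
    mids = dict(zip(inds, _unique_tags(len(inds), 10, rng)))
    primers = {}
    for locus in truth.config.loci:
        for p in range(truth.config.n_primer_pairs):
            primers[(locus, f"pp{p + 1}")] = (
                "".join(rng.choice(list(BASES), size=20)),
                "".join(rng.choice(list(BASES), size=20)))
    margins = {locus: (0, 0) for locus in truth.config.loci}
    return SurveyDesign(mids, primers, margins)


@dataclass
class SurveyDataset:
    truth: MetapopTruth
    design: SurveyDesign
    reads: list                       # raw SequencingRead (MID+primer+exon)
    read_truth: dict                  # read id -> template source metadata


def simulate_survey_dataset(truth: MetapopTruth,
                            rng_design: Optional[np.random.Generator] = None,
                            rng_chim: Optional[np.random.Generator] = None,
                            rng_err: Optional[np.random.Generator] = None) -> SurveyDataset:
    """454-style survey reads for every individual and locus.

    Raw reads carry MID + forward primer + exon + reverse-complemented
    reverse primer; half are emitted reverse-complemented. Sequencing errors
    (including 'N' emission), low-quality reads and truncations affect the
    exon insert; provenance and chimera status are recorded per read.
    """
    config = truth.config
    streams = config.rng_streams()
    rng_design = rng_design or streams["design"]
    rng_chim = rng_chim or streams["chimeras"]
    rng_err = rng_err or streams["errors"]

    design = make_survey_design(truth, rng_design)
    reads: list[SequencingRead] = []
    read_truth: dict[str, dict] = {}
    qm = DEFAULT_QUALITY_MODEL
    for ind in truth.individuals:
        mid = design.mids[ind.id]
        for locus in config.loci:
            g = truth.genotype_seqs(ind, locus)
            bias = rng_chim.uniform(*config.amplification_bias_range)
            total = int(rng_chim.integers(*config.reads_per_individual))
            per_amp = np.full(config.n_primer_pairs,
                              total // config.n_primer_pairs)
            per_amp[: total % config.n_primer_pairs] += 1
            for p, n_amp in enumerate(per_amp):
                pp = f"pp{p + 1}"
                amp = f"{locus}:{pp}"
                fwd, rev = design.primers[(locus, pp)]
                templates = simulate_pcr_amplicons(
                    g, config.chimera_rate, bias, int(n_amp), rng_chim)
                for k, t in enumerate(templates):
                    low_q = rng_err.random() < config.low_quality_read_rate
                    exon, equal_q, n_ind, n_sub = apply_454_errors(
                        t.sequence, config.homopolymer_indel_rate,
                        config.substitution_error_rate, rng_err,
                        n_emission_rate=config.n_emission_rate,
                        low_quality=low_q, quality_model=qm)
                    raw = mid + fwd + exon + revcomp(rev)
                    q_flank1 = _draw_qualities(len(mid) + len(fwd), rng_err,
                                               low_q, qm)
                    q_flank2 = _draw_qualities(len(rev), rng_err, low_q, qm)
                    quals = np.concatenate([q_flank1, equal_q, q_flank2])
                    if rng_err.random() < config.truncation_rate:
                        cut = int(rng_err.integers(120, len(raw)))
                        raw, quals = raw[:cut], quals[:cut]
                    if rng_err.random() < 0.5:
                        raw = revcomp(raw)
                        quals = quals[::-1]
                        orient = "reverse"
                    else:
                        orient = "forward"
                    rid = f"{ind.id}|{pp}|{amp}#{k}"
                    reads.append(SequencingRead(
                        rid, raw, quals, "long-amplicon", ind.id, pp, amp))
                    read_truth[rid] = {
                        "individual": ind.id, "locus": locus,
                        "source": t.source, "switch_point": t.switch_point,
                        "template": t.sequence, "orientation": orient,
                        "n_indels": n_ind, "n_subs": n_sub}
    return SurveyDataset(truth, design, reads, read_truth)


@dataclass
class DemeDataset:
    truth: MetapopTruth
    direct: dict                      # (individual, locus) -> DirectRead
    illumina: dict                    # (individual, locus) -> IlluminaReadSet
    biases: dict                      # (individual, locus) -> bias used


def simulate_deme_dataset(truth: MetapopTruth,
                          rng: Optional[np.random.Generator] = None) -> DemeDataset:
    """Direct-sequencing consensi plus Illumina-style reads for all animals.

    Per individual x locus an amplification bias is drawn from the config
    range; the better-amplified (major) allele is chosen at random.
    """
    config = truth.config
    rng = rng or config.rng_streams()["illumina"]
    direct, illumina, biases = {}, {}, {}
    for ind in truth.individuals:
        for locus in config.loci:
            s1, s2 = truth.genotype_seqs(ind, locus)
            if rng.random() < 0.5:
                s1, s2 = s2, s1
            bias = float(rng.uniform(*config.amplification_bias_range))
            n = int(rng.integers(*config.illumina_reads_per_individual))
            d, ill = simulate_direct_and_illumina(
                (s1, s2), bias, config.illumina_error_rate, n, rng,
                dropout_bias=config.dropout_bias,
                individual=ind.id, locus=locus)
            direct[(ind.id, locus)] = d
            illumina[(ind.id, locus)] = ill
            biases[(ind.id, locus)] = bias
    return DemeDataset(truth, direct, illumina, biases)
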