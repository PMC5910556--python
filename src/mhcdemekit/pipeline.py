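"""Workflow orchestration: survey, deme analysis and synthetic benchmark.

Ties the stages into the two study workflows (species-wide survey of
validated alleles; deme-level diploid typing with population-genetic
summaries and recombination screens) and an end-to-end benchmark in which
every metric is scored against the simulator's ground truth.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._seq import diff_sites
from .core import AlleleCatalog
from .deme_typing import run_deme_typing
from .popgen import (
    classify_allele_sharing,
    deme_summary,
    dloop_sharing,
    final_third_slope,
    fst_weir_cockerham,
    heterozygosity_stats,
    average_relatedness,
    pooled_frequencies,
    mean_pairwise_fst,
    rarefaction_curve,
    sample_size_correlation,
)
from .recomb import SiteMatrix, four_gamete_rm, geneconv_fragments, k2p_matrix
from .survey_calling import run_survey_calling
from .synthdata import (
    MetapopTruth,
    SimConfig,
    simulate_deme_dataset,
    simulate_metapopulation,
    simulate_survey_dataset,
)


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed (< 2^31) from a master seed and string tokens."""
    return zlib.crc32(":".join([str(seed), *map(str, tokens)]).encode()) % (2 ** 31)


# ---------------------------------------------------------------------------
# reference/known-catalog conventions for synthetic runs
# ---------------------------------------------------------------------------

def default_references(truth: MetapopTruth, n_per_locus: int = 2) -> dict:
    """Per-locus alignment references: the first ancestral alleles."""
    refs = {}
    for locus, d in truth.alleles.items():
        anc = [a.sequence for a in d.values() if a.class_label == "shared"]
        refs[locus] = anc[:n_per_locus]
    return refs


def known_catalog(truth: MetapopTruth, fraction: float = 0.5) -> AlleleCatalog:
    """A 'database' catalog holding a fraction of the ancestral alleles —
    the previously recorded alleles a survey would start from."""
    cat = AlleleCatalog()
    for locus, d in truth.alleles.items():
        anc = [a for a in d.values() if a.class_label == "shared"]
        for a in anc[: max(1, int(round(fraction * len(anc))))]:
            cat.new_entry(locus, a.sequence, status="known")
    return cat


# ---------------------------------------------------------------------------
# survey workflow
# ---------------------------------------------------------------------------

@dataclass
class SurveyBundle:
    result: object
    tables: dict
    stats: dict


def run_survey(truth: MetapopTruth, known: Optional[AlleleCatalog] = None,
               references: Optional[dict] = None, dataset=None,
               outdir: Optional[Path] = None, **call_params) -> SurveyBundle:
    """Survey workflow on a synthetic metapopulation: simulate 454-style
    reads, call and validate alleles, emit catalog + summary tables."""
    if dataset is None:
        dataset = simulate_survey_dataset(truth)
    references = references or default_references(truth)
    known = known if known is not None else known_catalog(truth)
    populations = {i.id: i.region for i in truth.individuals}
    res = run_survey_calling(dataset.reads, dataset.design.mid_table(),
                             dataset.design.primers, references, known,
                             populations=populations, **call_params)
    from .survey_calling import summarize_survey
    subspecies = {r: r for r in {i.region for i in truth.individuals}}
    tables = summarize_survey(res.catalog, res.genotypes, populations,
                              subspecies)
    tables["catalog"] = pd.DataFrame(
        [{"allele_id": e.allele_id, "locus": e.locus, "status": e.status,
          "functional_class": e.functional_class,
          "populations": ";".join(sorted(e.populations)),
          "sequence": e.sequence} for e in res.catalog])
    tables["rejections"] = pd.DataFrame(
        [{"locus": c.locus, "reason": r, "n_support": len(c.support),
          "raw_reads": c.raw_read_count} for c, r in res.rejected])
    if outdir is not None:
        h = mio.config_hash(vars(truth.config))
        seed = truth.config.seed
        for name, df in tables.items():
            mio.write_tsv(df, Path(outdir) / f"survey_{name}.tsv", seed, h)
        mio.write_fasta({e.allele_id: e.sequence for e in res.catalog},
                        Path(outdir) / "survey_catalog.fasta")
    return SurveyBundle(res, tables, res.stats)


# ---------------------------------------------------------------------------
# deme workflow
# ---------------------------------------------------------------------------

@dataclass
class DemeBundle:
    calls: list
    genotype_table: pd.DataFrame
    mhc_summary: pd.DataFrame
    msat_summary: pd.DataFrame
    sharing: object
    rarefaction: dict
    fst: dict
    recombination: pd.DataFrame
    fragments: pd.DataFrame
    dloop: dict
    slopes: dict
    r_squared: dict


def run_deme_analysis(truth: MetapopTruth, catalog: AlleleCatalog,
                      seed: Optional[int] = None, hwe_reps: int = 5000,
                      geneconv_permutations: int = 10_000,
                      outdir: Optional[Path] = None, **typing_params) -> DemeBundle:
    """Deme workflow: diploid typing from direct + short-read data, then the
    per-deme summary statistics, sharing classification, rarefaction,
    F_ST/relatedness on microsatellites, Rm and gene-conversion screens."""
    config = truth.config
    seed = config.seed if seed is None else seed
    dataset = simulate_deme_dataset(truth)
    calls = run_deme_typing(dataset.direct, dataset.illumina, catalog,
                            seed=derive_seed(seed, "typing"), **typing_params)
    ind_info = {i.id: i for i in truth.individuals}

    # genotype table (Tables S5/S6 layout)
    seq_name: dict[tuple, str] = {}

    def name_of(locus: str, seq: str) -> str:
        entry = catalog.lookup(locus, seq)
        if entry is not None:
            return entry.allele_id
        key = (locus, seq)
        if key not in seq_name:
            seq_name[key] = f"{locus}-new{len([k for k in seq_name if k[0] == locus]) + 1:02d}"
        return seq_name[key]

    rows = []
    for c in calls:
        ind = ind_info[c.individual]
        row = {"individual": c.individual, "deme": ind.deme,
               "region": ind.region, "locus": c.locus,
               "excluded": c.excluded, "reason": c.reason}
        if not c.excluded:
            a1, a2 = c.alleles
            row.update(allele1=name_of(c.locus, a1), allele2=name_of(c.locus, a2),
                       support1=c.support.get(a1, ""),
                       support2=c.support.get(a2, ""))
        rows.append(row)
    genotype_table = pd.DataFrame(rows)

    # per-deme MHC summaries + sharing
    mhc_rows = []
    observations = []
    deme_geno: dict[str, dict] = {}
    for c in calls:
        if c.excluded:
            continue
        ind = ind_info[c.individual]
        a1, a2 = (name_of(c.locus, s) for s in c.alleles)
        deme_geno.setdefault(ind.deme, {}).setdefault(
            c.individual, {})[c.locus] = (a1, a2)
        for a in (a1, a2):
            observations.append((a, ind.deme, ind.region))
    loci = sorted(config.loci)
    for deme in sorted(deme_geno):
        freqs = pooled_frequencies(deme_geno[deme])
        for locus in loci:
            sub = {i: g for i, g in deme_geno[deme].items() if locus in g}
            if not sub:
                continue
            mhc_rows.append(deme_summary(deme, sub, freqs, locus,
                                         hwe_reps=hwe_reps,
                                         seed=derive_seed(seed, "hwe", deme, locus)))
    mhc_summary = pd.DataFrame(mhc_rows)

    survey_ids = {e.allele_id for e in catalog}
    sharing = classify_allele_sharing(observations, survey_alleles=survey_ids)

    # rarefaction per class (copies pooled over demes)
    copies: dict[str, dict] = {"shared": {}, "region_specific": {}}
    for a, _d, _r in observations:
        cls = sharing.classes[a]
        copies[cls][a] = copies[cls].get(a, 0) + 1
    rarefaction, slopes = {}, {}
    for cls, d in copies.items():
        if len(d) >= 1 and sum(d.values()) >= 3:
            curve = rarefaction_curve(list(d.values()))
            rarefaction[cls] = curve
            slopes[cls] = final_third_slope(curve)

    # sample-size correlation per class (points: deme x locus)
    r_squared = {}
    for cls in ("shared", "region_specific"):
        ns, counts = [], []
        for deme in sorted(deme_geno):
            for locus in loci:
                inds = [i for i, g in deme_geno[deme].items() if locus in g]
                if not inds:
                    continue
                alleles_here = {a for i in inds
                                for a in deme_geno[deme][i][locus]
                                if sharing.classes.get(a) == cls}
                ns.append(len(inds))
                counts.append(len(alleles_here))
        if len(ns) >= 3 and np.var(ns) > 0:
            r_squared[cls] = sample_size_correlation(ns, counts)

    # microsatellites: Table 3-style per-deme summary + F_ST per region
    msat_rows = []
    msat_geno: dict[str, dict] = {}
    for i in truth.individuals:
        msat_geno.setdefault(i.deme, {})[i.id] = {
            f"msat{m}": g for m, g in i.microsats.items()}
    pooled = pooled_frequencies(
        {i: g for d in msat_geno.values() for i, g in d.items()})
    for deme in sorted(msat_geno):
        genos = msat_geno[deme]
        hobs = hexp = neff = 0.0
        nloci = 0
        for m in range(config.microsat_loci):
            locus = f"msat{m}"
            glist = [genos[i][locus] for i in genos]
            ho, he, ne = heterozygosity_stats(glist)
            hobs += ho
            hexp += he
            neff += ne
            nloci += 1
        rel = average_relatedness(genos, pooled)
        region = deme.split("D")[0]
        msat_rows.append({"region": region, "deme": deme, "n": len(genos),
                          "h_obs": hobs / nloci, "h_exp": hexp / nloci,
                          "n_eff_alleles": neff / nloci,
                          "relatedness_mean": rel})
    msat_summary = pd.DataFrame(msat_rows)

    fst = {}
    regions = sorted({d.split("D")[0] for d in msat_geno})
    for region in regions:
        demes_r = {d: {f"msat{m}": [msat_geno[d][i][f"msat{m}"] for i in msat_geno[d]]
                       for m in range(config.microsat_loci)}
                   for d in msat_geno if d.startswith(region)}
        if len(demes_r) >= 2:
            theta = fst_weir_cockerham(demes_r)
            fst[region] = {"matrix": theta, "mean": mean_pairwise_fst(theta)}

    # D-loop haplotype sharing
    dloop = dloop_sharing({i.id: (i.mtdna, i.deme, i.region)
                           for i in truth.individuals})

    # recombination screens per deme x locus (alleles observed there)
    rec_rows, frag_rows = [], []
    for deme in sorted(deme_geno):
        for locus in loci:
            seqs: dict[str, str] = {}
            for i, g in deme_geno[deme].items():
                if locus not in g:
                    continue
                c = next(c for c in calls
                         if c.individual == i and c.locus == locus and not c.excluded)
                for aseq in c.alleles:
                    seqs[name_of(locus, aseq)] = aseq
            if len(seqs) < 2:
                continue
            mat = SiteMatrix(sorted(seqs), [seqs[k] for k in sorted(seqs)])
            rm, intervals = four_gamete_rm(mat)
            rec_rows.append({"deme": deme, "locus": locus, "rm": rm,
                             "intervals": ";".join(f"{a}-{b}" for a, b in intervals)})
            if len(seqs) >= 3:
                frags = geneconv_fragments(
                    mat, "both", geneconv_permutations,
                    seed=derive_seed(seed, "geneconv", deme, locus))
                for f in frags:
                    if f.sim_p < 0.05:
                        frag_rows.append({
                            "locus": locus, "deme": deme, "kind": f.kind,
                            "allele1": f.seq1, "allele2": f.seq2 or "",
                            "sim_p": f.sim_p, "corrected_p": f.corrected_p,
                            "begin": f.begin, "end": f.end, "length": f.length})
    recombination = pd.DataFrame(rec_rows)
    fragments = pd.DataFrame(frag_rows)

    bundle = DemeBundle(calls, genotype_table, mhc_summary, msat_summary,
                        sharing, rarefaction, fst, recombination, fragments,
                        dloop, slopes, r_squared)
    if outdir is not None:
        h = mio.config_hash(vars(config))
        mio.write_tsv(genotype_table, Path(outdir) / "genotypes.tsv", seed, h)
        mio.write_tsv(mhc_summary, Path(outdir) / "mhc_deme_summary.tsv", seed, h)
        mio.write_tsv(msat_summary, Path(outdir) / "microsat_summary.tsv", seed, h)
        mio.write_tsv(sharing.per_deme, Path(outdir) / "sharing.tsv", seed, h)
        mio.write_tsv(recombination, Path(outdir) / "rm_table.tsv", seed, h)
        mio.write_tsv(fragments, Path(outdir) / "geneconv_fragments.tsv", seed, h)
        for cls, curve in rarefaction.items():
            mio.write_tsv(curve, Path(outdir) / f"rarefaction_{cls}.tsv", seed, h)
    return bundle


# ---------------------------------------------------------------------------
# synthetic end-to-end benchmark
# ---------------------------------------------------------------------------

def benchmark_run(config: SimConfig, hwe_reps: int = 2000,
                  geneconv_permutations: int = 2000) -> dict:
    """One grid point of the synthetic benchmark: all recovery metrics
    scored against ground truth."""
    truth = simulate_metapopulation(config)
    dataset = simulate_survey_dataset(truth)
    survey = run_survey(truth, dataset=dataset)
    catalog = survey.result.catalog

    true_seqs = {(loc, a.sequence)
                 for loc, d in truth.alleles.items() for a in d.values()}
    carried2 = {(loc, a.sequence)
                for loc, d in truth.alleles.items() for a in d.values()
                if len(truth.carriers(loc, a.id)) >= 2}
    got = {(e.locus, e.sequence) for e in catalog}
    chimera_templates = {
        (rt["locus"], rt["template"])
        for rt in dataset.read_truth.values()
        if rt["source"] == "chimera"}
    chimeric_accepted = len((got - true_seqs) & chimera_templates)

    sensitivity = len(got & carried2) / len(carried2) if carried2 else 1.0
    precision = len(got & true_seqs) / len(got) if got else 1.0

    # deme typing accuracy: full catalog (survey + known) as phasing basis
    deme = run_deme_analysis(truth, catalog, hwe_reps=hwe_reps,
                             geneconv_permutations=geneconv_permutations)
    info = {i.id: i for i in truth.individuals}
    n_ok = n_called = 0
    for c in deme.calls:
        if c.excluded:
            continue
        n_called += 1
        ts = frozenset(truth.genotype_seqs(info[c.individual], c.locus))
        n_ok += frozenset(c.alleles) == ts
    accuracy = n_ok / n_called if n_called else 0.0

    return {
        "allele_recovery_sensitivity": sensitivity,
        "catalog_precision": precision,
        "chimeric_artifacts_accepted": chimeric_accepted,
        "genotype_accuracy": accuracy,
        "n_calls": n_called,
        "n_true_alleles_2carriers": len(carried2),
        "catalog_size": len(got),
        "slopes": deme.slopes,
        "r_squared": deme.r_squared,
        "bundle": deme,
        "truth": truth,
    }


def benchmark(config: SimConfig, chimera_rates=(0.0, 0.05, 0.1),
              seeds=(0,)) -> pd.DataFrame:
    """Grid benchmark over chimera rates and seeds (metrics vs truth)."""
    rows = []
    for rate in chimera_rates:
        for seed in seeds:
            cfg = SimConfig(**{**vars(config), "chimera_rate": rate,
                               "seed": derive_seed(config.seed, rate, seed)})
            m = benchmark_run(cfg)
            rows.append({"chimera_rate": rate, "seed": seed,
                         **{k: v for k, v in m.items()
                            if isinstance(v, (int, float))}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML-config entry point
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    workflow: str
    seed: int = 0
    outdir: str = "results"
    sim: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in ("workflow", "seed", "outdir", "sim", "params")
                 if f in raw}
        if "workflow" not in known:
            raise ValueError("run config needs a 'workflow' field")
        return cls(**known)


def execute(run_config: RunConfig) -> dict:
    """Execute a named workflow; returns a summary dict and writes outputs."""
    sim = SimConfig(**{**run_config.sim, "seed": run_config.seed})
    out = Path(run_config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = mio.config_hash(vars(sim))
    if run_config.workflow == "simulate":
        truth = simulate_metapopulation(sim)
        mio.write_truth_tables(truth, out, sim.seed, h)
        dataset = simulate_survey_dataset(truth)
        mio.write_fastq(dataset.reads, out / "survey_reads.fastq")
        mio.write_tsv(pd.DataFrame(
            [{"mid": m, "individual": i} for i, m in dataset.design.mids.items()]),
            out / "mid_table.tsv", sim.seed, h)
        mio.write_tsv(pd.DataFrame(
            [{"locus": loc, "primer_pair": pp, "forward": f, "reverse": r}
             for (loc, pp), (f, r) in dataset.design.primers.items()]),
            out / "primer_table.tsv", sim.seed, h)
        return {"individuals": len(truth.individuals),
                "reads": len(dataset.reads)}
    if run_config.workflow == "survey":
        truth = simulate_metapopulation(sim)
        bundle = run_survey(truth, outdir=out, **run_config.params)
        return bundle.stats
    if run_config.workflow == "deme":
        truth = simulate_metapopulation(sim)
        survey = run_survey(truth)
        bundle = run_deme_analysis(truth, survey.result.catalog, outdir=out,
                                   **run_config.params)
        return {"n_calls": len(bundle.calls)}
    if run_config.workflow == "benchmark":
        df = benchmark(sim, **run_config.params)
        mio.write_tsv(df, out / "benchmark.tsv", sim.seed, h)
        return {"rows": len(df)}
    raise ValueError(f"unknown workflow {run_config.workflow!r}")
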