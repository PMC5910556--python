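"""File interchange: FASTA/FASTQ via Biopython, TSV tables via pandas.

Every table written by the pipeline carries comment-line headers with the
tool version, a config hash and the seed, so a run can be audited and
restarted from its serialized intermediates.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import DirectRead, SequencingRead


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed: Optional[int], cfg_hash: Optional[str]) -> list:
    lines = [f"# mhc-deme-kit {__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_tsv(df: pd.DataFrame, path, seed: Optional[int] = None,
              cfg_hash: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fasta(records: dict, path) -> None:
    """``records`` maps id -> sequence (descriptions allowed via 'id desc')."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = []
    for rid, seq in records.items():
        parts = rid.split(None, 1)
        recs.append(SeqRecord(Seq(seq), id=parts[0],
                              description=parts[1] if len(parts) > 1 else ""))
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fastq(path, platform: str = "long-amplicon") -> list:
    """Reads with provenance parsed from ``individual|primerpair|amplification``
    read names."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        name = rec.id
        parts = name.split("|")
        ind = parts[0] if len(parts) >= 3 else "NA"
        pp = parts[1] if len(parts) >= 3 else "NA"
        amp = parts[2].split("#")[0] if len(parts) >= 3 else "NA"
        out.append(SequencingRead(
            name, str(rec.seq).upper(),
            np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            platform, ind, pp, amp))
    return out


def write_direct_fasta(directs: dict, path) -> None:
    """IUPAC consensi; peak metadata serialized as ``peaks=pos:base:ratio``
    in the description."""
    records = {}
    for (ind, locus), d in sorted(directs.items()):
        desc = ",".join(f"{p}:{b}:{r:g}" for p, (b, r) in sorted(d.peaks.items()))
        key = f"{ind}__{locus}" + (f" peaks={desc}" if desc else "")
        records[key] = d.sequence
    write_fasta(records, path)


def read_direct_fasta(path) -> dict:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ind, locus = rec.id.rsplit("__", 1)
        peaks = {}
        for token in rec.description.split():
            if token.startswith("peaks="):
                for item in token[len("peaks="):].split(","):
                    if item:
                        p, b, r = item.split(":")
                        peaks[int(p)] = (b, float(r))
        out[(ind, locus)] = DirectRead(ind, locus, str(rec.seq).upper(), peaks)
    return out


def write_truth_tables(truth, outdir, seed: Optional[int] = None,
                       cfg_hash: Optional[str] = None) -> None:
    outdir = Path(outdir)
    rows = [{"allele_id": a.id, "locus": a.locus, "class": a.class_label,
             "origin_region": a.origin_region or "",
             "origin_deme": a.origin_deme or "",
             "event": a.event or "",
             "donors": ";".join(a.donors) if a.donors else "",
             "breakpoints": ";".join(map(str, a.breakpoints)) if a.breakpoints else ""}
            for d in truth.alleles.values() for a in d.values()]
    write_tsv(pd.DataFrame(rows), outdir / "truth_alleles.tsv", seed, cfg_hash)

    rows = []
    for ind in truth.individuals:
        row = {"individual": ind.id, "deme": ind.deme, "region": ind.region,
               "natal_deme": ind.natal_deme, "sex": ind.sex,
               "mother": ind.mother or "", "father": ind.father or "",
               "mtdna": ind.mtdna}
        for locus, (a, b) in ind.genotypes.items():
            row[f"{locus}_1"], row[f"{locus}_2"] = a, b
        for m, (a, b) in ind.microsats.items():
            row[f"msat{m}_1"], row[f"msat{m}_2"] = a, b
        rows.append(row)
    write_tsv(pd.DataFrame(rows), outdir / "individuals.tsv", seed, cfg_hash)

    write_fasta({a.id: a.sequence for d in truth.alleles.values()
                 for a in d.values()}, outdir / "true_alleles.fasta")

    if truth.events:
        write_tsv(pd.DataFrame(truth.events), outdir / "events.tsv", seed,
                  cfg_hash)
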