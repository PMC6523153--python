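"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: marker map TSV, dense genotype TSV (and PLINK .raw import), long
response TSV, gene annotation BED (0-based half-open on disk, 1-based
inclusive in memory), promoter FASTA, MEME-minimal motifs (read through
Bio.motifs), one-symbol-per-line TF lists, SIF-style edge lists and JSON
summaries.  Readers validate and report the offending file/line on error.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import PWM, Genotypes

FLOAT_FMT = "%.10g"


def write_marker_map(mmap: pd.DataFrame, path):
    mmap[["marker_id", "chrom", "pos_bp"]].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    mmap = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "pos_bp": np.int64})
    for col in ("marker_id", "chrom", "pos_bp"):
        if col not in mmap.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (mmap["pos_bp"] < 0).any():
        bad = int(mmap.index[mmap["pos_bp"] < 0][0]) + 2
        raise ValueError(f"{path}: line {bad}: negative position")
    return mmap


def write_genotypes(G: Genotypes, path):
    df = pd.DataFrame(G.dosages, index=pd.Index(G.animal_ids, name="animal_id"),
                      columns=G.marker_ids)
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> Genotypes:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {r + 2}: dosage {vals[r, c]!r} for marker {df.columns[c]} "
            "outside {0,1,2}"
        )
    return Genotypes(list(df.index.astype(str)), list(df.columns), vals.astype(np.int8))


def read_plink_raw(path) -> Genotypes:
    """Import a PLINK --recode A (.raw) dosage file; NA is mean-imputed."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    for col in meta[:2]:
        if col not in df.columns:
            raise ValueError(f"{path}: not a PLINK .raw file (missing {col})")
    snp_cols = [c for c in df.columns if c not in meta]
    vals = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        col_mean = np.nanmean(vals, axis=0)
        r, c = np.where(np.isnan(vals))
        vals[r, c] = col_mean[c]
    markers = [c.rsplit("_", 1)[0] for c in snp_cols]
    return Genotypes(list(df["IID"].astype(str)), markers, np.rint(vals).astype(np.int8))


def write_responses(responses: pd.DataFrame, path):
    # full precision: a re-read bundle must drive a bit-identical analysis
    responses.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "trait": str})
    for col in ("animal_id", "trait", "debv", "reliability"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = (df["reliability"] < 0) | (df["reliability"] > 1)
    if bad.any():
        raise ValueError(f"{path}: line {int(df.index[bad][0]) + 2}: reliability outside [0,1]")
    return df


def write_gene_bed(genes: pd.DataFrame, path):
    """Genes as BED6 (chrom, start0, end, name, score, strand)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,  # to 0-based half-open
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValueError(f"{path}: line {int(df.index[bad][0]) + 1}: end <= start")
    return pd.DataFrame(
        {
            "gene_id": df["name"].astype(str),
            "chrom": df["chrom"],
            "start": df["start"] + 1,  # to 1-based inclusive
            "end": df["end"],
            "strand": df["strand"],
        }
    )


def write_promoters(promoters: dict, path):
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()]
    SeqIO.write(records, path, "fasta")


def read_promoters(path) -> dict:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{path}: sequence {rec.id}: non-ACGTN characters")
        out[rec.id] = seq
    return out


def write_meme(pwms: dict, path, background=(0.25, 0.25, 0.25, 0.25)):
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n" % tuple(background))
        for mid, pwm in pwms.items():
            fh.write(f"\nMOTIF {mid}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme(path) -> dict:
    with open(path) as fh:
        record = motifs.parse(fh, "minimal")
    out = {}
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        mat /= mat.sum(axis=1, keepdims=True)
        out[m.name] = PWM(m.name, mat)
    return out


def write_tf_list(tfs, path):
    Path(path).write_text("".join(f"{t}\n" for t in tfs))


def read_tf_list(path) -> list:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _fmt(v):
    if isinstance(v, float):
        if math.isinf(v):
            return "inf"
        return FLOAT_FMT % v
    return v


def write_table(df: pd.DataFrame, path, index=False):
    """TSV with stable float formatting; +inf serialized as "inf"."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=index)


def write_edge_list(G, path):
    """SIF-style TSV: nodeA, "co", nodeB, weight."""
    rows = [(str(a), "co", str(b), d.get("weight", 1.0)) for a, b, d in G.edges(data=True)]
    rows.sort()
    write_table(pd.DataFrame(rows, columns=["node_a", "interaction", "node_b", "weight"]), path)


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
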