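"""Readers and writers for the plain-text formats the pipeline speaks.

Conventions: BED is 0-based half-open; GTF is 1-based closed; all internal
coordinates are 0-based half-open.  Expression matrices travel as a TSV
(gene_id index, sample columns) plus a two-column samples TSV mapping
sample -> tissue.  TE identity in BED6 uses the name field, written as
``family:te_id``; a plain name (RepeatMasker style, where the name IS the
family) is accepted on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GeneModel, GeneTEPairing, TEAnnotation, TEElement
from .expression import ExpressionMatrix
from .pwm import PWM

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_bed6", "write_bed6",
    "read_gtf", "write_gtf",
    "read_orthologs_tsv", "write_orthologs_tsv",
    "read_pairings_tsv", "write_pairings_tsv",
    "read_fasta", "write_fasta",
    "read_meme_motifs", "read_motif_tsv", "write_meme_motifs",
    "read_gene_list", "write_gene_list",
    "write_json_report",
]


# --------------------------------------------------------------------------
# expression

def read_expression_tsv(path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    bad = values.columns[~values.apply(
        lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric expression column(s) {list(bad)}")
    samples = pd.read_csv(samples_path, sep="\t")
    if not {"sample", "tissue"} <= set(samples.columns):
        raise ValueError(f"{samples_path}: needs columns 'sample' and 'tissue'")
    tissue = samples.set_index("sample")["tissue"]
    return ExpressionMatrix(values, tissue)


def write_expression_tsv(expr: ExpressionMatrix, path, samples_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id",
                       float_format="%.10g")
    pd.DataFrame({
        "sample": list(expr.sample_ids),
        "tissue": [expr.tissue_of_sample[s] for s in expr.sample_ids],
    }).to_csv(samples_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# BED6

def read_bed6(path) -> TEAnnotation:
    elements: list[TEElement] = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                skipped += 1
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            if ":" in name:
                family, te_id = name.split(":", 1)
            else:
                family, te_id = name, f"{name}_{ln}"
            elements.append(TEElement(te_id, chrom, start, end, strand, family))
    if skipped:
        logger.info("%s: skipped %d comment/track lines", path, skipped)
    return TEAnnotation(elements)


def write_bed6(te: TEAnnotation, path) -> None:
    with open(path, "w") as fh:
        for el in te:
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t"
                     f"{el.family}:{el.te_id}\t0\t{el.strand}\n")


# --------------------------------------------------------------------------
# GTF (1-based closed on disk)

def _parse_gtf_attributes(text: str, where: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ValueError(f"{where}: malformed attribute {chunk!r}")
        key, val = chunk.split(" ", 1)
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Build gene models from GTF2.2 transcript (or exon) features."""
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GTF fields, got {len(parts)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_text = parts
            if feature not in ("transcript", "exon"):
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            if s1 > e1:
                raise ValueError(f"{path}:{ln}: start > end")
            attrs = _parse_gtf_attributes(attr_text, f"{path}:{ln}")
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError(f"{path}:{ln}: gene_id/transcript_id missing")
            key = attrs["transcript_id"]
            s0, e0 = s1 - 1, e1  # to 0-based half-open
            rec = tx.setdefault(key, {
                "gene_id": attrs["gene_id"], "chrom": chrom, "strand": strand,
                "start": s0, "end": e0})
            rec["start"] = min(rec["start"], s0)
            rec["end"] = max(rec["end"], e0)
    genes: dict[str, dict] = {}
    for rec in tx.values():
        g = genes.setdefault(rec["gene_id"], {
            "chrom": rec["chrom"], "strand": rec["strand"], "transcripts": []})
        g["transcripts"].append((rec["start"], rec["end"]))
    return [
        GeneModel(gid, g["chrom"], g["strand"], tuple(sorted(g["transcripts"])))
        for gid, g in genes.items()
    ]


def write_gtf(genes: list[GeneModel], path, source: str = "te_regnet") -> None:
    with open(path, "w") as fh:
        for g in genes:
            gs = min(s for s, _ in g.transcripts)
            ge = max(e for _, e in g.transcripts)
            fh.write(f"{g.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                     f'gene_id "{g.gene_id}";\n')
            for i, (s, e) in enumerate(g.transcripts, start=1):
                tid = f"{g.gene_id}.t{i}"
                for feature in ("transcript", "exon"):
                    fh.write(f"{g.chrom}\t{source}\t{feature}\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t.\t"
                             f'gene_id "{g.gene_id}"; transcript_id "{tid}";\n')


# --------------------------------------------------------------------------
# small TSVs

def read_orthologs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ortholog map needs two columns")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_orthologs_tsv(pairs, path) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False)


def read_pairings_tsv(path) -> list[GeneTEPairing]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneTEPairing(str(r.gene_id), str(r.te_id), int(r.distance),
                      str(r.mode), float(r.window_kb))
        for r in df.itertuples(index=False)
    ]


def write_pairings_tsv(pairings, path) -> None:
    pd.DataFrame(
        [(p.gene_id, p.te_id, p.distance, p.mode, p.window_kb) for p in pairings],
        columns=["gene_id", "te_id", "distance", "mode", "window_kb"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# motifs

def read_meme_motifs(path, pseudocount: float = 0.01) -> list[PWM]:
    """Parse MEME minimal-format motifs into PWM objects."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    background = np.array([record.background[b] for b in "ACGT"], dtype=float)
    out = []
    for m in record:
        probs = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out.append(PWM(m.name, probs, background, pseudocount))
    return out


def write_meme_motifs(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for p in pwms:
            fh.write(f"MOTIF {p.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} "
                     f"nsites= 20 E= 0\n")
            for row in p.probabilities:
                fh.write(" {:8.6f} {:8.6f} {:8.6f} {:8.6f}\n".format(*row))
            fh.write("\n")


def read_motif_tsv(path, tf_name: str | None = None,
                   pseudocount: float = 0.01) -> PWM:
    """Plain 4-column (A C G T) probability matrix, one row per position."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in list("ACGT")]
    if len(cols) != 4:
        raise ValueError(f"{path}: need exactly the columns A, C, G, T")
    probs = df[sorted(cols, key=lambda c: "ACGT".index(c.upper()))].to_numpy(float)
    return PWM(tf_name or Path(path).stem, probs, pseudocount=pseudocount)


# --------------------------------------------------------------------------
# reports

def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
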