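"""Readers and writers for all external file formats.

Supported inputs: GFF3 gene models (via gffutils, longest-CDS isoform
selection), a simple TSV gene table (the simulator's native dialect),
protein/CDS FASTA, BLAST tabular (outfmt 6), TSV pair lists, TSV expression
matrices, plain-text id lists and colinearity-anchor tables. All tabular
outputs are plain TSV, bit-exact for a fixed input and configuration.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .model import DuplicatePair, ExpressionProfile, GeneModel, HomologyHit, Mode, pair_key

logger = logging.getLogger("dupstruct.io")

GENE_TABLE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "n_cds_exons", "is_te"]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(
    path: str | Path,
    fmt: str = "auto",
    isoform_rule: str = "longest_cds",
) -> dict[str, GeneModel]:
    """Read gene models from GFF3 or the TSV gene-table dialect.

    For GFF3, exactly one model is kept per gene locus: the transcript with
    maximal summed CDS length (ties broken by lexicographically smallest
    transcript id). ``n_cds_exons`` counts CDS features of that transcript.
    Sequences are attached separately with :func:`attach_sequences`.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "table"
    if fmt == "gff3":
        return _read_gff3(path, isoform_rule)
    if fmt == "table":
        return read_gene_table(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _read_gff3(path: Path, isoform_rule: str) -> dict[str, GeneModel]:
    import gffutils

    if isoform_rule != "longest_cds":
        raise ValueError(f"unsupported isoform rule {isoform_rule!r}")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: Optional[tuple[int, str, int]] = None  # (-cds_len, tid, n_exons)
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            cds_len = sum(c.end - c.start + 1 for c in cds)
            if cds_len == 0:
                continue
            cand = (-cds_len, mrna.id, len(cds))
            if best is None or cand < best:
                best = cand
        if best is None:
            logger.warning("gene %s has no transcript with CDS; skipped", gene.id)
            continue
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else "+",
            n_cds_exons=best[2],
            cds_seq="",
            protein_seq="",
        )
    return genes


def read_gene_table(path: str | Path) -> dict[str, GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns {missing}")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in genes:
            raise ValueError(f"duplicated gene id {row.gene_id} in {path}")
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            n_cds_exons=int(row.n_cds_exons),
            cds_seq="",
            protein_seq="",
            is_te=bool(row.is_te),
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for g in rows:
            w.writerow([g.gene_id, g.chromosome, g.start, g.end, g.strand,
                        g.n_cds_exons, int(g.is_te)])


def attach_sequences(
    genes: dict[str, GeneModel],
    cds_fasta: str | Path | None = None,
    protein_fasta: str | Path | None = None,
    validate: bool = True,
) -> dict[str, GeneModel]:
    """Attach CDS/protein sequences by gene id and validate consistency.

    Genes failing the 3x-protein-length CDS consistency check are rejected
    (dropped with a warning), enforcing the load-time invariant.
    """
    if cds_fasta is not None:
        for rec in SeqIO.parse(str(cds_fasta), "fasta"):
            if rec.id in genes:
                genes[rec.id].cds_seq = str(rec.seq).upper()
    if protein_fasta is not None:
        for rec in SeqIO.parse(str(protein_fasta), "fasta"):
            if rec.id in genes:
                genes[rec.id].protein_seq = str(rec.seq)
    if validate:
        bad = []
        for g in genes.values():
            if not g.cds_seq and not g.protein_seq:
                continue
            try:
                g.validate()
            except ValueError as exc:
                logger.warning("rejected gene at load: %s", exc)
                bad.append(g.gene_id)
        for gid in bad:
            del genes[gid]
    return genes


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(seqs):
            fh.write(f">{gid}\n")
            s = seqs[gid]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6) hits.

    Self-hits are dropped; duplicate (query, subject) rows are collapsed
    keeping the minimal E-value (bitscore of that best row). Output order is
    deterministic and independent of input row order.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            q, s = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric evalue/bitscore") from exc
            n_rows += 1
            if q == s:
                continue
            key = (q, s)
            cand = (evalue, -bitscore)
            if key not in best or cand < (best[key][0], -best[key][1]):
                best[key] = (evalue, bitscore)
    if n_rows == 0:
        logger.warning("hit file %s is empty", path)
    return [
        HomologyHit(q, s, ev, bs)
        for (q, s), (ev, bs) in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# pair lists
# ---------------------------------------------------------------------------

def read_pair_list(
    path: str | Path,
    known_ids: set[str] | None = None,
    label: str = "",
) -> list[tuple[str, str]]:
    """Read a two-column TSV of gene-id pairs; unordered, de-duplicated.

    Rows naming unknown genes (when ``known_ids`` is given) or degenerate
    (a, a) rows are dropped with a warning.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                logger.warning("%s:%d: degenerate pair (%s, %s) rejected", path, lineno, a, b)
                continue
            if known_ids is not None and (a not in known_ids or b not in known_ids):
                logger.warning("%s:%d: unknown gene id in pair (%s, %s); dropped",
                               path, lineno, a, b)
                continue
            key = pair_key(a, b)
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    return pairs


def write_pair_list(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pair_key(a, b) for a, b in pairs):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> dict[str, ExpressionProfile]:
    """Read a genes x samples TSV matrix into expression profiles.

    Missing cells and duplicated gene ids are errors (no imputation).
    Profiles shorter than 3 samples are rejected (Pearson r needs >= 3).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(f"expression matrix {path} has fewer than 3 samples")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene id(s) in expression matrix: {dup}")
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing expression values for gene(s): {bad[:5]}")
    return {
        gid: ExpressionProfile(gid, [float(v) for v in row])
        for gid, row in zip(df.index, df.to_numpy())
    }


def write_expression_matrix(profiles: dict[str, list[float]],
                            sample_names: list[str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id"] + sample_names)
        for gid in sorted(profiles):
            w.writerow([gid] + [f"{v:.6g}" for v in profiles[gid]])


# ---------------------------------------------------------------------------
# id lists and anchors
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> set[str]:
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    return ids


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(gid + "\n")


ANCHOR_COLUMNS = ["focal_id", "other_id", "other_chromosome", "other_order"]


def read_anchor_file(path: str | Path) -> list[dict]:
    """Read an inter-genome homolog anchor table.

    Columns: focal gene id, outgroup gene id, outgroup chromosome, outgroup
    order index (integer rank of the homolog along its chromosome).
    """
    df = pd.read_csv(path, sep="\t", dtype={"other_chromosome": str})
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anchor file {path} missing columns {missing}")
    return [
        {"focal_id": r.focal_id, "other_id": r.other_id,
         "other_chromosome": r.other_chromosome, "other_order": int(r.other_order)}
        for r in df.itertuples(index=False)
    ]


def write_anchor_file(anchors: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANCHOR_COLUMNS)
        for a in anchors:
            w.writerow([a["focal_id"], a["other_id"], a["other_chromosome"], a["other_order"]])


# ---------------------------------------------------------------------------
# classified pairs
# ---------------------------------------------------------------------------

PAIRS_COLUMNS = ["gene_a", "gene_b", "mode", "parental_id", "transposed_id", "evalue"]


def write_pairs_tsv(pairs: Iterable[DuplicatePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIRS_COLUMNS)
        for p in sorted(pairs, key=lambda p: p.key):
            w.writerow([
                p.gene_a, p.gene_b, p.mode.value,
                p.parental_id or "", p.transposed_id or "",
                "" if math.isnan(p.source_evalue) else f"{p.source_evalue:.3g}",
            ])


def read_pairs_tsv(path: str | Path) -> list[DuplicatePair]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(DuplicatePair(
            gene_a=r.gene_a, gene_b=r.gene_b, mode=Mode(r.mode),
            parental_id=r.parental_id or None,
            transposed_id=r.transposed_id or None,
            source_evalue=float(r.evalue) if r.evalue != "" else float("nan"),
        ))
    return out
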