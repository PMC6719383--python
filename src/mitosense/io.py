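"""Readers and writers for the plain-text formats the pipeline touches.

BED is 0-based half-open and passes through unchanged; GFF3 is 1-based
inclusive and is shifted to the internal convention on input (start - 1).
Count matrices are TSV with a header row of sample ids and ``gene_id``
as the first column.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import BIOTYPES, GeneRecord, GenomeTable, InteractionNetwork, SampleMeta

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _norm_biotype(raw: str) -> str:
    raw = raw.strip()
    if raw in BIOTYPES:
        return raw
    low = raw.lower()
    if "mirna" in low:
        return "miRNA"
    if "rna" in low:
        return "ncRNA"
    if low in {"protein_coding", "coding"}:
        return "protein_coding"
    return "other"


def read_gene_table(path, fmt: str = "BED") -> GenomeTable:
    """Read a genome table from BED or GFF3 into an ordered GenomeTable."""
    fmt = fmt.upper()
    if fmt == "BED":
        records = _read_bed(path)
    elif fmt == "GFF3":
        records = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene table format: {fmt}")
    return GenomeTable(records)


def _read_bed(path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"BED needs >= 4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}")
            strand = fields[5] if len(fields) > 5 else "."
            biotype = _norm_biotype(fields[6]) if len(fields) > 6 else "protein_coding"
            try:
                records.append(
                    GeneRecord(fields[3], fields[0], start, end, strand, biotype)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    return records


_GFF_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def _read_gff3(path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"GFF3 needs 9 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}")
            attrs = dict(_GFF_ATTR.findall(fields[8]))
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise ParseError(path, lineno, "gene feature without ID attribute")
            biotype = _norm_biotype(
                attrs.get("biotype", attrs.get("gene_biotype", "protein_coding"))
            )
            try:
                records.append(
                    GeneRecord(gene_id, fields[0], start1 - 1, end1, fields[6], biotype)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    return records


def write_bed(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for g in genome:
            fh.write(f"{g.arm}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n")


def read_edge_list(path, directed: bool = False, allow_self_loops: bool = False) -> InteractionNetwork:
    """Read a TSV edge list (source, target[, confidence]).

    A header line is detected if the third column of the first row is
    non-numeric and equals 'confidence' (or the first two are
    'source'/'target').
    """
    edges: list[tuple] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split("\t")
        if first[0].lower() in {"source", "src"} or (
            len(first) > 2 and first[2].lower().startswith("conf")
        ):
            start = 1
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "edge row needs >= 2 columns")
        if len(fields) >= 3 and fields[2].strip() != "":
            try:
                conf = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric confidence {fields[2]!r}")
            edges.append((fields[0], fields[1], conf))
        else:
            edges.append((fields[0], fields[1]))
    if not edges:
        logger.warning("empty edge list: %s", path)
    return InteractionNetwork.from_edges(
        edges, directed=directed, allow_self_loops=allow_self_loops
    )


def write_edge_list(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tconfidence\n")
        for u, v, data in net.graph.edges(data=True):
            conf = data.get("confidence")
            fh.write(f"{u}\t{v}\t{'' if conf is None else conf}\n")


# -- matrices and metadata -------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Genes x samples integer count matrix, ``gene_id`` as index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in counts: {dups[:5]}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleMeta(r.sample_id, r.sex, r.mito, r.nuc, int(r.replicate))
        for r in df.itertuples()
    ]


def write_sample_meta(metas: Iterable[SampleMeta], path) -> None:
    rows = [
        {"sample_id": m.sample_id, "sex": m.sex, "mito": m.mito, "nuc": m.nuc,
         "replicate": m.replicate}
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and # comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_set_table(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, set) -> mapping set name -> gene ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, set_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, name in zip(df[gene_col], df[set_col]):
        out.setdefault(name, set()).add(gene)
    return out


def write_set_table(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tset\n")
        for name in sorted(sets):
            for gid in sorted(sets[name]):
                fh.write(f"{gid}\t{name}\n")


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x stages/samples float matrix, ``gene_id`` as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
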