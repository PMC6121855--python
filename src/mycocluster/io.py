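"""Readers and writers for the pipeline's external formats.

A *genome bundle* is the on-disk form of a set of :class:`GenomeRecord`:

* one protein FASTA per genome (``<genome_id>.faa``, headers are gene ids),
* one gene table (``genes.tsv``: genome_id, scaffold_id, order_index,
  gene_id, function_label) — a GFF3 file with ``gene`` features is accepted
  as an alternative dialect on input,
* one metadata table (``metadata.tsv``: genome_id, phenotype,
  comma-separated ecology labels).

Readers and writers are exact inverses on valid data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote

import pandas as pd
from Bio import SeqIO

from .core import GeneRecord, GenomeRecord, HomologGroup, SupportTree

GENE_TABLE_COLUMNS = [
    "genome_id", "scaffold_id", "order_index", "gene_id", "function_label",
]
METADATA_COLUMNS = ["genome_id", "phenotype", "ecology"]


# ---------------------------------------------------------------------------
# gene tables

def _read_gene_table_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if "function_label" not in df.columns:
        df["function_label"] = ""
    df["order_index"] = df["order_index"].astype(int)
    return df[GENE_TABLE_COLUMNS]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = unquote(value.strip())
    return out


def _read_gene_table_gff3(path: Path) -> pd.DataFrame:
    """GFF3 dialect: ``gene`` features only; gene ids from ``ID``; genome id
    from a ``genome_id`` attribute or, failing that, the file stem; the order
    index is the rank of the feature start within its scaffold."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, _end, _score, _strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            a = _parse_gff_attributes(attrs)
            if "ID" not in a:
                raise ValueError(f"{path}: gene feature without ID: {line!r}")
            rows.append({
                "genome_id": a.get("genome_id", path.stem),
                "scaffold_id": seqid,
                "start": int(start),
                "gene_id": a["ID"],
                "function_label": a.get("function", ""),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    df = df.sort_values(["genome_id", "scaffold_id", "start"], kind="mergesort")
    df["order_index"] = df.groupby(["genome_id", "scaffold_id"]).cumcount()
    return df[GENE_TABLE_COLUMNS].reset_index(drop=True)


def read_gene_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gene_table_gff3(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff"):
        return _read_gene_table_gff3(path)
    return _read_gene_table_tsv(path)


# ---------------------------------------------------------------------------
# genome bundles

def _read_fasta_sequences(fasta_path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_genome_bundle(fasta_path, gene_table_path, metadata_path) -> list[GenomeRecord]:
    """Load genomes from FASTA (a file, or a directory of ``*.faa`` files),
    a gene table (TSV or GFF3), and a metadata table."""
    fasta_path = Path(fasta_path)
    seqs: dict[str, str] = {}
    if fasta_path.is_dir():
        for f in sorted(fasta_path.glob("*.faa")) + sorted(fasta_path.glob("*.fasta")):
            seqs.update(_read_fasta_sequences(f))
    else:
        seqs = _read_fasta_sequences(fasta_path)

    table = read_gene_table(gene_table_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: metadata missing columns {sorted(missing)}")

    genomes: dict[str, GenomeRecord] = {}
    for _, row in meta.iterrows():
        ecology = frozenset(e for e in row["ecology"].split(",") if e)
        genomes[row["genome_id"]] = GenomeRecord(
            genome_id=row["genome_id"], genes=[],
            phenotype=row["phenotype"], ecology=ecology,
        )

    for _, row in table.iterrows():
        gid = row["gene_id"]
        if gid not in seqs:
            raise ValueError(f"gene {gid} listed in gene table but absent from FASTA")
        genome_id = row["genome_id"]
        if genome_id not in genomes:
            genomes[genome_id] = GenomeRecord(genome_id=genome_id)
        genomes[genome_id].genes.append(GeneRecord(
            gene_id=gid,
            genome_id=genome_id,
            scaffold_id=row["scaffold_id"],
            order_index=int(row["order_index"]),
            protein_seq=seqs[gid],
            function_label=row["function_label"] or None,
        ))

    out = [genomes[k] for k in sorted(genomes)]
    for g in out:
        g.sort_genes()
        g.validate()
    return out


def write_genome_bundle(genomes: Sequence[GenomeRecord], out_dir) -> dict[str, Path]:
    """Write genomes as one FASTA per genome plus the gene and metadata
    tables. Returns the paths written, keyed by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gene_rows, meta_rows = [], []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        fasta = out_dir / f"{genome.genome_id}.faa"
        with open(fasta, "w") as fh:
            for gene in sorted(genome.genes, key=lambda g: (g.scaffold_id, g.order_index)):
                fh.write(f">{gene.gene_id}\n{gene.protein_seq}\n")
                gene_rows.append({
                    "genome_id": gene.genome_id,
                    "scaffold_id": gene.scaffold_id,
                    "order_index": gene.order_index,
                    "gene_id": gene.gene_id,
                    "function_label": gene.function_label or "",
                })
        paths[f"fasta:{genome.genome_id}"] = fasta
        meta_rows.append({
            "genome_id": genome.genome_id,
            "phenotype": genome.phenotype,
            "ecology": ",".join(sorted(genome.ecology)),
        })

    genes_path = out_dir / "genes.tsv"
    pd.DataFrame(gene_rows, columns=GENE_TABLE_COLUMNS).to_csv(
        genes_path, sep="\t", index=False)
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(
        meta_path, sep="\t", index=False)
    paths["gene_table"] = genes_path
    paths["metadata"] = meta_path
    return paths


def read_bundle_dir(bundle_dir) -> list[GenomeRecord]:
    """Load a bundle written by :func:`write_genome_bundle`."""
    bundle_dir = Path(bundle_dir)
    return read_genome_bundle(
        bundle_dir, bundle_dir / "genes.tsv", bundle_dir / "metadata.tsv")


# ---------------------------------------------------------------------------
# trees

def read_newick(path) -> SupportTree:
    return SupportTree.read(path)


def write_newick(tree: SupportTree, path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# homolog groups

def write_groups(groups: Iterable[HomologGroup], path) -> None:
    rows = []
    for grp in sorted(groups, key=lambda g: g.group_id):
        for genome_id, gene_id in sorted(grp.members):
            rows.append({"group_id": grp.group_id,
                         "genome_id": genome_id, "gene_id": gene_id})
    pd.DataFrame(rows, columns=["group_id", "genome_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_groups(path) -> list[HomologGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups = []
    for group_id, sub in df.groupby("group_id", sort=True):
        members = frozenset(zip(sub["genome_id"], sub["gene_id"]))
        groups.append(HomologGroup(group_id=str(group_id), members=members))
    return groups
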