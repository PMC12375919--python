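"""Reference gene models, sequences, trees and read-support tables.

File dialects
-------------
* Gene-model table: tab-delimited with columns ``gene_id``, ``exon_start``,
  ``exon_end``, ``donor``, ``acceptor`` — one row per exon, 1-based
  inclusive CDS-local coordinates (stated in the file header line starting
  with ``#``). ``donor``/``acceptor`` describe the intron *following* an
  exon and are ``.`` for the last exon.
* Sequences: FASTA with headers ``gene_id|sample_id``.
* Read support: tab-delimited ``gene_id``, ``position``,
  ``reads_supporting_lof``, ``reads_opposing_lof``.
* Trees: newick, rooted, unique tip labels.

All coordinates in interchange files are 1-based inclusive; conversion to
any internal convention is centralized here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = set("ACGTN-")
CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"


class GeneModelError(ValueError):
    """Malformed or inconsistent gene-model input."""


@dataclass(frozen=True)
class GeneModel:
    """A reference coding sequence with exon/intron structure.

    ``exon_bounds`` are 1-based inclusive spans in CDS-local coordinates
    (introns excised), so consecutive exons are contiguous: the first exon
    starts at 1 and each next exon starts one past the previous end.
    ``donors``/``acceptors`` hold the 2-mer splice dinucleotides of each
    intron (``intron_count`` entries, GT/AG in a canonical reference).
    """

    gene_id: str
    exon_bounds: tuple[tuple[int, int], ...]
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    is_reference: bool = True

    def __post_init__(self) -> None:
        if not self.exon_bounds:
            raise GeneModelError(f"{self.gene_id}: gene model has no exons")
        prev_end = 0
        for start, end in self.exon_bounds:
            if start > end:
                raise GeneModelError(
                    f"{self.gene_id}: exon span ({start}, {end}) has start > end"
                )
            if start <= prev_end:
                raise GeneModelError(
                    f"{self.gene_id}: exon ({start}, {end}) overlaps or is out of "
                    f"order with previous exon ending at {prev_end}"
                )
            if start != prev_end + 1:
                raise GeneModelError(
                    f"{self.gene_id}: exon ({start}, {end}) leaves a gap in "
                    f"CDS-local coordinates after {prev_end}"
                )
            prev_end = end
        n_introns = len(self.exon_bounds) - 1
        donors = self.donors or tuple([CANONICAL_DONOR] * n_introns)
        acceptors = self.acceptors or tuple([CANONICAL_ACCEPTOR] * n_introns)
        if len(donors) != n_introns or len(acceptors) != n_introns:
            raise GeneModelError(
                f"{self.gene_id}: expected {n_introns} donor/acceptor pairs, "
                f"got {len(donors)}/{len(acceptors)}"
            )
        object.__setattr__(self, "donors", donors)
        object.__setattr__(self, "acceptors", acceptors)
        if self.is_reference and self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: reference CDS length {self.cds_length} "
                "is not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return self.exon_bounds[-1][1]

    @property
    def intron_count(self) -> int:
        return len(self.exon_bounds) - 1


@dataclass(frozen=True)
class GeneSet:
    """A collection of gene models with precomputed totals."""

    models: tuple[GeneModel, ...]

    def __post_init__(self) -> None:
        if not self.models:
            raise GeneModelError("a gene set needs at least one gene")
        ids = [m.gene_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise GeneModelError("duplicate gene_id in gene set")

    @property
    def n_genes(self) -> int:
        return len(self.models)

    @property
    def total_cds_length(self) -> int:
        return sum(m.cds_length for m in self.models)

    @property
    def total_introns(self) -> int:
        return sum(m.intron_count for m in self.models)

    def __getitem__(self, gene_id: str) -> GeneModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    def __iter__(self):
        return iter(self.models)


@dataclass(frozen=True)
class ReadSupportRecord:
    """Read counts for and against a candidate LoF allele at one site."""

    gene_id: str
    position: int  # CDS-local, 1-based
    reads_supporting_lof: int
    reads_opposing_lof: int

    def __post_init__(self) -> None:
        if self.reads_supporting_lof < 0 or self.reads_opposing_lof < 0:
            raise ValueError(
                f"{self.gene_id}:{self.position}: negative read count"
            )

    @property
    def total_reads(self) -> int:
        return self.reads_supporting_lof + self.reads_opposing_lof


def read_gene_models(path: str | Path) -> GeneSet:
    """Read a tab-delimited gene-model table into a validated :class:`GeneSet`."""
    path = Path(path)
    rows: dict[str, list[tuple[int, int, str, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("gene_id", "exon_start", "exon_end"):
                    if col not in header:
                        raise GeneModelError(
                            f"{path}: missing required column {col!r}"
                        )
                continue
            rec = dict(zip(header, fields))
            try:
                start = int(rec["exon_start"])
                end = int(rec["exon_end"])
            except (KeyError, ValueError) as exc:
                raise GeneModelError(
                    f"{path}, line {lineno}: malformed exon coordinates"
                ) from exc
            gid = rec["gene_id"]
            if gid not in rows:
                rows[gid] = []
                order.append(gid)
            rows[gid].append(
                (start, end, rec.get("donor", "."), rec.get("acceptor", "."))
            )
    models = []
    for gid in order:
        exons = sorted(rows[gid])
        donors = tuple(d for _, _, d, _ in exons[:-1])
        acceptors = tuple(a for _, _, _, a in exons[:-1])
        if any(d == "." for d in donors) or any(a == "." for a in acceptors):
            donors, acceptors = (), ()  # fall back to canonical GT/AG
        models.append(
            GeneModel(
                gene_id=gid,
                exon_bounds=tuple((s, e) for s, e, _, _ in exons),
                donors=donors,
                acceptors=acceptors,
            )
        )
    return GeneSet(models=tuple(models))


def write_gene_models(gene_set: GeneSet, path: str | Path) -> None:
    """Write a :class:`GeneSet` in the dialect :func:`read_gene_models` reads."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive, CDS-local\n")
        fh.write("gene_id\texon_start\texon_end\tdonor\tacceptor\n")
        for model in gene_set:
            for i, (start, end) in enumerate(model.exon_bounds):
                last = i == len(model.exon_bounds) - 1
                donor = "." if last else model.donors[i]
                acceptor = "." if last else model.acceptors[i]
                fh.write(f"{model.gene_id}\t{start}\t{end}\t{donor}\t{acceptor}\n")


def read_sequences(path: str | Path) -> dict[str, dict[str, str]]:
    """Read FASTA into ``{sample_id: {gene_id: sequence}}``.

    Headers are ``gene_id|sample_id``; a header without ``|`` is assigned
    the sample id ``"."``. Sequences are uppercased and restricted to
    ``ACGTN-``.
    """
    result: dict[str, dict[str, str]] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        parts = record.id.split("|")
        gene_id = parts[0]
        sample_id = parts[1] if len(parts) > 1 else "."
        seq = str(record.seq).upper()
        for pos, char in enumerate(seq, start=1):
            if char not in VALID_ALPHABET:
                raise ValueError(
                    f"{record.id}: invalid character {char!r} at position {pos}"
                )
        result.setdefault(sample_id, {})[gene_id] = seq
    if n == 0:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return result


def write_sequences(
    sequences: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    """Write ``{sample_id: {gene_id: sequence}}`` as ``gene|sample`` FASTA."""
    with open(path, "w") as fh:
        for sample_id in sorted(sequences):
            for gene_id in sorted(sequences[sample_id]):
                fh.write(f">{gene_id}|{sample_id}\n")
                seq = sequences[sample_id][gene_id]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree with unique tip labels.

    Polytomies are accepted with a warning; duplicate tip labels are an
    error.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"{path}: duplicate tip labels in tree") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate tip labels in tree")
    for node in tree.preorder_node_iter():
        if len(node.child_nodes()) > 2:
            warnings.warn(
                f"{path}: tree contains a polytomy "
                f"({len(node.child_nodes())} children); origins mapped to a "
                "polytomy are assigned to its branch",
                stacklevel=2,
            )
            break
    return tree


def read_read_support(path: str | Path) -> list[ReadSupportRecord]:
    """Read the tab-delimited read-support table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "position", "reads_supporting_lof", "reads_opposing_lof"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ReadSupportRecord(
            gene_id=str(row.gene_id),
            position=int(row.position),
            reads_supporting_lof=int(row.reads_supporting_lof),
            reads_opposing_lof=int(row.reads_opposing_lof),
        )
        for row in df.itertuples()
    ]


def write_read_support(
    records: Iterable[ReadSupportRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "position": r.position,
                "reads_supporting_lof": r.reads_supporting_lof,
                "reads_opposing_lof": r.reads_opposing_lof,
            }
            for r in records
        ],
        columns=[
            "gene_id",
            "position",
            "reads_supporting_lof",
            "reads_opposing_lof",
        ],
    ).to_csv(path, sep="\t", index=False)
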