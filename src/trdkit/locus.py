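"""Germline gene data model, gene-table I/O and redundant-model collapsing.

A TRD locus annotation is held as a :class:`GeneTable` of :class:`GermlineGene`
records.  Coordinates are 1-based inclusive throughout (the convention of
genome-browser gene tables and of GFF3, which this module writes natively).
Gene models that represent the same gene on duplicated/misassembled scaffold
regions carry a shared ``redundancy_group`` marker and are merged by
:func:`collapse_redundant_models`, keeping the first-named model as the
representative and recording the merged members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GermlineGene",
    "GeneTable",
    "parse_gene_table",
    "collapse_redundant_models",
    "extract_gene_sequence",
    "write_annotation",
    "read_annotation",
    "load_genome",
]

_VALID_TYPES = {"V", "D", "J", "C"}


@dataclass
class GermlineGene:
    """A named V/D/J/C germline gene model.

    ``start``/``end`` are 1-based inclusive scaffold coordinates.  For minus
    orientation, ``sequence`` is the reverse complement of the genome slice,
    i.e. always the coding strand.
    """

    name: str
    gene_type: str
    scaffold: str
    start: int
    end: int
    orientation: str
    subgroup: str = ""
    sequence: str | None = None
    exons: list[tuple[str, int, int]] = field(default_factory=list)
    redundancy_group: str = ""
    functionality: str = "unset"
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_type not in _VALID_TYPES:
            raise ValueError(
                f"gene {self.name!r}: gene_type must be one of {sorted(_VALID_TYPES)}, "
                f"got {self.gene_type!r}"
            )
        if self.start > self.end:
            raise ValueError(f"gene {self.name!r}: start {self.start} > end {self.end}")
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"gene {self.name!r}: orientation must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneTable:
    """Ordered collection of germline gene records with unique names."""

    records: list[GermlineGene]
    source: str = ""

    def __post_init__(self) -> None:
        names = [g.name for g in self.records]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names in table: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> GermlineGene:
        for g in self.records:
            if g.name == name:
                return g
        raise KeyError(name)

    def by_type(self, gene_type: str) -> list[GermlineGene]:
        return [g for g in self.records if g.gene_type == gene_type]

    def by_subgroup(self, subgroup: str) -> list[GermlineGene]:
        return [g for g in self.records if g.subgroup == subgroup]


def _infer_type_and_subgroup(name: str) -> tuple[str, str]:
    """Infer gene type (and V subgroup) from a TRD gene symbol."""
    for prefix, gtype in (("TRDV", "V"), ("TRDD", "D"), ("TRDJ", "J"), ("TRDC", "C")):
        if name.upper().startswith(prefix):
            if gtype == "V":
                # subgroup digit follows TRDV, e.g. TRDV1a -> TRDV1
                rest = name[4:]
                digits = ""
                for ch in rest:
                    if ch.isdigit():
                        digits += ch
                    else:
                        break
                return gtype, f"TRDV{digits}" if digits else ""
            return gtype, ""
    raise ValueError(f"cannot infer gene type from name {name!r}")


def parse_gene_table(path: str | Path) -> GeneTable:
    """Parse a tab-separated gene-coordinate table into a :class:`GeneTable`.

    Required columns: ``name``, ``scaffold``, ``start``, ``end``,
    ``orientation``.  Optional: ``gene_type``, ``subgroup``, ``group``
    (redundancy-group marker, preserved verbatim).  Missing type/subgroup are
    inferred from the gene symbol.  A row whose start exceeds its end (as
    printed for one J gene in published tables) is normalized by swapping,
    with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected a header line")
    header = lines[0].rstrip("\n").split("\t")
    idx = {col.strip().lower(): i for i, col in enumerate(header)}
    for col in ("name", "scaffold", "start", "end", "orientation"):
        if col not in idx:
            raise ValueError(f"{path}: missing required column {col!r}")

    records: list[GermlineGene] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(idx):
            fields += [""] * (len(idx) - len(fields))
        try:
            name = fields[idx["name"]].strip()
            scaffold = fields[idx["scaffold"]].strip()
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
            orientation = fields[idx["orientation"]].strip()
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        if not name or not scaffold or orientation not in {"+", "-"}:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
        if start > end:
            warnings.warn(
                f"{path} line {lineno}: start {start} > end {end} for {name}; "
                "coordinates swapped",
                stacklevel=2,
            )
            start, end = end, start
        if "gene_type" in idx and fields[idx["gene_type"]].strip():
            gene_type = fields[idx["gene_type"]].strip()
            subgroup = fields[idx["subgroup"]].strip() if "subgroup" in idx else ""
        else:
            gene_type, subgroup = _infer_type_and_subgroup(name)
        group = fields[idx["group"]].strip() if "group" in idx else ""
        records.append(
            GermlineGene(
                name=name,
                gene_type=gene_type,
                subgroup=subgroup,
                scaffold=scaffold,
                start=start,
                end=end,
                orientation=orientation,
                redundancy_group=group,
            )
        )
    return GeneTable(records=records, source=str(path))


def collapse_redundant_models(table: GeneTable) -> GeneTable:
    """Merge gene models that share a redundancy-group marker.

    Models flagged with the same marker are taken to represent a single gene:
    the first-named model (table order) is kept as the representative and the
    merged model names are recorded in its ``members`` list.  Models without a
    marker pass through unchanged.  A marker carried by exactly one model is
    ignored with a warning.
    """
    group_sizes: dict[str, int] = {}
    for g in table:
        if g.redundancy_group:
            group_sizes[g.redundancy_group] = group_sizes.get(g.redundancy_group, 0) + 1

    seen_groups: set[str] = set()
    out: list[GermlineGene] = []
    for g in table:
        marker = g.redundancy_group
        if marker and group_sizes[marker] == 1:
            warnings.warn(
                f"redundancy marker {marker!r} appears on a single record "
                f"({g.name}); treated as no group",
                stacklevel=2,
            )
            marker = ""
        if not marker:
            out.append(g)
            continue
        if marker in seen_groups:
            continue  # already merged into the representative
        seen_groups.add(marker)
        members = [h.name for h in table if h.redundancy_group == g.redundancy_group]
        rep = GermlineGene(
            name=g.name,
            gene_type=g.gene_type,
            subgroup=g.subgroup,
            scaffold=g.scaffold,
            start=g.start,
            end=g.end,
            orientation=g.orientation,
            sequence=g.sequence,
            exons=list(g.exons),
            redundancy_group=g.redundancy_group,
            functionality=g.functionality,
            members=members,
        )
        out.append(rep)
    return GeneTable(records=out, source=table.source)


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome/locus file into a scaffold-name → sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_gene_sequence(
    genome: Mapping[str, str], gene: GermlineGene
) -> GermlineGene:
    """Fill ``gene.sequence`` from the genome (coding strand).

    The slice is ``genome[scaffold][start..end]`` 1-based inclusive, reverse
    complemented when orientation is ``-``.
    """
    if gene.scaffold not in genome:
        raise KeyError(f"gene {gene.name}: scaffold {gene.scaffold!r} not in genome")
    scaffold = genome[gene.scaffold]
    if not (1 <= gene.start <= gene.end <= len(scaffold)):
        raise ValueError(
            f"gene {gene.name}: coordinates {gene.start}..{gene.end} out of range "
            f"for scaffold {gene.scaffold} (length {len(scaffold)})"
        )
    seq = scaffold[gene.start - 1 : gene.end]
    if gene.orientation == "-":
        seq = str(Seq(seq).reverse_complement())
    gene.sequence = seq
    return gene


_GFF_TYPE = {"V": "V_gene_segment", "D": "D_gene_segment",
             "J": "J_gene_segment", "C": "C_gene_segment"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


def write_annotation(genes: GeneTable | Iterable[GermlineGene], path: str | Path) -> None:
    """Write gene records as GFF3: one gene feature per record plus exon rows."""
    records = list(genes)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in records:
            attrs = [f"ID={g.name}", f"Name={g.name}"]
            if g.subgroup:
                attrs.append(f"subgroup={g.subgroup}")
            if g.members:
                attrs.append("members=" + ",".join(g.members))
            fh.write(
                "\t".join(
                    [
                        g.scaffold,
                        "trdkit",
                        _GFF_TYPE[g.gene_type],
                        str(g.start),
                        str(g.end),
                        ".",
                        g.orientation,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for label, estart, eend in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.scaffold,
                            "trdkit",
                            "exon",
                            str(estart),
                            str(eend),
                            ".",
                            g.orientation,
                            ".",
                            f"ID={g.name}.{label};Parent={g.name};exon_label={label}",
                        ]
                    )
                    + "\n"
                )


def read_annotation(path: str | Path) -> GeneTable:
    """Read a GFF3 file written by :func:`write_annotation` back to a table."""
    records: dict[str, GermlineGene] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            scaffold, _, ftype, start, end, _, strand, _, attr_str = cols
            attrs = dict(
                kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv
            )
            if ftype in _GFF_TYPE_REV:
                name = attrs["ID"]
                members = attrs.get("members", "")
                records[name] = GermlineGene(
                    name=name,
                    gene_type=_GFF_TYPE_REV[ftype],
                    subgroup=attrs.get("subgroup", ""),
                    scaffold=scaffold,
                    start=int(start),
                    end=int(end),
                    orientation=strand,
                    members=members.split(",") if members else [],
                )
            elif ftype == "exon":
                parent = attrs["Parent"]
                records[parent].exons.append(
                    (attrs.get("exon_label", "exon"), int(start), int(end))
                )
    return GeneTable(records=list(records.values()), source=str(path))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    """Write a gene table as TSV in the same column layout parse_gene_table reads."""
    with open(path, "w") as fh:
        fh.write("name\tgene_type\tsubgroup\tscaffold\tstart\tend\torientation\tgroup\n")
        for g in table:
            fh.write(
                f"{g.name}\t{g.gene_type}\t{g.subgroup}\t{g.scaffold}\t"
                f"{g.start}\t{g.end}\t{g.orientation}\t{g.redundancy_group}\n"
            )
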