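"""Genome data model and FASTA/GFF3/TSV input-output.

Internal coordinates are 0-based half-open throughout the package; GFF3 is
read and written 1-based inclusive. Domain labels (e.g. Pfam accessions)
are normalized by uppercasing and stripping version suffixes, so
``PF00589.25`` and ``pf00589`` compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

_PFAM_VERSION = re.compile(r"^(PF\d{5})\.\d+$", re.IGNORECASE)


def normalize_domain_label(label: str) -> str:
    """Uppercase a domain accession and drop a Pfam version suffix."""
    label = label.strip()
    m = _PFAM_VERSION.match(label)
    if m:
        return m.group(1).upper()
    return label.upper()


@dataclass(frozen=True)
class Contig:
    """A single replicon or assembly contig."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneFeature:
    """A gene with optional domain labels, as produced by an upstream annotator.

    ``start``/``end`` are 0-based half-open on ``contig_id``; ``domain_labels``
    holds normalized accessions (see :func:`normalize_domain_label`).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    domain_labels: frozenset[str] = frozenset()
    product_label: Optional[str] = None
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        self.domain_labels = frozenset(
            normalize_domain_label(d) for d in self.domain_labels
        )

    def overlap(self, start: int, end: int) -> int:
        """Length of coordinate intersection with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class AnnotatedGenome:
    """Contigs plus position-sorted gene features; the substrate of detection."""

    genome_id: str
    contigs: list[Contig]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {c.id: c for c in self.contigs}
        if len(by_id) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        seen: set[str] = set()
        for f in self.features:
            if f.contig_id not in by_id:
                raise ValueError(
                    f"feature {f.gene_id} references unknown contig {f.contig_id}"
                )
            if f.end > by_id[f.contig_id].length:
                raise ValueError(
                    f"feature {f.gene_id} extends past end of contig {f.contig_id}"
                )
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)
        order = {c.id: i for i, c in enumerate(self.contigs)}
        self.features.sort(key=lambda f: (order[f.contig_id], f.start, f.end))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def features_on(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]


def _parse_domain_labels(attrs: Mapping[str, Sequence[str]], domain_key: str) -> frozenset[str]:
    labels: set[str] = set()
    for entry in attrs.get("Dbxref", []):
        for part in entry.split(","):
            part = part.strip()
            if part.upper().startswith("PFAM:"):
                labels.add(normalize_domain_label(part.split(":", 1)[1]))
    for entry in attrs.get(domain_key, []):
        for part in entry.split(","):
            if part.strip():
                labels.add(normalize_domain_label(part))
    return frozenset(labels)


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    *,
    genome_id: Optional[str] = None,
    domain_attribute: str = "domain",
    feature_types: Iterable[str] = ("CDS", "gene"),
) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an :class:`AnnotatedGenome`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Domain labels come from ``Dbxref`` entries prefixed ``Pfam:`` and from the
    ``domain_attribute`` GFF3 attribute (comma-separated). When both a CDS and
    a gene line share an ID, the CDS line wins.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = [
        Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    contig_ids = {c.id for c in contigs}
    wanted = set(feature_types)

    features: dict[str, GeneFeature] = {}
    seen_cds: set[str] = set()
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted parse errors
                raise ValueError(f"{gff_path}:{lineno}: unparseable GFF line: {exc}")
            if feat.featuretype not in wanted:
                continue
            if feat.seqid not in contig_ids:
                raise ValueError(
                    f"{gff_path}:{lineno}: feature references unknown contig "
                    f"{feat.seqid}"
                )
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("Name") or [f"feature_{lineno}"])[0]
            if gene_id in features and (
                feat.featuretype != "CDS" or gene_id in seen_cds
            ):
                continue
            if feat.featuretype == "CDS":
                seen_cds.add(gene_id)
            product = (attrs.get("product") or attrs.get("gene") or [None])[0]
            translation = (attrs.get("translation") or [None])[0]
            features[gene_id] = GeneFeature(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "+",
                domain_labels=_parse_domain_labels(attrs, domain_attribute),
                product_label=product,
                protein_seq=translation,
            )
    return AnnotatedGenome(
        genome_id=genome_id or fasta_path.stem,
        contigs=contigs,
        features=list(features.values()),
    )


def _feature_line(f: GeneFeature, source: str = "picmi") -> str:
    attrs = [f"ID={f.gene_id}"]
    if f.product_label:
        attrs.append(f"product={f.product_label}")
    if f.domain_labels:
        attrs.append("domain=" + ",".join(sorted(f.domain_labels)))
    if f.protein_seq:
        attrs.append(f"translation={f.protein_seq}")
    return "\t".join(
        [
            f.contig_id,
            source,
            "CDS",
            str(f.start + 1),
            str(f.end),
            ".",
            f.strand,
            ".",
            ";".join(attrs),
        ]
    )


def write_genome(
    genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write FASTA + GFF3; feature lines round-trip byte-stably through
    :func:`read_genome` + :func:`write_genome`."""
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in genome.contigs
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.contigs:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for f in genome.features:
            fh.write(_feature_line(f) + "\n")


def write_elements(elements: Sequence, out_dir: str | Path) -> dict[str, Path]:
    """Write detected elements as multi-FASTA + GFF3 + TSV summary.

    Accepts :class:`picmi.detect.PicmiElement` objects. Returns the paths
    written under keys ``fasta``, ``gff3``, ``tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "elements.fasta"
    gff_path = out_dir / "elements.gff3"
    tsv_path = out_dir / "elements.tsv"

    records = []
    rows = []
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for el in elements:
            eid = el.element_id
            records.append(SeqRecord(Seq(el.element_seq), id=eid, description=""))
            for f in el.internal_features():
                gff.write(_feature_line(f) + "\n")
            rows.append(
                {
                    "element_id": eid,
                    "genome_id": el.candidate.genome_id,
                    "contig_id": el.candidate.contig_id,
                    "element_start": el.element_start,
                    "element_end": el.element_end,
                    "element_len": len(el.element_seq),
                    "orientation": el.orientation,
                    "repeat_len": el.repeat.length if el.repeat else 0,
                    "repeat_seq": el.repeat.seq if el.repeat else "",
                    "n_small_orfs": len(el.small_orfs),
                }
            )
    SeqIO.write(records, str(fasta_path), "fasta")
    columns = [
        "element_id",
        "genome_id",
        "contig_id",
        "element_start",
        "element_end",
        "element_len",
        "orientation",
        "repeat_len",
        "repeat_seq",
        "n_small_orfs",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(tsv_path, sep="\t", index=False)
    return {"fasta": fasta_path, "gff3": gff_path, "tsv": tsv_path}


def write_report(rows: Sequence[Mapping], path: str | Path, columns=None) -> Path:
    """Write free-form report rows as TSV with a stable column order."""
    path = Path(path)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    pd.DataFrame(list(rows), columns=columns).to_csv(path, sep="\t", index=False)
    return path
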