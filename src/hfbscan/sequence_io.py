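"""FASTA/GFF3 input, CDS translation, and gene-structure statistics.

Provides the plumbing layer for the hydrophobin census: protein records
read from FASTA, standard-code CDS translation (so amino-acid counts can
be checked against annotated CDS lengths, aa = bp/3 - 1 for a
stop-terminated CDS), and exon/intron statistics derived from GFF3 gene
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ProteinRecord",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "reverse_translate",
    "gene_structure_stats",
    "gene_table",
]

#: Canonical amino-acid alphabet; X tolerated in provided records only.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Fixed codon per residue used by :func:`reverse_translate` (round trips
#: with :func:`translate_cds`; codon choice is arbitrary but stable).
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with provenance.

    ``source`` records whether the sequence was read as-is from a protein
    FASTA (``provided``) or produced by :func:`translate_cds`
    (``translated``).
    """

    id: str
    sequence: str
    source: Literal["provided", "translated"] = "provided"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ProteinRecord {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(
                f"ProteinRecord {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Gene-structure statistics derived from GFF3 exon/CDS features.

    Intron count is always derived as ``exon_count - 1``; if the source
    annotation carries explicit intron features that disagree,
    ``intron_annotation_disagrees`` is set instead of trusting either.
    """

    gene_id: str
    cds_length: int
    gene_length: int
    exon_count: int
    intron_count: int
    strand: Literal["+", "-"]
    intron_annotation_disagrees: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.cds_length > self.gene_length:
            raise ValueError(
                f"{self.gene_id}: CDS length exceeds gene length"
            )
        if self.exon_count < 1 or self.intron_count < 0:
            raise ValueError(f"{self.gene_id}: invalid exon/intron counts")


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated and case is normalized to
    upper. Duplicate ids raise ``ValueError``; an empty file returns an
    empty list with a warning.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no records in FASTA file {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def translate_cds(dna: str) -> str:
    """Translate a CDS with the standard genetic code.

    The terminal stop codon, if present, is excluded from the protein, so
    a stop-terminated CDS of ``3(n+1)`` bp yields ``n`` residues. Internal
    stops and non-ACGT symbols are rejected (ambiguity codes are not
    translated to X: downstream length arithmetic must stay exact).
    """
    dna = dna.upper()
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT symbol(s) in CDS: {sorted(bad)}")
    if len(dna) % 3 != 0:
        raise ValueError(f"CDS length {len(dna)} not divisible by 3")
    if not dna:
        raise ValueError("empty CDS")
    n_codons = len(dna) // 3
    protein: list[str] = []
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        if codon in _STANDARD_TABLE.stop_codons:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        protein.append(_STANDARD_TABLE.forward_table[codon])
    if not protein:
        raise ValueError("CDS encodes no residues")
    return "".join(protein)


def reverse_translate(protein: str, add_stop: bool = True) -> str:
    """Back-translate with a fixed codon per residue (plus TAA stop).

    Inverse of :func:`translate_cds` up to codon choice; used by the
    synthetic-data generator and round-trip tests.
    """
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValueError(f"cannot reverse-translate residue(s) {sorted(bad)}")
    cds = "".join(_CODON_OF[aa] for aa in protein)
    return cds + "TAA" if add_stop else cds


def _load_gff_db(gff: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(gff),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def gene_structure_stats(gff: str | Path, gene_id: str) -> GeneModel:
    """Derive a :class:`GeneModel` for one gene from a GFF3 file.

    Exon count is the number of ``exon`` features of the gene; the intron
    count is derived as ``exon_count - 1`` (boundaries between consecutive
    exons), never read from the annotation. Overlapping exon features are
    an error. GFF3 coordinates are 1-based inclusive.
    """
    db = _load_gff_db(gff)
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise ValueError(f"gene {gene_id!r} not found in {gff}") from exc

    exons = sorted(db.children(gene, featuretype="exon"), key=lambda f: f.start)
    cds_feats = list(db.children(gene, featuretype="CDS"))
    if not exons and not cds_feats:
        raise ValueError(f"gene {gene_id!r} has no exon or CDS features")
    if not exons:  # fall back to CDS segments as the transcribed blocks
        exons = sorted(cds_feats, key=lambda f: f.start)
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"gene {gene_id!r}: overlapping exon features at {a.end}/{b.start}"
            )
    cds_length = sum(f.end - f.start + 1 for f in cds_feats) if cds_feats else sum(
        f.end - f.start + 1 for f in exons
    )
    n_exons = len(exons)
    n_introns = n_exons - 1

    explicit_introns = list(db.children(gene, featuretype="intron"))
    disagrees = bool(explicit_introns) and len(explicit_introns) != n_introns

    return GeneModel(
        gene_id=gene_id,
        cds_length=cds_length,
        gene_length=gene.end - gene.start + 1,
        exon_count=n_exons,
        intron_count=n_introns,
        strand="-" if gene.strand == "-" else "+",
        intron_annotation_disagrees=disagrees,
    )


def gene_table(models: Iterable[GeneModel]) -> "pd.DataFrame":
    """Tabulate gene models in census-report column order."""
    import pandas as pd

    rows = [
        {
            "name": m.gene_id,
            "cds_bp": m.cds_length,
            "dna_bp": m.gene_length,
            "n_introns": m.intron_count,
            "n_exons": m.exon_count,
            "n_amino_acids": m.cds_length // 3 - 1,
            "intron_annotation_disagrees": m.intron_annotation_disagrees,
        }
        for m in models
    ]
    return pd.DataFrame(rows)
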