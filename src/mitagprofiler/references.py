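"""Reference rDNA operons: the per-taxon 16S/23S/5S gene set used for recruitment.

An operon reference carries, per taxon, the three ribosomal gene sequences,
the taxonomic lineage (domain → genus) and the per-genome operon copy
number.  Copy number matters because a cell with twelve operon copies
contributes twelve times the rDNA reads of a single-copy cell at equal
abundance; downstream normalisation divides it back out.

FASTA convention (one record per gene):

    >taxonID|gene|copies=N|lineage=domain;phylum;class;order;family;genus
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
GENE_NAMES = ("16S", "23S", "5S")

#: Gene lengths (bp) of the trimmed reference alignment used throughout:
#: full-length 16S, 23S and 5S rRNA genes.
GENE_LENGTHS = {"16S": 1819, "23S": 3731, "5S": 115}


@dataclass(frozen=True)
class OperonReference:
    """One taxon's assembled rDNA operon.

    Attributes
    ----------
    taxon_id:
        Unique identifier; recruitment counts partition over these.
    lineage:
        Rank labels ordered domain → genus (may stop early for taxa
        unresolved below e.g. family level).
    genes:
        Mapping gene name (``16S``/``23S``/``5S``) → nucleotide sequence.
    copy_number:
        rDNA operon copies per genome (≥ 1).
    """

    taxon_id: str
    lineage: tuple[str, ...]
    genes: Mapping[str, str] = field(default_factory=dict)
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")
        for gene in self.genes:
            if gene not in GENE_NAMES:
                raise ValueError(f"unknown gene name {gene!r}; expected one of {GENE_NAMES}")

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.genes.items()}

    def with_identity(self, taxon_id: str, lineage: tuple[str, ...],
                      copy_number: int | None = None) -> "OperonReference":
        """Return a copy re-labelled with another taxon's metadata."""
        return replace(
            self,
            taxon_id=taxon_id,
            lineage=tuple(lineage),
            copy_number=self.copy_number if copy_number is None else copy_number,
        )


def check_unique_taxa(refs: Iterable[OperonReference]) -> list[OperonReference]:
    refs = list(refs)
    seen: set[str] = set()
    for ref in refs:
        if ref.taxon_id in seen:
            raise ValueError(f"duplicate taxon_id in references: {ref.taxon_id!r}")
        seen.add(ref.taxon_id)
    return refs


def write_operons_fasta(refs: Iterable[OperonReference], path: str | Path) -> None:
    records = []
    for ref in refs:
        lineage = ";".join(ref.lineage)
        for gene in GENE_NAMES:
            if gene not in ref.genes:
                continue
            rid = f"{ref.taxon_id}|{gene}|copies={ref.copy_number}|lineage={lineage}"
            records.append(SeqRecord(Seq(ref.genes[gene]), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_operons_fasta(path: str | Path) -> list[OperonReference]:
    """Parse the pipe-delimited operon FASTA back into references."""
    by_taxon: dict[str, dict] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            taxon_id, gene, copies_f, lineage_f = rec.id.split("|", 3)
            copies = int(copies_f.removeprefix("copies="))
            lineage = tuple(lineage_f.removeprefix("lineage=").split(";"))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed operon FASTA header: {rec.id!r}") from exc
        entry = by_taxon.setdefault(
            taxon_id, {"lineage": lineage, "copies": copies, "genes": {}}
        )
        entry["genes"][gene] = str(rec.seq).upper()
    return check_unique_taxa(
        OperonReference(
            taxon_id=t,
            lineage=e["lineage"],
            genes=e["genes"],
            copy_number=e["copies"],
        )
        for t, e in by_taxon.items()
    )
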