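"""Reference tag library construction by in-silico NlaIII/MmeI digestion.

NlaIII cuts cDNA at every CATG; MmeI then cuts 17 bp downstream of the
CATG recognition junction, so each qualifying site yields a 21-base tag:
``CATG`` plus the 17 bases that follow it.  The reference library holds
*all* such tags of a transcriptome (not only the 3'-most one that the
bead-bound protocol actually sequences), each annotated with its gene
origins and an ambiguity flag.

Coordinates are 0-based; a tag occupies the half-open interval
``[offset, offset + 21)`` of the strand it was read from.  For minus-strand
tags (``strand_mode="both"``) the offset refers to the reverse complement
of the record sequence, so ``revcomp(seq)[offset:offset+21] == tag``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

ANCHOR = "CATG"
DOWNSTREAM = 17
TAG_LENGTH = len(ANCHOR) + DOWNSTREAM  # 21


def find_catg_sites(sequence: str) -> list[int]:
    """Positions of the 'C' of every CATG occurrence in *sequence*.

    Scanning is exhaustive and case-insensitive; CATG cannot self-overlap
    so a simple forward scan finds every site.  Returns a strictly
    increasing list; an empty sequence yields an empty list.
    """
    seq = sequence.upper()
    sites: list[int] = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(ANCHOR, pos + 1)
    return sites


def extract_tags(sequence: str) -> list[tuple[int, str]]:
    """All (offset, 21-mer) tags of *sequence*.

    A CATG site qualifies only if at least 17 bases follow it
    (``offset + 21 <= len(sequence)``).  Tags containing ``N`` are
    excluded: clean tags are N-free by filtering, so such reference
    entries could never be matched.
    """
    seq = sequence.upper()
    out = []
    for pos in find_catg_sites(seq):
        if pos + TAG_LENGTH > len(seq):
            continue
        tag = seq[pos:pos + TAG_LENGTH]
        if "N" in tag:
            continue
        out.append((pos, tag))
    return out


def canonical_tag(sequence: str) -> str | None:
    """Tag of the 3'-most qualifying CATG site, or None.

    This is the tag the bead-based protocol sequences: NlaIII digestion
    leaves the 3'-most fragment bound to the oligo(dT) beads.
    """
    tags = extract_tags(sequence)
    return tags[-1][1] if tags else None


@dataclass(frozen=True)
class ReferenceTag:
    """One 21-base reference tag and its origins.

    origins is a frozenset of ``(gene_id, offset, strand)`` triples;
    ``is_gene_unique`` is True when all origins share one gene.
    """

    tag: str
    origins: frozenset[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH or not self.tag.startswith(ANCHOR):
            raise ValueError(f"not a valid reference tag: {self.tag!r}")
        if not self.origins:
            raise ValueError("reference tag with no origins")

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.origins)

    @property
    def is_gene_unique(self) -> bool:
        return len(self.gene_ids) == 1


@dataclass
class ReferenceTagLibrary:
    """All reference tags of a transcriptome, keyed by tag sequence."""

    tags: dict[str, ReferenceTag]
    gene_ids: list[str]
    genes_taggable: int
    strand_mode: str = "sense_only"

    @property
    def genes_total(self) -> int:
        return len(self.gene_ids)

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def genes_of(self, tag: str) -> frozenset[str]:
        """Gene ids whose reference tags include *tag* (empty if absent)."""
        entry = self.tags.get(tag)
        return entry.gene_ids if entry is not None else frozenset()


def build_reference_library(
    records: Iterable[tuple[str, str]],
    strand_mode: str = "sense_only",
) -> ReferenceTagLibrary:
    """Digest every record and merge tags across genes.

    Parameters
    ----------
    records
        Iterable of ``(gene_id, sequence)``; gene ids must be unique.
    strand_mode
        ``"sense_only"`` (default; assembled unigenes have a determined
        orientation) or ``"both"`` to also scan the reverse complement.
    """
    if strand_mode not in ("sense_only", "both"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    origins: dict[str, set[tuple[str, int, str]]] = {}
    gene_ids: list[str] = []
    seen: set[str] = set()
    taggable = 0
    for gene_id, sequence in records:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id: {gene_id!r}")
        seen.add(gene_id)
        gene_ids.append(gene_id)
        strands = [("+", sequence)]
        if strand_mode == "both":
            strands.append(("-", reverse_complement(sequence.upper())))
        any_tag = False
        for strand, seq in strands:
            for offset, tag in extract_tags(seq):
                origins.setdefault(tag, set()).add((gene_id, offset, strand))
                any_tag = True
        if any_tag:
            taggable += 1
    tags = {
        tag: ReferenceTag(tag=tag, origins=frozenset(orig))
        for tag, orig in origins.items()
    }
    log.info(
        "reference library: %d genes (%d taggable), %d distinct tags [%s]",
        len(gene_ids), taggable, len(tags), strand_mode,
    )
    return ReferenceTagLibrary(
        tags=tags, gene_ids=gene_ids, genes_taggable=taggable,
        strand_mode=strand_mode,
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped, mixed-case) FASTA into (id, seq) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def build_reference_library_from_fasta(path, strand_mode: str = "sense_only") -> ReferenceTagLibrary:
    return build_reference_library(read_fasta(path), strand_mode=strand_mode)


def write_reference_tsv(library: ReferenceTagLibrary, path) -> None:
    """Write the library as TSV: tag, genes, offsets, strands, gene_unique."""
    with open(path, "w") as fh:
        fh.write("tag\tgene_ids\toffsets\tstrands\tgene_unique\n")
        for tag in sorted(library.tags):
            entry = library.tags[tag]
            origin_list = sorted(entry.origins)
            fh.write("\t".join([
                tag,
                ";".join(g for g, _, _ in origin_list),
                ";".join(str(o) for _, o, _ in origin_list),
                ";".join(s for _, _, s in origin_list),
                str(entry.is_gene_unique).lower(),
            ]) + "\n")
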