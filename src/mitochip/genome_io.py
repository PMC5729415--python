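"""Annotated organelle genome I/O and ortholog pairing.

Reads GenBank flat files into light-weight records, extracts strand-aware,
exon-joined (sense/mRNA-like) gene sequences, applies C-to-U RNA-editing
tables so that downstream probe design works against the edited transcript
sequence, and pairs orthologous genes across two genomes by gene symbol.

Coordinates are 0-based, half-open everywhere inside the package; the
GenBank reader converts from the format's 1-based inclusive convention at
the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: feature categories eligible for downstream quantification
QUANTIFIABLE_CATEGORIES = frozenset({"protein", "orf"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: symbol, category, strand and genomic intervals.

    ``intervals`` is an ordered list of ``(start, end)`` 0-based half-open
    genomic intervals in ascending genomic order; multi-interval features
    represent spliced genes.  ``category`` is one of ``protein``, ``orf``,
    ``tRNA``, ``rRNA``.
    """

    name: str
    category: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name}: no intervals")
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"feature {self.name}: empty interval [{start}, {end})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.intervals)

    def exon_boundaries(self) -> frozenset[int]:
        """Splice-junction offsets in the spliced sense-strand sequence.

        A boundary at offset ``j`` sits between sense positions ``j-1`` and
        ``j``; windows spanning a boundary cross an exon junction.
        """
        cuts: list[int] = []
        total = self.spliced_length
        acc = 0
        for start, end in self.intervals[:-1]:
            acc += end - start
            cuts.append(acc)
        if self.strand == "-":
            cuts = [total - c for c in cuts]
        return frozenset(cuts)


@dataclass(frozen=True)
class GenomeRecord:
    """An organelle genome: accession, sequence and gene features."""

    accession: str
    sequence: str
    features: tuple[GeneFeature, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.accession}: ambiguity codes other than N are not "
                f"supported: {sorted(bad)}"
            )
        for feat in self.features:
            for start, end in feat.intervals:
                if start < 0 or end > self.length:
                    raise ValueError(
                        f"{self.accession}: feature {feat.name} interval "
                        f"[{start}, {end}) outside genome of length {self.length}"
                    )

    def get_feature(self, name: str) -> GeneFeature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise KeyError(name)


@dataclass(frozen=True)
class EditingSite:
    """A C-to-U editing site in spliced sense-strand CDS coordinates.

    ``genomic_base`` is the unedited base expected at ``cds_position``
    (normally C) and ``edited_base`` the base after editing in cDNA space
    (normally T).
    """

    gene: str
    cds_position: int
    genomic_base: str = "C"
    edited_base: str = "T"

    def __post_init__(self) -> None:
        if self.edited_base == self.genomic_base:
            raise ValueError(
                f"{self.gene} pos {self.cds_position}: edited base equals "
                "genomic base"
            )


@dataclass(frozen=True)
class OrthologPair:
    """Edited sense-strand sequences of one gene in both species.

    Species A plays the tobacco role, species B the Arabidopsis role.
    ``boundaries_a``/``boundaries_b`` hold splice-junction offsets that
    probe windows must not span.
    """

    gene: str
    seq_a: str
    seq_b: str
    category: str
    editing_applied: tuple[bool, bool] = (False, False)
    boundaries_a: frozenset[int] = frozenset()
    boundaries_b: frozenset[int] = frozenset()


@dataclass(frozen=True)
class UnpairedGene:
    """A gene present in only one of the two genomes."""

    gene: str
    species: str  # "A" or "B"
    seq: str
    category: str
    editing_applied: bool = False
    boundaries: frozenset[int] = frozenset()


@dataclass
class PairingResult:
    pairs: list[OrthologPair] = field(default_factory=list)
    unpaired: list[UnpairedGene] = field(default_factory=list)


def _classify(feature_type: str, name: str) -> str:
    if feature_type == "tRNA":
        return "tRNA"
    if feature_type == "rRNA":
        return "rRNA"
    return "orf" if name.lower().startswith("orf") else "protein"


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    CDS, tRNA and rRNA features are parsed; plain ``gene`` features (which
    duplicate the CDS span without exon structure) and anything else are
    ignored.  Features without a usable name qualifier are logged and
    skipped.  Duplicate gene symbols are disambiguated with a numeric
    suffix and a warning.

    Raises
    ------
    ValueError
        If the record carries no sequence (missing ORIGIN) or contains
        ambiguity codes other than N.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        sequence = str(record.seq).upper()
    except Exception as exc:  # Bio.Seq.UndefinedSequenceError
        raise ValueError(f"{path}: GenBank record has no sequence (ORIGIN)") from exc
    if not sequence:
        raise ValueError(f"{path}: GenBank record has no sequence (ORIGIN)")

    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = _feature_name(feat)
        if name is None:
            logger.warning(
                "%s: skipping %s feature at %s without gene/product/locus_tag",
                record.id, feat.type, feat.location,
            )
            continue
        if feat.location is None or feat.location.strand is None:
            logger.warning("%s: skipping strandless feature %s", record.id, name)
            continue
        if name in seen:
            seen[name] += 1
            new_name = f"{name}.{seen[name]}"
            warnings.warn(
                f"{record.id}: duplicate gene name {name!r} renamed to {new_name!r}",
                stacklevel=2,
            )
            name = new_name
        else:
            seen[name] = 1
        intervals = tuple(
            sorted((int(part.start), int(part.end)) for part in feat.location.parts)
        )
        strand = "+" if feat.location.strand >= 0 else "-"
        features.append(
            GeneFeature(
                name=name,
                category=_classify(feat.type, name),
                strand=strand,
                intervals=intervals,
            )
        )
    return GenomeRecord(
        accession=record.id or record.name, sequence=sequence,
        features=tuple(features),
    )


def extract_gene_sequence(record: GenomeRecord, feature: GeneFeature) -> str:
    """Spliced sense-strand (mRNA-like) sequence of ``feature``.

    Intervals are concatenated in ascending genomic order; minus-strand
    features are reverse complemented after concatenation.
    """
    parts = []
    for start, end in feature.intervals:
        if start < 0 or end > record.length:
            raise ValueError(
                f"{feature.name}: interval [{start}, {end}) out of bounds for "
                f"{record.accession} (length {record.length})"
            )
        parts.append(record.sequence[start:end])
    joined = "".join(parts)
    return reverse_complement(joined) if feature.strand == "-" else joined


def apply_editing(
    seq: str, sites: Sequence[EditingSite], *, check: bool = True
) -> str:
    """Substitute edited bases into ``seq`` at each site's CDS position.

    With ``check=True`` (default) every site's ``genomic_base`` must match
    the input; this guards against coordinate-convention mistakes.  With
    ``check=False`` the call is idempotent on already-edited sequences.
    """
    if not sites:
        return seq
    out = list(seq)
    for site in sites:
        pos = site.cds_position
        if pos < 0 or pos >= len(seq):
            raise ValueError(
                f"editing site {site.gene} pos {pos}: outside sequence of "
                f"length {len(seq)}"
            )
        if check and out[pos] != site.genomic_base:
            raise ValueError(
                f"editing site {site.gene} pos {pos}: expected "
                f"{site.genomic_base!r}, sequence has {out[pos]!r}"
            )
        out[pos] = site.edited_base
    return "".join(out)


def read_editing_table(path: str | Path) -> dict[str, list[EditingSite]]:
    """Read an editing TSV (columns: gene, cds_position, from, to).

    Returns a mapping gene symbol -> list of sites sorted by position.
    """
    sites: dict[str, list[EditingSite]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["gene", "cds_position", "from", "to"]
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            gene, pos, base_from, base_to = fields
            sites.setdefault(gene, []).append(
                EditingSite(
                    gene=gene,
                    cds_position=int(pos),
                    genomic_base=base_from.upper(),
                    edited_base=base_to.upper(),
                )
            )
    for gene_sites in sites.values():
        gene_sites.sort(key=lambda s: s.cds_position)
    return sites


def write_editing_table(
    path: str | Path, sites: Mapping[str, Sequence[EditingSite]]
) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tcds_position\tfrom\tto\n")
        for gene in sorted(sites):
            for site in sites[gene]:
                handle.write(
                    f"{gene}\t{site.cds_position}\t{site.genomic_base}\t"
                    f"{site.edited_base}\n"
                )


def _extract_all(
    record: GenomeRecord,
    editing: Mapping[str, Sequence[EditingSite]] | None,
    name_map: Mapping[str, str] | None,
) -> dict[str, tuple[str, str, bool, frozenset[int]]]:
    """gene -> (edited sense seq, category, editing applied?, boundaries)."""
    out: dict[str, tuple[str, str, bool, frozenset[int]]] = {}
    for feat in record.features:
        name = name_map.get(feat.name, feat.name) if name_map else feat.name
        seq = extract_gene_sequence(record, feat)
        edited = False
        if editing and feat.name in editing:
            seq = apply_editing(seq, editing[feat.name])
            edited = True
        elif editing and name != feat.name and name in editing:
            seq = apply_editing(seq, editing[name])
            edited = True
        out[name] = (seq, feat.category, edited, feat.exon_boundaries())
    return out


def pair_orthologs(
    rec_a: GenomeRecord,
    rec_b: GenomeRecord,
    name_map: Mapping[str, str] | None = None,
    editing_a: Mapping[str, Sequence[EditingSite]] | None = None,
    editing_b: Mapping[str, Sequence[EditingSite]] | None = None,
) -> PairingResult:
    """Pair genes across two genomes by (mapped) symbol.

    Each species' own editing table is applied to its own sequences before
    pairing.  Genes found in only one genome are returned in the unpaired
    report; they receive species-specific probes downstream.
    """
    genes_a = _extract_all(rec_a, editing_a, name_map)
    genes_b = _extract_all(rec_b, editing_b, name_map)
    result = PairingResult()
    for gene in sorted(set(genes_a) | set(genes_b)):
        in_a, in_b = gene in genes_a, gene in genes_b
        if in_a and in_b:
            seq_a, cat_a, ed_a, bnd_a = genes_a[gene]
            seq_b, cat_b, ed_b, bnd_b = genes_b[gene]
            if cat_a != cat_b:
                logger.warning(
                    "gene %s: category differs across species (%s vs %s); "
                    "using %s", gene, cat_a, cat_b, cat_b,
                )
            result.pairs.append(
                OrthologPair(
                    gene=gene, seq_a=seq_a, seq_b=seq_b, category=cat_b,
                    editing_applied=(ed_a, ed_b),
                    boundaries_a=bnd_a, boundaries_b=bnd_b,
                )
            )
        else:
            species = "A" if in_a else "B"
            seq, cat, ed, bnd = (genes_a if in_a else genes_b)[gene]
            result.unpaired.append(
                UnpairedGene(
                    gene=gene, species=species, seq=seq, category=cat,
                    editing_applied=ed, boundaries=bnd,
                )
            )
    return result


def read_name_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping variant gene spellings to canonical ones."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            variant, canonical = line.split("\t")[:2]
            mapping[variant] = canonical
    return mapping


def write_gene_fasta(
    path: str | Path, genes: Mapping[str, str] | Iterable[tuple[str, str]]
) -> None:
    """Dump per-gene sense-strand sequences as FASTA."""
    items = genes.items() if isinstance(genes, Mapping) else genes
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def translate_cds(seq: str) -> str:
    """Standard-code translation helper (diagnostics only)."""
    return str(Seq(seq).translate())
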