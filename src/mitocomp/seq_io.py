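"""Reading and writing genome records, and the internal data model.

GenBank flat files use 1-based inclusive coordinates; internally
everything is 0-based half-open, converted once at the I/O boundary
(Biopython already stores locations that way, so the conversion happens
inside Bio.SeqIO and we only validate). Features carry a coarse type
(CDS/rRNA/tRNA/spacer) and a gene-class label separating annotated
genes from unassigned ORFs (the ymf genes of ciliate mitochondria).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codes import DEFAULT_CODE_ID, get_code, revcomp

log = logging.getLogger(__name__)

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "spacer")
GENE_CLASSES = ("known", "orf", "rna", "noncoding")

VALID_BASES = set("ACGTN")


class SeqIoError(ValueError):
    """Malformed input file or feature table."""


class IntegrityError(SeqIoError):
    """Record violates an internal-model invariant."""


class InternalStopError(ValueError):
    def __init__(self, name: str, position_aa: int):
        self.name = name
        self.position_aa = position_aa
        super().__init__(
            f"internal stop codon in {name!r} at amino-acid position {position_aa} "
            "(wrong frame or wrong genetic code?)"
        )


@dataclass
class Feature:
    """A stranded genome feature in 0-based half-open coordinates."""

    name: str
    ftype: str  # CDS | rRNA | tRNA | spacer
    start: int
    end: int
    strand: str  # '+' | '-'
    gene_class: str  # known | orf | rna | noncoding
    # multi-segment (GenBank join) locations; defaults to the single span
    parts: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise IntegrityError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.gene_class not in GENE_CLASSES:
            raise IntegrityError(f"{self.name}: unknown gene class {self.gene_class!r}")
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"{self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise IntegrityError(f"{self.name}: strand must be '+' or '-'")
        if not self.parts:
            self.parts = [(self.start, self.end)]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def __len__(self) -> int:
        return self.length


@dataclass
class GenomeRecord:
    """A (linear) genome sequence with its typed feature table."""

    id: str
    sequence: str
    topology: str = "linear"
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise SeqIoError(
                f"{self.id}: ambiguity characters other than N not supported: "
                f"{sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise IntegrityError(f"{self.id}: topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise IntegrityError(
                    f"{self.id}: feature {f.name} end {f.end} beyond genome "
                    f"length {len(self.sequence)}"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes(self) -> List[Feature]:
        """All annotated gene features (everything except derived spacers)."""
        return [f for f in self.features if f.ftype != "spacer"]


@dataclass
class CodingSequence:
    """An in-frame coding sequence and its translation."""

    name: str
    nucleotides: str
    protein: str
    code_id: int
    trailing_stop: bool = False

    def __post_init__(self):
        expected = len(self.nucleotides) // 3 - (1 if self.trailing_stop else 0)
        if len(self.protein) != expected:
            raise IntegrityError(
                f"{self.name}: protein length {len(self.protein)} != {expected}"
            )


def classify_gene(name: str, ftype: str) -> str:
    """Gene class from the annotated name: ymf* are unassigned ORFs."""
    if ftype in ("rRNA", "tRNA"):
        return "rna"
    if ftype == "spacer":
        return "noncoding"
    return "orf" if name.lower().startswith("ymf") else "known"


def _feature_name(sf: SeqFeature, index: int) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return f"{sf.type}_{index}"


def read_genbank(path) -> GenomeRecord:
    """Read a GenBank flat file into a GenomeRecord.

    Only LOCUS/FEATURES/ORIGIN content is required. CDS/rRNA/tRNA
    features are captured; join/complement locations are resolved into
    ordered parts. Raises on coordinate or length inconsistencies.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise SeqIoError(f"{path}: cannot parse GenBank record: {exc}") from exc
    topology = rec.annotations.get("topology", "linear")
    features: List[Feature] = []
    for i, sf in enumerate(rec.features):
        if sf.type not in ("CDS", "rRNA", "tRNA"):
            continue
        name = _feature_name(sf, i)
        loc = sf.location
        if loc is None:
            raise SeqIoError(f"{path}: feature {name!r} has unresolvable location")
        parts = sorted((int(p.start), int(p.end)) for p in loc.parts)
        strand = "-" if loc.strand == -1 else "+"
        feat = Feature(
            name=name,
            ftype=sf.type,
            start=int(loc.start),
            end=int(loc.end),
            strand=strand,
            gene_class=classify_gene(name, sf.type),
            parts=parts,
        )
        if sf.type == "CDS" and feat.length % 3 != 0:
            raise IntegrityError(
                f"{path}: CDS {name!r} length {feat.length} not a multiple of 3"
            )
        features.append(feat)
    return GenomeRecord(
        id=rec.id or rec.name, sequence=str(rec.seq), topology=topology, features=features
    )


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trip safe)."""
    seq_rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description="",
        annotations={"molecule_type": "DNA", "topology": record.topology},
    )
    for f in record.features:
        if f.ftype == "spacer":
            continue
        strand = -1 if f.strand == "-" else 1
        if len(f.parts) == 1:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:
            from Bio.SeqFeature import CompoundLocation

            loc = CompoundLocation(
                [SimpleLocation(s, e, strand=strand) for s, e in f.parts]
            )
        seq_rec.features.append(
            SeqFeature(loc, type=f.ftype, qualifiers={"gene": [f.name]})
        )
    SeqIO.write([seq_rec], str(path), "genbank")


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA into ordered (id, uppercase sequence) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise SeqIoError(f"{path}: duplicate FASTA ids: {dupes}")
    if not records:
        log.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path, wrap: int = 60) -> None:
    with open(str(path), "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def feature_nucleotides(record: GenomeRecord, feature: Feature) -> str:
    """Coding-strand nucleotides of a feature (parts joined, '-' revcomp'd)."""
    nt = "".join(record.sequence[s:e] for s, e in feature.parts)
    return revcomp(nt) if feature.strand == "-" else nt


def extract_cds(
    record: GenomeRecord, feature: Feature, code_id: int = DEFAULT_CODE_ID
) -> CodingSequence:
    """Extract and translate a CDS feature under the given genetic code.

    Minus-strand features are reverse-complemented; a trailing stop is
    flagged and excluded from the protein; an internal stop raises
    InternalStopError with its amino-acid position.
    """
    if feature.ftype != "CDS":
        raise ValueError(f"{feature.name}: extract_cds requires a CDS feature")
    nt = feature_nucleotides(record, feature)
    if len(nt) % 3 != 0:
        raise IntegrityError(
            f"{feature.name}: CDS length {len(nt)} not a multiple of 3"
        )
    code = get_code(code_id)
    aa = code.translate(nt)
    trailing_stop = aa.endswith("*")
    body = aa[:-1] if trailing_stop else aa
    if "*" in body:
        raise InternalStopError(feature.name, body.index("*"))
    return CodingSequence(
        name=feature.name,
        nucleotides=nt,
        protein=body,
        code_id=code_id,
        trailing_stop=trailing_stop,
    )
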