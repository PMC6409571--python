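"""Readers and writers for genome sequences and tRNA/CDS annotations.

All coordinates are held internally as 0-based half-open intervals; the
native conventions of each dialect (GFF3 and tRNAscan-SE are 1-based
inclusive) are converted on the way in and restored on the way out.

tRNA isotypes use the single-letter amino-acid code extended with
``O`` (pyrrolysine), ``U`` (selenocysteine) and ``X`` (undetermined);
predictors occasionally emit ambiguous isotype calls, which map to ``X``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: 20 standard amino acids + pyrrolysine (O) + selenocysteine (U) + undetermined (X)
ISOTYPE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("OUX")

_ISOTYPE_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Pyl": "O", "Sec": "U", "SeC": "U", "Undet": "X", "Xxx": "X",
    "iMet": "M", "fMet": "M",
}

# tRNA genes are typically ~72-95 bp; lengths far outside this range are
# suspicious annotations but not fatal.
TRNA_MIN_LEN = 50
TRNA_MAX_LEN = 200


def map_isotype(name: str) -> str:
    """Map an isotype name (3-letter, or already 1-letter) to the single-letter code.

    Unknown or ambiguous names (e.g. ``Glu|Gly`` from a predictor that could
    not discriminate) map to ``X`` with a warning.
    """
    name = name.strip()
    if len(name) == 1 and name.upper() in ISOTYPE_ALPHABET:
        return name.upper()
    if name in _ISOTYPE_3TO1:
        return _ISOTYPE_3TO1[name]
    title = name[:1].upper() + name[1:].lower()
    if title in _ISOTYPE_3TO1:
        return _ISOTYPE_3TO1[title]
    warnings.warn(f"unknown tRNA isotype name {name!r}; mapped to X")
    return "X"


@dataclass
class GenomeRecord:
    """One genome/replicon: identifier, length, composition and metadata."""

    genome_id: str
    length_bp: int
    gc_fraction: float
    circular: bool = False
    metadata: dict[str, str] = field(default_factory=dict)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"genome {self.genome_id}: length_bp must be > 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"genome {self.genome_id}: gc_fraction outside [0, 1]")


@dataclass(frozen=True)
class TrnaGene:
    """An annotated tRNA gene (0-based half-open coordinates)."""

    genome_id: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"tRNA gene on {self.genome_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.isotype not in ISOTYPE_ALPHABET:
            raise ValueError(f"isotype {self.isotype!r} outside the isotype alphabet")
        length = self.end - self.start
        if not TRNA_MIN_LEN <= length <= TRNA_MAX_LEN:
            warnings.warn(
                f"tRNA gene on {self.genome_id} at {self.start} has unusual "
                f"length {length} bp (expected {TRNA_MIN_LEN}-{TRNA_MAX_LEN})"
            )
        if self.anticodon is not None and (
            len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT")
        ):
            object.__setattr__(self, "anticodon", None)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CdsRecord:
    """A protein-coding gene; ``sequence`` is the coding strand 5'->3'."""

    genome_id: str
    cds_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CDS {self.cds_id}: start >= end")
        if self.sequence is not None:
            if len(self.sequence) < 3:
                raise ValueError(f"CDS {self.cds_id}: sequence shorter than one codon")
            rem = len(self.sequence) % 3
            if rem:
                warnings.warn(
                    f"CDS {self.cds_id}: length {len(self.sequence)} not divisible "
                    f"by 3; trailing {rem} nt trimmed"
                )
                self.sequence = self.sequence[: len(self.sequence) - rem]


def compute_gc(sequence: str) -> float:
    """GC fraction over unambiguous bases only: (G+C)/(A+C+G+T)."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    return gc / total if total else 0.0


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeRecord]:
    """Read genome FASTA into :class:`GenomeRecord` objects with sequences retained."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        records.append(
            GenomeRecord(
                genome_id=rec.id,
                length_bp=len(seq),
                gc_fraction=compute_gc(seq),
                circular=circular,
                sequence=seq,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


# ---------------------------------------------------------------------------
# tRNA annotation dialects
# ---------------------------------------------------------------------------

TRNA_DIALECTS = ("trnascan_tsv", "gff3", "simple_tsv")


def read_trna_annotations(path: str | Path, dialect: str) -> list[TrnaGene]:
    """Read tRNA gene annotations in one of the supported dialects.

    ``trnascan_tsv``
        tRNAscan-SE 2.0 tabular output (1-based inclusive; begin > end
        encodes the minus strand).
    ``gff3``
        features of type ``tRNA`` with a ``product`` attribute such as
        ``tRNA-Met`` and an optional ``anticodon`` attribute.
    ``simple_tsv``
        the internal table written by :func:`write_trna_table`
        (0-based half-open, explicit strand column).
    """
    if dialect == "trnascan_tsv":
        return _read_trnascan(path)
    if dialect == "gff3":
        return _read_trna_gff3(path)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {TRNA_DIALECTS}")


def _read_trnascan(path: str | Path) -> list[TrnaGene]:
    genes: list[TrnaGene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            # header block: column-name lines and the ----- ruler
            if fields[0].startswith(("Sequence", "Name", "--")):
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: malformed tRNAscan-SE row: {line!r}")
            try:
                begin, end = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates in tRNAscan-SE row"
                ) from exc
            genes.append(
                _gene_from_one_based(
                    genome_id=fields[0],
                    begin=begin,
                    end=end,
                    isotype=map_isotype(fields[4]),
                    anticodon=fields[5].upper() or None,
                )
            )
    return genes


def _gene_from_one_based(
    genome_id: str, begin: int, end: int, isotype: str, anticodon: str | None
) -> TrnaGene:
    """1-based inclusive coordinates; begin > end means minus strand."""
    if begin > end:
        strand, begin, end = "-", end, begin
    else:
        strand = "+"
    return TrnaGene(
        genome_id=genome_id,
        start=begin - 1,
        end=end,
        strand=strand,
        isotype=isotype,
        anticodon=anticodon,
    )


def _read_trna_gff3(path: str | Path) -> list[TrnaGene]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("tRNA"):
        product = feat.attributes.get("product", [""])[0]
        isotype_name = feat.attributes.get("isotype", [None])[0]
        if isotype_name is None and product.startswith("tRNA-"):
            isotype_name = product.split("-", 1)[1].split("(")[0]
        isotype = map_isotype(isotype_name) if isotype_name else "X"
        anticodon = feat.attributes.get("anticodon", [None])[0]
        if anticodon is None and "(" in product and product.endswith(")"):
            anticodon = product.rsplit("(", 1)[1][:-1]
        genes.append(
            TrnaGene(
                genome_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                isotype=isotype,
                anticodon=anticodon.upper() if anticodon else None,
            )
        )
    return genes


_SIMPLE_COLUMNS = ["genome_id", "start", "end", "strand", "isotype", "anticodon"]


def _read_simple_tsv(path: str | Path) -> list[TrnaGene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SIMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: simple TSV missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            TrnaGene(
                genome_id=row.genome_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                isotype=row.isotype,
                anticodon=row.anticodon or None,
            )
        )
    return genes


def write_trna_table(genes: Iterable[TrnaGene], path: str | Path) -> None:
    """Write the internal simple TSV dialect (round-trips through
    ``read_trna_annotations(..., dialect="simple_tsv")`` exactly)."""
    rows = [
        {
            "genome_id": g.genome_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "isotype": g.isotype,
            "anticodon": g.anticodon or "",
        }
        for g in genes
    ]
    write_report(rows, path, columns=_SIMPLE_COLUMNS)


# ---------------------------------------------------------------------------
# CDS input
# ---------------------------------------------------------------------------


def read_cds(
    path: str | Path,
    genome_sequences: dict[str, str] | None = None,
    dialect: str = "gff3",
) -> list[CdsRecord]:
    """Read CDS annotations from GFF3 (sequences extracted from the genome)
    or from a FASTA of CDS nucleotide sequences.

    Minus-strand GFF3 features are reverse-complemented so that ``sequence``
    is always the coding strand 5'->3'.
    """
    if dialect == "fasta":
        return _read_cds_fasta(path)
    if dialect != "gff3":
        raise ValueError(f"unknown CDS dialect {dialect!r}")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for feat in db.features_of_type("CDS"):
        seq = None
        if genome_sequences is not None:
            genome_seq = genome_sequences.get(feat.seqid)
            if genome_seq is not None:
                if feat.end > len(genome_seq):
                    raise ValueError(
                        f"CDS {feat.id} end {feat.end} exceeds genome "
                        f"{feat.seqid} length {len(genome_seq)}"
                    )
                seq = genome_seq[feat.start - 1 : feat.end]
                if feat.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
        records.append(
            CdsRecord(
                genome_id=feat.seqid,
                cds_id=feat.id or f"{feat.seqid}:{feat.start}-{feat.end}",
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                product=feat.attributes.get("product", [""])[0],
                sequence=seq,
            )
        )
    return records


def _read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        # description after the id may carry the product annotation
        product = rec.description[len(rec.id) :].strip()
        seq = str(rec.seq).upper()
        records.append(
            CdsRecord(
                genome_id=rec.id.rsplit("_", 1)[0] if "_" in rec.id else rec.id,
                cds_id=rec.id,
                start=0,
                end=len(seq),
                strand="+",
                product=product,
                sequence=seq,
            )
        )
    if not records:
        raise ValueError(f"no CDS FASTA records found in {path}")
    return records


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def write_report(
    table: Sequence[dict] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a table of named fields as a deterministic TSV report.

    Rows are sorted by ``genome_id`` then ``start`` when those columns are
    present. Tab characters inside fields would corrupt the format and are
    rejected.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    sort_keys = [c for c in ("genome_id", "start") if c in df.columns]
    if sort_keys and len(df):
        df = df.sort_values(sort_keys, kind="mergesort")
    for col in df.columns:
        if df[col].dtype == object and df[col].astype(str).str.contains("\t").any():
            raise ValueError(f"field {col!r} contains a tab character")
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
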