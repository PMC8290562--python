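"""Readers and writers for every external format the pipeline touches.

Dialects
--------
* Proteome FASTA: one protein per gene; the record id is the first
  whitespace-delimited token of the header.
* Reference-database FASTA: headers ``>species|gene_id|family`` where the
  family label is one of A, BF, BH, C, D, E, F, G, H or NONABC (the
  non-transporter proteome background).
* HMMER3 ``--domtblout`` per-domain tables (whitespace-delimited, ``#``
  comments); alignment coordinates come from the "ali from/to" columns.
* BLAST tabular output, 12 columns (``outfmt 6`` defaults):
  qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore.
* Species metadata TSV with columns species_id, taxon_order,
  busco_single_copy_pct.

External coordinates stay 1-based inclusive on the record types; interval
arithmetic elsewhere converts to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import is_valid_sequence
from .errors import ParseError, ValidationError

#: The nine ABC transporter families distinguished by the classifier.
#: BF = ABC-B full transporters (P-glycoproteins, two NBDs),
#: BH = ABC-B half transporters (one NBD).
ABC_FAMILIES = ("A", "BF", "BH", "C", "D", "E", "F", "G", "H")
NONABC = "NONABC"
REFERENCE_VOCABULARY = ABC_FAMILIES + (NONABC,)

EXCLUDED = "EXCLUDED"

MAX_X_FRACTION = 0.5


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein of a unigene proteome."""

    protein_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        if not is_valid_sequence(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: sequence contains non-standard residues"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One NBD-profile match on a protein (1-based inclusive coordinates)."""

    protein_id: str
    profile_id: str
    seq_start: int
    seq_end: int
    full_seq_evalue: float
    domain_ievalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.seq_start <= self.seq_end):
            raise ValidationError(
                f"{self.protein_id}: invalid interval {self.seq_start}..{self.seq_end}"
            )
        if self.full_seq_evalue < 0 or self.domain_ievalue < 0:
            raise ValidationError(f"{self.protein_id}: negative e-value")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open residue interval."""
        return (self.seq_start - 1, self.seq_end)


@dataclass(frozen=True)
class SimilarityHit:
    """One query -> reference alignment record with its family label."""

    query_id: str
    subject_id: str
    subject_family: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative e-value")
        if self.subject_family not in REFERENCE_VOCABULARY:
            raise ValidationError(
                f"{self.query_id}: unknown subject family {self.subject_family!r}"
            )


@dataclass(frozen=True)
class RefRecord:
    subject_id: str
    species: str
    family: str
    sequence: str

    @property
    def full_id(self) -> str:
        return f"{self.species}|{self.subject_id}|{self.family}"


@dataclass
class ReferenceDB:
    """Family-labelled reference proteins (the 'known ABC set' database)."""

    records: list[RefRecord]
    _by_id: dict[str, RefRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.family not in REFERENCE_VOCABULARY:
                raise ValidationError(f"unknown family label {rec.family!r}")
            for key in (rec.full_id, f"{rec.species}|{rec.subject_id}", rec.subject_id):
                self._by_id.setdefault(key, rec)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, subject_id: str) -> RefRecord:
        try:
            return self._by_id[subject_id]
        except KeyError:
            raise ParseError(f"subject id {subject_id!r} not in reference database")

    def family_of(self, subject_id: str) -> str:
        return self.lookup(subject_id).family


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    taxon_order: str
    busco_single_copy_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.busco_single_copy_pct <= 100.0):
            raise ValidationError(
                f"{self.species_id}: BUSCO score {self.busco_single_copy_pct} "
                "outside [0, 100]"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read a proteome FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal ``*`` stop characters stripped.
    Records whose sequence is more than half ``X`` are dropped with a
    warning; duplicate ids raise :class:`ParseError`.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                if line[1:].strip() == "":
                    raise ParseError(f"{path}: malformed empty header at line {lineno}")
                header_lines.append(lineno)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[idx]
        protein_id = rec.id
        seq = str(rec.seq).upper().strip("*")
        if not protein_id:
            raise ParseError(f"{path}: malformed header at line {lineno}")
        if protein_id in seen:
            raise ParseError(f"{path}: duplicate protein id {protein_id!r}")
        seen.add(protein_id)
        if len(seq) == 0:
            raise ParseError(f"{path}: empty sequence for {protein_id!r}")
        if seq.count("X") / len(seq) > MAX_X_FRACTION:
            warnings.warn(
                f"{protein_id}: more than {MAX_X_FRACTION:.0%} unknown residues; "
                "record dropped"
            )
            continue
        records.append(ProteinRecord(protein_id, species_id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=rec.species_id)
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_reference_db(path: str | Path) -> ReferenceDB:
    """Read a reference FASTA with ``>species|gene_id|family`` headers."""
    refs: list[RefRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3 or not all(parts):
            raise ParseError(f"reference header not 'species|gene|family': >{rec.id}")
        species, gene_id, family = parts
        if family not in REFERENCE_VOCABULARY:
            raise ParseError(f"unknown family label in header: >{rec.id}")
        refs.append(RefRecord(gene_id, species, family, str(rec.seq).upper().strip("*")))
    return ReferenceDB(refs)


def write_reference_db(db: ReferenceDB, path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.full_id, description="")
        for rec in db.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER3 domtblout

_DOMTBL_MIN_FIELDS = 22


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table into :class:`DomainHit` objects."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ParseError(f"{path}: line {lineno}: expected >= "
                                 f"{_DOMTBL_MIN_FIELDS} fields, got {len(fields)}")
            try:
                full_e = float(fields[6])
                ieval = float(fields[12])
                bits = float(fields[13])
                ali_from = int(fields[17])
                ali_to = int(fields[18])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric field")
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    profile_id=fields[3],
                    seq_start=ali_from,
                    seq_end=ali_to,
                    full_seq_evalue=full_e,
                    domain_ievalue=ieval,
                    bitscore=bits,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular


def parse_blast_tab(path: str | Path, reference_db: ReferenceDB) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular output, labelling subjects from the DB."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric field")
            subject = reference_db.lookup(fields[1])
            hits.append(
                SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_family=subject.family,
                    percent_identity=pident,
                    evalue=evalue,
                    bitscore=bits,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Species metadata

_META_COLUMNS = ("species_id", "taxon_order", "busco_single_copy_pct")


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    return [
        SpeciesMeta(str(r.species_id), str(r.taxon_order), float(r.busco_single_copy_pct))
        for r in df.itertuples()
    ]


def write_species_meta(meta: Sequence[SpeciesMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.species_id, m.taxon_order, m.busco_single_copy_pct) for m in meta],
        columns=list(_META_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables

RESULT_COLUMNS = (
    "protein_id",
    "species",
    "family",
    "length",
    "rule_used",
    "top_hit",
    "top_evalue",
    "nbd_count",
)


def write_results(calls, records, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write classified calls as ``<prefix>.tsv`` + ``<prefix>.faa``.

    Only calls with a family assignment (not EXCLUDED) are written.  Rows
    are ordered by (species, family, protein_id) so repeated runs produce
    byte-identical output.
    """
    out_prefix = Path(out_prefix)
    by_id: Mapping[str, ProteinRecord]
    if isinstance(records, Mapping):
        by_id = records
    else:
        by_id = {rec.protein_id: rec for rec in records}
    rows = []
    fasta_records = []
    kept = [c for c in calls if c.family != EXCLUDED]
    for call in kept:
        if call.protein_id not in by_id:
            raise ValidationError(f"no sequence record for {call.protein_id!r}")
    kept.sort(key=lambda c: (by_id[c.protein_id].species_id, c.family, c.protein_id))
    for call in kept:
        rec = by_id[call.protein_id]
        rows.append(
            (
                call.protein_id,
                rec.species_id,
                call.family,
                len(rec),
                call.rule_used,
                call.top_hit_id,
                "" if call.top_evalue is None else f"{call.top_evalue:.6g}",
                call.nbd_count,
            )
        )
        fasta_records.append(rec)
    tsv_path = Path(str(out_prefix) + ".tsv")
    faa_path = Path(str(out_prefix) + ".faa")
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    write_fasta(fasta_records, faa_path)
    return tsv_path, faa_path
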