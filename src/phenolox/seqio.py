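"""Sequence I/O, genetic code tables, and coordinate conventions.

All coordinates inside the package are 0-based half-open; every file
interface (domain tables, anchor profiles) speaks 1-based inclusive, the
convention of the scan tools whose outputs we consume. Conversion happens
at the file boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X")
CDS_ALPHABET = set("ACGTN")

#: the six diagnostic-domain names used across the package
DOMAIN_VOCABULARY = (
    "TYROSINASE",
    "PPO1_DWL",
    "PPO1_KFDV",
    "CU_OXIDASE_3",
    "CU_OXIDASE",
    "CU_OXIDASE_2",
)

# external domain-scan names -> internal vocabulary
_DOMAIN_ALIASES = {
    "TYROSINASE": "TYROSINASE",
    "PPO1_DWL": "PPO1_DWL",
    "PPO1_KFDV": "PPO1_KFDV",
    "CU-OXIDASE_3": "CU_OXIDASE_3",
    "CU_OXIDASE_3": "CU_OXIDASE_3",
    "CU-OXIDASE": "CU_OXIDASE",
    "CU_OXIDASE": "CU_OXIDASE",
    "CU-OXIDASE_2": "CU_OXIDASE_2",
    "CU_OXIDASE_2": "CU_OXIDASE_2",
}


class SeqIOError(ValueError):
    """Raised for malformed sequence input or table rows."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or coding sequence with its species tag.

    Species is an explicit tag, never parsed from the FASTA header:
    proteome headers vary wildly between source databases.
    """

    id: str
    species: str
    kind: str  # "protein" or "cds"
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        if self.kind not in ("protein", "cds"):
            raise SeqIOError(f"unknown record kind {self.kind!r}")
        if not self.seq:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        seq = self.seq
        if self.kind == "protein":
            body, tail = seq[:-1], seq[-1]
            if tail == "*":
                seq = body
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise SeqIOError(
                    f"record {self.id!r}: invalid protein characters {sorted(bad)}"
                )
        else:
            bad = set(seq) - CDS_ALPHABET
            if bad:
                raise SeqIOError(
                    f"record {self.id!r}: invalid nucleotide characters {sorted(bad)}"
                )
            if len(seq) % 3 != 0:
                raise SeqIOError(
                    f"record {self.id!r}: CDS length {len(seq)} not divisible by 3"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table (NCBI table 1 or 11)."""

    table_id: int
    codon_to_aa: dict

    @classmethod
    def from_table(cls, table_id: int) -> "GeneticCode":
        if table_id not in (1, 11):
            raise SeqIOError(f"unsupported genetic code table {table_id}")
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(table_id=table_id, codon_to_aa=mapping)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    @property
    def sense_codons(self) -> list:
        return [c for c, aa in self.codon_to_aa.items() if aa != "*"]

    def synonymous_families(self) -> dict:
        """Map amino acid -> sorted list of its sense codons."""
        fams: dict = {}
        for codon, aa in self.codon_to_aa.items():
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        return {aa: sorted(cs) for aa, cs in fams.items()}


STANDARD_CODE = GeneticCode.from_table(1)
BACTERIAL_CODE = GeneticCode.from_table(11)


class Translation(NamedTuple):
    """Protein product of a CDS plus stop-codon flags."""

    protein: str
    internal_stop: bool
    terminal_stop: bool

    def __str__(self) -> str:  # convenience for printing
        return self.protein


def translate(cds: str, code: GeneticCode = STANDARD_CODE) -> Translation:
    """Translate a CDS codon by codon.

    Codons containing N become 'X'; stop codons become '*'. A stop before
    the final codon sets ``internal_stop``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SeqIOError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - CDS_ALPHABET
    if bad:
        raise SeqIOError(f"invalid nucleotide characters {sorted(bad)}")
    aas = []
    internal = terminal = False
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            aas.append("X")
            continue
        aa = code.codon_to_aa[codon]
        if aa == "*":
            if i == n_codons - 1:
                terminal = True
            else:
                internal = True
        aas.append(aa)
    return Translation("".join(aas), internal, terminal)


def read_fasta(path, kind: str, species: str) -> list:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; input is
    upcased; order is preserved. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list = []
    seen: set = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise SeqIOError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        records.append(
            SequenceRecord(id=rid, species=species, kind=kind, seq=str(entry.seq).upper())
        )
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_species_map(path) -> dict:
    """Read a two-column TSV (id, species); '#'-prefixed lines are comments."""
    mapping: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"{path}:{lineno}: expected 'id<TAB>species'")
        mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# coordinate conversion

def to_internal(start_1based: int, end_1based: int) -> tuple:
    """External 1-based inclusive span -> internal 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(start: int, end: int) -> tuple:
    """Internal 0-based half-open span -> external 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# hmmscan-style per-domain table

@dataclass(frozen=True)
class RawDomainRow:
    protein_id: str
    accession: str
    domain: str
    start: int  # internal
    end: int
    score: float


def read_domtbl(path) -> list:
    """Read a whitespace-delimited per-domain table.

    Expected columns: target id, domain accession, domain name, envelope
    start, envelope end, score (1-based inclusive coordinates). Unknown
    domain names are rejected so downstream class calls stay within the
    closed vocabulary.
    """
    rows: list = []
    text = Path(path).read_text().splitlines()
    for lineno, line in enumerate(text, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise SeqIOError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        pid, acc, name = parts[0], parts[1], parts[2]
        try:
            s1, e1 = int(parts[3]), int(parts[4])
            score = float(parts[5])
        except ValueError as exc:
            raise SeqIOError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
        if e1 < s1:
            raise SeqIOError(f"{path}:{lineno}: end {e1} < start {s1}")
        key = name.upper()
        if key not in _DOMAIN_ALIASES:
            raise SeqIOError(f"{path}:{lineno}: unknown domain name {name!r}")
        start, end = to_internal(s1, e1)
        rows.append(
            RawDomainRow(
                protein_id=pid,
                accession=acc,
                domain=_DOMAIN_ALIASES[key],
                start=start,
                end=end,
                score=score,
            )
        )
    if not rows:
        log.warning("domain table %s contained no rows", path)
    return rows


# ---------------------------------------------------------------------------
# TSV / Newick writers

def write_tsv(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write records as TSV with a '#'-prefixed header line.

    An empty row list still produces the header (columns required then).
    """
    path = Path(path)
    if columns is None:
        if not rows:
            raise SeqIOError("write_tsv needs explicit columns for an empty table")
        columns = list(rows[0].keys())
    with path.open("w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def read_tsv(path) -> list:
    """Read back a '#'-headed TSV into a list of dicts of strings."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise SeqIOError(f"{path}: missing '#' header line")
    columns = lines[0][1:].split("\t")
    out = []
    for line in lines[1:]:
        if not line:
            continue
        out.append(dict(zip(columns, line.split("\t"))))
    return out


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_newick(newick: str, path) -> None:
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")
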