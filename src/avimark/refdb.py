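"""Host-annotated fecal 16S reference database construction.

Parses GenBank flat files, keeps records whose ``isolation_source``
indicates feces, drops viral/vertebrate source organisms, requires a
usable ``host`` qualifier, and normalizes common host names to binomials.
The surviving records form the reference database that the unique-window
scan is run against.
"""

from __future__ import annotations

import gzip
import io
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

DEFAULT_SOURCE_TERMS = frozenset({"feces", "fecal", "faeces", "faecal", "stool"})

#: hosts considered "trivial" (no usable host annotation)
_TRIVIAL_HOSTS = {"", "unknown", "n/a", "na", "none", "not available",
                  "missing", "unidentified"}

#: minimal shipped common-name -> binomial mapping; user-extensible
DEFAULT_HOST_MAP: Dict[str, str] = {
    "swine": "Sus scrofa",
    "pig": "Sus scrofa",
    "dog": "Canis lupus",
    "human": "Homo sapiens",
    "cattle": "Bos taurus",
    "cow": "Bos taurus",
    "bovine": "Bos taurus",
    "horse": "Equus caballus",
    "sheep": "Ovis aries",
    "chicken": "Gallus gallus",
    "mouse": "Mus musculus",
}

_VIRAL_WORDS = ("virus", "phage", "viridae", "virinae", "virales", "satellite")
_VERTEBRATE_WORDS = (
    "homo sapiens", "sus scrofa", "bos taurus", "canis lupus", "gallus gallus",
    "equus", "ovis aries", "capra", "mus musculus", "rattus", "danio rerio",
    "felis catus", "oryctolagus", "anas platyrhynchos", "meleagris",
)

_VALID = set("ACGTRYSWKMBDHVN")


@dataclass
class ReferenceRecord:
    """One annotated 16S sequence with host and isolation-source metadata."""

    accession: str
    sequence: str
    organism: str
    host_raw: Optional[str] = None
    host_normalized: Optional[str] = None
    isolation_source_raw: Optional[str] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.accession}: non-IUPAC symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Per-rule tallies from :func:`filter_fecal`; every input record is
    assigned exactly one fate."""

    n_input: int = 0
    n_pass_source: int = 0
    n_fail_source: int = 0
    n_fail_taxon: int = 0
    n_fail_host: int = 0
    n_final: int = 0

    def validate(self) -> None:
        if self.n_input != (self.n_final + self.n_fail_source
                            + self.n_fail_taxon + self.n_fail_host):
            raise ValueError("inconsistent filter report")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class ParseError:
    """A record-level parsing failure; parsing of other records continues."""

    index: int
    message: str


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_genbank(stream, errors: Optional[List[ParseError]] = None
                  ) -> List[ReferenceRecord]:
    """Parse GenBank flat-file text into :class:`ReferenceRecord` objects.

    ``stream`` may be a file path, an open text handle, or the raw text.
    Malformed records are collected into ``errors`` (if given) and skipped;
    well-formed neighbours are unaffected.
    """
    import os

    if isinstance(stream, str) and "\n" not in stream and os.path.exists(stream):
        with _open_maybe_gzip(stream) as fh:
            text = fh.read()
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    # split into LOCUS..// chunks so one bad record cannot poison the rest
    chunks = []
    current: List[str] = []
    for line in text.splitlines(keepends=True):
        if line.startswith("LOCUS") and current:
            chunks.append("".join(current))
            current = []
        current.append(line)
    if current and "".join(current).strip():
        chunks.append("".join(current))
    records: List[ReferenceRecord] = []
    for i, chunk in enumerate(chunks):
        try:
            seqrec = SeqIO.read(io.StringIO(chunk), "genbank")
            seq = str(seqrec.seq).upper()
            if not seq or set(seq) == {"N"} and "ORIGIN" not in chunk:
                raise ValueError("record lacks sequence data")
            host = None
            iso = None
            organism = seqrec.annotations.get("organism", "") or ""
            for feat in seqrec.features:
                if feat.type == "source":
                    q = feat.qualifiers
                    host = (q.get("host") or [None])[0]
                    iso = (q.get("isolation_source") or [None])[0]
                    if not organism:
                        organism = (q.get("organism") or [""])[0]
                    break
            records.append(ReferenceRecord(
                accession=seqrec.id or seqrec.name,
                sequence=seq, organism=organism,
                host_raw=host, isolation_source_raw=iso))
        except Exception as exc:  # record-level failure
            if errors is not None:
                errors.append(ParseError(index=i, message=str(exc)))
    return records


def default_taxon_predicate(organism: str) -> bool:
    """True when the organism looks viral or vertebrate (to be excluded).

    A deliberately simple word-list stand-in for a real taxonomy lookup;
    pluggable so users can wire in NCBI taxonomy.
    """
    low = (organism or "").lower()
    if any(w in low for w in _VIRAL_WORDS):
        return True
    if any(w in low for w in _VERTEBRATE_WORDS):
        return True
    return False


_BINOMIAL_RE = re.compile(r"^[A-Z][a-z]+ [a-z][a-z-]+$")


def normalize_host(host_raw: str,
                   mapping: Optional[Dict[str, str]] = None) -> Optional[str]:
    """Map a common host name to a binomial; never guess.

    Case-insensitive exact-token lookup after whitespace trimming.  Names
    that already look binomial (capitalized genus + lowercase epithet) pass
    through unchanged.  Unmatched names return ``None`` (unresolved).
    """
    if host_raw is None:
        return None
    name = " ".join(host_raw.split())
    if not name:
        return None
    if _BINOMIAL_RE.match(name):
        return name
    table = DEFAULT_HOST_MAP if mapping is None else mapping
    lowered = {k.strip().lower(): v for k, v in table.items()}
    return lowered.get(name.lower())


def filter_fecal(records: Sequence[ReferenceRecord],
                 source_terms: Optional[Iterable[str]] = None,
                 excluded_taxa: Optional[Callable[[str], bool]] = None,
                 host_map: Optional[Dict[str, str]] = None,
                 ) -> Tuple[List[ReferenceRecord], FilterReport]:
    """Apply the fecal-source filtering rules; first failing rule wins.

    Rules in order: (a) isolation_source present and contains a source term
    (case-insensitive substring); (b) source organism not viral/vertebrate
    per the predicate; (c) host present and non-trivial.  Passing records
    get ``host_normalized`` set (normalized binomial when resolvable, the
    raw host verbatim otherwise — normalization never guesses).
    """
    terms = [t.lower() for t in (source_terms or DEFAULT_SOURCE_TERMS)]
    pred = excluded_taxa or default_taxon_predicate
    rep = FilterReport(n_input=len(records))
    out: List[ReferenceRecord] = []
    for rec in records:
        iso = (rec.isolation_source_raw or "").lower()
        if not iso or not any(t in iso for t in terms):
            rep.n_fail_source += 1
            continue
        rep.n_pass_source += 1
        if pred(rec.organism):
            rep.n_fail_taxon += 1
            continue
        host = (rec.host_raw or "").strip()
        if host.lower() in _TRIVIAL_HOSTS:
            rep.n_fail_host += 1
            continue
        normalized = normalize_host(host, host_map)
        out.append(ReferenceRecord(
            accession=rec.accession, sequence=rec.sequence,
            organism=rec.organism, host_raw=rec.host_raw,
            host_normalized=normalized if normalized else host,
            isolation_source_raw=rec.isolation_source_raw))
    rep.n_final = len(out)
    rep.validate()
    return out, rep


def write_fasta(records: Sequence[ReferenceRecord], handle) -> None:
    """FASTA with ``>accession|host=<binomial>|src=<isolation_source>``."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for rec in records:
            host = rec.host_normalized or ""
            src = rec.isolation_source_raw or ""
            fh.write(f">{rec.accession}|host={host}|src={src}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i:i + 70] + "\n")
    finally:
        if own:
            fh.close()


def write_metadata_tsv(records: Sequence[ReferenceRecord], handle) -> None:
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write("accession\torganism\thost_raw\thost_normalized\t"
                 "isolation_source_raw\tlength\n")
        for r in records:
            fh.write("\t".join([
                r.accession, r.organism, r.host_raw or "",
                r.host_normalized or "", r.isolation_source_raw or "",
                str(r.length)]) + "\n")
    finally:
        if own:
            fh.close()


def read_database_fasta(path_or_handle) -> List[Tuple[str, str, Dict[str, str]]]:
    """Read a database FASTA written by :func:`write_fasta`.

    Returns (accession, sequence, metadata) triples; metadata holds any
    ``key=value`` fields found in the header.
    """
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle) if own else path_or_handle
    try:
        out = []
        for rec in SeqIO.parse(fh, "fasta"):
            parts = rec.description.split("|")
            meta = {}
            for p in parts[1:]:
                if "=" in p:
                    key, val = p.split("=", 1)
                    meta[key] = val
            out.append((parts[0].split()[0], str(rec.seq).upper(), meta))
        return out
    finally:
        if own:
            fh.close()
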