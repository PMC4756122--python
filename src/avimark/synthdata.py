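"""Deterministic synthetic-data generators with ground truth.

The generators emulate the inputs of a 16S V1-V3 amplicon MST study:

* a host-annotated reference database of 16S-like records sharing a
  conserved backbone with hypervariable regions (per-host signature
  mutations plus light within-host strain divergence) and, for designated
  hosts, fully randomized "planted unique" windows;
* per-host read sets: 5'-anchored pyrosequencing-like reads with
  substitution errors;
* qPCR dilution series following a log-linear Ct model with Gaussian noise
  and logistic detection dropout near the limit of detection.

Every generator is a pure function of (spec, seed) and ships a truth table;
per-host RNG substreams make record generation independent of which host
subset is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QpcrSpec:
    """Log-linear Ct model: Ct = intercept - slope*log10(copies) + N(0, sigma);
    detection is Bernoulli with a logistic dropout curve in log10 copies.

    The logistic midpoint sits at ``lod_copies / 4`` with steepness
    ``dropout_steepness`` per decade, which places detection probability
    ~0.998 at the nominal LOD and ~0.28 one 5-fold dilution below it —
    mimicking Poisson template limitation at a few copies per reaction.
    ``dropout_steepness = 0`` disables dropout entirely.
    """

    slope_magnitude: float = 3.4
    intercept: float = 40.1
    sigma_ct: float = 0.3
    lod_copies: float = 5.0
    dropout_steepness: float = 10.0

    def p_detect(self, copies: float) -> float:
        if self.dropout_steepness == 0:
            return 1.0
        x = self.dropout_steepness * (math.log10(copies)
                                      - math.log10(self.lod_copies / 4.0))
        return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SynthSpec:
    """Stated world for the synthetic MST study."""

    seed: int
    n_hosts: int = 6
    backbone_length: int = 500
    n_refs_per_host: int = 3
    #: (start, end, per-host divergence rate), 0-based half-open; None
    #: derives three V-region-like spans proportional to the backbone
    #: ((60,140), (210,290), (380,460) at the default 500 bp)
    variable_regions: Optional[Tuple[Tuple[int, int, float], ...]] = None
    #: (host index, start, length, divergence); divergence 1.0 = fully random
    planted_unique: Tuple[Tuple[int, int, int, float], ...] = ()
    #: within-host strain-level substitution rate inside variable regions
    strain_divergence: float = 0.02
    read_error_rate: float = 0.001
    reads_per_host: int = 100
    #: reads are 5'-anchored; length ~ U[min_read_frac*L, L]
    min_read_frac: float = 0.7
    #: fraction of reference records drawn to pass the fecal-source filters
    source_pass_fraction: float = 0.8
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)

    def __post_init__(self):
        L = self.backbone_length
        if self.variable_regions is None:
            derived = tuple(
                (int(a * L), int(b * L), rate)
                for a, b, rate in ((0.12, 0.28, 0.10), (0.42, 0.58, 0.12),
                                   (0.76, 0.92, 0.10)))
            object.__setattr__(self, "variable_regions", derived)
        for s, e, r in self.variable_regions:
            if not (0 <= s < e <= L) or not 0.0 <= r <= 1.0:
                raise ValueError("variable region outside backbone or bad rate")
        spans = sorted((s, s + ln) for _, s, ln, _ in self.planted_unique)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("planted unique regions overlap")
        for h, s, ln, d in self.planted_unique:
            if not (0 <= h < self.n_hosts):
                raise ValueError("planted host index out of range")
            if not (0 <= s and s + ln <= L and ln >= 18):
                raise ValueError("planted region outside backbone or too short")
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergence must be in [0, 1]")


def default_spec(seed: int, n_hosts: int = 6,
                 planted_length: int = 24) -> SynthSpec:
    """A convenience world: one planted unique window per host, placed in
    conserved backbone segments, non-overlapping."""
    starts = [10, 145, 175, 295, 325, 465, 37, 380]
    planted = tuple((h, starts[h], planted_length, 1.0)
                    for h in range(n_hosts))
    return SynthSpec(seed=seed, n_hosts=n_hosts, planted_unique=planted)


# host naming: (common name used in the host qualifier, binomial truth)
_HOST_NAMES = [
    ("swine", "Sus scrofa"), ("dog", "Canis lupus"),
    ("cattle", "Bos taurus"), ("horse", "Equus caballus"),
    ("sheep", "Ovis aries"), ("chicken", "Gallus gallus"),
    ("human", "Homo sapiens"), ("mouse", "Mus musculus"),
]

_FATES = ("pass", "fail_source", "fail_taxon", "fail_host")


def host_label(host: int) -> str:
    return f"host{host}"


def _rng(spec: SynthSpec, *stream) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *stream])


def _backbone(spec: SynthSpec) -> np.ndarray:
    return _rng(spec, 0).integers(0, 4, size=spec.backbone_length)


def _mutate(codes: np.ndarray, positions: np.ndarray,
            rng: np.random.Generator) -> None:
    """Substitute each given position with a uniformly chosen *different* base."""
    shifts = rng.integers(1, 4, size=positions.size)
    codes[positions] = (codes[positions] + shifts) % 4


def host_record_codes(spec: SynthSpec, host: int) -> List[np.ndarray]:
    """Integer-coded sequences of one host's reference records (ground truth
    shared with the read generator)."""
    backbone = _backbone(spec)
    rng = _rng(spec, 1, host)
    # host signature in variable regions
    sig = backbone.copy()
    for s, e, rate in spec.variable_regions:
        pos = np.arange(s, e)[rng.random(e - s) < rate]
        _mutate(sig, pos, rng)
    # planted unique windows for this host: every position randomized away
    # from the backbone at the stated divergence
    for h, s, ln, div in spec.planted_unique:
        if h != host:
            continue
        pos = np.arange(s, s + ln)[rng.random(ln) < div]
        _mutate(sig, pos, rng)
    records = []
    for r in range(spec.n_refs_per_host):
        rec = sig.copy()
        rrng = _rng(spec, 2, host, r)
        for s, e, _ in spec.variable_regions:
            pos = np.arange(s, e)[rrng.random(e - s) < spec.strain_divergence]
            _mutate(rec, pos, rrng)
        records.append(rec)
    return records


def codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def make_reference_db(spec: SynthSpec,
                      hosts: Optional[Sequence[int]] = None
                      ) -> Tuple[str, pd.DataFrame]:
    """GenBank flat-file text plus a truth table.

    The truth table has one row per record (accession, host, record index,
    intended filter fate, host qualifier, binomial) and carries the planted
    region coordinates in its ``attrs["planted"]``.
    """
    host_list = list(range(spec.n_hosts)) if hosts is None else sorted(hosts)
    chunks: List[str] = []
    rows = []
    for host in host_list:
        common, binomial = _HOST_NAMES[host % len(_HOST_NAMES)]
        frng = _rng(spec, 3, host)
        for r, codes in enumerate(host_record_codes(spec, host)):
            acc = f"SYN{host:02d}{r:03d}"
            if frng.random() < spec.source_pass_fraction:
                fate = "pass"
            else:
                fate = _FATES[1 + int(frng.integers(0, 3))]
            iso = {"pass": "fecal sample",
                   "fail_source": "soil",
                   "fail_taxon": "fecal sample",
                   "fail_host": "stool"}[fate]
            organism = (f"Enterovirus sp. {acc}" if fate == "fail_taxon"
                        else f"Lactobacillus sp. {acc}")
            host_q = None if fate == "fail_host" else (
                common if r % 2 == 0 else binomial)
            chunks.append(_genbank_record(acc, codes_to_str(codes), organism,
                                          host_q, iso))
            rows.append({"accession": acc, "host": host,
                         "host_label": host_label(host), "record": r,
                         "fate": fate, "host_qualifier": host_q or "",
                         "binomial": binomial, "length": len(codes)})
    truth = pd.DataFrame(rows)
    truth.attrs["planted"] = [
        {"host": h, "start": s, "end": s + ln, "divergence": d}
        for h, s, ln, d in spec.planted_unique]
    truth.attrs["variable_regions"] = [list(v) for v in spec.variable_regions]
    return "".join(chunks), truth


def _genbank_record(accession: str, seq: str, organism: str,
                    host: Optional[str], isolation_source: str) -> str:
    """One GenBank flat-file record (written through Biopython)."""
    import io

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(seq), id=accession, name=accession,
                    description=f"{organism} 16S ribosomal RNA gene, "
                                "partial sequence")
    rec.annotations.update(
        molecule_type="DNA", organism=organism, source=organism,
        topology="linear", data_file_division="BCT", date="01-JAN-2015",
        accessions=[accession])
    quals = {"organism": [organism], "mol_type": ["genomic DNA"],
             "isolation_source": [isolation_source]}
    if host is not None:
        quals["host"] = [host]
    rec.features.append(SeqFeature(SimpleLocation(0, len(seq)),
                                   type="source", qualifiers=quals))
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()


def make_grouped_reads(spec: SynthSpec,
                       hosts: Optional[Sequence[int]] = None
                       ) -> Tuple[Dict[str, List[Tuple[str, str]]], pd.DataFrame]:
    """Per-host read sets with substitution errors, plus truth labels.

    Reads are 5'-anchored (primer-anchored pyrosequencing) with lengths
    uniform on [min_read_frac * L, L]; each read derives from one of the
    host's reference records.
    """
    host_list = list(range(spec.n_hosts)) if hosts is None else sorted(hosts)
    groups: Dict[str, List[Tuple[str, str]]] = {}
    rows = []
    for host in host_list:
        records = host_record_codes(spec, host)
        rng = _rng(spec, 4, host)
        reads = []
        lab = host_label(host)
        lo = int(round(spec.min_read_frac * spec.backbone_length))
        for i in range(spec.reads_per_host):
            ridx = int(rng.integers(0, len(records)))
            length = int(rng.integers(lo, spec.backbone_length + 1))
            codes = records[ridx][:length].copy()
            err = np.flatnonzero(rng.random(length) < spec.read_error_rate)
            n_err = err.size
            if n_err:
                _mutate(codes, err, rng)
            rid = f"{lab}_read{i:04d}"
            reads.append((rid, codes_to_str(codes)))
            rows.append({"read_id": rid, "host": host, "host_label": lab,
                         "record": ridx, "length": length, "n_errors": n_err,
                         "error_positions": ",".join(map(str, err.tolist()))})
        groups[lab] = reads
    return groups, pd.DataFrame(rows)


def make_qpcr_series(spec: SynthSpec, copies_levels: Sequence[float],
                     n_replicates: int = 3,
                     assay_id: str = "assay") -> Tuple[pd.DataFrame, dict]:
    """Replicate dilution-series Ct table plus generator truth.

    Undetected wells get ``ct = NaN``.  Truth records the planted curve and
    the smallest tested level whose theoretical detection probability
    reaches 0.9 (the LOD the estimator should recover).
    """
    q = spec.qpcr
    rng = _rng(spec, 5)
    rows = []
    for copies in copies_levels:
        if copies <= 0:
            raise ValueError("copy levels must be positive")
        for rep in range(n_replicates):
            detected = rng.random() < q.p_detect(copies)
            ct = (q.intercept - q.slope_magnitude * math.log10(copies)
                  + rng.normal(0.0, q.sigma_ct)) if detected else math.nan
            rows.append({"assay": assay_id, "copies": float(copies),
                         "replicate": rep, "detected": bool(detected),
                         "ct": ct})
    qualifying = [c for c in sorted(copies_levels) if q.p_detect(c) >= 0.9]
    truth = {"slope_magnitude": q.slope_magnitude, "intercept": q.intercept,
             "sigma_ct": q.sigma_ct, "lod_copies": q.lod_copies,
             "lod_level_truth": qualifying[0] if qualifying else None}
    return pd.DataFrame(rows), truth


def write_reads_fasta(groups: Dict[str, List[Tuple[str, str]]],
                      prefix: str) -> Dict[str, str]:
    """One FASTA per group; returns group -> path."""
    paths = {}
    for group, reads in groups.items():
        path = f"{prefix}.{group}.fasta"
        with open(path, "w") as fh:
            for rid, seq in reads:
                fh.write(f">{rid}\n{seq}\n")
        paths[group] = path
    return paths
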