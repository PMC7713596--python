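"""Reading, validating and summarizing species-labeled barcode alignments.

Input is a pre-aligned multi-FASTA (the alignment itself is produced
externally, e.g. with ClustalW or MAFFT — this package validates but never
aligns).  Species labels come either from a ``sp=`` token in the FASTA
header, from the remainder of the description line, or from a sidecar
two-column TSV mapping record id to species.

Coordinates are 0-based, half-open throughout the package; 1-based inclusive
coordinates appear only in human-facing reports.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DesignError, IdentityUndefinedError, InputError, LabelingError

ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its species label."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        if not self.species:
            raise LabelingError(f"record {self.id!r}: empty species label")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise InputError(f"record {self.id!r}: illegal characters {sorted(bad)}")


class SnpClass(str, Enum):
    """HRM substitution classes, in decreasing order of typical Tm shift.

    Class 1 (C/T and its complement G/A) melts apart most readily; class 4
    (A/T) least.  The pair is canonicalized on the plus strand, so the
    nomenclature is strand-symmetric.
    """

    CLASS1_CT_GA = "class1_CT_GA"
    CLASS2_CA_GT = "class2_CA_GT"
    CLASS3_CG = "class3_CG"
    CLASS4_AT = "class4_AT"
    MULTIALLELIC = "multiallelic"
    INDEL = "indel"


#: discriminability rank: lower = easier to resolve by HRM
SNP_CLASS_RANK = {
    SnpClass.CLASS1_CT_GA: 1,
    SnpClass.CLASS2_CA_GT: 2,
    SnpClass.CLASS3_CG: 3,
    SnpClass.CLASS4_AT: 4,
}

_PAIR_CLASS = {
    frozenset("CT"): SnpClass.CLASS1_CT_GA,
    frozenset("GA"): SnpClass.CLASS1_CT_GA,
    frozenset("CA"): SnpClass.CLASS2_CA_GT,
    frozenset("GT"): SnpClass.CLASS2_CA_GT,
    frozenset("CG"): SnpClass.CLASS3_CG,
    frozenset("AT"): SnpClass.CLASS4_AT,
}


def classify_substitution(a: str, b: str) -> SnpClass:
    """HRM class of a biallelic substitution, canonicalized per strand."""
    pair = frozenset((a.upper(), b.upper()))
    if len(pair) != 2 or not pair <= UNAMBIGUOUS:
        raise InputError(f"not an unambiguous substitution pair: {a}/{b}")
    return _PAIR_CLASS[pair]


@dataclass(frozen=True)
class VariantColumn:
    """An alignment column whose per-species majority bases differ."""

    column: int  # 0-based alignment index
    states: Mapping[str, Counter]  # species -> observed character multiset
    majority: Mapping[str, str]  # species -> majority unambiguous base
    snp_class: SnpClass


@dataclass
class SpeciesSet:
    """Labeled barcode records sharing one aligned length; the design-time
    reference universe."""

    records: list[BarcodeRecord]
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("SpeciesSet requires at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(f"records have unequal aligned lengths: {sorted(lengths)}")
        length = lengths.pop()
        if self.alignment_length and self.alignment_length != length:
            raise AlignmentError(
                f"declared alignment_length {self.alignment_length} != actual {length}"
            )
        self.alignment_length = length

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def by_species(self) -> dict[str, list[BarcodeRecord]]:
        out: dict[str, list[BarcodeRecord]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r)
        return out

    def consensus(self, species: str) -> str:
        """Majority sequence of one species.  The majority at each column is
        taken over unambiguous observations only; a column with none is 'N'
        (or '-' if every record is gapped there).  Ties break to the
        alphabetically first base for determinism."""
        recs = [r for r in self.records if r.species == species]
        if not recs:
            raise InputError(f"unknown species {species!r}")
        cols = []
        for i in range(self.alignment_length):
            obs = Counter(r.sequence[i].upper() for r in recs)
            unamb = {b: n for b, n in obs.items() if b in UNAMBIGUOUS}
            if unamb:
                best = max(sorted(unamb), key=lambda b: unamb[b])
                cols.append(best)
            elif set(obs) == {"-"}:
                cols.append("-")
            else:
                cols.append("N")
        return "".join(cols)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "n_records": len(recs), "alignment_length": self.alignment_length}
            for sp, recs in self.by_species().items()
        ]
        return pd.DataFrame(rows)


_SP_TOKEN = re.compile(r"sp=([^\s]+)")


def _species_from_header(record: SeqRecord) -> str | None:
    m = _SP_TOKEN.search(record.description)
    if m:
        return m.group(1)
    parts = record.description.split(None, 1)
    if len(parts) == 2 and parts[1].strip():
        return parts[1].strip().replace(" ", "_")
    return None


def read_species_map(path) -> dict[str, str]:
    """Sidecar TSV (record_id <tab> species) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"species map {path} needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_species_fasta(path, species_map: Mapping[str, str] | str | Path | None = None) -> SpeciesSet:
    """Read an aligned multi-FASTA into a :class:`SpeciesSet`.

    Labels are resolved in order: explicit ``species_map`` (dict or TSV
    path), then a ``sp=Name`` header token, then the description text after
    the record id.  Record order is preserved.
    """
    if isinstance(species_map, (str, Path)):
        species_map = read_species_map(species_map)
    try:
        seq_records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    if not seq_records:
        raise InputError(f"no FASTA records found in {path}")
    records = []
    for rec in seq_records:
        species = None
        if species_map is not None:
            species = species_map.get(rec.id)
        if species is None:
            species = _species_from_header(rec)
        if species is None:
            raise LabelingError(f"record {rec.id!r} has no species label")
        records.append(BarcodeRecord(id=rec.id, species=species, sequence=str(rec.seq).upper()))
    return SpeciesSet(records=records)


def write_species_fasta(s: SpeciesSet, path) -> None:
    """Write a SpeciesSet back to FASTA with ``sp=`` header tokens
    (round-trips exactly through :func:`read_species_fasta`)."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"sp={r.species}")
        for r in s.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def variable_columns(s: SpeciesSet) -> list[VariantColumn]:
    """Columns where at least two species differ in majority base.

    Per species the majority is taken over unambiguous observations; species
    with no unambiguous base at a column are skipped there.  A column
    containing any gap character is tagged ``indel``; otherwise two distinct
    majorities give the substitution class, more give ``multiallelic``.
    """
    species = s.species()
    if len(species) < 2:
        raise DesignError("variant calling needs at least two species")
    by_sp = s.by_species()
    out: list[VariantColumn] = []
    for i in range(s.alignment_length):
        states: dict[str, Counter] = {}
        majority: dict[str, str] = {}
        has_gap = False
        for sp in species:
            obs = Counter(r.sequence[i].upper() for r in by_sp[sp])
            states[sp] = obs
            if "-" in obs:
                has_gap = True
            unamb = {b: n for b, n in obs.items() if b in UNAMBIGUOUS}
            if unamb:
                majority[sp] = max(sorted(unamb), key=lambda b: unamb[b])
        distinct = set(majority.values())
        if len(distinct) < 2:
            continue
        if has_gap:
            snp_class = SnpClass.INDEL
        elif len(distinct) == 2:
            snp_class = classify_substitution(*sorted(distinct))
        else:
            snp_class = SnpClass.MULTIALLELIC
        out.append(VariantColumn(column=i, states=states, majority=majority, snp_class=snp_class))
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over gap-free columns of two aligned sequences.

    Columns where either sequence has a gap are excluded from the
    denominator; the standard >=99% rule for barcode identification can be
    applied to the returned value.
    """
    if len(a) != len(b):
        raise AlignmentError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    matches = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise IdentityUndefinedError("no gap-free columns to compare")
    return 100.0 * matches / compared
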