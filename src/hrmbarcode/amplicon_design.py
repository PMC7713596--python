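"""Short discriminative amplicon design from species-labeled alignments.

Finds primer-length windows whose per-species majority sequences are
conserved across the species set, enumerates candidate amplicons (pairs of
conserved flanks spanning at least one variant column, product size in the
mini-amplicon range), extracts per-species amplicon haplotypes, and applies
primers to arbitrary templates by in-silico PCR.

The HRM mini-amplicon rationale: genotyping resolution degrades with
amplicon length, and degraded specimens only amplify short fragments, so
candidate products default to 60-140 bp.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barcode_io import SpeciesSet, VariantColumn, variable_columns
from .errors import DesignError, InputError
from .melt_thermo import ThermoParams, revcomp, two_state_tm

_ACGT = frozenset("ACGT")

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair in the usual table layout: both sequences written
    5'->3', the reverse primer on the minus strand; Ta is the PCR annealing
    temperature and expected_size the product length on the reference."""

    name: str
    fwd_seq: str
    rev_seq: str
    ta: float | None = None
    expected_size: int | None = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.fwd_seq), ("reverse", self.rev_seq)):
            if not 15 <= len(seq) <= 30:
                raise InputError(f"{self.name} {label} primer length {len(seq)} outside 15-30")
            if set(seq.upper()) - _ACGT:
                raise InputError(f"{self.name} {label} primer contains ambiguity codes")


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints; defaults target HRM mini-amplicons."""

    product_size_range: tuple[int, int] = (60, 140)
    primer_len_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (30.0, 70.0)
    tm_range: tuple[float, float] = (45.0, 65.0)
    max_flank_variability: float = 0.0

    def __post_init__(self) -> None:
        for name in ("product_size_range", "primer_len_range", "gc_range", "tm_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InputError(f"{name} is empty: {lo} > {hi}")
        if not 0.0 <= self.max_flank_variability <= 1.0:
            raise InputError("max_flank_variability must be in [0,1]")


@dataclass(frozen=True)
class FlankWindow:
    """A conserved, gap-free primer footprint: alignment columns
    [start, end) and the (modal) plus-strand sequence there."""

    start: int
    end: int
    sequence: str


@dataclass
class CandidateAmplicon:
    """A primer pair anchored on the alignment, with the per-species
    amplicon haplotypes it would produce and the variant columns it spans."""

    primer_pair: PrimerPair
    interval: tuple[int, int]  # alignment columns, incl. primer footprints
    per_species_haplotypes: dict[str, list[str]]
    contained_variants: list[VariantColumn] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.primer_pair.name

    def informative_variant_count(self) -> int:
        return len(self.contained_variants)

    def max_product_size(self) -> int:
        return max(len(h) for hs in self.per_species_haplotypes.values() for h in hs)


def gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def expand_degenerate(seq: str, cap: int = 4) -> list[str]:
    """Expand IUPAC codes into concrete haplotypes, capped (with a warning)
    to keep per-species curve sets finite."""
    seq = seq.upper()
    if not set(seq) - _ACGT:
        return [seq]
    pools = [IUPAC_EXPAND[b] for b in seq]
    n = 1
    for p in pools:
        n *= len(p)
        if n > cap:
            warnings.warn(f"degenerate expansion capped at {cap} haplotypes")
            break
    out = []
    for combo in itertools.product(*pools):
        out.append("".join(combo))
        if len(out) >= cap:
            break
    return out


def find_conserved_flanks(s: SpeciesSet, c: PrimerConstraints | None = None) -> list[FlankWindow]:
    """All primer-length alignment windows whose per-species majority
    sequences are gap-free, unambiguous, and identical across species (up to
    ``max_flank_variability`` fraction of deviating species)."""
    c = c or PrimerConstraints()
    species = s.species()
    if len(species) < 2:
        raise DesignError("flank discovery needs at least two species")
    consensi = [s.consensus(sp) for sp in species]
    lo, hi = c.primer_len_range
    out: list[FlankWindow] = []
    for length in range(lo, hi + 1):
        for start in range(0, s.alignment_length - length + 1):
            windows = [cons[start : start + length] for cons in consensi]
            if any(set(w) - _ACGT for w in windows):
                continue
            counts = pd.Series(windows).value_counts()
            modal = counts.index[0]
            deviating = (len(windows) - counts.iloc[0]) / len(windows)
            if deviating <= c.max_flank_variability:
                out.append(FlankWindow(start=start, end=start + length, sequence=modal))
    return out


def _degapped_slices(s: SpeciesSet, start: int, end: int, cap: int = 4) -> dict[str, list[str]]:
    """Unique ungapped per-species sequences of alignment slice [start, end),
    degenerate positions expanded up to ``cap`` haplotypes per species."""
    out: dict[str, list[str]] = {}
    for sp, recs in s.by_species().items():
        haps: list[str] = []
        for r in recs:
            raw = r.sequence[start:end].replace("-", "")
            for h in expand_degenerate(raw, cap=cap):
                if h not in haps:
                    haps.append(h)
                if len(haps) >= cap:
                    break
        out[sp] = haps[:cap]
    return out


def enumerate_candidate_amplicons(
    s: SpeciesSet,
    c: PrimerConstraints | None = None,
    thermo: ThermoParams | None = None,
    name_prefix: str = "amp",
) -> list[CandidateAmplicon]:
    """All flank pairs giving an in-range product that spans >=1 variant
    column, with primers passing :func:`primer_checks`.

    Sorted by informative-variant count (desc), then shorter product, then
    leftmost start — small amplicons are preferred because degraded DNA only
    supports short products.
    """
    c = c or PrimerConstraints()
    thermo = thermo or ThermoParams.default()
    variants = variable_columns(s)
    if not variants:
        return []
    variant_cols = np.array([v.column for v in variants])
    flanks = find_conserved_flanks(s, c)
    # gap-aware product-size screen: ungapped length of [a,b) per record
    nongap = np.array(
        [[0 if ch == "-" else 1 for ch in r.sequence] for r in s.records]
    ).cumsum(axis=1)

    def ungapped_len(a: int, b: int) -> tuple[int, int]:
        lens = nongap[:, b - 1] - (nongap[:, a - 1] if a > 0 else 0)
        return int(lens.min()), int(lens.max())

    primer_ok: dict[str, bool] = {}

    def check(seq: str) -> bool:
        if seq not in primer_ok:
            primer_ok[seq] = primer_checks(seq, c, thermo).passed
        return primer_ok[seq]

    lo, hi = c.product_size_range
    out: list[CandidateAmplicon] = []
    lefts = sorted(flanks, key=lambda f: (f.start, f.end))
    for left in lefts:
        for right in flanks:
            if right.start < left.end:
                continue
            if right.end - left.start > hi + 10:  # gap slack; exact check below
                continue
            lmin, lmax = ungapped_len(left.start, right.end)
            if lmin < lo or lmax > hi:
                continue
            mask = (variant_cols >= left.start) & (variant_cols < right.end)
            if not mask.any():
                continue
            fwd = left.sequence
            rev = revcomp(right.sequence)
            if not (check(fwd) and check(rev)):
                continue
            haps = _degapped_slices(s, left.start, right.end)
            if any(not (lo <= len(h) <= hi) for hs in haps.values() for h in hs):
                continue
            contained = [v for v, m in zip(variants, mask) if m]
            pair = PrimerPair(
                name=f"{name_prefix}_{left.start}_{right.end}",
                fwd_seq=fwd,
                rev_seq=rev,
                expected_size=lmax,
            )
            out.append(
                CandidateAmplicon(
                    primer_pair=pair,
                    interval=(left.start, right.end),
                    per_species_haplotypes=haps,
                    contained_variants=contained,
                )
            )
    out.sort(key=lambda a: (-a.informative_variant_count(), a.max_product_size(), a.interval[0]))
    return out


def dedupe_candidates(candidates: Sequence[CandidateAmplicon]) -> list[CandidateAmplicon]:
    """Keep the best-ranked candidate per distinct contained-variant set.

    Exhaustive enumeration yields many sliding near-duplicates spanning the
    same polymorphic columns; for scoring and panel selection one
    representative per informative content is enough.
    """
    seen: set[frozenset] = set()
    out: list[CandidateAmplicon] = []
    for c in candidates:
        key = frozenset(v.column for v in c.contained_variants)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x not in _ACGT)


def _find_sites(template: str, site: str, max_mismatch: int, anchor_index: int) -> list[int]:
    """Start positions where ``site`` matches with <= max_mismatch
    mismatches and an exact base at ``anchor_index`` (the primer 3' end)."""
    hits = []
    m = len(site)
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        if window[anchor_index] != site[anchor_index]:
            continue
        if _mismatches(window, site) <= max_mismatch:
            hits.append(i)
    return hits


def in_silico_pcr(p: PrimerPair, template: str, max_mismatch: int = 0) -> str | None:
    """Product of a primer pair on an ungapped plus-strand template.

    The forward primer anneals on the plus strand, the reverse primer's
    reverse complement downstream of it; each site tolerates up to
    ``max_mismatch`` internal mismatches but the 3'-terminal base must match
    exactly (polymerase extension requirement).  Returns the inclusive
    product spanning both footprints; with multiple placements the shortest
    product wins with a warning; no placement returns None.
    """
    template = template.upper().replace("-", "")
    fwd = p.fwd_seq.upper()
    rev_site = revcomp(p.rev_seq.upper())
    fwd_hits = _find_sites(template, fwd, max_mismatch, anchor_index=len(fwd) - 1)
    rev_hits = _find_sites(template, rev_site, max_mismatch, anchor_index=0)
    products = []
    for i in fwd_hits:
        for j in rev_hits:
            if j >= i + len(fwd):
                products.append(template[i : j + len(rev_site)])
    if not products:
        return None
    if len(products) > 1:
        warnings.warn(f"{p.name}: {len(products)} possible placements; returning shortest")
    return min(products, key=len)


@dataclass(frozen=True)
class PrimerReport:
    """Minimal primer quality report (length, composition, screening Tm,
    self-complementarity) with a pass/fail verdict against constraints."""

    sequence: str
    length: int
    gc_percent: float
    tm: float
    max_self_comp_run: int
    max_3p_hairpin_stem: int
    passed: bool
    failures: tuple[str, ...] = ()
    self_complementary: bool = False


def _max_self_comp_run(seq: str) -> int:
    """Longest substring whose reverse complement is also a substring
    (primer-dimer propensity)."""
    best = 0
    n = len(seq)
    for i in range(n):
        for j in range(i + best + 1, n + 1):
            if revcomp(seq[i:j]) in seq:
                best = j - i
            else:
                break
    return best


def _max_3p_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest 3'-terminal suffix that can fold back onto the primer with a
    loop of >= min_loop bases."""
    n = len(seq)
    best = 0
    for k in range(1, n // 2 + 1):
        stem = revcomp(seq[n - k :])
        if stem in seq[: n - k - min_loop]:
            best = k
    return best


def primer_checks(
    seq: str, c: PrimerConstraints | None = None, p: ThermoParams | None = None
) -> PrimerReport:
    """Screen one primer against length/GC/Tm constraints and flag
    self-complementarity (a stand-in for a full Primer3-style evaluation)."""
    c = c or PrimerConstraints()
    p = p or ThermoParams.default()
    seq = seq.upper()
    if set(seq) - _ACGT:
        raise InputError("primer_checks requires an unambiguous sequence")
    length = len(seq)
    gc = gc_percent(seq)
    tm = two_state_tm(seq, p)
    self_run = _max_self_comp_run(seq)
    hairpin = _max_3p_hairpin_stem(seq)
    failures = []
    if not c.primer_len_range[0] <= length <= c.primer_len_range[1]:
        failures.append("length")
    if not c.gc_range[0] <= gc <= c.gc_range[1]:
        failures.append("gc_range")
    if not c.tm_range[0] <= tm <= c.tm_range[1]:
        failures.append("tm_range")
    return PrimerReport(
        sequence=seq,
        length=length,
        gc_percent=gc,
        tm=tm,
        max_self_comp_run=self_run,
        max_3p_hairpin_stem=hairpin,
        passed=not failures,
        failures=tuple(failures),
        self_complementary=self_run >= max(8, length // 2),
    )


def amplicon_from_primers(
    p: PrimerPair,
    s: SpeciesSet,
    variants: Sequence[VariantColumn] | None = None,
    max_mismatch: int = 0,
) -> CandidateAmplicon:
    """Anchor an existing primer pair (e.g. a published table) on a
    reference SpeciesSet by in-silico PCR.

    Haplotypes are the unique products over each species' records; the
    alignment interval is located on the first amplifying record.  A species
    yielding no product raises :class:`DesignError`.
    """
    if variants is None:
        variants = variable_columns(s)
    haps: dict[str, list[str]] = {}
    interval: tuple[int, int] | None = None
    for sp, recs in s.by_species().items():
        products: list[str] = []
        for r in recs:
            degapped = r.sequence.replace("-", "")
            product = in_silico_pcr(p, degapped, max_mismatch=max_mismatch)
            if product is None:
                continue
            if product not in products:
                products.append(product)
            if interval is None:
                # map degapped product position back to alignment columns
                dg_start = degapped.find(product)
                cols = [i for i, ch in enumerate(r.sequence) if ch != "-"]
                interval = (cols[dg_start], cols[dg_start + len(product) - 1] + 1)
        if not products:
            raise DesignError(f"{p.name}: no product for species {sp!r}")
        haps[sp] = products
    assert interval is not None
    contained = [v for v in variants if interval[0] <= v.column < interval[1]]
    return CandidateAmplicon(
        primer_pair=p,
        interval=interval,
        per_species_haplotypes=haps,
        contained_variants=contained,
    )


def read_primer_table(path=None) -> list[PrimerPair]:
    """Read a primer TSV in the usual publication layout (Name, Direction,
    Sequence, Ta, Amplicon_size; one Forward and one Reverse row per pair).
    With no path, the packaged blowfly COI primer set is returned."""
    if path is None:
        path = resources.files("hrmbarcode").joinpath("data/primers_blowfly_coi.tsv")
        with resources.as_file(path) as fp:
            return read_primer_table(fp)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    pairs: list[PrimerPair] = []
    pending: dict | None = None
    for _, row in df.iterrows():
        direction = row["Direction"].strip().lower()
        if direction == "forward":
            pending = {
                "name": row["Name"].strip().removesuffix("F"),
                "fwd": row["Sequence"].strip().upper(),
                "ta": float(row["Ta"]) if row.get("Ta", "") else None,
                "size": int(float(row["Amplicon_size"])) if row.get("Amplicon_size", "") else None,
            }
        elif direction == "reverse":
            if pending is None:
                raise InputError("reverse primer row without preceding forward row")
            pairs.append(
                PrimerPair(
                    name=pending["name"],
                    fwd_seq=pending["fwd"],
                    rev_seq=row["Sequence"].strip().upper(),
                    ta=pending["ta"],
                    expected_size=pending["size"],
                )
            )
            pending = None
        else:
            raise InputError(f"unknown primer direction {row['Direction']!r}")
    if pending is not None:
        raise InputError(f"unpaired forward primer {pending['name']!r}")
    return pairs


def candidate_report(candidates: Sequence[CandidateAmplicon]) -> pd.DataFrame:
    """Human-facing candidate table (1-based inclusive interval)."""
    rows = []
    for a in candidates:
        rows.append(
            {
                "name": a.name,
                "start_1based": a.interval[0] + 1,
                "end_1based": a.interval[1],
                "fwd_primer": a.primer_pair.fwd_seq,
                "rev_primer": a.primer_pair.rev_seq,
                "max_product_bp": a.max_product_size(),
                "informative_variants": a.informative_variant_count(),
                "variant_classes": ",".join(v.snp_class.value for v in a.contained_variants),
            }
        )
    return pd.DataFrame(rows)
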