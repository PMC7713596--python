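"""Synthetic inputs for the whole pipeline: species-structured barcode
haplotypes with planted variants, degradation-dependent amplification
success, and noisy melt replicates.

The haplotype generator plants variants at stated columns on top of a shared
random background, keeps declared flank windows conserved across species,
and sprinkles within-species divergence elsewhere — a deliberately stylized
stand-in for a curated COI reference alignment.  It makes no attempt at
phylogenetically realistic evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .amplicon_design import read_primer_table
from .barcode_io import BarcodeRecord, SpeciesSet
from .errors import InputError, ModelError
from .melt_thermo import MeltCurve, _interp_tm, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedVariant:
    """One alignment column with a fixed base per species (in model species
    order).  The species partition and HRM class follow from the bases."""

    column: int
    bases: tuple[str, ...]


@dataclass(frozen=True)
class SpeciesSimModel:
    """Everything needed to generate a deterministic reference alignment.

    ``fixed_segments`` are sequences written verbatim into the shared
    background (e.g. real primer footprints); both they and
    ``flank_windows`` are conserved across species and protected from
    within-species divergence, as are planted columns.
    """

    species: tuple[str, ...]
    haplotypes_per_species: int = 1
    alignment_length: int = 400
    flank_windows: tuple[tuple[int, int], ...] = ()  # (start, length)
    fixed_segments: tuple[tuple[int, str], ...] = ()  # (start, sequence)
    planted: tuple[PlantedVariant, ...] = ()
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ModelError("need at least one species")
        if not 0.0 <= self.divergence <= 1.0:
            raise ModelError("divergence must be in [0,1]")
        if self.haplotypes_per_species < 1:
            raise ModelError("haplotypes_per_species must be >= 1")
        protected = self.protected_columns()
        for v in self.planted:
            if not 0 <= v.column < self.alignment_length:
                raise ModelError(f"planted column {v.column} outside alignment")
            if v.column in protected:
                raise ModelError(f"planted column {v.column} inside a conserved window")
            if len(v.bases) != len(self.species):
                raise ModelError(
                    f"planted column {v.column}: {len(v.bases)} bases for {len(self.species)} species"
                )
        for start, length in self.flank_windows:
            if not (0 <= start and start + length <= self.alignment_length):
                raise ModelError("flank window outside alignment")
        for start, seg in self.fixed_segments:
            if not (0 <= start and start + len(seg) <= self.alignment_length):
                raise ModelError("fixed segment outside alignment")

    def protected_columns(self) -> set[int]:
        cols: set[int] = set()
        for start, length in self.flank_windows:
            cols.update(range(start, start + length))
        for start, seg in self.fixed_segments:
            cols.update(range(start, start + len(seg)))
        return cols


def simulate_haplotypes(m: SpeciesSimModel) -> SpeciesSet:
    """Deterministic (seeded) SpeciesSet realizing the model: shared random
    background, fixed segments and flanks conserved, planted variants exact,
    within-species mutations only at unprotected non-planted columns."""
    rng = np.random.default_rng(m.seed)
    background = rng.choice(_BASES, size=m.alignment_length)
    for start, seg in m.fixed_segments:
        background[start : start + len(seg)] = list(seg.upper())
    untouchable = m.protected_columns() | {v.column for v in m.planted}
    mutable = np.array(
        sorted(set(range(m.alignment_length)) - untouchable), dtype=int
    )
    records: list[BarcodeRecord] = []
    for si, sp in enumerate(m.species):
        base = background.copy()
        for v in m.planted:
            base[v.column] = v.bases[si].upper()
        for k in range(m.haplotypes_per_species):
            hap = base.copy()
            if m.divergence > 0 and mutable.size:
                hit = mutable[rng.random(mutable.size) < m.divergence]
                for col in hit:
                    choices = [b for b in "ACGT" if b != hap[col]]
                    hap[col] = choices[rng.integers(3)]
            records.append(
                BarcodeRecord(id=f"{sp}_h{k + 1}", species=sp, sequence="".join(hap))
            )
    return SpeciesSet(records=records)


def blowfly_reference_model(
    seed: int = 2020,
    haplotypes_per_species: int = 1,
    divergence: float = 0.0,
) -> SpeciesSimModel:
    """A six-species Calliphoridae-style COI model with the published HRM
    primer footprints embedded and two polymorphic windows.

    Window 1 (inside the 82 bp product) separates every species pair except
    C. megacephala / C. albiceps; window 2 (inside the 124 bp product)
    separates every pair except L. cuprina / L. eximia.  Synthetic: the
    planted columns are GC-content ladders, not the true COI positions.
    A third ladder outside both amplicons makes whole-barcode identities
    species-specific.
    """
    primers = {p.name: p for p in read_primer_table()}
    hrm82, hrm124 = primers["HRM_82"], primers["HRM_124"]
    species = (
        "Lucilia_eximia",
        "Lucilia_cuprina",
        "Chrysomya_megacephala",
        "Chrysomya_albiceps",
        "Chrysomya_putoria",
        "Cochliomyia_macellaria",
    )
    # region 1: fwd at 40, 42-base insert, rev footprint ends at 122 -> 82 bp
    seg_a = ((40, hrm82.fwd_seq), (102, revcomp(hrm82.rev_seq)))
    # region 2: fwd(22) at 180, 81-base insert, rev(21) ends at 304 -> 124 bp
    seg_b = ((180, hrm124.fwd_seq), (283, revcomp(hrm124.rev_seq)))

    def ladder(cols: Sequence[int], levels: Sequence[int]) -> list[PlantedVariant]:
        return [
            PlantedVariant(
                column=c,
                bases=tuple("G" if lvl > j else "A" for lvl in levels),
            )
            for j, c in enumerate(cols)
        ]

    # levels = number of G's a species carries; equal levels (with nested
    # columns) -> identical amplicon haplotypes -> indistinguishable pair
    planted = (
        # 82 bp insert: megacephala == albiceps
        *ladder(range(62, 94, 4), levels=(0, 2, 4, 4, 6, 8)),
        # 124 bp insert: eximia == cuprina
        *ladder(range(205, 261, 7), levels=(4, 4, 0, 2, 6, 8)),
        # outside both amplicons: all six species distinct
        *ladder(range(330, 355, 5), levels=(0, 1, 2, 3, 4, 5)),
    )
    return SpeciesSimModel(
        species=species,
        haplotypes_per_species=haplotypes_per_species,
        alignment_length=380,
        fixed_segments=seg_a + seg_b,
        planted=planted,
        divergence=divergence,
        seed=seed,
    )


def classifier_reference_tms() -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Benchmark reference layout for classifier recovery studies.

    Six species, two amplicons, reference cluster means separated by at
    least 0.5 degC within each amplicon; the pair merged on one amplicon is
    split by the other (the two-assay identification geometry).  Also
    returns the Tm pair of a planted novel species lying >= 1 degC away
    from every reference cluster on both amplicons, which a correct
    classifier must report as NRC.
    """
    reference = {
        "amp1": {
            "Lucilia_eximia": 78.0,
            "Lucilia_cuprina": 78.6,
            "Chrysomya_megacephala": 79.4,
            "Chrysomya_albiceps": 79.4,
            "Chrysomya_putoria": 80.2,
            "Cochliomyia_macellaria": 81.0,
        },
        "amp2": {
            "Lucilia_eximia": 81.2,
            "Lucilia_cuprina": 81.2,
            "Chrysomya_megacephala": 78.8,
            "Chrysomya_albiceps": 79.4,
            "Chrysomya_putoria": 80.2,
            "Cochliomyia_macellaria": 78.2,
        },
    }
    novel = {"amp1": 83.0, "amp2": 83.2}
    return reference, novel


@dataclass(frozen=True)
class DegradationModel:
    """Exponential fragmentation: breakpoints are memoryless with rate
    1/mean_fragment_length, so a stretch of length a survives intact in one
    template copy with probability exp(-a/mean)."""

    mean_fragment_length: float
    copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_fragment_length <= 0:
            raise ModelError("mean_fragment_length must be positive")
        if self.copies < 1:
            raise ModelError("copies must be >= 1")


def simulate_amplification(
    d: DegradationModel, amplicon_length: float, trials: int = 10_000
) -> float:
    """Monte-Carlo fraction of trials where at least one template copy has
    an intact stretch covering the amplicon.

    Draws depend only on the model seed, not the length, so success sets are
    nested across lengths: estimated success is exactly monotone decreasing
    in amplicon length for a fixed model.
    """
    if amplicon_length < 0:
        raise InputError("amplicon_length must be non-negative")
    rng = np.random.default_rng(d.seed)
    p_intact = math.exp(-amplicon_length / d.mean_fragment_length)
    draws = rng.random((trials, d.copies))
    success = (draws < p_intact).any(axis=1)
    return float(success.mean())


def simulate_melt_replicates(
    true_tm: float, noise_sd: float, n: int, seed: int = 0
) -> list[float]:
    """Gaussian Tm jitter around a true value; deterministic under seed."""
    if noise_sd < 0 or n < 1:
        raise InputError("need noise_sd >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    return list(true_tm + rng.normal(0.0, noise_sd, size=n))


def shift_curve(curve: MeltCurve, delta_t: float) -> MeltCurve:
    """Rigidly shift a melt curve along the temperature axis (the default
    noise model for simulated raw traces), re-sampled on the original grid."""
    temps = curve.temperatures
    shifted = np.interp(
        temps - delta_t, temps, curve.helicity, left=curve.helicity[0], right=curve.helicity[-1]
    )
    tm, ok = _interp_tm(temps, shifted)
    return MeltCurve(temperatures=temps, helicity=shifted, tm=tm, tm_in_range=ok)


def simulate_melt_curves(
    true_curve: MeltCurve, noise_sd: float, n: int, seed: int = 0
) -> list[MeltCurve]:
    """Replicate curves under rigid Tm jitter."""
    deltas = simulate_melt_replicates(0.0, noise_sd, n, seed=seed)
    return [shift_curve(true_curve, d) for d in deltas]
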