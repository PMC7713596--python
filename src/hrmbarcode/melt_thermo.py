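"""Nearest-neighbor DNA melting model for short amplicons.

The module predicts helicity-vs-temperature curves (and the derived melting
temperature Tm) for ungapped duplex DNA from a unified nearest-neighbor
stack table.  The statistical-mechanical model is a zipper/partition-function
treatment of a single duplex:

* a microstate is any subset of the N-1 base-pair stacks of an N-mer;
* its energy is the sum of the formed stacks' free energies, plus a
  cooperativity penalty ``gamma`` per maximal helical run, plus the duplex
  initiation terms;
* helicity(T) is the Boltzmann-expected fraction of formed stacks,
  evaluated with a transfer-matrix recursion in O(N) per temperature.

Salt enters through the entropic correction dS' = dS + 0.368 ln[Na+] per
stack.  A brute-force enumerator over all 2^(N-1) states is provided as an
independent oracle for short sequences, and a classical two-state Tm formula
as a quick screening estimate (the only place strand concentration and the
duplex symmetry factor matter).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import GridMismatchError, InputError

# Gas constant in the two unit systems used below.
R_KCAL = 0.0019872  # kcal / (mol K)
R_CAL = 1.9872  # cal / (mol K)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TemperatureGrid:
    """Uniform acquisition grid, default 65-97 degC at 25 points per degree
    (the melt-acquisition density of HRM-capable qPCR instruments)."""

    t_min: float = 65.0
    t_max: float = 97.0
    points_per_degree: int = 25

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise InputError(f"t_min must be below t_max, got {self.t_min}..{self.t_max}")
        if self.points_per_degree < 1:
            raise InputError("points_per_degree must be >= 1")

    def temperatures(self) -> np.ndarray:
        n = round((self.t_max - self.t_min) * self.points_per_degree) + 1
        return np.linspace(self.t_min, self.t_max, n)


def _load_default_table() -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
    raw = json.loads(
        resources.files("hrmbarcode").joinpath("data/nn_unified.json").read_text()
    )
    stacks = {k: (float(v[0]), float(v[1])) for k, v in raw["stacks"].items()}
    init = {k: (float(v[0]), float(v[1])) for k, v in raw["init"].items()}
    return stacks, init


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameter bundle.

    nn_table maps each plus-strand dinucleotide to (dH kcal/mol, dS cal/mol K);
    init_terms maps terminal base-pair class ('AT'/'GC') to initiation
    (dH, dS).  junction_penalty_kcal is the cooperativity cost gamma charged
    per maximal helical run; 0 gives a pure zipper with unrealistically
    broad transitions, the default 6 kcal/mol gives instrument-like sharp
    amplicon melts.
    """

    nn_table: Mapping[str, tuple[float, float]] = field(default_factory=lambda: _load_default_table()[0])
    init_terms: Mapping[str, tuple[float, float]] = field(default_factory=lambda: _load_default_table()[1])
    monovalent_salt_M: float = 0.05
    strand_conc_M: float = 2.5e-7
    junction_penalty_kcal: float = 6.0
    grid: TemperatureGrid = field(default_factory=TemperatureGrid)

    def __post_init__(self) -> None:
        if self.monovalent_salt_M <= 0 or self.strand_conc_M <= 0:
            raise InputError("salt and strand concentrations must be positive")
        if self.junction_penalty_kcal < 0:
            raise InputError("junction penalty must be non-negative")
        for stack, (dh, _) in self.nn_table.items():
            if dh >= 0:
                raise InputError(f"stacking dH must be negative ({stack}: {dh})")

    @classmethod
    def default(cls) -> "ThermoParams":
        return cls()

    def with_grid(self, grid: TemperatureGrid) -> "ThermoParams":
        return replace(self, grid=grid)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ThermoParams":
        """Build from a plain config mapping (documented schema: keys
        monovalent_salt_M, strand_conc_M, junction_penalty_kcal, grid
        {t_min,t_max,points_per_degree}, optional nn_table / init_terms)."""
        kwargs: dict = {}
        for key in ("monovalent_salt_M", "strand_conc_M", "junction_penalty_kcal"):
            if key in cfg:
                kwargs[key] = float(cfg[key])
        if "grid" in cfg:
            g = cfg["grid"]
            kwargs["grid"] = TemperatureGrid(
                t_min=float(g.get("t_min", 65.0)),
                t_max=float(g.get("t_max", 97.0)),
                points_per_degree=int(g.get("points_per_degree", 25)),
            )
        if "nn_table" in cfg:
            kwargs["nn_table"] = {k: (float(v[0]), float(v[1])) for k, v in cfg["nn_table"].items()}
        if "init_terms" in cfg:
            kwargs["init_terms"] = {k: (float(v[0]), float(v[1])) for k, v in cfg["init_terms"].items()}
        return cls(**kwargs)


@dataclass
class MeltCurve:
    """Helicity (or normalized fluorescence) sampled on a temperature grid.

    ``tm`` is the linear interpolation of the 0.5 crossing; ``tm_in_range``
    is False when the grid does not bracket the crossing (tm is then NaN).
    """

    temperatures: np.ndarray
    helicity: np.ndarray
    tm: float
    tm_in_range: bool = True

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.helicity = np.asarray(self.helicity, dtype=float)
        if self.temperatures.shape != self.helicity.shape:
            raise InputError("temperature and helicity arrays differ in length")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if len(seq) < 2:
        raise InputError("need at least 2 bases (one stack)")
    bad = set(seq) - _UNAMBIGUOUS
    if bad:
        raise InputError(f"ambiguity codes not allowed in melt prediction: {sorted(bad)}")
    return seq


def _stack_params(seq: str, p: ThermoParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-stack (dH, salt-corrected dS) arrays for the N-1 stacks of seq."""
    dh = np.empty(len(seq) - 1)
    ds = np.empty(len(seq) - 1)
    salt_ds = 0.368 * math.log(p.monovalent_salt_M)
    for i in range(len(seq) - 1):
        h, s = p.nn_table[seq[i : i + 2]]
        dh[i] = h
        ds[i] = s + salt_ds
    return dh, ds


def _init_params(seq: str, p: ThermoParams) -> tuple[float, float]:
    """Summed initiation (dH, dS) for the two duplex ends."""
    dh = ds = 0.0
    for base in (seq[0], seq[-1]):
        h, s = p.init_terms["AT" if base in "AT" else "GC"]
        dh += h
        ds += s
    return dh, ds


def stack_free_energies(seq: str, p: ThermoParams, temperature_c: float) -> np.ndarray:
    """Free energy dG_i (kcal/mol) of each of the N-1 stacks at one
    temperature, with the entropic salt correction applied."""
    seq = _check_sequence(seq)
    dh, ds = _stack_params(seq, p)
    t_k = temperature_c + 273.15
    return dh - t_k * ds / 1000.0


def _interp_tm(temps: np.ndarray, hel: np.ndarray) -> tuple[float, bool]:
    """Linear interpolation of the 0.5 crossing of a non-increasing curve."""
    below = np.nonzero(hel < 0.5)[0]
    if hel[0] < 0.5 or below.size == 0:
        return float("nan"), False
    j = below[0]
    h0, h1 = hel[j - 1], hel[j]
    t0, t1 = temps[j - 1], temps[j]
    if h0 == h1:
        return float(t0), True
    return float(t0 + (h0 - 0.5) * (t1 - t0) / (h0 - h1)), True


def helicity_curve(seq: str, p: ThermoParams | None = None) -> MeltCurve:
    """Predicted melt curve of a duplex by transfer-matrix recursion.

    The recursion tracks, at each stack, the partition function and the
    weighted formed-stack count split by the state of the previous stack,
    rescaling per step so amplicon-length sequences do not overflow.
    Additive state-energy constants (duplex initiation) cancel in the
    Boltzmann average and are therefore not carried explicitly.
    """
    p = p or ThermoParams.default()
    seq = _check_sequence(seq)
    temps = p.grid.temperatures()
    t_k = temps + 273.15
    rt = R_KCAL * t_k
    dh, ds = _stack_params(seq, p)
    dg = dh[:, None] - t_k[None, :] * ds[:, None] / 1000.0  # (N-1, nT)
    g = np.exp(-p.junction_penalty_kcal / rt)  # run-start weight

    z0 = np.ones_like(t_k)
    z1 = np.zeros_like(t_k)
    m0 = np.zeros_like(t_k)
    m1 = np.zeros_like(t_k)
    for i in range(len(seq) - 1):
        w = np.exp(-dg[i] / rt)
        nz0 = z0 + z1
        nm0 = m0 + m1
        nz1 = (z0 * g + z1) * w
        nm1 = (m0 * g + m1) * w + nz1
        scale = nz0 + nz1
        z0, z1 = nz0 / scale, nz1 / scale
        m0, m1 = nm0 / scale, nm1 / scale
    hel = (m0 + m1) / (len(seq) - 1)
    tm, ok = _interp_tm(temps, hel)
    return MeltCurve(temperatures=temps, helicity=hel, tm=tm, tm_in_range=ok)


_BRUTE_FORCE_MAX = 13


def brute_force_helicity(seq: str, p: ThermoParams | None = None) -> MeltCurve:
    """Exact enumeration of all 2^(N-1) stack subsets; oracle for
    :func:`helicity_curve`, refused above N=13."""
    p = p or ThermoParams.default()
    seq = _check_sequence(seq)
    if len(seq) > _BRUTE_FORCE_MAX:
        raise InputError(f"brute force limited to sequences of length <= {_BRUTE_FORCE_MAX}")
    temps = p.grid.temperatures()
    t_k = temps + 273.15
    rt = R_KCAL * t_k
    n_stacks = len(seq) - 1
    dh, ds = _stack_params(seq, p)
    dg = dh[:, None] - t_k[None, :] * ds[:, None] / 1000.0

    states = np.arange(2**n_stacks)
    bits = ((states[:, None] >> np.arange(n_stacks)) & 1).astype(float)  # (S, N-1)
    counts = bits.sum(axis=1)
    runs = bits[:, 0] + ((bits[:, 1:] > bits[:, :-1]).sum(axis=1) if n_stacks > 1 else 0.0)
    init_dh, init_ds = _init_params(seq, p)
    init_dg = init_dh - t_k * init_ds / 1000.0  # constant per T; cancels in the average

    energy = bits @ dg + p.junction_penalty_kcal * runs[:, None] + init_dg[None, :]
    energy -= energy.min(axis=0, keepdims=True)
    w = np.exp(-energy / rt[None, :])
    hel = (w * counts[:, None]).sum(axis=0) / (w.sum(axis=0) * n_stacks)
    tm, ok = _interp_tm(temps, hel)
    return MeltCurve(temperatures=temps, helicity=hel, tm=tm, tm_in_range=ok)


def two_state_tm(seq: str, p: ThermoParams | None = None) -> float:
    """Two-state melting temperature (degC) from summed nearest-neighbor
    dH/dS, entropic salt correction, and the standard concentration term.

    Tm = dH / (dS + R ln(C_T / x)) with x = 1 for self-complementary
    sequences and 4 otherwise.
    """
    p = p or ThermoParams.default()
    seq = _check_sequence(seq)
    dh, ds = _stack_params(seq, p)
    init_dh, init_ds = _init_params(seq, p)
    total_dh = dh.sum() + init_dh  # kcal/mol
    total_ds = ds.sum() + init_ds  # cal/(mol K), salt-corrected per stack
    x = 1.0 if seq == revcomp(seq) else 4.0
    tm_k = total_dh * 1000.0 / (total_ds + R_CAL * math.log(p.strand_conc_M / x))
    return tm_k - 273.15


def derivative_curve(c: MeltCurve) -> tuple[np.ndarray, np.ndarray]:
    """(temperatures, -d helicity/dT) by central differences; the negative
    derivative peaks at Tm for unimodal melts."""
    return c.temperatures, -np.gradient(c.helicity, c.temperatures)


def curve_distance(a: MeltCurve, b: MeltCurve) -> float:
    """Maximum absolute helicity difference over a shared grid."""
    if a.temperatures.shape != b.temperatures.shape or not np.allclose(
        a.temperatures, b.temperatures
    ):
        raise GridMismatchError("curves are sampled on different temperature grids")
    return float(np.max(np.abs(a.helicity - b.helicity)))


def write_curve_csv(c: MeltCurve, path) -> None:
    """Export a curve as 2-column CSV (temperature, signal)."""
    arr = np.column_stack([c.temperatures, c.helicity])
    np.savetxt(path, arr, delimiter=",", header="temperature,signal", comments="")


def read_curve_csv(path) -> MeltCurve:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    temps, hel = arr[:, 0], arr[:, 1]
    tm, ok = _interp_tm(temps, hel)
    return MeltCurve(temperatures=temps, helicity=hel, tm=tm, tm_in_range=ok)
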