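"""Observed melt-data processing and species calling.

Raw fluorescence traces are normalized between fitted pre- and post-melt
baselines (the standard HRM normalization), Tm is read off the 0.5 crossing
so observed and predicted values share one convention, triplicates are
summarized as mean / sample SD / Student-t CI95, and unknowns are pushed
through the decision tree: at each assay the sample either joins a
reference Tm cluster, descends with a multi-species cluster, or — matching
no cluster at all — is reported as NRC (No Reference Cluster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridMismatchError, InputError, NormalizationError
from .melt_thermo import MeltCurve, _interp_tm
from .panel_eval import DecisionTree

#: verdict kinds
SPECIES, AMBIGUOUS, NRC = "species", "ambiguous", "NRC"


@dataclass
class RawMeltTrace:
    """One raw fluorescence-vs-temperature acquisition."""

    sample_id: str
    amplicon: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise InputError(f"trace {self.sample_id}: array length mismatch")
        if not np.all(np.diff(self.temperatures) > 0):
            raise InputError(f"trace {self.sample_id}: temperatures must strictly increase")


def normalize_curve(
    r: RawMeltTrace,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> MeltCurve:
    """Two-baseline normalization onto [0, 1].

    A line is fitted to the fluorescence inside each window; the pre-melt
    (low-temperature) line is the upper baseline, the post-melt line the
    lower, and the signal is rescaled as (F - lower) / (upper - lower),
    clipped to [0, 1].  Windows must lie inside the trace, pre below post,
    each spanning at least 1 degC.
    """
    t = r.temperatures
    for name, (lo, hi) in (("pre", pre_window), ("post", post_window)):
        if hi - lo < 1.0:
            raise InputError(f"{name}_window must span at least 1 degC")
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise InputError(f"{name}_window {lo}-{hi} outside trace range {t[0]}-{t[-1]}")
    if pre_window[1] > post_window[0]:
        raise InputError("pre_window must lie below post_window")

    def fit_line(window: tuple[float, float]) -> np.ndarray:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 2:
            raise InputError(f"window {window} contains fewer than 2 points")
        slope, intercept = np.polyfit(t[mask], r.fluorescence[mask], 1)
        return slope * t + intercept

    upper = fit_line(pre_window)
    lower = fit_line(post_window)
    span = upper - lower
    if np.median(span) <= 0 or np.min(np.abs(span)) < 1e-12:
        raise NormalizationError(
            f"trace {r.sample_id}: pre- and post-melt baselines are degenerate"
        )
    norm = np.clip((r.fluorescence - lower) / span, 0.0, 1.0)
    tm, ok = _interp_tm(t, norm)
    return MeltCurve(temperatures=t, helicity=norm, tm=tm, tm_in_range=ok)


def tm_from_trace(
    r: RawMeltTrace,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> float:
    """Observed Tm: normalize, then interpolate the 0.5 crossing (the same
    convention used for predicted curves)."""
    return normalize_curve(r, pre_window, post_window).tm


def difference_plot(c: MeltCurve, ref: MeltCurve) -> np.ndarray:
    """Pointwise difference against a reference genotype's normalized curve."""
    if c.temperatures.shape != ref.temperatures.shape or not np.allclose(
        c.temperatures, ref.temperatures
    ):
        raise GridMismatchError("difference plot requires a shared grid")
    return c.helicity - ref.helicity


@dataclass(frozen=True)
class TmSummary:
    """Replicate summary; sd and ci95 are NaN-flagged for n < 2."""

    n: int
    mean: float
    sd: float
    ci95: float  # half-width

    @property
    def sd_defined(self) -> bool:
        return not math.isnan(self.sd)


def summarize_replicates(tms: Sequence[float]) -> TmSummary:
    """Mean, sample SD (n-1 denominator) and Student-t 95% CI half-width
    t_{0.975, n-1} * sd / sqrt(n) of replicate Tm values."""
    if len(tms) == 0:
        raise InputError("no replicates to summarize")
    arr = np.asarray(tms, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n < 2:
        return TmSummary(n=n, mean=mean, sd=float("nan"), ci95=float("nan"))
    sd = float(arr.std(ddof=1))
    ci95 = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return TmSummary(n=n, mean=mean, sd=sd, ci95=ci95)


@dataclass
class ReferencePanel:
    """Per-amplicon, per-species reference Tm summaries (the Supp.-4-style
    table: species, amplicon, n, mean, SD, CI95)."""

    entries: dict[tuple[str, str], TmSummary]  # (amplicon, species) -> summary

    def get(self, amplicon: str, species: str) -> TmSummary | None:
        return self.entries.get((amplicon, species))

    def mean_tms(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for (amp, sp), summ in self.entries.items():
            out.setdefault(amp, {})[sp] = summ.mean
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "amplicon": amp,
                "n": s.n,
                "tm_mean": s.mean,
                "sd": s.sd,
                "ci95": s.ci95,
            }
            for (amp, sp), s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferencePanel":
        entries = {}
        for _, row in df.iterrows():
            entries[(str(row["amplicon"]), str(row["species"]))] = TmSummary(
                n=int(row["n"]),
                mean=float(row["tm_mean"]),
                sd=float(row["sd"]),
                ci95=float(row["ci95"]),
            )
        return cls(entries=entries)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferencePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class NodeMatch:
    """Per-node detail of a classification walk."""

    amplicon: str
    matched_group: list[str] | None
    best_species: str | None
    delta_tm: float | None
    tolerance: float | None


@dataclass
class SpeciesCall:
    """Classifier verdict: a species, an ambiguous species set, or NRC."""

    sample_id: str
    verdict: str  # SPECIES | AMBIGUOUS | NRC
    species: str | None = None
    group: list[str] = field(default_factory=list)
    details: list[NodeMatch] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _cluster_match(
    sample_mean: float,
    cluster: Sequence[str],
    amplicon: str,
    ref: ReferencePanel,
    tolerance_k: float,
    sd_floor: float,
) -> tuple[float, str, float] | None:
    """Best matching member of a cluster, or None if no member is within
    tolerance_k * max(ref SD, sd_floor) of the sample mean."""
    best: tuple[float, str, float] | None = None
    for sp in cluster:
        summ = ref.get(amplicon, sp)
        if summ is None:
            continue
        sd = summ.sd if summ.sd_defined else 0.0
        tol = tolerance_k * max(sd, sd_floor)
        delta = abs(sample_mean - summ.mean)
        if delta <= tol and (best is None or delta < best[0]):
            best = (delta, sp, tol)
    return best


def call_species(
    sample_id: str,
    sample: Mapping[str, TmSummary],
    ref: ReferencePanel,
    tree: DecisionTree,
    tolerance_k: float = 3.0,
    sd_floor: float = 0.15,
) -> SpeciesCall:
    """Hierarchical species call for one sample.

    The sample descends the decision tree in node order: at each node its
    mean Tm for that amplicon is matched against the reference clusters
    (nearest matching cluster wins).  A matched singleton ends the walk with
    a species verdict; a matched group descends; no match at an applicable
    node is NRC; running out of assays with a multi-species group left (or
    missing data for a needed assay) yields an ambiguous verdict.
    """
    current: set[str] | None = None
    details: list[NodeMatch] = []
    flags: list[str] = []
    for node in tree.nodes:
        clusters = [
            [sp for sp in grp if current is None or sp in current]
            for grp in node.partition
        ]
        clusters = [c for c in clusters if c]
        if not clusters:
            continue
        if node.amplicon not in sample:
            if current is None or len(current) != 1:
                group = sorted(current) if current else sorted(tree.all_species())
                flags.append(f"missing data for amplicon {node.amplicon}")
                return SpeciesCall(
                    sample_id=sample_id,
                    verdict=AMBIGUOUS,
                    group=group,
                    details=details,
                    flags=flags,
                )
            continue
        mean = sample[node.amplicon].mean
        best_cluster: tuple[float, list[str], str, float] | None = None
        for cluster in clusters:
            hit = _cluster_match(mean, cluster, node.amplicon, ref, tolerance_k, sd_floor)
            if hit is not None and (best_cluster is None or hit[0] < best_cluster[0]):
                best_cluster = (hit[0], cluster, hit[1], hit[2])
        if best_cluster is None:
            details.append(
                NodeMatch(node.amplicon, None, None, None, None)
            )
            return SpeciesCall(
                sample_id=sample_id, verdict=NRC, details=details, flags=flags
            )
        delta, cluster, best_sp, tol = best_cluster
        details.append(
            NodeMatch(node.amplicon, list(cluster), best_sp, delta, tol)
        )
        current = set(cluster) if current is None else set(cluster) & current
        if len(current) == 1:
            return SpeciesCall(
                sample_id=sample_id,
                verdict=SPECIES,
                species=next(iter(current)),
                details=details,
                flags=flags,
            )
    if current is None:
        raise InputError("decision tree has no applicable nodes for this sample")
    return SpeciesCall(
        sample_id=sample_id,
        verdict=AMBIGUOUS,
        group=sorted(current),
        details=details,
        flags=flags,
    )


def read_tm_replicates(path) -> dict[tuple[str, str], list[float]]:
    """Replicate CSV (sample, amplicon, replicate, tm) ->
    (sample, amplicon) -> Tm list."""
    df = pd.read_csv(path)
    required = {"sample", "amplicon", "tm"}
    if not required <= set(df.columns):
        raise InputError(f"replicate CSV needs columns {sorted(required)}")
    out: dict[tuple[str, str], list[float]] = {}
    for _, row in df.iterrows():
        out.setdefault((str(row["sample"]), str(row["amplicon"])), []).append(float(row["tm"]))
    return out


def read_raw_traces(path) -> list[RawMeltTrace]:
    """Long-format trace CSV (sample, amplicon, temperature, fluorescence),
    one header line — the canonical dialect instrument exports map onto."""
    df = pd.read_csv(path)
    required = {"sample", "amplicon", "temperature", "fluorescence"}
    if not required <= set(df.columns):
        raise InputError(f"trace CSV needs columns {sorted(required)}")
    traces = []
    for (sample, amplicon), grp in df.groupby(["sample", "amplicon"], sort=False):
        grp = grp.sort_values("temperature")
        traces.append(
            RawMeltTrace(
                sample_id=str(sample),
                amplicon=str(amplicon),
                temperatures=grp["temperature"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
            )
        )
    return traces


def calls_report(calls: Sequence[SpeciesCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample_id,
                "verdict": c.verdict,
                "species": c.species or "",
                "group": ";".join(c.group),
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows)
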