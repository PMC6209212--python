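"""Release scenarios, reporting and configuration.

A :class:`ScenarioSpec` bundles everything one simulation campaign needs:
the spatial domain and mesh, piecewise-constant initial densities per
genotype, vital-rate parameters, the inheritance mode (Mendelian or
gene-drive conversion with efficiency ``f``), the uniform diffusion law and
the Monte Carlo sample count.  Seven built-in scenarios cover a
laboratory-analogue equal release and three field release strategies (same
strip, concentrated core, and wider strip), each in a Mendelian and a
drive variant.

Reports integrate the per-genotype fields over the domain with the
composite trapezoidal rule and derive genotype percentages and the
transgene allele frequency ``q``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .diffusion_fem import Mesh, SpatialField, build_three_block_mesh
from .genetics import GenotypeFrequencies, allele_frequency, frequencies_for
from .reaction import ModelParameters
from .splitting import TimeGrid
from .uncertainty import DiffusionLaw, EnsembleResult

__all__ = [
    "MeshSpec",
    "Segment",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "builtin_scenario",
    "integrated_totals",
    "summary_report",
    "Dispersal",
    "dispersal_to_kappa",
    "save_scenario",
    "load_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
]


@dataclass(frozen=True)
class MeshSpec:
    """Mesh layout: block edges (km) and uniform vertex count per block."""

    order: str = "linear"
    nodes_per_block: tuple[int, ...] = (20, 40, 20)
    block_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)

    def build(self) -> Mesh:
        return build_three_block_mesh(
            order=self.order,
            nodes_per_block=tuple(self.nodes_per_block),
            block_edges=tuple(self.block_edges),
        )


class Segment(NamedTuple):
    """A constant-density release segment ``[x_start, x_end]`` (km)."""

    x_start: float
    x_end: float
    density: float  # individuals per km


@dataclass(frozen=True)
class ScenarioSpec:
    """Full specification of one simulation campaign."""

    name: str
    segments: tuple[tuple[Segment, ...], ...]  # per genotype (wild, het, hom)
    inheritance: str = "mendelian"
    f: float = 0.0
    L: float = 30.0
    time_grid: TimeGrid = field(default_factory=TimeGrid)
    params: ModelParameters = field(default_factory=ModelParameters)
    diffusion: DiffusionLaw = field(default_factory=DiffusionLaw)
    mesh: MeshSpec = field(default_factory=MeshSpec)
    N_s: int = 150

    def __post_init__(self) -> None:
        if len(self.segments) != 3:
            raise ValueError("segments must list the three genotypes")
        segs = tuple(
            tuple(Segment(*s) for s in genotype) for genotype in self.segments
        )
        for genotype in segs:
            for s in genotype:
                if not (0 <= s.x_start <= s.x_end <= self.L):
                    raise ValueError(f"segment {s} outside [0, {self.L}]")
                if s.density < 0:
                    raise ValueError("densities must be nonnegative")
        object.__setattr__(self, "segments", segs)
        if self.inheritance == "mendelian" and self.f != 0.0:
            raise ValueError("Mendelian inheritance requires f = 0")
        if abs(self.mesh.block_edges[-1] - self.L) > 1e-12:
            raise ValueError("mesh must span the scenario domain")

    # -- model building -------------------------------------------------

    def build_mesh(self) -> Mesh:
        return self.mesh.build()

    def frequencies(self) -> GenotypeFrequencies:
        return frequencies_for(self.inheritance, self.f)

    def initial_field(self, mesh: Mesh, tol: float = 1e-9) -> SpatialField:
        """Nodal interpolation of the piecewise-constant initial densities.

        Segments are closed intervals: a node lying exactly on a segment
        boundary receives the inside value.
        """
        values = np.zeros((3, mesh.n_nodes))
        for g, genotype in enumerate(self.segments):
            for s in genotype:
                inside = (mesh.nodes >= s.x_start - tol) & (mesh.nodes <= s.x_end + tol)
                values[g, inside] += s.density
        return SpatialField(mesh, values)

    def nominal_release_totals(self) -> np.ndarray:
        """Stated release counts: density times segment length, per genotype."""
        return np.array(
            [
                sum(s.density * (s.x_end - s.x_start) for s in genotype)
                for genotype in self.segments
            ]
        )

    def with_(self, **overrides) -> "ScenarioSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


def _strip(density: float, x0: float = 13.0, x1: float = 17.0) -> tuple[Segment, ...]:
    return (Segment(x0, x1, density),)


_REGISTRY: dict[str, dict] = {
    # laboratory-analogue equal release, 1000 wild + 1000 het over 4 km
    "baseline": dict(
        segments=(_strip(250.0), _strip(250.0), ()), inheritance="mendelian", f=0.0
    ),
    # 2000 wild + 1000 het on the same 4 km strip
    "exp1_mendelian": dict(
        segments=(_strip(500.0), _strip(250.0), ()), inheritance="mendelian", f=0.0
    ),
    # 2000 wild + 860 het + 140 hom on the same strip (drive split of 1000)
    "exp1_mcr": dict(
        segments=(_strip(500.0), _strip(215.0), _strip(35.0)),
        inheritance="mcr",
        f=0.14,
    ),
    # 1000 het concentrated on the central 1 km
    "exp2_mendelian": dict(
        segments=(_strip(500.0), _strip(1000.0, 14.5, 15.5), ()),
        inheritance="mendelian",
        f=0.0,
    ),
    "exp2_mcr": dict(
        segments=(
            _strip(500.0),
            _strip(860.0, 14.5, 15.5),
            _strip(140.0, 14.5, 15.5),
        ),
        inheritance="mcr",
        f=0.14,
    ),
    # 1000 het spread over the wider 6 km strip
    "exp3_mendelian": dict(
        segments=(_strip(500.0), _strip(166.67, 12.0, 18.0), ()),
        inheritance="mendelian",
        f=0.0,
    ),
    "exp3_mcr": dict(
        segments=(
            _strip(500.0),
            _strip(143.33, 12.0, 18.0),
            _strip(23.33, 12.0, 18.0),
        ),
        inheritance="mcr",
        f=0.14,
    ),
}

SCENARIO_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def builtin_scenario(name: str, **overrides) -> ScenarioSpec:
    """Build one of the named release scenarios with default settings.

    Keyword overrides replace top-level :class:`ScenarioSpec` fields, e.g.
    ``builtin_scenario("baseline", N_s=20)``.
    """
    try:
        spec = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        ) from None
    return ScenarioSpec(name=name, **spec).with_(**overrides) if overrides else ScenarioSpec(name=name, **spec)


# -- reporting -----------------------------------------------------------


def integrated_totals(field_or_values, mesh: Mesh | None = None) -> pd.Series:
    """Trapezoidal totals, percentages and allele frequency of a field.

    Accepts a :class:`SpatialField` or a ``(3, n_nodes)`` array plus mesh.
    """
    if isinstance(field_or_values, SpatialField):
        values, mesh = field_or_values.values, field_or_values.mesh
    else:
        if mesh is None:
            raise ValueError("mesh required when passing a bare array")
        values = np.asarray(field_or_values, dtype=float)
    totals = np.trapezoid(values, mesh.nodes, axis=1)
    state = allele_frequency(*totals)
    grand = totals.sum()
    return pd.Series(
        {
            "wild": totals[0],
            "heterozygous": totals[1],
            "homozygous": totals[2],
            "total": grand,
            "pct_wild": 100.0 * totals[0] / grand,
            "pct_heterozygous": 100.0 * totals[1] / grand,
            "pct_homozygous": 100.0 * totals[2] / grand,
            "q": state.q,
        }
    )


def summary_report(result: EnsembleResult) -> pd.DataFrame:
    """Per-output-time totals of the ensemble-mean fields.

    One row per output time with trapezoidal totals per genotype, the
    grand total, genotype percentages and the transgene frequency ``q``.
    """
    rows = []
    for i, t in enumerate(result.times):
        row = integrated_totals(result.mean[i], result.mesh)
        row["time"] = t
        rows.append(row)
    report = pd.DataFrame(rows).set_index("time")
    return report


def rounded_report(report: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: percentages to 2 decimals, q to 3 decimals."""
    out = report.copy()
    for col in ("wild", "heterozygous", "homozygous", "total"):
        out[col] = out[col].round(2)
    for col in ("pct_wild", "pct_heterozygous", "pct_homozygous"):
        out[col] = out[col].round(2)
    out["q"] = out["q"].round(3)
    return out


# -- parameter provenance ------------------------------------------------


class Dispersal(NamedTuple):
    dispersal_m: float  # per-period displacement in metres
    kappa: float  # km^2 per week


def dispersal_to_kappa(
    intercept: float = 58.741,
    slope: float = 23.731,
    days: float = 7.0,
    dimensionality_constant: int = 2,
) -> Dispersal:
    """Diffusion coefficient from a linear dispersal-vs-time regression.

    The regression ``y = intercept + slope * x`` gives the displacement in
    metres after ``x`` days; treating that displacement as the root mean
    square displacement over one week, ``kappa = <x^2> / (q_i t)`` with
    ``q_i = 2, 4, 6`` for 1, 2, 3 dimensions and ``t`` = 1 week.
    """
    if dimensionality_constant not in (2, 4, 6):
        raise ValueError("dimensionality constant must be 2, 4 or 6")
    d_m = intercept + slope * days
    kappa = (d_m / 1000.0) ** 2 / dimensionality_constant
    return Dispersal(dispersal_m=d_m, kappa=kappa)


# -- configuration round-trip -------------------------------------------


def scenario_to_dict(s: ScenarioSpec) -> dict:
    """Plain-dict form of a scenario (for YAML serialization)."""
    return {
        "name": s.name,
        "L": s.L,
        "inheritance": s.inheritance,
        "f": s.f,
        "N_s": s.N_s,
        "segments": {
            g: [list(seg) for seg in genotype]
            for g, genotype in zip(("wild", "heterozygous", "homozygous"), s.segments)
        },
        "time_grid": {
            "T": s.time_grid.T,
            "dt": s.time_grid.dt,
            "output_times": list(s.time_grid.output_times),
        },
        "params": {
            "epsilon": s.params.epsilon,
            "delta1": s.params.delta1,
            "delta2": s.params.delta2,
            "C": s.params.C,
        },
        "diffusion": {
            "s_i": s.diffusion.s_i,
            "s_f": s.diffusion.s_f,
            "coupling": s.diffusion.coupling,
            "seed": s.diffusion.seed,
        },
        "mesh": {
            "order": s.mesh.order,
            "nodes_per_block": list(s.mesh.nodes_per_block),
            "block_edges": list(s.mesh.block_edges),
        },
    }


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section}: {sorted(unknown)}")


def scenario_from_dict(d: dict) -> ScenarioSpec:
    """Inverse of :func:`scenario_to_dict`; unknown keys are errors."""
    _check_keys(
        "scenario",
        d,
        {"name", "L", "inheritance", "f", "N_s", "segments", "time_grid", "params", "diffusion", "mesh"},
    )
    seg_in = d.get("segments", {})
    _check_keys("segments", seg_in, {"wild", "heterozygous", "homozygous"})
    segments = tuple(
        tuple(Segment(*seg) for seg in seg_in.get(g, []))
        for g in ("wild", "heterozygous", "homozygous")
    )
    tg = d.get("time_grid", {})
    _check_keys("time_grid", tg, {"T", "dt", "output_times"})
    pr = d.get("params", {})
    _check_keys("params", pr, {"epsilon", "delta1", "delta2", "C"})
    df = d.get("diffusion", {})
    _check_keys("diffusion", df, {"s_i", "s_f", "coupling", "seed"})
    ms = d.get("mesh", {})
    _check_keys("mesh", ms, {"order", "nodes_per_block", "block_edges"})
    kwargs: dict = dict(name=d["name"], segments=segments)
    for key in ("L", "inheritance", "f", "N_s"):
        if key in d:
            kwargs[key] = d[key]
    if tg:
        tg = dict(tg)
        if "output_times" in tg:
            tg["output_times"] = tuple(tg["output_times"])
        kwargs["time_grid"] = TimeGrid(**tg)
    if pr:
        kwargs["params"] = ModelParameters(**pr)
    if df:
        kwargs["diffusion"] = DiffusionLaw(**df)
    if ms:
        ms = dict(ms)
        for key in ("nodes_per_block", "block_edges"):
            if key in ms:
                ms[key] = tuple(ms[key])
        kwargs["mesh"] = MeshSpec(**ms)
    return ScenarioSpec(**kwargs)


def save_scenario(s: ScenarioSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


def load_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
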