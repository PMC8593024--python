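"""Orchestration of the three computational studies, with statistics.

1. Connector-geometry sweep: mean flow-Hoover coefficient and maximum
   scaffold shear across connector shapes, lengths and diameters.
2. Seeding-efficiency sweep: particle-simulation efficiency across cell
   concentrations and perfusion rates, with Pearson correlations.
3. Configuration comparison: six reactor configurations scored by 60-min
   enrichment (synthesized activity) and axial distribution Hoover.

The module also hosts the frozen printed-value fixtures of the reference
study (connector-table Hoover coefficients, shear maxima, reported
efficiencies and correlations) used for worked-example arithmetic, and
small statistics helpers.  Note the reference report labels *signed
Pearson r* as "R^2"; this package reports r and r^2 separately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import flow as fl
from . import geometry as geo
from .hoover import axial_distribution_hoover, default_planes, flow_homogeneity
from .scaffold import generate_scaffold
from .seeding import (CellSuspension, DepositionParams, PerfusionProtocol,
                      oscillating_once, simulate_seeding)

# ---------------------------------------------------------------------------
# printed-value fixtures (digit-for-digit transcription of the reference
# study's tables/text; used as inputs to worked-example arithmetic)
# ---------------------------------------------------------------------------

#: mean flow-Hoover coefficient by connector length, cylindrical (D = 10 mm)
#: and conical (base D = 10 mm) nozzles
TABLE1_MEAN_HOOVER = MappingProxyType({
    ("cylindrical", 1): 0.6073, ("conical", 1): 0.5571,
    ("cylindrical", 2): 0.5208, ("conical", 2): 0.4915,
    ("cylindrical", 3): 0.4911, ("conical", 3): 0.4542,
    ("cylindrical", 4): 0.4665, ("conical", 4): 0.4075,
    ("cylindrical", 5): 0.4594, ("conical", 5): 0.4238,
    ("cylindrical", 10): 0.4441, ("conical", 10): 0.4301,
})

#: diameter study, cylindrical nozzles at L = 10 mm
DIAMETER_STUDY_MEAN_HOOVER = MappingProxyType({1.0: 0.6205, 10.0: 0.4441})

#: maximum shear rate (1/s) in the scaffold for the same two diameters
DIAMETER_STUDY_MAX_SHEAR = MappingProxyType({1.0: 49.0, 10.0: 18.0})

#: reported operating points and correlations of the seeding experiments
REFERENCE_EFFICIENCIES = MappingProxyType({
    "optimum": 0.80,            # at <= 0.4e6 cells/ml, 0.5 ml/min
    "rate_low": 0.90,           # below 0.5 ml/min
    "rate_high": 0.05,          # at 2 ml/min
})
REFERENCE_CORRELATIONS = MappingProxyType({
    "concentration": -0.7726,   # printed as "R^2"; signed Pearson r
    "rate": -0.9018,
})

#: experimental 60-min readouts (context only, not reproduction targets)
REFERENCE_PET = MappingProxyType({
    "type1_enc+_MBq": 0.80, "type2_enc+_MBq": 1.05,
    "oscillating_hoover": 0.24,
})


@dataclass(frozen=True)
class ReferenceFixtures:
    table1: MappingProxyType = field(
        default_factory=lambda: TABLE1_MEAN_HOOVER)
    diameter_study: MappingProxyType = field(
        default_factory=lambda: DIAMETER_STUDY_MEAN_HOOVER)
    shear_study: MappingProxyType = field(
        default_factory=lambda: DIAMETER_STUDY_MAX_SHEAR)
    reference_efficiencies: MappingProxyType = field(
        default_factory=lambda: REFERENCE_EFFICIENCIES)
    correlations: MappingProxyType = field(
        default_factory=lambda: REFERENCE_CORRELATIONS)


# ---------------------------------------------------------------------------
# small statistics helpers
# ---------------------------------------------------------------------------

def percent_change(reference: float, value: float) -> float:
    """Percent reduction from ``reference`` to ``value`` (positive = drop)."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (reference - value) / reference


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("pearson_r needs >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def welch_t(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class SweepReport:
    df: pd.DataFrame
    rankings: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# desk-scale study rigs
# ---------------------------------------------------------------------------

#: desk-scale defaults: coarse surrogate grid for the homogenized solver.
#: The generator's correlation length must resolve on the coarse grid, so
#: the surrogate is generated at 2 mm texture; the Brinkman permeability
#: always uses the true macro-pore scale of the block (0.107 mm is below
#: the continuum grid, the 0.5 mm generator default is the modeled value).
COARSE_VOXEL_MM = 1.0
COARSE_TEXTURE_MM = 2.0
TRUE_PORE_SCALE_MM = 0.5
COARSE_GAP_MM = 1.0


def coarse_scaffold(seed: int):
    return generate_scaffold(voxel_mm=COARSE_VOXEL_MM,
                             pore_scale_mm=COARSE_TEXTURE_MM, seed=seed)


def build_preset_domain(type_label: str, encasement: bool, seed: int,
                        voxel_mm: float = COARSE_VOXEL_MM):
    s = coarse_scaffold(seed) if voxel_mm == COARSE_VOXEL_MM else \
        generate_scaffold(voxel_mm=voxel_mm, seed=seed)
    gap = None if encasement else max(geo.DEFAULT_GAP_MM, voxel_mm)
    cfg = geo.preset(type_label, encasement=encasement, gap_mm=gap)
    return geo.build_domain(s, cfg)


def _sweep_domain(scaffold, shape: str, length_mm: float, diameter_mm: float):
    if shape == geo.CYLINDRICAL:
        conn = geo.ConnectorSpec(geo.CYLINDRICAL, diameter_mm, length_mm)
    else:
        # diffuser: throat = tubing bore, base covering the full face
        conn = geo.ConnectorSpec(geo.CONICAL, 1.6, length_mm, width_mm=15.0)
    cfg = geo.ReactorConfig(chamber_mm=(10.0, 10.0, 20.0), inlet=conn,
                            outlet=conn, encasement=True)
    return geo.build_domain(scaffold, cfg)


def connector_sweep(scaffold_seeds=(1, 2, 3, 4, 5),
                    shapes=(geo.CYLINDRICAL, geo.CONICAL),
                    lengths=(1, 2, 3, 4, 5, 10),
                    diameters=(10.0,),
                    rate_ml_min: float = 1.0) -> SweepReport:
    """Mean flow-Hoover and max scaffold shear per connector configuration.

    Conditions mirror the reference flow study: 1 ml/min, homogenized
    scaffold at the block porosity, 24 evaluation planes at 1 mm.
    Cylindrical nozzles are swept over ``diameters``; conical diffusers
    expand from the tubing throat to the full face.
    """
    rows = []
    for seed in scaffold_seeds:
        s = coarse_scaffold(seed)
        for shape in shapes:
            for L in lengths:
                dias = diameters if shape == geo.CYLINDRICAL else (10.0,)
                for D in dias:
                    try:
                        dom = _sweep_domain(s, shape, float(L), float(D))
                        ff = fl.solve_flow(dom, inlet_flow_ml_min=rate_ml_min,
                                           mode=fl.HOMOGENIZED,
                                           pore_scale_mm=TRUE_PORE_SCALE_MM)
                        hbar = flow_homogeneity(ff).mean
                        shear = fl.max_shear_in_scaffold(ff)
                        err = ""
                    except Exception as exc:  # propagate per cell
                        hbar, shear, err = np.nan, np.nan, str(exc)
                    rows.append(dict(seed=seed, shape=shape, length_mm=L,
                                     diameter_mm=D, mean_hoover=hbar,
                                     max_shear_s1=shear, error=err,
                                     config_hash=_config_hash(
                                         [shape, L, D, seed, rate_ml_min])))
    df = pd.DataFrame(rows)
    agg = (df.groupby(["shape", "length_mm", "diameter_mm"])
             [["mean_hoover", "max_shear_s1"]]
             .agg(["mean", "std"]))
    ranking = (df.groupby(["shape", "length_mm", "diameter_mm"])
                 ["mean_hoover"].mean().sort_values())
    return SweepReport(df=df, rankings={"by_mean_hoover": ranking},
                       stats={"aggregate": agg},
                       meta={"seeds": list(scaffold_seeds),
                             "rate_ml_min": rate_ml_min})


def _seeding_rig(seed: int = 1, encasement: bool = True,
                 type_label: str = "type2"):
    """Domain + forward flows reused across seeding conditions."""
    dom = build_preset_domain(type_label, encasement, seed)
    return dom


def efficiency_sweep(concentrations=None, rates=None,
                     params: DepositionParams | None = None,
                     seeds=(0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
                     scaffold_seed: int = 1,
                     n_particles: int = 3000) -> SweepReport:
    """Seeding efficiency vs cell concentration and vs perfusion rate.

    The concentration sweep runs at 0.5 ml/min; the rate sweep at
    0.4e6 cells/ml — the reference operating protocol.  Pearson r of
    efficiency against the swept variable is reported per sweep.
    """
    params = params or DepositionParams()
    concentrations = ([0.06e6, 0.4e6, 0.8e6, 1.22e6]
                      if concentrations is None else list(concentrations))
    rates = [0.25, 0.5, 1.0, 2.0] if rates is None else list(rates)
    if not concentrations and not rates:
        raise ValueError("empty sweep grid")
    dom = _seeding_rig(scaffold_seed)
    flows = {}

    def flow_at(rate):
        if rate not in flows:
            flows[rate] = fl.solve_flow(dom, inlet_flow_ml_min=rate,
                                        mode=fl.HOMOGENIZED,
                                        pore_scale_mm=TRUE_PORE_SCALE_MM)
        return flows[rate]

    rows = []
    for conc in concentrations:
        for seed in seeds:
            res = simulate_seeding(
                flow_at(0.5), None, dom, PerfusionProtocol(rate_ml_min=0.5),
                CellSuspension(concentration_cells_ml=conc), params,
                seed=seed, n_particles=n_particles,
                pore_scale_mm=TRUE_PORE_SCALE_MM)
            rows.append(dict(sweep="concentration", value=conc, seed=seed,
                             efficiency=res.efficiency))
    for rate in rates:
        for seed in seeds:
            res = simulate_seeding(
                flow_at(rate), None, dom, PerfusionProtocol(rate_ml_min=rate),
                CellSuspension(concentration_cells_ml=0.4e6), params,
                seed=seed, n_particles=n_particles,
                pore_scale_mm=TRUE_PORE_SCALE_MM)
            rows.append(dict(sweep="rate", value=rate, seed=seed,
                             efficiency=res.efficiency))
    df = pd.DataFrame(rows)
    stats_d = {}
    for name in ("concentration", "rate"):
        sub = df[df.sweep == name]
        if len(sub["value"].unique()) >= 3:
            if sub["efficiency"].std() == 0:
                stats_d[f"pearson_r_{name}"] = float("nan")  # degenerate
            else:
                stats_d[f"pearson_r_{name}"] = pearson_r(
                    sub["value"], sub["efficiency"])
    return SweepReport(
        df=df, stats=stats_d,
        rankings={"median_by_condition":
                  df.groupby(["sweep", "value"])["efficiency"].median()},
        meta={"seeds": list(seeds), "params": params})


DEFAULT_CONFIGS = ("type1_enc-", "type2_enc-", "type1_enc+", "type2_enc+",
                   "type3_enc+", "type2_enc+_osc")


def configuration_comparison(configs=DEFAULT_CONFIGS,
                             seeds=(0, 1, 2, 3, 4),
                             params: DepositionParams | None = None,
                             scaffold_seed: int = 1,
                             n_particles: int = 3000) -> SweepReport:
    """Compare reactor configurations on enrichment and axial homogeneity.

    Each configuration is run at the imaging protocol (0.4e6 cells/ml,
    0.5 ml/min, 60 min seeding + 40 min washout; the oscillating variant
    reverses once at 30 min); reported per run are the 60-min whole-block
    enrichment (simulated label activity, MBq) and the 60-min axial Hoover
    coefficient, with Welch t-tests between configurations.
    """
    from .pet import enrichment_and_hoover_timecourse, synthesize_pet

    params = params or DepositionParams()
    rows = []
    for name in configs:
        base = name.replace("_osc", "")
        type_label, enc = base.split("_enc")
        encasement = enc == "+"
        osc = name.endswith("_osc")
        dom = build_preset_domain(type_label, encasement, scaffold_seed)
        ff = fl.solve_flow(dom, inlet_flow_ml_min=0.5, mode=fl.HOMOGENIZED,
                           pore_scale_mm=TRUE_PORE_SCALE_MM)
        prot = (oscillating_once(30.0, rate_ml_min=0.5) if osc
                else PerfusionProtocol(rate_ml_min=0.5))
        planes = default_planes(dom)
        for seed in seeds:
            try:
                res = simulate_seeding(ff, None, dom, prot, CellSuspension(),
                                       params, seed=seed,
                                       n_particles=n_particles,
                                       pore_scale_mm=TRUE_PORE_SCALE_MM)
                series = synthesize_pet(res, dom, noise="none", seed=seed)
                tc = enrichment_and_hoover_timecourse(series, dom, planes)
                k60 = np.argmin(np.abs(tc.index.to_numpy() - 60.0))
                rows.append(dict(
                    config=name, seed=seed,
                    efficiency=res.efficiency,
                    enrichment_MBq=float(tc["activity_MBq"].iloc[k60]),
                    hoover_60min=float(tc["axial_hoover"].iloc[k60]),
                    error=""))
            except Exception as exc:
                rows.append(dict(config=name, seed=seed, efficiency=np.nan,
                                 enrichment_MBq=np.nan, hoover_60min=np.nan,
                                 error=str(exc)))
    df = pd.DataFrame(rows)
    means = df.groupby("config")[["enrichment_MBq", "hoover_60min",
                                  "efficiency"]].mean()
    tests = {}
    ok = df[df.error == ""]
    for a in configs:
        for b in configs:
            if a < b:
                ga = ok[ok.config == a]["hoover_60min"]
                gb = ok[ok.config == b]["hoover_60min"]
                if len(ga) >= 2 and len(gb) >= 2:
                    tests[(a, b)] = welch_t(ga, gb)
    return SweepReport(
        df=df,
        rankings={"by_hoover": means["hoover_60min"].sort_values(),
                  "by_enrichment":
                  means["enrichment_MBq"].sort_values(ascending=False)},
        stats={"welch_hoover": tests},
        meta={"seeds": list(seeds), "configs": list(configs)})
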