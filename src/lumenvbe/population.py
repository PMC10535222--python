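"""Virtual populations: healthy volunteers and Crohn's disease patients.

Provides between-subject sampling (lognormal CVs with physiological
truncation), per-occasion within-subject variability (WSV) for the fluid
residence times, and a one-at-a-time local sensitivity analysis around the
representative subject.

The Crohn's-disease population differs from healthy volunteers in four
parameters: hepatic CYP3A4 abundance, small-intestinal and colonic CYP3A4
totals, and serum albumin.  Lower albumin raises the unbound fraction (the
binding model in :mod:`lumenvbe.pbpk_core` rescales fu from HSA), and lower
CYP3A4 reduces both gut-wall and hepatic first-pass extraction, so the CD
representative shows higher systemic exposure for the same dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pbpk_core
from .pbpk_core import SubjectPhysiology, default_subject

__all__ = [
    "PopulationSpec",
    "WsvRow",
    "WsvSpec",
    "default_healthy_population",
    "crohns_population",
    "default_wsv",
    "sample_subjects",
    "apply_wsv",
    "local_sensitivity_analysis",
    "cohort_table",
]

#: Between-subject CVs (%) by parameter.  Not reported for the source
#: populations; package defaults are 30% on enzyme abundances, 20% on
#: residence times and filtration, 15% on albumin and body weight.
DEFAULT_BSV: dict[str, float] = {
    "gastric_pellet_mrt": 20.0,
    "si_pellet_mrt": 20.0,
    "gastric_fluid_mrt": 20.0,
    "si_fluid_mrt": 20.0,
    "colon_fluid_mrt_whole": 20.0,
    "colon_fluid_mrt_ascending": 20.0,
    "gfr": 20.0,
    "liver_cyp3a4": 30.0,
    "si_cyp3a4_total": 30.0,
    "colon_cyp3a4_total": 30.0,
    "hsa": 15.0,
    "body_weight": 15.0,
}

#: Physiological truncation bounds for sampled parameters.  Fluid-MRT bounds
#: reuse the occasion-variability limits; the rest are wide guards.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gastric_pellet_mrt": (0.1, 6.0),
    "si_pellet_mrt": (0.5, 12.0),
    "gastric_fluid_mrt": (0.01, 12.0),
    "si_fluid_mrt": (0.5, 12.0),
    "colon_fluid_mrt_whole": (0.1, 240.0),
    "colon_fluid_mrt_ascending": (0.1, 72.0),
    "gfr": (40.0, 300.0),
    "liver_cyp3a4": (10.0, 400.0),
    "si_cyp3a4_total": (1.0, 200.0),
    "colon_cyp3a4_total": (0.02, 10.0),
    "hsa": (15.0, 60.0),
    "body_weight": (40.0, 130.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Means (sex-specific representatives), BSV CVs and truncation bounds."""

    label: str
    male: SubjectPhysiology
    female: SubjectPhysiology
    bsv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BSV))
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    proportion_female: float = 0.5
    age_range: tuple[float, float] = (20.0, 50.0)

    def representative(self, sex: str = "M") -> SubjectPhysiology:
        return self.male if sex == "M" else self.female

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion_female <= 1.0):
            raise ValueError("proportion_female must be in [0, 1]")
        if any(cv < 0 for cv in self.bsv.values()):
            raise ValueError("BSV CVs must be non-negative")


def default_healthy_population() -> PopulationSpec:
    """Healthy-volunteer population (pure; repeated calls are identical)."""
    return PopulationSpec(label="HV", male=default_subject("M"), female=default_subject("F"))


def crohns_population() -> PopulationSpec:
    """Crohn's-disease population: the healthy spec with four overrides.

    Hepatic CYP3A4 55.4 (M) / 80.5 (F) pmol/mg, SI CYP3A4 8.6 nmol, colonic
    CYP3A4 0.2 nmol, HSA 30.13 (M) / 25.2 (F) g/L.  Everything else equals
    the healthy-volunteer spec.
    """
    hv = default_healthy_population()
    male = replace(hv.male, liver_cyp3a4=55.4, si_cyp3a4_total=8.6,
                   colon_cyp3a4_total=0.2, hsa=30.13)
    female = replace(hv.female, liver_cyp3a4=80.5, si_cyp3a4_total=8.6,
                     colon_cyp3a4_total=0.2, hsa=25.2)
    return PopulationSpec(label="CD", male=male, female=female)


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Mean-one multiplicative lognormal deviate(s) at the given CV (%)."""
    if cv_pct == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p((cv_pct / 100.0) ** 2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def sample_subjects(spec: PopulationSpec, n: int, seed: int | None = None) -> list[SubjectPhysiology]:
    """Monte-Carlo cohort of ``n`` virtual subjects.

    Each parameter with a BSV entry is the sex-specific mean times a mean-one
    lognormal deviate, clamped to its bounds.  Sex assignment matches the
    female proportion exactly for even counts (random remainder otherwise);
    age is uniform over the population range.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_female = int(round(n * spec.proportion_female))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    subjects = []
    for i in range(n):
        base = spec.representative(sexes[i])
        updates: dict[str, float] = {}
        for param, cv in spec.bsv.items():
            value = getattr(base, param) * _lognormal_factor(rng, cv)
            lo, hi = spec.bounds.get(param, (0.0, np.inf))
            updates[param] = float(np.clip(value, lo, hi))
        updates["age"] = float(rng.uniform(*spec.age_range))
        subjects.append(replace(base, **updates))
    return subjects


def cohort_table(subjects: Sequence[SubjectPhysiology]) -> pd.DataFrame:
    """One row per subject with the sampled scalar parameters."""
    cols = ["sex", "age", "body_weight", *DEFAULT_BSV.keys()]
    rows = [{c: getattr(s, c) for c in dict.fromkeys(cols)} for s in subjects]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Within-subject (occasion) variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WsvRow:
    """Occasion CV (%) and truncation limits for one parameter."""

    cv: float
    min_limit: float
    max_limit: float

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.min_limit > self.max_limit:
            raise ValueError("min_limit must not exceed max_limit")


#: param name -> WsvRow
WsvSpec = Mapping[str, WsvRow]


def default_wsv() -> dict[str, WsvRow]:
    """Occasion variability of the fluid residence times.

    Fasted gastric fluid MRT CV 38.217% on [0.01, 12] h; SI fluid MRT
    21.132% on [0.5, 12] h; whole/ascending colonic fluid MRTs 44.962% on
    [0.1, 240] and [0.1, 72] h.
    """
    return {
        "gastric_fluid_mrt": WsvRow(38.217, 0.01, 12.0),
        "si_fluid_mrt": WsvRow(21.132, 0.5, 12.0),
        "colon_fluid_mrt_whole": WsvRow(44.962, 0.1, 240.0),
        "colon_fluid_mrt_ascending": WsvRow(44.962, 0.1, 72.0),
    }


def apply_wsv(
    subject: SubjectPhysiology,
    occasion: int,
    wsv: WsvSpec | None = None,
    seed: int | None = None,
) -> SubjectPhysiology:
    """Occasion-specific physiology: WSV parameters redrawn multiplicatively.

    Each listed parameter is multiplied by an independent mean-one lognormal
    deviate at its occasion CV, then clamped to its limits.  Occasions are
    independent redraws (occasion index enters the random stream), and all
    non-WSV parameters are untouched.
    """
    if occasion not in (1, 2):
        raise ValueError("occasion must be 1 or 2")
    rows = default_wsv() if wsv is None else wsv
    if isinstance(seed, np.random.SeedSequence):
        ss = np.random.SeedSequence(entropy=seed.entropy,
                                    spawn_key=(*seed.spawn_key, occasion))
    else:
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(occasion,))
    rng = np.random.default_rng(ss)
    updates = {}
    for param, row in rows.items():
        value = getattr(subject, param) * _lognormal_factor(rng, row.cv)
        updates[param] = float(np.clip(value, row.min_limit, row.max_limit))
    return replace(subject, **updates)


# ---------------------------------------------------------------------------
# Local sensitivity analysis
# ---------------------------------------------------------------------------

#: One-at-a-time sweep ranges around the representative subject, spanning the
#: healthy and Crohn's-disease extremes per parameter.
DEFAULT_LSA_RANGES: dict[str, tuple[float, float]] = {
    "gastric_fluid_mrt": (0.27, 2.5),
    "si_fluid_mrt": (3.4, 6.0),
    "liver_cyp3a4": (34.35, 137.0),
    "si_cyp3a4_total": (8.6, 65.4),
    "colon_cyp3a4_total": (0.2, 1.99),
    "hsa": (30.0, 50.0),
}


def local_sensitivity_analysis(
    base: SubjectPhysiology,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    endpoints: Sequence[str] = ("c_max", "auc_last"),
    drug=None,
    formulation=None,
    dose_mg: float = 3.0,
    n_points: int = 5,
    t_end: float = 24.0,
) -> pd.DataFrame:
    """One-at-a-time parameter sweep of plasma exposure endpoints.

    Each parameter is swept over its range (log-spaced when the range spans
    more than 3x) with everything else held at the representative values;
    endpoints are plasma C_max and AUC_last from deterministic simulations.
    Returns a tidy table with endpoint ratios relative to the base subject.
    """
    from .formulation import entocort_reference
    from .vbe import nca

    ranges = dict(DEFAULT_LSA_RANGES) if ranges is None else dict(ranges)
    for param in ranges:
        if not hasattr(base, param):
            raise ValueError(f"unknown physiology parameter: {param}")
    drug = drug if drug is not None else pbpk_core.default_drug()
    formulation = formulation if formulation is not None else entocort_reference()

    def endpoints_for(subject: SubjectPhysiology) -> dict[str, float]:
        model = pbpk_core.build_subject_model(drug, subject, formulation, dose_mg)
        res = pbpk_core.simulate_dose(model, t_end=t_end)
        m = nca(res.times, res.plasma_conc)
        return {"c_max": m.c_max, "auc_last": m.auc_last}

    base_vals = endpoints_for(base)
    rows = []
    for param, (lo, hi) in ranges.items():
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid range for {param}: ({lo}, {hi})")
        grid = (np.geomspace(lo, hi, n_points) if hi / lo > 3.0
                else np.linspace(lo, hi, n_points))
        for value in grid:
            vals = endpoints_for(replace(base, **{param: float(value)}))
            row = {"parameter": param, "value": float(value)}
            for ep in endpoints:
                row[ep] = vals[ep]
                row[f"{ep}_ratio"] = vals[ep] / base_vals[ep]
            rows.append(row)
    return pd.DataFrame(rows)
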