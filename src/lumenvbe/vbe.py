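"""Virtual bioequivalence trials: 2x2 crossover design, NCA, BE statistics.

A virtual BE trial samples a cohort, randomises it 50/50 to the TR / RT
sequences, draws occasion (period) physiology, simulates the administered
formulation per subject-period, and computes noncompartmental metrics
(AUC_last, C_max) in plasma and in the lumen and enterocyte layers of all
eight gut segments — 17 analysis sites per metric.

The BE analysis is the standard crossover contrast on log-transformed
metrics.  For balanced complete 2x2 data the linear mixed-effect model with
sequence/period/treatment fixed effects and subject-within-sequence random
effect reduces to a closed form: the treatment effect is half the difference
of the mean within-subject period differences between sequences, with a
t-based 90% CI on n1 + n2 - 2 degrees of freedom.  Bioequivalence requires
the 90% CI of the geometric mean ratio to lie within [0.80, 1.25]; a
formulation passes overall when at least 80% of trials (8 of 10 by default)
individually conclude BE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import pbpk_core
from .formulation import VirtualFormulation
from .pbpk_core import GUT_SEGMENTS, DrugParams, ModelOptions
from .population import PopulationSpec, WsvSpec, apply_wsv, default_wsv, sample_subjects

__all__ = [
    "TrialDesign",
    "PKMetrics",
    "BEOutcome",
    "TrialDecision",
    "nca",
    "run_vbe",
    "crossover_be",
    "be_analysis",
    "multi_trial_decision",
    "decision_table",
    "DEFAULT_PLASMA_GRID",
    "BE_LIMITS",
]

BE_LIMITS = (0.80, 1.25)

#: Plasma sampling times (h) of the virtual trial.  Gut sites are modelling
#: constructs, not assayed samples, and use the dense solver grid.
DEFAULT_PLASMA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0)


@dataclass(frozen=True)
class TrialDesign:
    """Replicated two-sequence, two-period crossover design."""

    n_trials: int = 10
    n_subjects_per_trial: int = 12
    seed: int = 0
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if self.n_subjects_per_trial % 2:
            raise ValueError("n_subjects_per_trial must be even for sequence balance")
        if self.n_trials < 1 or self.n_subjects_per_trial < 4:
            raise ValueError("need >= 1 trial and >= 4 subjects")


@dataclass(frozen=True)
class PKMetrics:
    """Noncompartmental metrics of one concentration-time course."""

    auc_last: float
    c_max: float
    t_max: float
    site: str = ""
    layer: str = ""
    all_zero: bool = False


def nca(times: Sequence[float], conc: Sequence[float]) -> PKMetrics:
    """AUC_last (linear trapezoid to the last positive sample), C_max, t_max.

    t_max is the earliest time attaining the maximum.  An all-zero profile
    returns zero metrics with ``all_zero=True``.
    """
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.any(c > 0.0):
        return PKMetrics(0.0, 0.0, 0.0, all_zero=True)
    i_max = int(np.argmax(c))
    last = int(np.nonzero(c > 0.0)[0][-1])
    auc = float(np.trapezoid(c[: last + 1], t[: last + 1]))
    return PKMetrics(auc_last=auc, c_max=float(c[i_max]), t_max=float(t[i_max]))


def _site_metrics(result: pbpk_core.SimResult, plasma_grid: np.ndarray) -> list[dict]:
    rows = []
    mask = np.isin(np.round(result.times, 9), np.round(plasma_grid, 9))
    m = nca(result.times[mask], result.plasma_conc[mask])
    rows.append({"site": "plasma", "layer": "plasma",
                 "auc_last": m.auc_last, "c_max": m.c_max, "t_max": m.t_max})
    for seg in GUT_SEGMENTS:
        for layer in ("lumen", "enterocyte"):
            m = nca(result.times, result.site_concentration(seg, layer))
            rows.append({"site": seg, "layer": layer,
                         "auc_last": m.auc_last, "c_max": m.c_max, "t_max": m.t_max})
    return rows


def run_vbe(
    reference: VirtualFormulation,
    test: VirtualFormulation,
    population: PopulationSpec,
    design: TrialDesign,
    drug: DrugParams | None = None,
    dose_mg: float = 3.0,
    wsv: WsvSpec | None = None,
    options: ModelOptions | None = None,
    plasma_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate the replicated crossover trials; return the tidy PK table.

    Columns: trial, subject, sequence, period, treatment, site, layer,
    metric, value.  A fresh cohort is drawn per trial; within a trial the
    same subjects receive both formulations.  The occasion (period) WSV
    redraw is shared by whichever treatment that period carries.  Fully
    deterministic under ``design.seed``.
    """
    drug = drug if drug is not None else pbpk_core.default_drug()
    wsv = default_wsv() if wsv is None else wsv
    pgrid = np.asarray(DEFAULT_PLASMA_GRID if plasma_grid is None else plasma_grid, float)
    root = np.random.SeedSequence(design.seed)
    trial_seeds = root.spawn(design.n_trials)

    records = []
    for trial in range(design.n_trials):
        tseed = trial_seeds[trial]
        cohort_seed, occasions_seed = tseed.spawn(2)
        subjects = sample_subjects(population, design.n_subjects_per_trial, seed=cohort_seed)
        half = design.n_subjects_per_trial // 2
        sequences = ["TR"] * half + ["RT"] * half
        subj_seeds = occasions_seed.spawn(design.n_subjects_per_trial)
        for i, (subject, seq) in enumerate(zip(subjects, sequences)):
            for period in (1, 2):
                occ = apply_wsv(subject, period, wsv, seed=subj_seeds[i])
                treatment = seq[period - 1]
                formulation = test if treatment == "T" else reference
                model = pbpk_core.build_subject_model(drug, occ, formulation, dose_mg,
                                                      options=options)
                try:
                    result = pbpk_core.simulate_dose(model, t_end=design.t_end)
                except RuntimeError as err:
                    raise RuntimeError(
                        f"trial {trial + 1}, subject {i + 1}, period {period}: {err}"
                    ) from err
                for row in _site_metrics(result, pgrid):
                    base = {"trial": trial + 1, "subject": i + 1, "sequence": seq,
                            "period": period, "treatment": treatment,
                            "site": row["site"], "layer": row["layer"]}
                    for metric in ("auc_last", "c_max"):
                        records.append({**base, "metric": metric, "value": row[metric]})
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class BEOutcome:
    """Geometric mean ratio, 90% CI and BE flag for one site/metric/trial."""

    site: str
    layer: str
    metric: str
    gmr: float
    ci_low: float
    ci_high: float
    be_flag: bool
    trial: int = 0
    n_trials_be: int | None = None


def crossover_be(table: pd.DataFrame, site: str = "", layer: str = "",
                 metric: str = "", trial: int = 0) -> BEOutcome:
    """Closed-form crossover analysis of one trial's metric values.

    ``table`` holds one row per subject-period with columns subject,
    sequence, period, treatment, value.  The data must be balanced and
    complete (every subject observed once under T and once under R).
    Log-scale treatment contrast: half the between-sequence difference of
    mean within-subject period differences; 90% t-interval on n - 2 df.
    """
    required = {"subject", "sequence", "period", "treatment", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["value"] <= 0).any():
        raise ValueError("all metric values must be positive for log analysis")

    wide = table.pivot_table(index=["subject", "sequence"], columns="treatment",
                             values="value", aggfunc="first")
    if wide.isna().any().any() or set(wide.columns) != {"T", "R"} or len(wide) * 2 != len(table):
        raise ValueError("unbalanced or incomplete 2x2 data (dropouts are not modeled)")
    d = np.log(wide["T"]) - np.log(wide["R"])
    seq = wide.index.get_level_values("sequence")
    d1, d2 = d[seq == "TR"].to_numpy(), d[seq == "RT"].to_numpy()
    n1, n2 = len(d1), len(d2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both sequences must be represented")
    est = 0.5 * (d1.mean() + d2.mean())
    df = n1 + n2 - 2
    s2 = (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)) / df
    se = 0.5 * math.sqrt(s2) * math.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = stats.t.ppf(0.95, df)
    lo, hi = est - tcrit * se, est + tcrit * se
    gmr, ci_low, ci_high = math.exp(est), math.exp(lo), math.exp(hi)
    be = (ci_low >= BE_LIMITS[0]) and (ci_high <= BE_LIMITS[1])
    return BEOutcome(site=site, layer=layer, metric=metric, gmr=gmr,
                     ci_low=ci_low, ci_high=ci_high, be_flag=be, trial=trial)


def be_analysis(pk_table: pd.DataFrame) -> pd.DataFrame:
    """Crossover BE per (trial, site, layer, metric) over a full PK table."""
    rows = []
    for (trial, site, layer, metric), grp in pk_table.groupby(
        ["trial", "site", "layer", "metric"], sort=True
    ):
        out = crossover_be(grp, site=site, layer=layer, metric=metric, trial=trial)
        rows.append({"trial": trial, "site": site, "layer": layer, "metric": metric,
                     "gmr": out.gmr, "ci_low": out.ci_low, "ci_high": out.ci_high,
                     "be_flag": out.be_flag})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialDecision:
    """Formulation-level decision for one site/metric across trials."""

    site: str
    layer: str
    metric: str
    n_trials: int
    n_trials_be: int
    be: bool

    @property
    def incidence(self) -> float:
        return self.n_trials_be / self.n_trials


def multi_trial_decision(
    flags: Sequence[bool],
    site: str = "",
    layer: str = "",
    metric: str = "",
) -> TrialDecision:
    """BE across replicated trials: pass when >= 80% of trials conclude BE
    (>= 8 of 10 in the default design; ceil(0.8 n) generally)."""
    n = len(flags)
    if n == 0:
        raise ValueError("need at least one trial outcome")
    n_be = int(np.sum(flags))
    threshold = math.ceil(0.8 * n)
    return TrialDecision(site=site, layer=layer, metric=metric,
                         n_trials=n, n_trials_be=n_be, be=n_be >= threshold)


def decision_table(be_results: pd.DataFrame, combine: bool = True) -> pd.DataFrame:
    """Per-site/metric decisions from a multi-trial BE results table.

    When ``combine`` is true a 'combined' metric is added: within each trial
    a site is BE only if both AUC_last and C_max are BE, and the >= 80% rule
    is then applied to the per-trial combined flags.
    """
    work = be_results.copy()
    if combine:
        piv = work.pivot_table(index=["trial", "site", "layer"], columns="metric",
                               values="be_flag", aggfunc="first")
        comb = (piv["auc_last"] & piv["c_max"]).rename("be_flag").reset_index()
        comb["metric"] = "combined"
        comb["gmr"] = np.nan
        work = pd.concat([work, comb], ignore_index=True)
    rows = []
    for (site, layer, metric), grp in work.groupby(["site", "layer", "metric"], sort=True):
        dec = multi_trial_decision(grp["be_flag"].to_list(), site, layer, metric)
        rows.append({"site": site, "layer": layer, "metric": metric,
                     "n_trials": dec.n_trials, "n_trials_be": dec.n_trials_be,
                     "incidence": dec.incidence, "be": dec.be})
    return pd.DataFrame(rows)
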