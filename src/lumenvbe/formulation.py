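"""Dissolution profiles, Weibull release kinetics and f2 similarity.

Controlled-release multiparticulate products (the motivating case is an
enteric-coated budesonide pellet formulation) are characterised in vitro by a
cumulative percent-released curve.  This module provides the empirical Weibull
release model

    F(t) = F_max * (1 - exp(-((t - T_lag)^beta) / alpha))

the f2 similarity factor used by regulators to compare two dissolution curves,

    f2 = 50 * log10( 100 / sqrt(1 + mean_t (R_t - T_t)^2) )

a bootstrap f2 over replicate dissolution units, and the construction rules
for "virtual" test formulations derived from a reference curve by shifting the
percent released at every time point (delta mode) or by changing the enteric
trigger pH (which leaves the curve itself untouched).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DissolutionProfile",
    "WeibullParams",
    "VirtualFormulation",
    "evaluate_weibull",
    "fit_weibull",
    "make_virtual_formulation",
    "similarity_f2",
    "bootstrap_f2",
    "generate_dissolution_replicates",
    "entocort_reference",
    "reference_profile",
    "default_f2_grid",
    "virtual_library",
    "read_profile_csv",
    "write_profile_csv",
    "read_library_json",
    "write_library_json",
]

#: Default in-vitro sampling grid (h).  The completion-time convention places
#: 100% release at 12 h, so the grid runs to 12 h.
DEFAULT_F2_GRID = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)

_MONOTONE_TOL = 1e-9


def default_f2_grid() -> np.ndarray:
    """Default sampling times (h) used for f2 comparisons."""
    return np.asarray(DEFAULT_F2_GRID, dtype=float)


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the empirical Weibull cumulative-release function.

    f_max   asymptotic percent released, in (0, 100]
    alpha   scale, units h**beta
    beta    shape (dimensionless)
    t_lag   lag before any release, h
    """

    f_max: float
    alpha: float
    beta: float
    t_lag: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_max <= 100.0):
            raise ValueError(f"f_max must be in (0, 100], got {self.f_max}")
        if self.alpha <= 0.0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta <= 0.0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.t_lag < 0.0:
            raise ValueError(f"t_lag must be non-negative, got {self.t_lag}")


@dataclass(frozen=True)
class DissolutionProfile:
    """A sampled cumulative-release curve: percent of dose vs time."""

    times: np.ndarray
    released: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        released = np.asarray(self.released, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "released", released)
        if times.ndim != 1 or released.shape != times.shape:
            raise ValueError("times and released must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("profile must contain at least one sample")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(released < -_MONOTONE_TOL) or np.any(released > 100.0 + _MONOTONE_TOL):
            raise ValueError("released values must lie in [0, 100]")
        if np.any(np.diff(released) < -_MONOTONE_TOL):
            raise ValueError("released values must be non-decreasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class VirtualFormulation:
    """A formulation defined by its Weibull release curve and trigger pH.

    ``provenance`` records how the formulation was derived from the reference
    (e.g. ``"delta:+10"`` or ``"trigger_ph:6.0"``); ``f2_vs_reference`` is an
    input attribute (carried, not recomputed) when supplied.
    """

    label: str
    weibull: WeibullParams
    trigger_ph: float
    provenance: str = "reference"
    f2_vs_reference: float | None = None

    def __post_init__(self) -> None:
        if not (1.0 <= self.trigger_ph <= 9.0):
            raise ValueError(f"trigger_ph must be in [1, 9], got {self.trigger_ph}")

    def profile(self, grid: Sequence[float] | None = None) -> DissolutionProfile:
        """Sample the Weibull curve on ``grid`` (default f2 grid)."""
        t = default_f2_grid() if grid is None else np.asarray(grid, dtype=float)
        return DissolutionProfile(t, evaluate_weibull(self.weibull, t), label=self.label)


def evaluate_weibull(params: WeibullParams, t) -> np.ndarray | float:
    """Percent released at time(s) ``t`` (h) under the Weibull model.

    Returns 0 for t <= t_lag and approaches ``f_max`` as t grows.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    dt = np.maximum(t_arr - params.t_lag, 0.0)
    with np.errstate(divide="ignore"):
        out = params.f_max * -np.expm1(-(dt ** params.beta) / params.alpha)
    return out if np.ndim(t) else float(out)


def fit_weibull(
    profile: DissolutionProfile,
    fix_fmax: float | None = None,
    fit_lag: bool = False,
) -> tuple[WeibullParams, float]:
    """Least-squares fit of the Weibull model to a sampled profile.

    Returns ``(params, rss)``.  ``fix_fmax`` pins the asymptote (commonly 100
    when the completion-time convention has been applied).  Raises if the
    profile carries no release or the optimiser fails to converge.
    """
    t = profile.times
    y = profile.released
    if len(profile) < 4:
        raise ValueError("need at least 4 sampled points to fit")
    if np.all(y <= _MONOTONE_TOL):
        raise ValueError("profile shows no release; nothing to fit")

    fmax0 = float(fix_fmax) if fix_fmax is not None else min(100.0, max(y.max() * 1.02, 1e-3))
    # linearised start: log(-log(1 - F/fmax)) = beta*log(t) - log(alpha)
    frac = np.clip(y / fmax0, 1e-9, 1.0 - 1e-9)
    mask = (t > 0) & (y > 0) & (y < fmax0)
    if mask.sum() >= 2:
        lx = np.log(t[mask])
        ly = np.log(-np.log(1.0 - frac[mask]))
        beta0, neg_log_alpha = np.polyfit(lx, ly, 1)
        beta0 = float(np.clip(beta0, 0.05, 8.0))
        alpha0 = float(np.clip(np.exp(-neg_log_alpha), 1e-4, 1e4))
    else:
        beta0, alpha0 = 1.0, max(float(np.median(t)), 0.5)

    def unpack(x):
        la, lb = x[0], x[1]
        fmax = fmax0 if fix_fmax is not None else float(np.clip(x[2], 1e-3, 100.0))
        tlag = max(x[3], 0.0) if fit_lag else 0.0
        return fmax, np.exp(la), np.exp(lb), tlag

    def resid(x):
        fmax, alpha, beta, tlag = unpack(x)
        dt = np.maximum(t - tlag, 0.0)
        pred = fmax * -np.expm1(-(dt ** beta) / alpha)
        return pred - y

    x0 = [np.log(alpha0), np.log(beta0)]
    if fix_fmax is None:
        x0.append(fmax0)
    else:
        x0.append(0.0)  # unused slot
    x0.append(0.0)
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    if not sol.success:
        raise RuntimeError(
            f"Weibull fit did not converge (status {sol.status}: {sol.message}); "
            f"start=(alpha={alpha0:.4g}, beta={beta0:.4g}, fmax={fmax0:.4g})"
        )
    fmax, alpha, beta, tlag = unpack(sol.x)
    rss = float(np.sum(sol.fun ** 2))
    return WeibullParams(f_max=fmax, alpha=alpha, beta=beta, t_lag=tlag), rss


def similarity_f2(reference: DissolutionProfile, test: DissolutionProfile) -> float:
    """f2 similarity factor between two profiles on the same time grid.

    All supplied points enter the mean squared difference (no 85%-release
    point exclusion; see ``similarity_f2_fda`` for the regulatory truncation).
    Values above 50 conventionally indicate similarity; identity gives 100.
    """
    if reference.times.shape != test.times.shape or not np.allclose(
        reference.times, test.times, rtol=0, atol=1e-12
    ):
        raise ValueError("profiles must be sampled on the same time grid")
    msd = float(np.mean((reference.released - test.released) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def similarity_f2_fda(reference: DissolutionProfile, test: DissolutionProfile) -> float:
    """f2 with the FDA point-truncation rule.

    Drops sampling points after the first at which both profiles exceed 85%
    release (at most one such point is retained).  Provided as an option; the
    plain :func:`similarity_f2` (all points) is the package default.
    """
    if reference.times.shape != test.times.shape or not np.allclose(
        reference.times, test.times, rtol=0, atol=1e-12
    ):
        raise ValueError("profiles must be sampled on the same time grid")
    both85 = (reference.released > 85.0) & (test.released > 85.0)
    idx = np.argmax(both85) if both85.any() else len(reference) - 1
    sl = slice(0, idx + 1)
    msd = float(np.mean((reference.released[sl] - test.released[sl]) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def bootstrap_f2(
    reference_units: Sequence[DissolutionProfile],
    test_units: Sequence[DissolutionProfile],
    n_boot: int = 1000,
    seed: int | None = None,
    ci: tuple[float, float] = (5.0, 95.0),
) -> dict:
    """Bootstrap f2 over replicate dissolution units (vessels).

    Units are resampled with replacement independently on each side; f2 is
    computed between the resampled means.  Returns the median of the bootstrap
    distribution as the point estimate with percentile CI bounds.
    """
    if len(reference_units) < 2 or len(test_units) < 2:
        raise ValueError("need at least 2 units per side to bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile bounds", stacklevel=2)
    grid = reference_units[0].times
    for u in (*reference_units, *test_units):
        if u.times.shape != grid.shape or not np.allclose(u.times, grid):
            raise ValueError("all units must share one time grid")
    ref = np.stack([u.released for u in reference_units])
    tst = np.stack([u.released for u in test_units])
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        r = ref[rng.integers(0, ref.shape[0], ref.shape[0])].mean(axis=0)
        s = tst[rng.integers(0, tst.shape[0], tst.shape[0])].mean(axis=0)
        msd = float(np.mean((r - s) ** 2))
        vals[b] = 50.0 * np.log10(100.0 / np.sqrt(1.0 + msd))
    lo, hi = np.percentile(vals, ci)
    return {
        "f2": float(np.median(vals)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": int(n_boot),
    }


def generate_dissolution_replicates(
    params: WeibullParams,
    cv: float,
    n_units: int,
    grid: Sequence[float] | None = None,
    seed: int | None = None,
) -> list[DissolutionProfile]:
    """Synthetic replicate dissolution units around a Weibull curve.

    Each unit is the noiseless curve perturbed pointwise by mean-one
    multiplicative lognormal noise at the given CV (%), clipped to [0, 100]
    and monotonised by cumulative max.  cv=0 returns identical units.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    t = default_f2_grid() if grid is None else np.asarray(grid, dtype=float)
    base = evaluate_weibull(params, t)
    rng = np.random.default_rng(seed)
    units = []
    sigma = np.sqrt(np.log1p((cv / 100.0) ** 2))
    for k in range(n_units):
        if cv == 0:
            y = base.copy()
        else:
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=t.size)
            y = np.minimum(np.maximum.accumulate(np.clip(base * noise, 0.0, 100.0)), 100.0)
        units.append(DissolutionProfile(t, y, label=f"unit_{k + 1}"))
    return units


# ---------------------------------------------------------------------------
# Reference formulation and virtual library construction
# ---------------------------------------------------------------------------

#: Weibull parameters of the enteric-coated reference product (trigger pH 5.5).
ENTOCORT_WEIBULL = WeibullParams(f_max=100.0, alpha=3.12, beta=0.94, t_lag=0.0)

#: Library of virtual formulations: label -> (modification, carried f2).
#: Delta entries shift percent released at every time point; pH entries change
#: only the enteric trigger.  f2 values are carried attributes of the library.
VIRTUAL_PANEL: tuple[tuple[str, str, float, float | None], ...] = (
    ("+20%", "delta", 20.0, 36.1),
    ("+10%", "delta", 10.0, 50.8),
    ("+5%", "delta", 5.0, 65.5),
    ("+3%", "delta", 3.0, 75.8),
    ("-5%", "delta", -5.0, 65.5),
    ("-10%", "delta", -10.0, 50.8),
    ("pH threshold = 5", "trigger_ph", 5.0, None),
    ("pH threshold = 6", "trigger_ph", 6.0, None),
)


def entocort_reference() -> VirtualFormulation:
    """The reference controlled-release formulation (trigger pH 5.5)."""
    return VirtualFormulation(
        label="reference", weibull=ENTOCORT_WEIBULL, trigger_ph=5.5, provenance="reference"
    )


def reference_profile(grid: Sequence[float] | None = None) -> DissolutionProfile:
    """Sampled reference curve with the completion-time convention applied.

    The Weibull curve is sampled on the grid and release is standardised to
    100% at 12 h (the asymptote is not quite reached on a finite grid).
    """
    t = default_f2_grid() if grid is None else np.asarray(grid, dtype=float)
    y = evaluate_weibull(ENTOCORT_WEIBULL, t)
    y = _standardize_completion(t, y, t_complete=12.0)
    return DissolutionProfile(t, y, label="reference")


def _standardize_completion(t: np.ndarray, y: np.ndarray, t_complete: float) -> np.ndarray:
    y = np.clip(y, 0.0, 100.0)
    y[t >= t_complete - 1e-12] = 100.0
    return np.maximum.accumulate(y)


def make_virtual_formulation(
    reference: DissolutionProfile,
    delta: float | None = None,
    trigger_ph: float | None = None,
    reference_trigger_ph: float = 5.5,
    label: str | None = None,
    f2_vs_reference: float | None = None,
) -> VirtualFormulation:
    """Derive a virtual test formulation from a reference dissolution curve.

    Exactly one of ``delta`` / ``trigger_ph`` must be given.

    delta mode: adds ``delta`` percent-points to every sampled release value,
    caps at 100%, standardises 100% release at 12 h (at 7 h for delta = +20,
    whose shifted curve completes much earlier), refits the Weibull with
    f_max fixed at 100 and computes f2 vs the reference curve.

    trigger-pH mode: the release curve (hence Weibull fit) is unchanged; only
    the enteric trigger pH differs.
    """
    if (delta is None) == (trigger_ph is None):
        raise ValueError("supply exactly one of delta / trigger_ph")

    if trigger_ph is not None:
        params, _ = fit_weibull(reference, fix_fmax=100.0)
        return VirtualFormulation(
            label=label or f"pH threshold = {trigger_ph:g}",
            weibull=params,
            trigger_ph=float(trigger_ph),
            provenance=f"trigger_ph:{trigger_ph:g}",
            f2_vs_reference=f2_vs_reference,
        )

    y = reference.released + float(delta)
    if np.any(y < -_MONOTONE_TOL):
        raise ValueError(f"delta {delta} drives release negative at some time point")
    t_complete = 7.0 if delta >= 20.0 else 12.0
    y = _standardize_completion(reference.times.copy(), y, t_complete=t_complete)
    modified = DissolutionProfile(reference.times, y, label=label or f"{delta:+g}%")
    params, _ = fit_weibull(modified, fix_fmax=100.0)
    f2 = f2_vs_reference if f2_vs_reference is not None else similarity_f2(reference, modified)
    return VirtualFormulation(
        label=label or f"{delta:+g}%",
        weibull=params,
        trigger_ph=reference_trigger_ph,
        provenance=f"delta:{delta:+g}",
        f2_vs_reference=f2,
    )


def virtual_library(
    reference: DissolutionProfile | None = None,
    panel=VIRTUAL_PANEL,
) -> list[VirtualFormulation]:
    """Build the standard 8-formulation virtual panel from a reference curve.

    Delta variants are refit from the shifted, completion-standardised
    profile; trigger-pH variants leave the release curve untouched and carry
    the reference Weibull parameters verbatim.
    """
    ref = reference if reference is not None else reference_profile()
    out = []
    for label, mode, value, f2 in panel:
        if mode == "delta":
            out.append(
                make_virtual_formulation(ref, delta=value, label=label, f2_vs_reference=f2)
            )
        else:
            out.append(VirtualFormulation(
                label=label, weibull=ENTOCORT_WEIBULL, trigger_ph=value,
                provenance=f"trigger_ph:{value:g}", f2_vs_reference=f2,
            ))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profile_csv(path) -> list[DissolutionProfile]:
    """Read dissolution profile(s): columns ``time_h`` and ``released_pct``
    (or ``released_pct_1..k`` for replicate units)."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("CSV must have a 'time_h' column")
    t = df["time_h"].to_numpy(float)
    cols = [c for c in df.columns if c.startswith("released_pct")]
    if not cols:
        raise ValueError("CSV must have released_pct column(s)")
    return [DissolutionProfile(t, df[c].to_numpy(float), label=c) for c in cols]


def write_profile_csv(path, profiles: Sequence[DissolutionProfile]) -> None:
    t = profiles[0].times
    data = {"time_h": t}
    if len(profiles) == 1:
        data["released_pct"] = profiles[0].released
    else:
        for i, p in enumerate(profiles, 1):
            data[f"released_pct_{i}"] = p.released
    pd.DataFrame(data).to_csv(path, index=False)


def write_library_json(path, formulations: Sequence[VirtualFormulation]) -> None:
    rows = []
    for f in formulations:
        row = {"label": f.label, **asdict(f.weibull), "trigger_ph": f.trigger_ph,
               "provenance": f.provenance, "f2_vs_reference": f.f2_vs_reference}
        rows.append(row)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2)


def read_library_json(path) -> list[VirtualFormulation]:
    with open(path) as fh:
        rows = json.load(fh)
    return [
        VirtualFormulation(
            label=r["label"],
            weibull=WeibullParams(r["f_max"], r["alpha"], r["beta"], r.get("t_lag", 0.0)),
            trigger_ph=r["trigger_ph"],
            provenance=r.get("provenance", ""),
            f2_vs_reference=r.get("f2_vs_reference"),
        )
        for r in rows
    ]
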