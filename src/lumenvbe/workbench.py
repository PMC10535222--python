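"""End-to-end experiment drivers: formulation panels, populations, provenance.

`run_paper_panel` executes the full study design — a panel of virtual
formulations (+20/+10/+5/+3/-5/-10 percent-point dissolution shifts and two
trigger-pH variants) against the reference in healthy and Crohn's-disease
populations — at a configurable scale, writing PK tables, per-trial BE
results, decision tables, heatmap CSV/PNG and a seed/version manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .discordance import build_heatmap
from .formulation import VirtualFormulation, entocort_reference, virtual_library
from .pbpk_core import DrugParams, default_drug, build_subject_model, simulate_dose
from .population import (PopulationSpec, crohns_population,
                         default_healthy_population)
from .vbe import TrialDesign, be_analysis, decision_table, nca, run_vbe

__all__ = ["ExperimentConfig", "run_paper_panel", "validate_model"]

log = logging.getLogger("lumenvbe")


@dataclass(frozen=True)
class ExperimentConfig:
    """Panel experiment definition.

    ``scale`` multiplies the trial count and cohort size of the full design
    (10 trials x 12 subjects); the continuous-integration default runs a
    reduced panel.  ``formulations=None`` means the standard 8-formulation
    library.
    """

    output_dir: str = "panel_output"
    populations: tuple[str, ...] = ("HV", "CD")
    formulations: tuple[str, ...] | None = ("+10%", "-10%", "+5%")
    n_trials: int = 3
    n_subjects: int = 8
    dose_mg: float = 3.0
    seed: int = 0
    layer: str = "enterocyte"

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_subjects < 4:
            raise ValueError("scale too small: need >= 1 trial and >= 4 subjects")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_POPULATIONS = {"HV": default_healthy_population, "CD": crohns_population}


def run_paper_panel(config: ExperimentConfig, drug: DrugParams | None = None) -> dict:
    """Run the formulation panel in each population; write all artifacts.

    Returns a manifest dict (also written as ``manifest.json``).  Completed
    (population, formulation) units are recorded in ``state.json``; rerunning
    after a partial failure skips finished units, and identical configs
    reproduce identical CSVs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    drug = drug if drug is not None else default_drug()
    reference = entocort_reference()
    library = {f.label: f for f in virtual_library()}
    labels = list(library) if config.formulations is None else list(config.formulations)
    unknown = [l for l in labels if l not in library]
    if unknown:
        raise ValueError(f"unknown formulation labels: {unknown}")

    state_path = outdir / "state.json"
    state = json.loads(state_path.read_text()) if state_path.exists() else {"done": []}
    chash = config.config_hash()
    if state.get("config_hash") not in (None, chash):
        state = {"done": []}
    state["config_hash"] = chash

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": chash,
        "outputs": {},
        "seeds": {},
    }

    for pop_label in config.populations:
        population = _POPULATIONS[pop_label]()
        pop_decisions = []
        for j, label in enumerate(labels):
            unit = f"{pop_label}/{label}"
            safe = label.replace("%", "pct").replace(" ", "").replace("=", "")
            pk_path = outdir / f"pk_{pop_label}_{safe}.csv"
            be_path = outdir / f"be_{pop_label}_{safe}.csv"
            # deterministic per-unit seed derived from the config seed
            unit_seed = (config.seed * 10007 + hash_label(unit)) % (2**31)
            manifest["seeds"][unit] = unit_seed
            if unit in state["done"] and pk_path.exists() and be_path.exists():
                log.info("skipping completed unit %s", unit)
                be = pd.read_csv(be_path)
            else:
                t0 = time.time()
                design = TrialDesign(n_trials=config.n_trials,
                                     n_subjects_per_trial=config.n_subjects,
                                     seed=unit_seed)
                pk = run_vbe(reference, library[label], population, design,
                             drug=drug, dose_mg=config.dose_mg)
                be = be_analysis(pk)
                pk.to_csv(pk_path, index=False)
                be.to_csv(be_path, index=False)
                state["done"].append(unit)
                state_path.write_text(json.dumps(state, indent=2))
                log.info("unit %s: %d trials x %d subjects in %.1f s",
                         unit, config.n_trials, config.n_subjects, time.time() - t0)
            dec = decision_table(be)
            dec.insert(0, "formulation", label)
            dec.insert(1, "f2", library[label].f2_vs_reference)
            pop_decisions.append(dec)

        decisions = pd.concat(pop_decisions, ignore_index=True)
        dec_path = outdir / f"decisions_{pop_label}.csv"
        decisions.to_csv(dec_path, index=False)
        heat_csv = outdir / f"heatmap_{pop_label}_{config.layer}_combined.csv"
        heat_png = outdir / f"heatmap_{pop_label}_{config.layer}_combined.png"
        cells, fig = build_heatmap(decisions, layer=config.layer, metric="combined",
                                   csv_path=heat_csv, figure_path=heat_png)
        manifest["outputs"][pop_label] = {
            "decisions": str(dec_path),
            "heatmap_csv": str(heat_csv),
            "heatmap_png": str(heat_png),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def hash_label(label: str) -> int:
    """Stable small integer from a unit label (process-independent)."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")


def validate_model(
    observed: pd.DataFrame,
    drug: DrugParams | None = None,
    population: PopulationSpec | None = None,
    dose_col: str = "dose_mg",
) -> pd.DataFrame:
    """Simulated/observed exposure ratio table for user-supplied PK data.

    ``observed`` needs columns ``dose_mg``, ``obs_auc_nM_h``, ``obs_cmax_nM``
    and optionally ``study`` and ``sex``.  Each dose is simulated for the
    population representative; rows with missing observations are skipped
    with a warning.  No acceptance claim attaches to the ratios.
    """
    import warnings

    drug = drug if drug is not None else default_drug()
    population = population if population is not None else default_healthy_population()
    reference = entocort_reference()
    rows = []
    for _, rec in observed.iterrows():
        if pd.isna(rec.get("obs_auc_nM_h")) or pd.isna(rec.get("obs_cmax_nM")):
            warnings.warn(f"skipping row with missing observations: {rec.to_dict()}",
                          stacklevel=2)
            continue
        subject = population.representative(rec.get("sex", "M"))
        model = build_subject_model(drug, subject, reference, float(rec[dose_col]))
        res = simulate_dose(model)
        m = nca(res.times, res.plasma_conc)
        rows.append({
            "study": rec.get("study", ""),
            "dose_mg": float(rec[dose_col]),
            "obs_auc_nM_h": float(rec["obs_auc_nM_h"]),
            "sim_auc_nM_h": m.auc_last,
            "ratio_auc": round(m.auc_last / float(rec["obs_auc_nM_h"]), 2),
            "obs_cmax_nM": float(rec["obs_cmax_nM"]),
            "sim_cmax_nM": m.c_max,
            "ratio_cmax": round(m.c_max / float(rec["obs_cmax_nM"]), 2),
        })
    return pd.DataFrame(rows)
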