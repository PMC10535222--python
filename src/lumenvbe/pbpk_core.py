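"""Mechanistic single-subject gut absorption / PK simulation.

The model tracks an orally dosed controlled-release multiparticulate product
through a segmented gastrointestinal tract (stomach + duodenum, two jejunum,
four ileum and one colon segment).  For each gut segment it resolves three
layers: undissolved pellets, dissolved drug in the luminal fluid, and drug
inside the enterocyte layer.  Systemic disposition is a lumped two-compartment
model behind a well-stirred hepatic first pass.

Processes (all first order except P-gp efflux):

* pellet transit — first-order compartment chains honouring the gastric and
  small-intestinal pellet mean residence times (SI MRT is split across the
  seven SI segments proportionally to length);
* pH-triggered release — the enteric coat opens only in segments whose pH is
  at or above the formulation trigger pH; release applies the Weibull hazard
  h(t) = F'(t) / (100 - F(t)) to the remaining solid, so stationary pellets
  reproduce the in-vitro Weibull curve exactly;
* luminal transit of dissolved drug with fluid MRTs; colon exit is fecal loss;
* apical uptake into enterocytes: permeability x fluid-wetted segment area x
  regional absorption scalar; P-gp Michaelis-Menten efflux back to lumen on
  unbound enterocyte concentration;
* enterocyte CYP3A4 metabolism (abundance-scaled per segment) competing with
  basolateral transfer to portal blood;
* hepatic first pass (well-stirred extraction ratio), then central/peripheral
  distribution, hepatic and renal (fu x GFR) elimination.

Every flux lands in an explicit ledger, so the state vector conserves dose to
solver tolerance at all times; `SimResult.mass_balance_error()` exposes the
worst relative ledger defect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .formulation import VirtualFormulation, WeibullParams

__all__ = [
    "DrugParams",
    "SegmentSpec",
    "SubjectPhysiology",
    "ModelOptions",
    "GutModel",
    "SimResult",
    "renal_clearance",
    "apical_permeability",
    "scale_hepatic_clint",
    "hepatic_extraction",
    "scale_fu_for_hsa",
    "build_subject_model",
    "simulate_dose",
    "regional_fraction_absorbed",
    "default_drug",
    "default_segments",
    "default_subject",
    "GUT_SEGMENTS",
    "default_output_grid",
]

#: Gut segments with an absorptive enterocyte layer, in anatomical order.
GUT_SEGMENTS = (
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "ileum4",
    "colon",
)

_SI_SEGMENTS = GUT_SEGMENTS[:7]  # small intestine (shares the SI MRTs)


def default_output_grid(t_end: float = 24.0, step: float = 0.25) -> np.ndarray:
    return np.arange(0.0, t_end + step / 2, step)


# ---------------------------------------------------------------------------
# Elementary pharmacokinetic relations
# ---------------------------------------------------------------------------

def renal_clearance(fu: float, gfr_ml_min: float) -> float:
    """Renal clearance CL_R = fu x GFR, returned in L/h.

    Filtration-only renal elimination of the unbound drug: GFR in mL/min is
    converted to L/h (x 60 / 1000).
    """
    if not (0.0 <= fu <= 1.0):
        raise ValueError(f"fu must be in [0, 1], got {fu}")
    if gfr_ml_min < 0:
        raise ValueError("GFR must be non-negative")
    return fu * gfr_ml_min * 60.0 / 1000.0


def apical_permeability(log_p: float, a: float = 2.36e-6, b: float = 1.1) -> float:
    """Intrinsic apical transcellular permeability from lipophilicity.

    P_trans,0 = a x (P_o:w)^b with P_o:w = 10^log_p and a in cm/s; the result
    is reported in 1e-6 cm/s units (so a = 2.36e-6 cm/s contributes 2.36).
    """
    return a * (10.0 ** log_p) ** b * 1e6


def scale_hepatic_clint(
    clint_ul_min_pmol: float,
    abundance_pmol_mg: float,
    mppgl_mg_g: float,
    liver_mass_g: float,
) -> float:
    """Scale per-pmol intrinsic clearance to whole-liver CL_int in L/h."""
    for v in (clint_ul_min_pmol, abundance_pmol_mg, mppgl_mg_g, liver_mass_g):
        if v < 0:
            raise ValueError("all scaling factors must be non-negative")
    # uL/min/pmol -> L/min/pmol is 1e-6; x pmol/mg x mg/g x g x 60 min/h
    return clint_ul_min_pmol * 1e-6 * abundance_pmol_mg * mppgl_mg_g * liver_mass_g * 60.0


def hepatic_extraction(clint_liver_l_h: float, fu_blood: float, q_h_l_h: float) -> float:
    """Well-stirred hepatic extraction ratio E_H = fu CL_int / (Q_H + fu CL_int)."""
    if q_h_l_h <= 0:
        raise ValueError("hepatic blood flow must be positive")
    num = fu_blood * clint_liver_l_h
    return num / (q_h_l_h + num)


def scale_fu_for_hsa(fu_ref: float, hsa_ref: float, hsa: float) -> float:
    """Unbound plasma fraction at a different albumin concentration.

    Binding capacity is taken proportional to HSA concentration:
    fu' = 1 / (1 + (1 - fu)/fu * HSA'/HSA_ref).  Lower albumin (e.g. active
    Crohn's disease) raises the unbound fraction.
    """
    if not (0 < fu_ref <= 1):
        raise ValueError("fu_ref must be in (0, 1]")
    if hsa <= 0 or hsa_ref <= 0:
        raise ValueError("HSA concentrations must be positive")
    return 1.0 / (1.0 + (1.0 - fu_ref) / fu_ref * (hsa / hsa_ref))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugParams:
    """Compound-specific parameters (defaults describe budesonide)."""

    mol_weight: float = 430.53           # g/mol
    log_p: float = 2.62                  # octanol:water
    fu_plasma: float = 0.15              # unbound fraction at reference HSA
    fu_ref_hsa: float = 50.34            # g/L, albumin at which fu_plasma holds
    blood_plasma_ratio: float = 0.8
    fu_gut: float = 1.0                  # unbound fraction in enterocytes
    clint_cyp3a4: float = 4.1            # uL/min/pmol isoform
    pgp_jmax: float = 93.0               # pmol/min/cm2 (efflux Vmax density)
    pgp_km: float = 9.4                  # uM
    apical_ptrans0: float = 1798.5       # 1e-6 cm/s
    basolateral_ptrans0: float = 6000.0  # 1e-6 cm/s
    p_para: float = 0.05506              # 1e-6 cm/s, paracellular
    kp_scalar: float = 0.8
    vss_per_kg: float = 2.69             # L/kg
    perm_coeff_a: float = 2.36e-6
    perm_coeff_b: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.fu_plasma <= 1):
            raise ValueError("fu_plasma must be in (0, 1]")
        for name in ("mol_weight", "blood_plasma_ratio", "clint_cyp3a4", "pgp_km",
                     "apical_ptrans0", "basolateral_ptrans0", "kp_scalar", "vss_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SegmentSpec:
    """Anatomy, pH and drug-handling scalars of one GI segment."""

    name: str
    ph: float
    fluid_volume: float            # mL
    radius: float                  # cm
    length: float                  # cm
    absorption_scalar: float = 0.0
    cyp3a4_abundance_share: float = 0.0   # share of SI total (colon uses its own total)
    transporter_rel_abundance: float = 0.0
    accessibility: float = 1.0     # fraction of mucosa in contact with fluid

    def __post_init__(self) -> None:
        if not (1.0 <= self.ph <= 9.0):
            raise ValueError(f"{self.name}: ph must be in [1, 9]")
        if self.fluid_volume <= 0:
            raise ValueError(f"{self.name}: fluid_volume must be positive")
        for attr in ("absorption_scalar", "cyp3a4_abundance_share",
                     "transporter_rel_abundance", "accessibility"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")

    @property
    def wetted_area(self) -> float:
        """Fluid-wetted mucosal area, cm^2: cylinder area scaled by the
        volume fraction the resting fluid occupies, which reduces to 2 V / r."""
        return 2.0 * self.fluid_volume / self.radius


def default_segments() -> tuple[SegmentSpec, ...]:
    """Fasted-state segment defaults.

    pH follows the typical fasted proximal-to-distal gradient with the
    caecal drop; fluid volumes are literature-typical fasted free water.
    Regional absorption scalars are 0.06 / 0.12 / 0.54 / 1.44 for duodenum /
    jejunum / ileum / colon.  Colonic mucosal accessibility is reduced
    (haustral sequestration, mucus) so colonic uptake is slow despite the
    large scalar.
    """
    return (
        SegmentSpec("stomach", 1.5, 46.0, 10.0, 20.0, 0.0, 0.0, 0.0, 1.0),
        SegmentSpec("duodenum", 6.0, 15.0, 1.6, 30.0, 0.06, 0.09, 0.75, 1.0),
        SegmentSpec("jejunum1", 6.2, 25.0, 1.4, 75.0, 0.12, 0.23, 1.0, 1.0),
        SegmentSpec("jejunum2", 6.4, 20.0, 1.3, 75.0, 0.12, 0.23, 1.0, 1.0),
        SegmentSpec("ileum1", 6.8, 12.0, 1.2, 65.0, 0.54, 0.13, 1.5, 1.0),
        SegmentSpec("ileum2", 7.0, 10.0, 1.1, 65.0, 0.54, 0.12, 2.0, 1.0),
        SegmentSpec("ileum3", 7.2, 8.0, 1.0, 65.0, 0.54, 0.11, 2.5, 1.0),
        SegmentSpec("ileum4", 7.4, 5.0, 1.0, 65.0, 0.54, 0.09, 3.0, 1.0),
        SegmentSpec("colon", 6.4, 13.0, 2.5, 150.0, 1.44, 0.0, 1.4, 0.05),
    )


@dataclass(frozen=True)
class SubjectPhysiology:
    """One virtual subject's GI / enzymatic / binding parameter set."""

    gastric_pellet_mrt: float = 0.8      # h
    si_pellet_mrt: float = 3.0           # h, split across SI segments by length
    gastric_fluid_mrt: float = 0.27      # h
    si_fluid_mrt: float = 3.4            # h
    colon_fluid_mrt_whole: float = 37.5  # h (male default)
    colon_fluid_mrt_ascending: float = 18.91  # h
    liver_cyp3a4: float = 137.0          # pmol/mg protein
    si_cyp3a4_total: float = 65.4        # nmol per small intestine
    colon_cyp3a4_total: float = 1.99     # nmol per colon
    hsa: float = 50.34                   # g/L
    gfr: float = 172.42                  # mL/min (per-1.73 m2 value used directly)
    liver_blood_flow: float = 90.0       # L/h
    liver_mass: float = 1650.0           # g
    mppgl: float = 40.0                  # mg microsomal protein / g liver
    body_weight: float = 81.0            # kg
    sex: str = "M"
    age: float = 24.0
    segments: tuple[SegmentSpec, ...] = field(default_factory=default_segments)

    def __post_init__(self) -> None:
        for name in ("gastric_pellet_mrt", "si_pellet_mrt", "gastric_fluid_mrt",
                     "si_fluid_mrt", "colon_fluid_mrt_whole", "liver_cyp3a4",
                     "hsa", "liver_blood_flow", "liver_mass", "mppgl", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        names = [s.name for s in self.segments]
        if names != ["stomach", *GUT_SEGMENTS]:
            raise ValueError(f"segments must be stomach + {GUT_SEGMENTS}, got {names}")

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)


def default_subject(sex: str = "M") -> SubjectPhysiology:
    """Representative healthy adult (male by default)."""
    if sex == "F":
        return SubjectPhysiology(
            sex="F", hsa=49.38, colon_fluid_mrt_whole=55.75,
            colon_fluid_mrt_ascending=23.11, body_weight=66.0,
        )
    return SubjectPhysiology()


def default_drug() -> DrugParams:
    return DrugParams()


@dataclass(frozen=True)
class ModelOptions:
    """Switches and calibration knobs of the gut model.

    The reduced-configuration switches (instant release, absorbing-segment
    subset, enterocyte bypass, one-compartment disposition) exist to let the
    model collapse onto closed-form solutions for verification.
    """

    enable_pgp: bool = True
    enable_gut_metabolism: bool = True
    direct_to_portal: bool = False          # bypass the enterocyte layer
    one_compartment: bool = False
    instant_release_segment: str | None = None  # dose starts dissolved here
    absorbing_segments: tuple[str, ...] | None = None  # None = all
    central_fraction: float = 0.35          # Vc as a fraction of Vss
    intercompartment_clearance: float = 30.0  # L/h between central/peripheral
    basolateral_area_multiplier: float = 5.0
    enterocyte_volume_fraction: float = 0.01  # of segment fluid volume
    rtol: float = 1e-8
    atol: float = 1e-10                      # nmol
    solver: str = "BDF"


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class GutModel:
    """Assembled ODE system for one subject / formulation / dose.

    Not built directly — use :func:`build_subject_model`.  Exposes the rate
    constants so reduced configurations can be checked against closed forms.
    """

    drug: DrugParams
    physio: SubjectPhysiology
    formulation: VirtualFormulation
    dose_mg: float
    options: ModelOptions

    # derived quantities (filled by build_subject_model)
    dose_nmol: float = 0.0
    fu: float = 0.0
    eh: float = 0.0
    cl_renal: float = 0.0
    cl_hepatic: float = 0.0
    vc: float = 0.0
    vp: float = 0.0
    n_states: int = 0
    a0: np.ndarray | None = None
    y0: np.ndarray | None = None
    lumen_volumes: np.ndarray | None = None  # L, stomach + 8 segments
    ent_volumes: np.ndarray | None = None    # L, 8 segments
    ka_lumen: np.ndarray | None = None       # 1/h apical uptake per segment
    triggered: np.ndarray | None = None      # bool per stomach+8
    pgp_vmax: np.ndarray | None = None       # nmol/h per segment
    pgp_km_nm: float = 0.0

    # state layout
    IDX_SOLID = slice(0, 9)
    IDX_LUMEN = slice(9, 18)
    IDX_ENT = slice(18, 26)
    IDX_CENTRAL = 26
    IDX_PERIPH = 27
    IDX_GUT_MET = 28
    IDX_LIVER_MET = 29
    IDX_RENAL = 30
    IDX_FECAL_SOLID = 31
    IDX_FECAL_DISS = 32
    IDX_ABS = slice(33, 41)

    def _hazard(self, t: float) -> float:
        """Weibull release hazard h(t) = F'(t) / (100 - F(t)), 1/h."""
        w = self.formulation.weibull
        dt = t - w.t_lag
        if dt <= 0.0:
            return 0.0
        dt = max(dt, 1e-6)
        u = dt ** w.beta / w.alpha
        fp = w.f_max * np.exp(-u) * w.beta * dt ** (w.beta - 1.0) / w.alpha
        s = 100.0 - w.f_max * -np.expm1(-u)
        return fp / max(s, 1e-12)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.a0 @ y
        h = self._hazard(t)
        if h > 0.0:
            trig = self.triggered
            rel = h * y[0:9] * trig
            dy[0:9] -= rel
            dy[9:18] += rel
        if self.options.enable_pgp:
            ent = y[18:26]
            cu = self.drug.fu_gut * ent / self.ent_volumes
            flux = self.pgp_vmax * cu / (self.pgp_km_nm + cu)
            dy[18:26] -= flux
            dy[10:18] += flux
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        j = self.a0.copy()
        h = self._hazard(t)
        if h > 0.0:
            for i in range(9):
                if self.triggered[i]:
                    j[i, i] -= h
                    j[9 + i, i] += h
        if self.options.enable_pgp:
            ent = y[18:26]
            g = self.drug.fu_gut / self.ent_volumes
            cu = g * ent
            d = self.pgp_vmax * self.pgp_km_nm * g / (self.pgp_km_nm + cu) ** 2
            for e in range(8):
                j[18 + e, 18 + e] -= d[e]
                j[10 + e, 18 + e] += d[e]
        return j


def build_subject_model(
    drug: DrugParams,
    physio: SubjectPhysiology,
    formulation: VirtualFormulation,
    dose_mg: float,
    options: ModelOptions | None = None,
) -> GutModel:
    """Assemble the gut/PK ODE system for one subject and formulation."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    opt = options or ModelOptions()
    m = GutModel(drug=drug, physio=physio, formulation=formulation,
                 dose_mg=dose_mg, options=opt)

    m.dose_nmol = dose_mg / drug.mol_weight * 1e6
    m.fu = scale_fu_for_hsa(drug.fu_plasma, drug.fu_ref_hsa, physio.hsa)
    fu_blood = m.fu / drug.blood_plasma_ratio
    clint_liver = scale_hepatic_clint(
        drug.clint_cyp3a4, physio.liver_cyp3a4, physio.mppgl, physio.liver_mass
    )
    m.eh = hepatic_extraction(clint_liver, fu_blood, physio.liver_blood_flow)
    m.cl_renal = renal_clearance(m.fu, physio.gfr)
    m.cl_hepatic = physio.liver_blood_flow * m.eh

    vss = drug.kp_scalar * drug.vss_per_kg * physio.body_weight
    if opt.one_compartment:
        m.vc, m.vp = vss, 0.0
        q_ic = 0.0
    else:
        m.vc = opt.central_fraction * vss
        m.vp = vss - m.vc
        q_ic = opt.intercompartment_clearance

    segs = physio.segments
    n_si = len(_SI_SEGMENTS)
    si_lengths = np.array([physio.segment(n).length for n in _SI_SEGMENTS])
    si_len_total = si_lengths.sum()

    # transit rate constants, stomach + 8 segments
    solid_mrt = np.empty(9)
    fluid_mrt = np.empty(9)
    solid_mrt[0] = physio.gastric_pellet_mrt
    fluid_mrt[0] = physio.gastric_fluid_mrt
    solid_mrt[1:8] = physio.si_pellet_mrt * si_lengths / si_len_total
    fluid_mrt[1:8] = physio.si_fluid_mrt * si_lengths / si_len_total
    solid_mrt[8] = physio.colon_fluid_mrt_whole
    fluid_mrt[8] = physio.colon_fluid_mrt_whole
    k_solid = 1.0 / solid_mrt
    k_fluid = 1.0 / fluid_mrt

    m.lumen_volumes = np.array([s.fluid_volume for s in segs]) / 1000.0  # L
    m.ent_volumes = m.lumen_volumes[1:] * opt.enterocyte_volume_fraction

    absorbing = set(opt.absorbing_segments) if opt.absorbing_segments is not None else set(GUT_SEGMENTS)
    p_apical = (drug.apical_ptrans0 + drug.p_para) * 3.6e-6  # (1e-6 cm/s) -> L/h per cm2
    p_baso = drug.basolateral_ptrans0 * 3.6e-6 * opt.basolateral_area_multiplier

    cla = np.zeros(8)   # lumen -> enterocyte, L/h
    clb = np.zeros(8)   # enterocyte -> portal, L/h
    clg = np.zeros(8)   # enterocyte CYP3A4, L/h
    vmax = np.zeros(8)  # P-gp, nmol/h
    for e, name in enumerate(GUT_SEGMENTS):
        s = physio.segment(name)
        area = s.wetted_area
        if name in absorbing:
            cla[e] = p_apical * area * s.accessibility * s.absorption_scalar
        clb[e] = p_baso * area
        abundance = (physio.colon_cyp3a4_total if name == "colon"
                     else physio.si_cyp3a4_total * s.cyp3a4_abundance_share)
        if opt.enable_gut_metabolism:
            # uL/min/pmol x nmol -> L/h is x 0.06
            clg[e] = drug.clint_cyp3a4 * abundance * 0.06
        vmax[e] = drug.pgp_jmax * area * s.transporter_rel_abundance * 0.06  # nmol/h
    m.ka_lumen = cla / m.lumen_volumes[1:]
    m.pgp_vmax = vmax
    m.pgp_km_nm = drug.pgp_km * 1000.0

    ph = np.array([s.ph for s in segs])
    m.triggered = ph >= formulation.trigger_ph
    if not m.triggered[1:].any():
        warnings.warn(
            f"trigger pH {formulation.trigger_ph} is above every intestinal segment pH; "
            "no release will occur", stacklevel=2,
        )

    # ----- linear transfer matrix -----
    n = 41
    a = np.zeros((n, n))
    S, L, E = 0, 9, 18
    CEN, PER = GutModel.IDX_CENTRAL, GutModel.IDX_PERIPH
    GM, LM, RN = GutModel.IDX_GUT_MET, GutModel.IDX_LIVER_MET, GutModel.IDX_RENAL
    FS, FD, AB = GutModel.IDX_FECAL_SOLID, GutModel.IDX_FECAL_DISS, 33

    for i in range(9):
        a[S + i, S + i] -= k_solid[i]
        a[S + i + 1 if i < 8 else FS, S + i] += k_solid[i]
        a[L + i, L + i] -= k_fluid[i]
        a[L + i + 1 if i < 8 else FD, L + i] += k_fluid[i]

    for e in range(8):
        li = L + 1 + e
        ka = cla[e] / m.lumen_volumes[1 + e]
        if ka == 0.0:
            continue
        a[li, li] -= ka
        if opt.direct_to_portal:
            a[CEN, li] += (1.0 - m.eh) * ka
            a[LM, li] += m.eh * ka
            a[AB + e, li] += ka
        else:
            a[E + e, li] += ka

    if not opt.direct_to_portal:
        for e in range(8):
            kb = clb[e] / m.ent_volumes[e]
            kg = clg[e] * drug.fu_gut / m.ent_volumes[e]
            a[E + e, E + e] -= kb + kg
            a[GM, E + e] += kg
            a[CEN, E + e] += (1.0 - m.eh) * kb
            a[LM, E + e] += m.eh * kb
            a[AB + e, E + e] += kb

    ke_h = m.cl_hepatic / m.vc
    ke_r = m.cl_renal / m.vc
    a[CEN, CEN] -= ke_h + ke_r
    a[LM, CEN] += ke_h
    a[RN, CEN] += ke_r
    if q_ic > 0.0:
        a[CEN, CEN] -= q_ic / m.vc
        a[PER, CEN] += q_ic / m.vc
        a[CEN, PER] += q_ic / m.vp
        a[PER, PER] -= q_ic / m.vp

    m.a0 = a
    m.n_states = n

    y0 = np.zeros(n)
    if opt.instant_release_segment is None:
        y0[S + 0] = m.dose_nmol
    else:
        names = ["stomach", *GUT_SEGMENTS]
        y0[L + names.index(opt.instant_release_segment)] = m.dose_nmol
    m.y0 = y0
    return m


# ---------------------------------------------------------------------------
# Simulation and result container
# ---------------------------------------------------------------------------

_LEDGER_COLS = (
    "undissolved", "dissolved_lumen", "enterocyte", "systemic",
    "gut_metabolized", "liver_metabolized", "renally_excreted",
    "fecal_solid", "fecal_dissolved",
)


@dataclass
class SimResult:
    """Concentration-time output of one simulation plus mass ledgers."""

    times: np.ndarray                     # h
    plasma_conc: np.ndarray               # nM
    lumen_conc: pd.DataFrame              # nM, columns = GUT_SEGMENTS
    enterocyte_conc: pd.DataFrame         # nM, columns = GUT_SEGMENTS
    ledgers: pd.DataFrame                 # nmol, columns = _LEDGER_COLS
    absorbed_per_segment: pd.DataFrame    # cumulative nmol to portal
    dose_nmol: float

    def mass_balance_error(self) -> float:
        """Worst relative deviation of the ledger total from the dose."""
        total = self.ledgers.sum(axis=1).to_numpy()
        return float(np.max(np.abs(total - self.dose_nmol)) / self.dose_nmol)

    def site_concentration(self, site: str, layer: str | None = None) -> np.ndarray:
        """Concentration series for a named analysis site.

        ``site='plasma'`` ignores layer; gut segments need layer 'lumen' or
        'enterocyte'.
        """
        if site == "plasma":
            return self.plasma_conc
        if layer == "lumen":
            return self.lumen_conc[site].to_numpy()
        if layer == "enterocyte":
            return self.enterocyte_conc[site].to_numpy()
        raise ValueError(f"unknown site/layer: {site}/{layer}")

    def to_tidy(self) -> pd.DataFrame:
        """Tidy export: time_h, site, layer, conc_nM."""
        frames = [pd.DataFrame({
            "time_h": self.times, "site": "plasma", "layer": "plasma",
            "conc_nM": self.plasma_conc,
        })]
        for seg in GUT_SEGMENTS:
            for layer, df in (("lumen", self.lumen_conc), ("enterocyte", self.enterocyte_conc)):
                frames.append(pd.DataFrame({
                    "time_h": self.times, "site": seg, "layer": layer,
                    "conc_nM": df[seg].to_numpy(),
                }))
        return pd.concat(frames, ignore_index=True)


def simulate_dose(
    model: GutModel,
    t_end: float = 24.0,
    output_grid: Sequence[float] | None = None,
) -> SimResult:
    """Integrate the assembled model and package concentrations + ledgers."""
    grid = default_output_grid(t_end) if output_grid is None else np.asarray(output_grid, float)
    if t_end < grid.max():
        raise ValueError("t_end must cover the output grid")
    opt = model.options
    sol = solve_ivp(
        model.rhs, (0.0, float(t_end)), model.y0, method=opt.solver,
        t_eval=grid, jac=model.jac, rtol=opt.rtol, atol=opt.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed: {sol.message}; formulation={model.formulation.label!r}, "
            f"dose={model.dose_mg} mg, trigger_ph={model.formulation.trigger_ph}"
        )
    y = sol.y
    solid = y[0:9]
    lumen = y[9:18]
    ent = y[18:26]

    lumen_conc = pd.DataFrame(
        {seg: lumen[1 + e] / model.lumen_volumes[1 + e] for e, seg in enumerate(GUT_SEGMENTS)}
    )
    ent_conc = pd.DataFrame(
        {seg: ent[e] / model.ent_volumes[e] for e, seg in enumerate(GUT_SEGMENTS)}
    )
    ledgers = pd.DataFrame({
        "undissolved": solid.sum(axis=0),
        "dissolved_lumen": lumen.sum(axis=0),
        "enterocyte": ent.sum(axis=0),
        "systemic": y[GutModel.IDX_CENTRAL] + y[GutModel.IDX_PERIPH],
        "gut_metabolized": y[GutModel.IDX_GUT_MET],
        "liver_metabolized": y[GutModel.IDX_LIVER_MET],
        "renally_excreted": y[GutModel.IDX_RENAL],
        "fecal_solid": y[GutModel.IDX_FECAL_SOLID],
        "fecal_dissolved": y[GutModel.IDX_FECAL_DISS],
    })
    absorbed = pd.DataFrame({seg: y[33 + e] for e, seg in enumerate(GUT_SEGMENTS)})
    return SimResult(
        times=sol.t, plasma_conc=y[GutModel.IDX_CENTRAL] / model.vc,
        lumen_conc=lumen_conc, enterocyte_conc=ent_conc, ledgers=ledgers,
        absorbed_per_segment=absorbed, dose_nmol=model.dose_nmol,
    )


def regional_fraction_absorbed(result: SimResult) -> pd.Series:
    """Fraction of the dose delivered to portal blood from each segment."""
    final = result.absorbed_per_segment.iloc[-1]
    return final / result.dose_nmol
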