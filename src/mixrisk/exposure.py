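"""Exposure design: MEC/PEC/5PEC levels, spiking plans, recovery accounting.

The three tested exposure levels per site are the median measured
environmental concentration (MEC) of each mixture component, its
predicted environmental concentration immediately after application
(PEC, over a 5 cm soil layer at 1.5 g/cm³ bulk density), and five times
PEC as the worst-case level.  This module also plans the laboratory
spiking (acetone-carrier sub-sample, water-carrier substances added while
moistening to 50% WHC) and books analytical recovery and 28-day
persistence against first-order decay expected from each substance's DT50.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidConfigError, UndefinedMECError

#: substances added with the moistening water rather than in acetone
WATER_CARRIER_DEFAULT = frozenset({"glyphosate", "ampa"})

EXPOSURE_LEVELS = ("MEC", "PEC", "5PEC")

RECOVERY_LOW = 80.0
RECOVERY_HIGH = 120.0


@dataclass(frozen=True)
class ExposureSet:
    """Per-pesticide MEC/PEC/5PEC concentrations for one site (mg/kg)."""

    site: str
    pesticides: tuple[str, ...]
    mec: dict[str, float]
    pec: dict[str, float]
    five_pec: dict[str, float]

    def __post_init__(self):
        for d in (self.mec, self.pec, self.five_pec):
            for p in self.pesticides:
                if p not in d:
                    raise InvalidConfigError(f"missing concentration for {p!r}")
                if d[p] < 0:
                    raise DomainError("concentrations must be >= 0")

    @classmethod
    def from_pec(cls, site: str, mec: dict[str, float], pec: dict[str, float],
                 worst_case_factor: float = 5.0) -> "ExposureSet":
        """Build a set with the worst-case level derived exactly as
        ``worst_case_factor`` × PEC."""
        pests = tuple(pec)
        return cls(site, pests, dict(mec), dict(pec),
                   {p: scale_worst_case(pec[p], worst_case_factor) for p in pests})

    def level(self, name: str) -> dict[str, float]:
        try:
            return {"MEC": self.mec, "PEC": self.pec, "5PEC": self.five_pec}[name]
        except KeyError:
            raise KeyError(f"unknown exposure level {name!r}") from None


@dataclass(frozen=True)
class SpikingPlan:
    """Laboratory plan to prepare one exposure level in one soil batch."""

    level: str
    total_soil_dry_mass_g: float
    spiked_submass_g: float          # acetone-carrier sub-sample (default 8% of soil)
    acetone_volume_ml: float         # 8 g soil : 1 ml acetone
    target_moisture_fraction_whc: float
    masses_mg: dict[str, float]      # per-pesticide mass on total dry soil
    carriers: dict[str, str]         # per-pesticide: "acetone" or "water"


@dataclass(frozen=True)
class RecoveryRecord:
    """Recovery / persistence bookkeeping for one pesticide in one level."""

    pesticide: str
    nominal: float
    measured_initial: float
    measured_final: float
    recovery_percent: float | None
    persistence_percent: float | None
    expected_residual_fraction: float | None
    category: str                    # low / nominal-range / high
    anomaly: bool


def pec_from_rate(rate_kg_ha: float, depth_cm: float = 5.0,
                  bulk_density_g_cm3: float = 1.5) -> float:
    """Initial soil concentration (mg a.s./kg dry soil) from an application
    rate.

    The rate is mixed into a layer of ``depth_cm`` over one hectare
    (10⁸ cm²) of soil with the given bulk density:
    PEC = rate·10⁶ mg / (10⁸·depth·ρ g / 1000 g/kg).  With the defaults
    (5 cm, 1.5 g/cm³), 0.75 kg/ha → exactly 1 mg/kg.
    """
    if rate_kg_ha < 0:
        raise DomainError("application rate must be >= 0")
    if depth_cm <= 0 or bulk_density_g_cm3 <= 0:
        raise DomainError("depth and bulk density must be > 0")
    soil_kg_per_ha = 1e8 * depth_cm * bulk_density_g_cm3 / 1000.0
    return rate_kg_ha * 1e6 / soil_kg_per_ha


MEC_POLICIES = ("detected_only", "half_loq", "zero")


def mec_from_monitoring(concentrations, below_loq=None,
                        policy: str = "detected_only",
                        loq: float | None = None) -> float:
    """Median measured concentration under a censoring policy.

    ``detected_only`` (default): median over detects; no detects raises
    :class:`UndefinedMECError`.  ``half_loq`` / ``zero``: non-detects are
    substituted with LOQ/2 or 0 before taking the median over all samples.
    Even sample counts use the midpoint of the two central values.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise UndefinedMECError("no samples supplied")
    if np.any(conc < 0):
        raise DomainError("concentrations must be >= 0")
    flags = (np.zeros(conc.size, dtype=bool) if below_loq is None
             else np.asarray(below_loq, dtype=bool))
    if policy == "detected_only":
        detected = conc[~flags]
        if detected.size == 0:
            raise UndefinedMECError("no detected samples; MEC undefined")
        return float(np.median(detected))
    if policy in ("half_loq", "zero"):
        if policy == "half_loq":
            if loq is None:
                raise InvalidConfigError("half_loq policy requires the LOQ")
            sub = loq / 2.0
        else:
            sub = 0.0
        vals = np.where(flags, sub, conc)
        return float(np.median(vals))
    raise InvalidConfigError(f"unknown MEC policy {policy!r} (expected {MEC_POLICIES})")


def scale_worst_case(pec: float, factor: float = 5.0) -> float:
    """Worst-case exposure level: exact multiplication of the PEC."""
    if pec < 0:
        raise DomainError("pec must be >= 0")
    if factor < 0:
        raise DomainError("factor must be >= 0")
    return pec * factor


def build_spiking_plan(level: str, concentrations: dict[str, float],
                       soil_mass_g: float,
                       solvent_fraction_soil: float = 0.08,
                       soil_g_per_ml_acetone: float = 8.0,
                       water_carrier=WATER_CARRIER_DEFAULT,
                       carriers: dict[str, str] | None = None,
                       target_moisture_fraction_whc: float = 0.5) -> SpikingPlan:
    """Spiking plan for one exposure level.

    8% of the dry soil (by default) is spiked with the acetone-carrier
    substances at a ratio of 8 g soil : 1 ml acetone; water-soluble
    substances (glyphosate, AMPA by default) are instead added with the
    water that brings the whole batch to 50% of the maximum WHC.
    Per-pesticide masses are computed on the *total* dry soil mass; a zero
    concentration yields a zero mass but the substance stays listed.
    """
    if soil_mass_g <= 0:
        raise DomainError("soil_mass_g must be > 0")
    if not 0 < solvent_fraction_soil < 1:
        raise InvalidConfigError("solvent_fraction_soil must be in (0, 1)")
    water_set = {w.lower() for w in water_carrier}
    assigned = {}
    for pest in concentrations:
        if carriers and pest in carriers:
            c = carriers[pest]
            if c not in ("acetone", "water"):
                raise InvalidConfigError(f"unknown carrier {c!r} for {pest!r}")
            assigned[pest] = c
        else:
            assigned[pest] = "water" if pest.lower() in water_set else "acetone"
    masses = {}
    for pest, conc in concentrations.items():
        if conc < 0:
            raise DomainError("concentrations must be >= 0")
        masses[pest] = conc * soil_mass_g / 1000.0  # mg/kg × g → mg
    submass = soil_mass_g * solvent_fraction_soil
    return SpikingPlan(
        level=level,
        total_soil_dry_mass_g=soil_mass_g,
        spiked_submass_g=submass,
        acetone_volume_ml=submass / soil_g_per_ml_acetone,
        target_moisture_fraction_whc=target_moisture_fraction_whc,
        masses_mg=masses,
        carriers=assigned,
    )


def expected_residual_fraction(dt50_days: float, test_days: float = 28.0) -> float:
    """First-order residue decay: fraction remaining after ``test_days``."""
    if dt50_days <= 0:
        raise DomainError("dt50_days must be > 0")
    if test_days < 0:
        raise DomainError("test_days must be >= 0")
    return float(2.0 ** (-test_days / dt50_days))


def recovery_category(recovery_percent: float) -> str:
    """Classify a recovery: < 80% low, 80–120% (closed) nominal-range,
    > 120% high."""
    if recovery_percent < RECOVERY_LOW:
        return "low"
    if recovery_percent <= RECOVERY_HIGH:
        return "nominal-range"
    return "high"


def recovery_report(pesticide: str, nominal: float, measured_initial: float,
                    measured_final: float, dt50_days: float | None = None,
                    test_days: float = 28.0, anomaly_factor: float = 3.0,
                    background: float = 0.0) -> RecoveryRecord:
    """Recovery and persistence bookkeeping for one substance.

    Recovery = 100 × initial/nominal; persistence = 100 × final/initial.
    When a DT50 is supplied, the first-order expected residual fraction is
    computed and the record is flagged anomalous if the observed
    persistence deviates from it by more than ``anomaly_factor`` in either
    direction.  An optional ``background`` concentration (e.g. residues
    already present in the control soil) is subtracted from the measured
    values first.  ``measured_initial`` = 0 leaves persistence undefined
    and flags the record.
    """
    if nominal <= 0:
        raise DomainError("nominal concentration must be > 0")
    if anomaly_factor <= 1:
        raise InvalidConfigError("anomaly_factor must be > 1")
    init = max(measured_initial - background, 0.0)
    final = max(measured_final - background, 0.0)
    recovery = 100.0 * init / nominal
    category = recovery_category(recovery)
    expected = (expected_residual_fraction(dt50_days, test_days)
                if dt50_days is not None else None)
    if init > 0:
        persistence = 100.0 * final / init
        anomaly = False
        if expected is not None:
            ratio = (persistence / 100.0) / expected if expected > 0 else np.inf
            anomaly = ratio > anomaly_factor or ratio < 1.0 / anomaly_factor
    else:
        persistence = None
        anomaly = True  # persistence undefined
    return RecoveryRecord(
        pesticide=pesticide, nominal=nominal,
        measured_initial=measured_initial, measured_final=measured_final,
        recovery_percent=recovery, persistence_percent=persistence,
        expected_residual_fraction=expected, category=category, anomaly=anomaly,
    )


# ---------------------------------------------------------------------------
# bundled case-study exposure table

def load_table1() -> pd.DataFrame:
    """The bundled case-study exposure table (55 site × pesticide rows).

    Columns: css, pesticide, mec_mg_kg, pec_mg_kg, five_pec_mg_kg — the
    published MEC/PEC/5PEC values of the five selected pesticides in each
    of the 11 case-study sites, transcribed verbatim.  Note the printed
    PEC column is rounded to three decimals; for a handful of rows the
    exact ×5 identity only holds against the unrounded PEC implied by the
    5PEC column.
    """
    ref = importlib.resources.files("mixrisk.data") / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_intext_noecs() -> dict[str, float]:
    """Reproduction NOECs quoted in the running text of the case study
    (mg a.s./kg dry soil), as used — i.e. already corrected."""
    ref = importlib.resources.files("mixrisk.data") / "noec_intext.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return dict(zip(df["pesticide"], df["noec_mg_kg"]))


def exposure_sets_from_table(df: pd.DataFrame) -> dict[str, ExposureSet]:
    """Build per-site ExposureSets from a table with the fixture schema."""
    out = {}
    for site, sub in df.groupby("css", sort=False):
        out[site] = ExposureSet(
            site=site,
            pesticides=tuple(sub["pesticide"]),
            mec=dict(zip(sub["pesticide"], sub["mec_mg_kg"])),
            pec=dict(zip(sub["pesticide"], sub["pec_mg_kg"])),
            five_pec=dict(zip(sub["pesticide"], sub["five_pec_mg_kg"])),
        )
    return out
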