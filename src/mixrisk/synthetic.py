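"""Synthetic monitoring, hazard and reproduction-test data.

The generator emulates the statistical structure of a residue-monitoring
campaign coupled to collembolan reproduction tests, so the whole analysis
pipeline can be exercised and calibrated without field data:

* residue concentrations are lognormal, left-censored at a limit of
  quantification (LOQ), with a per-pesticide true detection frequency;
* each pesticide carries a true springtail EC50 and a true NOEC placed at
  the ~30% single-substance effect level, the typical position of a NOEC
  relative to its dose-response curve;
* mixture potency follows concentration addition: toxic units
  TU = Σ Cᵢ/EC50ᵢ, mapped to reproduction inhibition through a
  log-logistic curve f(TU) = (λ·TU)^b / (TU50^b + (λ·TU)^b).  The synergy
  multiplier λ scales summed toxic units; λ = 1 is pure concentration
  addition, λ > 1 a more-than-additive mixture;
* jar-level counts are binomial (adult survival out of 10 introduced) and
  negative-binomial (juveniles, overdispersed relative to Poisson as real
  OECD-232 counts are), and adult body sizes are normal with a mean that
  shrinks with toxic pressure.

Every table is drawn from its own named random substream of the single
seed, so e.g. adding pesticides to the hazard database does not perturb
the reproduction-test draws at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DomainError, InvalidConfigError, InvalidDesignError

# named random substreams (spawn keys) — one per generated table
_STREAM_TRUTH = 0
_STREAM_MONITORING = 1
_STREAM_ECOTOX = 2
_STREAM_REPRO = 3
_STREAM_INFO = 4

NEGATIVE_CONTROL = "negative_control"
SOLVENT_CONTROL = "solvent_control"
CONTROL_LEVELS = (NEGATIVE_CONTROL, SOLVENT_CONTROL)

PESTICIDE_CLASSES = ("fungicide", "insecticide", "herbicide", "metabolite")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    The defaults describe one realistic monitoring-plus-bioassay campaign:
    11 sites, 25 candidate analytes, 20 soil samples per site, residues with
    a lognormal spread around tens of µg/kg, an LOQ of 0.005 mg/kg, and
    OECD-232 tests with 5 replicate jars of 10 introduced springtails whose
    control jars hold ~500 juveniles with a coefficient of variation of
    ~20% (negative-binomial dispersion 25).

    ``tu50`` and ``slope`` place the log-logistic mixture dose-response on
    the toxic-unit axis; ``noec_effect_level`` positions each true NOEC on
    the single-substance curve (0.3 = the 30%-effect level).
    ``synergy_lambda`` multiplies summed toxic units (1 = concentration
    addition holds exactly).
    """

    n_sites: int = 11
    n_pesticides: int = 25
    n_samples_per_site: int = 20
    detect_freq_range: tuple[float, float] = (0.2, 1.0)
    conc_lognormal_params: tuple[float, float] = (-3.5, 1.0)  # log-mean, log-sd (mg/kg)
    loq: float = 0.005  # mg/kg dry soil
    control_juvenile_mean: float = 500.0
    juvenile_dispersion: float = 25.0  # negative-binomial size k; CV^2 = 1/mean + 1/k
    survival_baseline: float = 0.95
    tu50: float = 1.0
    slope: float = 1.9
    synergy_lambda: float = 1.0
    noec_effect_level: float = 0.3
    ec50_lognormal_params: tuple[float, float] = (0.0, 1.0)  # mg/kg
    size_mean_mm: float = 1.5
    size_sd_mm: float = 0.15
    survival_tu50_ratio: float = 3.0  # survival endpoint is this many times less sensitive
    size_effect_max: float = 0.25  # maximal fractional shrink of adult size
    n_replicates: int = 5
    n_introduced: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.n_pesticides < 1:
            raise InvalidConfigError("n_sites and n_pesticides must be >= 1")
        if self.n_samples_per_site < 1:
            raise InvalidConfigError("n_samples_per_site must be >= 1")
        lo, hi = self.detect_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("detect_freq_range must satisfy 0 <= lo <= hi <= 1")
        for name in ("loq", "control_juvenile_mean", "juvenile_dispersion", "tu50",
                     "slope", "synergy_lambda", "size_mean_mm", "size_sd_mm",
                     "survival_tu50_ratio"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name, val in (("survival_baseline", self.survival_baseline),
                          ("noec_effect_level", self.noec_effect_level),
                          ("size_effect_max", self.size_effect_max)):
            if not 0.0 < val <= 1.0:
                raise InvalidConfigError(f"{name} must be in (0, 1]")
        if self.n_replicates < 1 or self.n_introduced < 1:
            raise InvalidConfigError("n_replicates and n_introduced must be >= 1")
        # NOEC must sit strictly below the EC50 on the toxic-unit axis
        if self.noec_tu_ratio() >= 1.0:
            raise InvalidConfigError(
                "tu50/slope/noec_effect_level place the NOEC at or above the EC50"
            )

    def noec_tu_ratio(self) -> float:
        """NOEC / EC50 concentration ratio implied by the dose-response.

        For a single substance the inhibition at concentration C is
        f(C/EC50), so the concentration causing effect level q is
        EC50 · TU50 · (q/(1−q))^(1/slope).
        """
        q = self.noec_effect_level
        return self.tu50 * (q / (1.0 - q)) ** (1.0 / self.slope)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TrueState:
    """Ground truth recorded alongside every generated dataset.

    Used by recovery tests: any estimate the pipeline produces can be
    compared against the value that actually generated the data.
    """

    sites: tuple[str, ...]
    pesticides: tuple[str, ...]
    ec50: np.ndarray          # mg/kg, per pesticide
    noec: np.ndarray          # mg/kg, per pesticide (strictly < ec50)
    detect_freq: np.ndarray   # fraction, per pesticide
    site_lambda: np.ndarray   # synergy multiplier actually applied, per site

    def __post_init__(self):
        if not np.all(self.noec < self.ec50):
            raise InvalidConfigError("TrueState requires NOEC < EC50 for every pesticide")

    def ec50_of(self, pesticides: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.pesticides)}
        return np.array([self.ec50[index[p]] for p in pesticides])

    def noec_of(self, pesticides: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.pesticides)}
        return np.array([self.noec[index[p]] for p in pesticides])

    def lambda_of(self, site: str) -> float:
        try:
            return float(self.site_lambda[self.sites.index(site)])
        except ValueError:
            return float(self.site_lambda[0])


def _rng(config: SimConfig, stream: int, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stream, index))
    return np.random.default_rng(ss)


def site_names(config: SimConfig) -> list[str]:
    return [f"site_{i + 1:02d}" for i in range(config.n_sites)]


def pesticide_names(config: SimConfig) -> list[str]:
    return [f"pest_{i + 1:02d}" for i in range(config.n_pesticides)]


def draw_true_state(config: SimConfig) -> TrueState:
    """Draw the per-pesticide ground truth from the truth substream."""
    mu, sigma = config.ec50_lognormal_params
    lo, hi = config.detect_freq_range
    ec50 = np.empty(config.n_pesticides)
    freq = np.empty(config.n_pesticides)
    # per-pesticide substreams: adding pesticides leaves earlier draws intact
    for j in range(config.n_pesticides):
        rng = _rng(config, _STREAM_TRUTH, j)
        ec50[j] = rng.lognormal(mean=mu, sigma=sigma)
        freq[j] = rng.uniform(lo, hi)
    noec = ec50 * config.noec_tu_ratio()
    lam = np.full(config.n_sites, config.synergy_lambda, dtype=float)
    return TrueState(
        sites=tuple(site_names(config)),
        pesticides=tuple(pesticide_names(config)),
        ec50=ec50,
        noec=noec,
        detect_freq=freq,
        site_lambda=lam,
    )


def dose_response(tu, tu50: float, slope: float, synergy_lambda: float = 1.0):
    """Log-logistic inhibition fraction at toxic-unit load ``tu``.

    f = (λ·tu)^slope / (tu50^slope + (λ·tu)^slope), monotone non-decreasing
    in both ``tu`` and ``synergy_lambda``; f(0) = 0, f(tu50/λ) = 1/2.
    Accepts scalars or arrays.
    """
    if tu50 <= 0 or slope <= 0 or synergy_lambda <= 0:
        raise DomainError("tu50, slope and synergy_lambda must be > 0")
    tu_arr = np.asarray(tu, dtype=float)
    if np.any(tu_arr < 0):
        raise DomainError("toxic units must be >= 0")
    x = (synergy_lambda * tu_arr) ** slope
    out = x / (tu50 ** slope + x)
    return float(out) if np.isscalar(tu) or tu_arr.ndim == 0 else out


def gen_monitoring(config: SimConfig, truth: TrueState | None = None) -> pd.DataFrame:
    """Residue-monitoring table: one row per site × pesticide × sample.

    A sample is a detect with the pesticide's true frequency; detected
    concentrations are drawn from the configured lognormal truncated at the
    LOQ (so the realized detection frequency is unbiased).  Non-detects are
    flagged ``below_loq`` and carry the LOQ as the censoring sentinel.
    """
    truth = truth if truth is not None else draw_true_state(config)
    mu, sigma = config.conc_lognormal_params
    dist = _sps.lognorm(s=sigma, scale=np.exp(mu))
    f_loq = dist.cdf(config.loq)
    frames = []
    for j, pest in enumerate(truth.pesticides):
        rng = _rng(config, _STREAM_MONITORING, j)
        n = config.n_sites * config.n_samples_per_site
        detected = rng.random(n) < truth.detect_freq[j]
        # inverse-CDF draw truncated below at the LOQ
        u = rng.uniform(f_loq, 1.0, size=n)
        conc = dist.ppf(u)
        conc = np.where(detected, conc, config.loq)
        frames.append(pd.DataFrame({
            "site": np.repeat(truth.sites, config.n_samples_per_site),
            "pesticide": pest,
            "sample_id": np.tile(
                [f"s{k + 1:03d}" for k in range(config.n_samples_per_site)],
                config.n_sites,
            ),
            "concentration": np.round(conc, 6),
            "below_loq": ~detected,
        }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["site", "pesticide", "sample_id"], ignore_index=True)


def gen_ecotox_db(config: SimConfig, truth: TrueState | None = None) -> pd.DataFrame:
    """Ecotoxicity endpoint table consistent with the ground truth.

    Per pesticide: the springtail reproduction NOEC and EC50 equal the true
    values; an earthworm LC50 is added with a lognormal interspecies spread,
    so every pesticide has ≥ 1 NOEC and ≥ 1 L(E)C50 across ≥ 2 species.
    Springtail tests are booked against 5% organic-matter artificial soil.
    """
    truth = truth if truth is not None else draw_true_state(config)
    rng = _rng(config, _STREAM_ECOTOX)
    spread = rng.lognormal(mean=0.5, sigma=0.5, size=len(truth.pesticides))
    rows = []
    for j, pest in enumerate(truth.pesticides):
        rows.append((pest, "Folsomia candida", "NOEC", "reproduction",
                     truth.noec[j], 5.0, "synthetic"))
        rows.append((pest, "Folsomia candida", "EC50", "reproduction",
                     truth.ec50[j], 5.0, "synthetic"))
        rows.append((pest, "Eisenia fetida", "LC50", "survival",
                     truth.ec50[j] * spread[j], 5.0, "synthetic"))
    df = pd.DataFrame(rows, columns=[
        "pesticide", "species", "endpoint_type", "effect",
        "value", "soil_om_percent", "source",
    ])
    df["value"] = df["value"].round(6)
    return df


def gen_pesticide_info(config: SimConfig, truth: TrueState | None = None,
                       banned_fraction: float = 0.1) -> pd.DataFrame:
    """Pesticide property table: class, log Pow, DT50, approval end, rate.

    A ``banned_fraction`` of substances get an approval end date before
    September 2020 so the regulatory exclusion path is exercised.
    """
    truth = truth if truth is not None else draw_true_state(config)
    rng = _rng(config, _STREAM_INFO)
    n = len(truth.pesticides)
    classes = [PESTICIDE_CLASSES[i % len(PESTICIDE_CLASSES)] for i in range(n)]
    log_pow = np.round(rng.uniform(-1.0, 6.0, size=n), 2)
    dt50 = np.round(rng.lognormal(mean=3.0, sigma=1.0, size=n), 1)  # median ~20 d
    rate = np.round(rng.lognormal(mean=0.0, sigma=0.7, size=n), 3)  # kg a.s./ha
    banned = rng.random(n) < banned_fraction
    approval_end = ["2020-06-30" if b else "" for b in banned]
    return pd.DataFrame({
        "name": truth.pesticides,
        "class": classes,
        "log_pow": log_pow,
        "dt50_days": dt50,
        "approval_end_date": approval_end,
        "application_rate": rate,
    })


def exposure_levels_from_set(exposure) -> dict[str, dict[str, float]]:
    """Expand an ExposureSet into named levels including the two controls."""
    zeros = {p: 0.0 for p in exposure.pesticides}
    return {
        NEGATIVE_CONTROL: dict(zeros),
        SOLVENT_CONTROL: dict(zeros),
        "MEC": dict(exposure.mec),
        "PEC": dict(exposure.pec),
        "5PEC": dict(exposure.five_pec),
    }


def toxic_units(concentrations: Mapping[str, float], truth: TrueState) -> float:
    """Summed toxic units TU = Σ Cᵢ / EC50ᵢ under concentration addition."""
    index = {p: i for i, p in enumerate(truth.pesticides)}
    tu = 0.0
    for pest, conc in concentrations.items():
        if pest not in index:
            raise InvalidDesignError(f"pesticide {pest!r} not present in TrueState")
        if conc < 0:
            raise DomainError("concentrations must be >= 0")
        tu += conc / truth.ec50[index[pest]]
    return tu


def gen_reproduction_test(exposure, truth: TrueState, config: SimConfig,
                          site: str | None = None) -> pd.DataFrame:
    """Simulate one OECD-232 test over named exposure levels.

    ``exposure`` is either an ExposureSet (levels MEC/PEC/5PEC plus controls
    are built automatically) or a mapping ``level -> {pesticide: mg/kg}``
    that must already contain both control levels (at zero concentration).

    Per jar: ``adults_surviving ~ Binomial(introduced, p)`` with survival
    probability declining with toxic units on a less sensitive curve than
    reproduction; ``juveniles ~ NegBin`` with mean
    ``control_juvenile_mean × (1 − f(TU))``; adult sizes normal with the
    mean shrunk by ``size_effect_max × f_surv(TU)``.
    """
    if hasattr(exposure, "pesticides") and hasattr(exposure, "pec"):
        levels = exposure_levels_from_set(exposure)
        site = site or exposure.site
    else:
        levels = {k: dict(v) for k, v in exposure.items()}
        missing = [c for c in CONTROL_LEVELS if c not in levels]
        if missing:
            raise InvalidDesignError(f"missing control levels: {missing}")
    site = site or truth.sites[0]
    lam = truth.lambda_of(site)
    rng = _rng(config, _STREAM_REPRO, zlib.crc32(site.encode()))

    rows = []
    for level, concs in levels.items():
        tu = 0.0 if level in CONTROL_LEVELS else toxic_units(concs, truth)
        f_rep = dose_response(tu, config.tu50, config.slope, lam)
        f_surv = dose_response(tu, config.tu50 * config.survival_tu50_ratio,
                               config.slope, lam)
        n = config.n_replicates
        p_surv = config.survival_baseline * (1.0 - f_surv)
        adults = rng.binomial(config.n_introduced, p_surv, size=n)
        mean_juv = config.control_juvenile_mean * (1.0 - f_rep)
        if mean_juv > 0:
            k = config.juvenile_dispersion
            juveniles = rng.negative_binomial(k, k / (k + mean_juv), size=n)
        else:
            juveniles = np.zeros(n, dtype=int)
        size_mean = config.size_mean_mm * (1.0 - config.size_effect_max * f_surv)
        for r in range(n):
            sizes = rng.normal(size_mean, config.size_sd_mm, size=int(adults[r]))
            sizes = np.clip(sizes, 0.05, None)
            rows.append({
                "site": site,
                "treatment": level,
                "replicate": r + 1,
                "introduced": config.n_introduced,
                "adults_surviving": int(adults[r]),
                "juveniles": int(juveniles[r]),
                "adult_sizes": [round(float(s), 3) for s in sizes],
            })
    return pd.DataFrame(rows)


def pack_sizes(sizes: Sequence[float]) -> str:
    """Serialize a per-jar size list for CSV (semicolon-separated mm)."""
    return ";".join(f"{s:g}" for s in sizes)


def unpack_sizes(text) -> list[float]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    if isinstance(text, (list, tuple, np.ndarray)):
        return [float(s) for s in text]
    return [float(tok) for tok in str(text).split(";") if tok]


def write_dataset(out_dir, config: SimConfig, truth: TrueState | None = None) -> dict:
    """Write monitoring/ecotox/pesticide-info CSVs plus a JSON sidecar.

    The sidecar echoes every generator parameter and the seed so any file
    on disk can be traced back to the exact configuration that produced it.
    Returns the table paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = truth if truth is not None else draw_true_state(config)
    paths = {}
    tables = {
        "monitoring": gen_monitoring(config, truth),
        "ecotox": gen_ecotox_db(config, truth),
        "pesticide_info": gen_pesticide_info(config, truth),
    }
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    sidecar = {
        "generator": "mixrisk.synthetic",
        "config": config.to_dict(),
        "true_state": {
            "sites": list(truth.sites),
            "pesticides": list(truth.pesticides),
            "ec50_mg_kg": [float(x) for x in truth.ec50],
            "noec_mg_kg": [float(x) for x in truth.noec],
            "detect_freq": [float(x) for x in truth.detect_freq],
            "site_lambda": [float(x) for x in truth.site_lambda],
        },
    }
    (out / "params.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = str(out / "params.json")
    return paths
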