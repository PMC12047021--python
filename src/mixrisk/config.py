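"""Pipeline-wide configuration.

Every tunable constant of the analysis lives here with its default:
assessment factors used in screening, the soil-layer geometry behind PEC
conversion, the log Pow correction on NOECs, the worst-case multiplier,
ranking depth, regulatory ban cutoff, and the statistical settings of the
reproduction-test analysis.  The config is echoed (with a hash) into every
report so results are traceable to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field

from .errors import InvalidConfigError

P_ADJUST_METHODS = ("holm", "bonferroni", "fdr_bh", "none")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings shared across prioritization, exposure design, risk
    assessment and endpoint statistics.

    Attributes
    ----------
    assessment_factor_acute : float
        Divisor applied to LC50/EC50 endpoints during screening (default 10,
        the acute toxicity-exposure-ratio trigger for soil fauna).
    assessment_factor_chronic : float
        Divisor applied to NOEC endpoints during screening (default 5, the
        long-term trigger).
    noec_correction_factor : float
        Factor applied to NOECs of lipophilic substances (log Pow > 2) when
        the test soil is not the 5%-organic-matter artificial soil.
    soil_depth_cm, bulk_density_g_cm3 : float
        Mixing-layer geometry converting an application rate (kg a.s./ha)
        into an initial soil concentration (mg/kg dry soil).
    worst_case_factor : float
        Multiplier taking PEC to the worst-case exposure level (default 5).
    top_k : int
        Number of pesticides selected per site.
    ban_cutoff_date : datetime.date
        Substances whose approval ended before this date are excluded from
        selection.
    alpha : float
        Two-sided significance level of all tests.
    p_adjust : str
        Multiple-comparison adjustment for Dunn's test
        (holm / bonferroni / fdr_bh / none).
    use_nominal_concentrations : bool
        Whether risk quotients use nominal (True) or measured exposure
        concentrations.
    severe_inhibition_threshold : float
        Observed inhibition (percent) above which an effect is considered
        near-complete when judging mixtures against the additivity screen.
    severe_rq_threshold : float
        ∑RQ below which a near-complete inhibition is judged
        greater-than-expected.
    seed : int
        Seed for every stochastic stage.
    """

    assessment_factor_acute: float = 10.0
    assessment_factor_chronic: float = 5.0
    noec_correction_factor: float = 2.0
    soil_depth_cm: float = 5.0
    bulk_density_g_cm3: float = 1.5
    worst_case_factor: float = 5.0
    top_k: int = 5
    ban_cutoff_date: _dt.date = _dt.date(2020, 9, 1)
    alpha: float = 0.05
    p_adjust: str = "holm"
    use_nominal_concentrations: bool = True
    severe_inhibition_threshold: float = 90.0
    severe_rq_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self):
        positive = (
            "assessment_factor_acute",
            "assessment_factor_chronic",
            "noec_correction_factor",
            "soil_depth_cm",
            "bulk_density_g_cm3",
            "severe_rq_threshold",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.worst_case_factor < 0:
            raise InvalidConfigError("worst_case_factor must be >= 0")
        if self.top_k < 1:
            raise InvalidConfigError("top_k must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.p_adjust not in P_ADJUST_METHODS:
            raise InvalidConfigError(
                f"p_adjust must be one of {P_ADJUST_METHODS}, got {self.p_adjust!r}"
            )
        if isinstance(self.ban_cutoff_date, str):
            object.__setattr__(
                self, "ban_cutoff_date", _dt.date.fromisoformat(self.ban_cutoff_date)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ban_cutoff_date"] = self.ban_cutoff_date.isoformat()
        return d

    def hash(self) -> str:
        """Stable short hash of the configuration (for report provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)


DEFAULT_CONFIG = PipelineConfig()
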