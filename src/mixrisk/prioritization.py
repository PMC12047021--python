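"""Monitoring-based pesticide prioritization.

Ranks the pesticides detected at a site by the product of their detection
frequency (percent of soil samples with the residue above the LOQ) and
their *relative* screening risk quotient, then selects the top-k mixture.
The screening RQ divides the initial predicted environmental concentration
by the most sensitive soil-invertebrate effect value after assessment
factors (LC/EC50 ÷ 10, NOEC ÷ 5 by default).  Within a site the RQs are
rescaled to a percentage of the site maximum, so the priority score is
scale-free.  Substances whose approval ended before the regulatory cutoff
are excluded before ranking.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, MissingHazardError, UnsupportedEndpointError

ENDPOINT_TYPES = ("NOEC", "EC50", "LC50")


@dataclass(frozen=True)
class PesticideInfo:
    """Identity and fate/regulatory properties of one active substance."""

    name: str
    pesticide_class: str = "fungicide"   # fungicide / insecticide / herbicide / metabolite
    log_pow: float | None = None
    dt50_days: float | None = None
    approval_end_date: _dt.date | None = None
    application_rate: float | None = None  # kg a.s./ha

    def __post_init__(self):
        if self.dt50_days is not None and not self.dt50_days > 0:
            raise DomainError("dt50_days must be > 0 when present")
        if isinstance(self.approval_end_date, str):
            d = _dt.date.fromisoformat(self.approval_end_date) if self.approval_end_date else None
            object.__setattr__(self, "approval_end_date", d)


@dataclass(frozen=True)
class EcotoxEndpoint:
    """One hazard value for one species (mg a.s./kg dry soil)."""

    pesticide: str
    species: str
    endpoint_type: str     # NOEC / EC50 / LC50
    value: float
    effect: str = "other"  # reproduction / survival / other
    soil_om_percent: float | None = None
    source: str = ""

    def __post_init__(self):
        if not self.value > 0:
            raise DomainError("endpoint value must be > 0")


@dataclass
class ScreenScore:
    """Per-pesticide screening result within one site."""

    pesticide: str
    freq_percent: float = 0.0
    pec_initial: float = 0.0
    adjusted_hazard: float | None = None
    hazard_endpoint: EcotoxEndpoint | None = None
    rq: float = 0.0
    rel_rq_percent: float = 0.0
    selected: bool = False
    excluded_reason: str | None = None

    @property
    def priority(self) -> float:
        return self.freq_percent * self.rel_rq_percent


@dataclass
class MixtureSelection:
    site: str
    scores: list[ScreenScore]
    k: int
    shortfall: bool = False

    @property
    def selected(self) -> list[str]:
        return [s.pesticide for s in self.scores if s.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "site": self.site,
            "pesticide": s.pesticide,
            "freq_percent": s.freq_percent,
            "pec_initial": s.pec_initial,
            "adjusted_hazard": s.adjusted_hazard,
            "rq": s.rq,
            "rel_rq_percent": s.rel_rq_percent,
            "priority": s.priority,
            "selected": s.selected,
            "excluded_reason": s.excluded_reason or "",
        } for s in self.scores])


def adjust_hazard(endpoint: EcotoxEndpoint, af_acute: float = 10.0,
                  af_chronic: float = 5.0) -> float:
    """Assessment-factor-adjusted effect concentration.

    L(E)C50 values are divided by the acute factor (default 10), NOECs by
    the chronic factor (default 5).
    """
    if endpoint.endpoint_type == "NOEC":
        return endpoint.value / af_chronic
    if endpoint.endpoint_type in ("EC50", "LC50"):
        return endpoint.value / af_acute
    raise UnsupportedEndpointError(
        f"unsupported endpoint type {endpoint.endpoint_type!r} (expected NOEC/EC50/LC50)"
    )


def detection_frequency(monitoring: pd.DataFrame, per_site: bool = True) -> pd.DataFrame:
    """Percent of samples with a detect, per (site,) pesticide.

    Rows flagged ``below_loq`` count as non-detected.  With
    ``per_site=False`` the frequency is pooled over the whole campaign.
    """
    detected = ~monitoring["below_loq"].astype(bool)
    df = monitoring.assign(_det=detected.astype(float))
    keys = ["site", "pesticide"] if per_site else ["pesticide"]
    out = df.groupby(keys, as_index=False)["_det"].mean()
    out["freq_percent"] = 100.0 * out.pop("_det")
    return out


def screening_rq(pec_initial: float, endpoints: list[EcotoxEndpoint],
                 af_acute: float = 10.0, af_chronic: float = 5.0,
                 pesticide: str = "?") -> ScreenScore:
    """Screening risk quotient of one pesticide.

    RQ = PEC_initial / min over endpoints of the adjusted hazard; the
    minimal endpoint is recorded.  An empty endpoint list raises
    :class:`MissingHazardError` carrying the pesticide name.
    """
    if pec_initial < 0:
        raise DomainError("pec_initial must be >= 0")
    if not endpoints:
        raise MissingHazardError(pesticide)
    adjusted = [(adjust_hazard(e, af_acute, af_chronic), e) for e in endpoints]
    min_adj, min_ep = min(adjusted, key=lambda t: t[0])
    return ScreenScore(
        pesticide=pesticide,
        pec_initial=pec_initial,
        adjusted_hazard=min_adj,
        hazard_endpoint=min_ep,
        rq=pec_initial / min_adj,
    )


def relative_rq(scores: list[ScreenScore]) -> list[ScreenScore]:
    """Fill ``rel_rq_percent`` = 100 × rq / max(rq) within the site.

    If every RQ is zero all relative RQs are set to zero (ranking then
    degrades to frequency only).
    """
    if not scores:
        raise DomainError("relative_rq requires at least one score")
    max_rq = max(s.rq for s in scores)
    for s in scores:
        s.rel_rq_percent = 100.0 * s.rq / max_rq if max_rq > 0 else 0.0
    return scores


def rank_and_select(scores: list[ScreenScore], infos: dict[str, PesticideInfo],
                    k: int = 5,
                    ban_cutoff: _dt.date = _dt.date(2020, 9, 1)) -> MixtureSelection:
    """Exclude banned substances, rank by priority and flag the top-k.

    Priority = freq_percent × rel_rq_percent.  Ties break on higher
    detection frequency, then lexicographic name, so the selection is
    deterministic and invariant to input row order.  Fewer than ``k``
    eligible pesticides yields all of them plus a shortfall flag.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    site = "?"
    for s in scores:
        info = infos.get(s.pesticide)
        end = info.approval_end_date if info else None
        if end is not None and end < ban_cutoff:
            s.excluded_reason = "banned"
            s.selected = False
    eligible = [s for s in scores if s.excluded_reason is None]
    ranked = sorted(eligible, key=lambda s: (-s.priority, -s.freq_percent, s.pesticide))
    for i, s in enumerate(ranked):
        s.selected = i < k
    ordered = ranked + [s for s in scores if s.excluded_reason is not None]
    return MixtureSelection(site=site, scores=ordered, k=k,
                            shortfall=len(eligible) < k)


def screen_site(site: str, monitoring: pd.DataFrame,
                endpoints_by_pesticide: dict[str, list[EcotoxEndpoint]],
                pec_by_pesticide: dict[str, float],
                infos: dict[str, PesticideInfo],
                k: int = 5, ban_cutoff: _dt.date = _dt.date(2020, 9, 1),
                af_acute: float = 10.0, af_chronic: float = 5.0,
                per_site_frequency: bool = True) -> MixtureSelection:
    """Convenience wrapper running the full screening for one site."""
    freq = detection_frequency(monitoring, per_site=per_site_frequency)
    if per_site_frequency:
        freq = freq[freq["site"] == site]
    fmap = dict(zip(freq["pesticide"], freq["freq_percent"]))
    scores = []
    for pest, f in sorted(fmap.items()):
        score = screening_rq(
            pec_by_pesticide.get(pest, 0.0),
            endpoints_by_pesticide.get(pest, []),
            af_acute=af_acute, af_chronic=af_chronic, pesticide=pest,
        )
        score.freq_percent = float(f)
        scores.append(score)
    relative_rq(scores)
    selection = rank_and_select(scores, infos, k=k, ban_cutoff=ban_cutoff)
    selection.site = site
    return selection
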