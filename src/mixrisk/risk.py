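"""NOEC-based mixture risk quotients and outcome classification.

The concentration-addition screen divides each component's nominal
exposure concentration by its springtail-reproduction NOEC and sums the
quotients (∑RQ).  NOECs of lipophilic substances (log Pow > 2) are halved
unless they come from the 5%-organic-matter artificial soil.  A mixture's
observed outcome (significance and percent inhibition of reproduction) is
then classified against the ∑RQ expectation: an effect where ∑RQ ≤ 1, or
a near-complete inhibition where ∑RQ is only modestly above 1, counts as
greater than expected under additivity — the signature of synergy the
screen is meant to flag.  Components without a NOEC contribute zero, so a
tainted ∑RQ is a lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError, InvalidDesignError

logger = logging.getLogger(__name__)

CLASSIFICATIONS = (
    "consistent-no-effect",
    "consistent-effect",
    "greater-than-expected",
    "less-than-expected",
    "indeterminate",
)


@dataclass(frozen=True)
class ComponentRQ:
    pesticide: str
    exposure_concentration: float   # mg/kg nominal
    noec_used: float | None         # mg/kg, after any correction
    rq: float
    correction_applied: bool = False
    missing_noec: bool = False


@dataclass
class MixtureAssessment:
    site: str
    level: str
    components: list[ComponentRQ]
    sum_rq: float
    any_missing: bool
    observed_inhibition_percent: float | None = None
    significant_effect: bool | None = None
    classification: str = "indeterminate"

    def component_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "pesticide": c.pesticide,
            "concentration_mg_kg": c.exposure_concentration,
            "noec_mg_kg": c.noec_used,
            "rq": c.rq,
            "correction_applied": c.correction_applied,
            "missing_noec": c.missing_noec,
        } for c in self.components])


def correct_noec(noec: float, log_pow: float | None,
                 test_soil_om_percent: float | None = None,
                 factor: float = 2.0) -> tuple[float, bool]:
    """Organic-matter correction of a reproduction NOEC.

    Substances with log Pow > 2 sorb to organic matter; their NOECs from
    tests in soils other than the 5%-OM artificial soil are divided by
    ``factor`` (default 2).  Unknown organic-matter content is treated as
    not-5% (correction applied — the conservative reading).  Returns the
    corrected value and a flag; the flag guards re-application, making the
    correction idempotent at the caller.
    """
    if not noec > 0:
        raise DomainError("noec must be > 0")
    if log_pow is not None and log_pow > 2 and test_soil_om_percent != 5:
        return noec / factor, True
    return noec, False


def component_rq(pesticide: str, concentration: float,
                 noec: float | None,
                 correction_applied: bool = False) -> ComponentRQ:
    """Risk quotient of one mixture component.

    RQ = nominal exposure concentration / NOEC.  A missing NOEC yields
    RQ = 0 with ``missing_noec`` set (and a logged warning): the component
    cannot raise the sum, so ∑RQ becomes a lower bound.
    """
    if concentration < 0:
        raise DomainError("concentration must be >= 0")
    if noec is None:
        logger.warning("no NOEC for %s; component contributes 0 to the sum", pesticide)
        return ComponentRQ(pesticide, concentration, None, 0.0,
                           correction_applied=False, missing_noec=True)
    if noec <= 0:
        raise DomainError("noec must be > 0")
    return ComponentRQ(pesticide, concentration, noec, concentration / noec,
                       correction_applied=correction_applied)


def sum_rq(concentrations: Mapping[str, float],
           noec_table: Mapping[str, float | None],
           site: str = "?", level: str = "?") -> MixtureAssessment:
    """∑RQ of one exposure level: the component quotients in input order
    and their sum.  Pesticides absent from ``noec_table`` count as missing
    NOECs.  An empty mixture is an error.
    """
    if not concentrations:
        raise InvalidDesignError("empty mixture")
    comps = [component_rq(p, c, noec_table.get(p)) for p, c in concentrations.items()]
    return MixtureAssessment(
        site=site, level=level, components=comps,
        sum_rq=sum(c.rq for c in comps),
        any_missing=any(c.missing_noec for c in comps),
    )


def classify_outcome(assessment: MixtureAssessment,
                     significant_effect: bool | None = None,
                     inhibition_percent: float | None = None,
                     severe_inhibition_threshold: float = 90.0,
                     severe_rq_threshold: float = 5.0) -> str:
    """Classify one mixture × level against the additivity expectation.

    Rules, in order:

    1. ∑RQ ≤ 1 and no significant effect → ``consistent-no-effect``;
    2. ∑RQ ≤ 1 but a significant effect → ``greater-than-expected``;
    3. ∑RQ > 1 with a significant effect whose inhibition reaches
       ``severe_inhibition_threshold`` (default 90%) while
       ∑RQ < ``severe_rq_threshold`` (default 5) → ``greater-than-expected``
       (NOEC-level quotients should not produce near-complete inhibition);
    4. ∑RQ > 1 with a significant effect otherwise → ``consistent-effect``;
    5. ∑RQ > 1 without a significant effect → ``less-than-expected``.

    Missing endpoint data → ``indeterminate``.  The assessment is updated
    in place and the classification returned.
    """
    if significant_effect is None:
        significant_effect = assessment.significant_effect
    if inhibition_percent is None:
        inhibition_percent = assessment.observed_inhibition_percent
    if inhibition_percent is not None and inhibition_percent > 100.0:
        raise DomainError("inhibition cannot exceed 100%")
    if significant_effect is None or (significant_effect and inhibition_percent is None):
        label = "indeterminate"
    elif assessment.sum_rq <= 1.0:
        label = "greater-than-expected" if significant_effect else "consistent-no-effect"
    elif significant_effect:
        severe = (inhibition_percent >= severe_inhibition_threshold
                  and assessment.sum_rq < severe_rq_threshold)
        label = "greater-than-expected" if severe else "consistent-effect"
    else:
        label = "less-than-expected"
    assessment.significant_effect = significant_effect
    assessment.observed_inhibition_percent = inhibition_percent
    assessment.classification = label
    return label
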