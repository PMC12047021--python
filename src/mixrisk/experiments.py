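"""Calibration studies and fixture-based computations.

These are the package's own end-to-end checks, reused by the test suite
and by ``scripts/acceptance.py``:

* ``null_calibration`` — size of the omnibus test on fully null
  reproduction tests (no toxic pressure anywhere);
* ``synergy_contrast`` — how often the outcome classifier calls a site
  greater-than-expected under pure concentration addition (λ = 1) versus
  under a three-fold synergy (λ = 3), with target ∑RQ drawn uniformly on
  (1, 5] and true NOECs at the 30% single-substance effect level;
* ``fixture_assessments`` — ∑RQ of the bundled case-study exposure table
  against the in-text NOEC subset.

The study sizes below (500 simulated tests/sites per condition) are the
package's reference conditions; both helpers accept smaller counts for
quick exploration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import exposure as _exp
from . import risk as _risk
from . import stats as _stats
from . import synthetic as _syn

_STREAM_TARGETS = 10  # substream for per-site target draws


def _study_config(seed: int, synergy_lambda: float = 1.0,
                  **overrides) -> _syn.SimConfig:
    base = dict(n_sites=1, n_pesticides=5, synergy_lambda=synergy_lambda, seed=seed)
    base.update(overrides)
    return _syn.SimConfig(**base)


def null_calibration(n_tests: int = 500, seed: int = 0, alpha: float = 0.05,
                     config: _syn.SimConfig | None = None) -> dict:
    """Rejection rate of the reproduction omnibus test on null tests.

    Every exposure level carries zero toxic units, so all jars are drawn
    from the control distribution; the omnibus Kruskal-Wallis across the
    gated control and the three levels should reject at ~alpha.
    """
    config = config or _study_config(seed)
    truth = _syn.draw_true_state(config)
    zeros = {p: 0.0 for p in truth.pesticides}
    levels = {
        _syn.NEGATIVE_CONTROL: zeros, _syn.SOLVENT_CONTROL: zeros,
        "MEC": zeros, "PEC": zeros, "5PEC": zeros,
    }
    rejections = 0
    for i in range(n_tests):
        jars = _syn.gen_reproduction_test(levels, truth, config,
                                          site=f"null_{seed}_{i:04d}")
        reports = _stats.analyze_test(jars, alpha=alpha)
        if reports["reproduction"].omnibus.pvalue < alpha:
            rejections += 1
    return {"n_tests": n_tests, "alpha": alpha,
            "rejection_rate": rejections / n_tests}


def synergy_contrast(n_sites: int = 500, synergy_lambda: float = 1.0,
                     seed: int = 0, rq_range: tuple[float, float] = (1.0, 5.0),
                     config: _syn.SimConfig | None = None) -> dict:
    """Greater-than-expected rate over simulated single-level sites.

    Per site: five equitoxic components at a target ∑RQ drawn uniformly on
    ``rq_range``; a reproduction test (one treatment level plus both
    controls, 5 jars each) is simulated with the site's synergy multiplier,
    analyzed, and the outcome classified against ∑RQ with the default
    thresholds.  Returns the classification counts.
    """
    config = (config or _study_config(seed)).replace(synergy_lambda=synergy_lambda)
    truth = _syn.draw_true_state(config)
    ratio = config.noec_tu_ratio()  # NOEC position: sum_rq = TU / ratio
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STREAM_TARGETS, int(round(synergy_lambda * 1000)))))
    lo, hi = rq_range
    targets = rng.uniform(lo, hi, size=n_sites)
    noec_table = dict(zip(truth.pesticides, truth.noec))
    zeros = {p: 0.0 for p in truth.pesticides}

    counts: dict[str, int] = {}
    for i, target in enumerate(targets):
        tu = ratio * target
        concs = {p: tu / len(truth.pesticides) * truth.ec50_of([p])[0]
                 for p in truth.pesticides}
        levels = {_syn.NEGATIVE_CONTROL: zeros, _syn.SOLVENT_CONTROL: zeros,
                  "PEC": concs}
        jars = _syn.gen_reproduction_test(
            levels, truth, config, site=f"contrast_{synergy_lambda:g}_{seed}_{i:04d}")
        report = _stats.analyze_test(jars)["reproduction"]
        row = report.table.set_index("treatment").loc["PEC"]
        assessment = _risk.sum_rq(concs, noec_table, site=f"s{i}", level="PEC")
        label = _risk.classify_outcome(
            assessment, bool(row["significant"]),
            100.0 - float(row["percent_of_control"]))
        counts[label] = counts.get(label, 0) + 1
    gte = counts.get("greater-than-expected", 0)
    return {
        "n_sites": n_sites, "synergy_lambda": synergy_lambda,
        "rq_range": list(rq_range), "counts": counts,
        "greater_than_expected_rate": gte / n_sites,
    }


def fixture_assessments(noecs: dict[str, float] | None = None) -> pd.DataFrame:
    """∑RQ of every bundled case-study site × level.

    Uses the in-text NOEC subset by default; components without a NOEC
    contribute zero, so sums are lower bounds (flagged).
    """
    noecs = noecs if noecs is not None else _exp.load_intext_noecs()
    table = _exp.load_table1()
    sets = _exp.exposure_sets_from_table(table)
    rows = []
    for site, exposure in sets.items():
        for level in _exp.EXPOSURE_LEVELS:
            a = _risk.sum_rq(exposure.level(level), noecs, site=site, level=level)
            rows.append({
                "site": site, "level": level, "sum_rq": a.sum_rq,
                "lower_bound": a.any_missing,
                "n_components_with_noec": sum(not c.missing_noec for c in a.components),
            })
    return pd.DataFrame(rows)
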