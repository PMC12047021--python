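"""OECD-232 reproduction-test statistics.

Implements the analysis applied to each collembolan test: guideline
validity criteria on the controls, a gate deciding whether treatments are
compared against the solvent or the negative control, a tie-corrected
Kruskal-Wallis omnibus test, Dunn's rank-based multiple comparisons
against the control, and percent-of-control effect summaries.

P-values
--------
With the guideline's five jars per group, the chi-square / normal
approximations behind Kruskal-Wallis and Dunn's test are poor.  Both
tests therefore compute an *exact* permutation p-value by enumerating
every distinct assignment of the pooled observations to groups whenever
that enumeration is small enough (``method="auto"``), falling back to the
asymptotic approximation for larger designs.  Tie structure is
permutation-invariant, so the enumeration only needs rank sums.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InvalidDesignError
from .synthetic import CONTROL_LEVELS, NEGATIVE_CONTROL, SOLVENT_CONTROL, unpack_sizes

ENDPOINTS = ("survival", "reproduction", "size")

#: validity criteria on control jars (guideline thresholds, strict)
SURVIVAL_THRESHOLD = 0.8
JUVENILE_THRESHOLD = 100.0
CV_THRESHOLD_PERCENT = 30.0

DEFAULT_MAX_EXACT = 200_000


@dataclass(frozen=True)
class KWResult:
    statistic: float
    df: int
    pvalue: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class DunnComparison:
    group: object          # label of the compared group
    n: int
    mean_rank: float
    z: float
    pvalue: float          # raw two-sided
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class ValidityReport:
    n_jars: int
    survival_fraction: float
    mean_juveniles: float
    cv_juveniles_percent: float
    survival_ok: bool
    juveniles_ok: bool
    cv_ok: bool

    @property
    def overall(self) -> bool:
        return self.survival_ok and self.juveniles_ok and self.cv_ok


@dataclass(frozen=True)
class GateResult:
    control_used: str              # "solvent", "negative" or "both"
    pvalues: dict
    warnings: tuple[str, ...] = ()


@dataclass
class EndpointReport:
    endpoint: str
    control_used: str
    valid: bool
    omnibus: KWResult
    table: pd.DataFrame            # per-treatment mean / percent_of_control / n
    comparisons: list[DunnComparison]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rank machinery

def _clean_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float).ravel() for g in groups]


def _n_arrangements(sizes) -> int:
    total = math.factorial(sum(sizes))
    for n in sizes:
        total //= math.factorial(n)
    return total


def _tie_stats(ranks_pooled: np.ndarray) -> tuple[float, float]:
    """Return (ΣT, tie correction divisor 1 − ΣT/(N³−N))."""
    N = ranks_pooled.size
    _, counts = np.unique(ranks_pooled, return_counts=True)
    sum_t = float(np.sum(counts.astype(float) ** 3 - counts))
    denom = N ** 3 - N
    return sum_t, 1.0 - (sum_t / denom if denom > 0 else 0.0)


def _h_statistic(rank_sums: np.ndarray, sizes: np.ndarray, N: int,
                 tie_divisor: float) -> np.ndarray:
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums ** 2 / sizes, axis=-1) - 3.0 * (N + 1)
    return h / tie_divisor


def _rank_sum_table(ranks: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Rank sums per group for every distinct assignment of the pooled
    observations to groups of the given sizes; shape (n_arrangements, k)."""
    out = []

    def rec(indices: tuple, acc: list):
        if len(acc) == len(sizes) - 1:
            acc.append(float(ranks[list(indices)].sum()))
            out.append(tuple(acc))
            acc.pop()
            return
        size = sizes[len(acc)]
        for combo in itertools.combinations(indices, size):
            chosen = set(combo)
            acc.append(float(ranks[list(combo)].sum()))
            rec(tuple(i for i in indices if i not in chosen), acc)
            acc.pop()

    rec(tuple(range(ranks.size)), [])
    return np.asarray(out)


def kruskal_wallis(groups, method: str = "auto",
                   max_exact: int = DEFAULT_MAX_EXACT) -> KWResult:
    """Tie-corrected Kruskal-Wallis test.

    H is computed on mid-ranks with the tie correction divisor
    1 − ΣT/(N³−N); df = k − 1.  ``method`` selects the p-value: "exact"
    enumerates the permutation distribution of H, "asymptotic" uses the
    chi-square upper tail, "auto" picks exact whenever the number of
    distinct arrangements is at most ``max_exact``.  A completely tied
    sample yields H = 0 and p = 1 (not an error).
    """
    gs = _clean_groups(groups)
    if len(gs) < 2:
        raise InvalidDesignError("kruskal_wallis requires >= 2 groups")
    if any(g.size == 0 for g in gs):
        raise InvalidDesignError("kruskal_wallis requires >= 1 observation per group")
    sizes = [g.size for g in gs]
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, df, 1.0, "degenerate")
    ranks = _sps.rankdata(pooled)
    N = pooled.size
    _, tie_div = _tie_stats(ranks)
    bounds = np.cumsum([0] + sizes)
    obs_sums = np.array([ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(gs))])
    h_obs = float(_h_statistic(obs_sums, np.array(sizes, float), N, tie_div))

    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (
        method == "auto" and _n_arrangements(sizes) <= max_exact
    )
    if use_exact:
        table = _rank_sum_table(ranks, sizes)
        h_all = _h_statistic(table, np.array(sizes, float), N, tie_div)
        p = float(np.mean(h_all >= h_obs - 1e-9))
        return KWResult(h_obs, df, p, "exact")
    p = float(_sps.chi2.sf(h_obs, df))
    return KWResult(h_obs, df, p, "asymptotic")


def dunn_posthoc(groups, control_index: int = 0, adjust: str = "holm",
                 alpha: float = 0.05, method: str = "auto",
                 max_exact: int = DEFAULT_MAX_EXACT,
                 labels=None) -> list[DunnComparison]:
    """Dunn's rank comparisons of every group against the control group.

    z = (mean-rank difference) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/nᵢ + 1/n_c)]
    on the mid-ranks of the pooled sample.  Two-sided p-values come from
    the exact permutation distribution of the mean-rank difference when the
    design is small (see module docstring), otherwise from the normal
    approximation.  Adjustment: holm (default), bonferroni, fdr_bh or none.
    Groups with zero observations are skipped with a warning.
    """
    gs = _clean_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    if not 0 <= control_index < len(gs):
        raise InvalidDesignError("control_index out of range")
    if gs[control_index].size == 0:
        raise InvalidDesignError("control group has no observations")

    keep, skipped = [], []
    for i, g in enumerate(gs):
        (keep if g.size > 0 else skipped).append(i)
    for i in skipped:
        warnings.warn(f"group {labels[i]!r} has no observations; comparison skipped")
    gs = [gs[i] for i in keep]
    labels = [labels[i] for i in keep]
    control_index = keep.index(control_index)

    sizes = [g.size for g in gs]
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = _sps.rankdata(pooled)
    sum_t, _ = _tie_stats(ranks)
    var_factor = N * (N + 1) / 12.0 - sum_t / (12.0 * (N - 1)) if N > 1 else 0.0
    bounds = np.cumsum([0] + sizes)
    mean_ranks = np.array([
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(gs))
    ])

    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (
        method == "auto" and _n_arrangements(sizes) <= max_exact
    )
    table = _rank_sum_table(ranks, sizes) if use_exact else None

    comps = []
    n_c = sizes[control_index]
    for i in range(len(gs)):
        if i == control_index:
            continue
        diff = mean_ranks[i] - mean_ranks[control_index]
        se = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / n_c))
        z = diff / se if se > 0 else 0.0
        if se == 0.0:
            p = 1.0
        elif use_exact:
            d_all = table[:, i] / sizes[i] - table[:, control_index] / n_c
            p = float(np.mean(np.abs(d_all) >= abs(diff) - 1e-9))
        else:
            p = float(2.0 * _sps.norm.sf(abs(z)))
        comps.append((labels[i], sizes[i], float(mean_ranks[i]), float(z), p))

    raw = [c[4] for c in comps]
    if adjust == "none" or not raw:
        adj = list(raw)
    else:
        adj = list(multipletests(raw, alpha=alpha, method=adjust)[1])
    return [
        DunnComparison(lab, n, mr, z, p, min(1.0, float(pa)), bool(pa < alpha))
        for (lab, n, mr, z, p), pa in zip(comps, adj)
    ]


# ---------------------------------------------------------------------------
# guideline checks and full-test analysis

def _jar_endpoint_values(jars: pd.DataFrame, endpoint: str) -> np.ndarray:
    """Per-jar value of an endpoint; size uses the jar-mean of adult sizes
    (the jar, not the animal, is the unit of replication)."""
    if endpoint == "survival":
        return jars["adults_surviving"].to_numpy(dtype=float)
    if endpoint == "reproduction":
        return jars["juveniles"].to_numpy(dtype=float)
    if endpoint == "size":
        vals = []
        for s in jars["adult_sizes"]:
            sizes = unpack_sizes(s)
            if sizes:
                vals.append(float(np.mean(sizes)))
        return np.asarray(vals, dtype=float)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def validity_check(control_jars: pd.DataFrame,
                   survival_threshold: float = SURVIVAL_THRESHOLD,
                   juvenile_threshold: float = JUVENILE_THRESHOLD,
                   cv_threshold_percent: float = CV_THRESHOLD_PERCENT) -> ValidityReport:
    """Guideline validity criteria evaluated on control jars.

    Mean adult survival must exceed 80% of introduced animals, mean
    juveniles per jar must exceed 100, and the CV of juvenile counts must
    stay below 30%.  Thresholds are strict inequalities: a control set
    sitting exactly on a threshold fails that criterion.
    """
    if control_jars is None or len(control_jars) < 2:
        raise InvalidDesignError("validity_check requires >= 2 control jars")
    surv = (control_jars["adults_surviving"] / control_jars["introduced"]).mean()
    juv = control_jars["juveniles"].to_numpy(dtype=float)
    mean_juv = float(juv.mean())
    cv = float(juv.std(ddof=1) / mean_juv * 100.0) if mean_juv > 0 else float("inf")
    return ValidityReport(
        n_jars=len(control_jars),
        survival_fraction=float(surv),
        mean_juveniles=mean_juv,
        cv_juveniles_percent=cv,
        survival_ok=bool(surv > survival_threshold),
        juveniles_ok=bool(mean_juv > juvenile_threshold),
        cv_ok=bool(cv < cv_threshold_percent),
    )


def control_gate(negative_jars: pd.DataFrame | None,
                 solvent_jars: pd.DataFrame | None,
                 alpha: float = 0.05,
                 endpoints=ENDPOINTS) -> GateResult:
    """Decide which control the treatments are compared against.

    Runs a two-group rank test (exact where feasible) per endpoint between
    the negative and solvent controls.  If no endpoint differs at ``alpha``
    the solvent control alone is used; otherwise both controls are
    retained and a warning is raised.  With one control missing, the
    available one is used with a warning.
    """
    notes = []
    has_neg = negative_jars is not None and len(negative_jars) > 0
    has_solv = solvent_jars is not None and len(solvent_jars) > 0
    if not has_neg and not has_solv:
        raise InvalidDesignError("no control jars supplied")
    if not has_solv:
        notes.append("solvent control absent; negative control used")
        return GateResult("negative", {}, tuple(notes))
    if not has_neg:
        notes.append("negative control absent; solvent control used")
        return GateResult("solvent", {}, tuple(notes))

    pvals = {}
    for ep in endpoints:
        a = _jar_endpoint_values(negative_jars, ep)
        b = _jar_endpoint_values(solvent_jars, ep)
        if a.size == 0 or b.size == 0:
            continue
        pvals[ep] = kruskal_wallis([a, b]).pvalue
    if any(p < alpha for p in pvals.values()):
        sig = [ep for ep, p in pvals.items() if p < alpha]
        notes.append(
            "negative and solvent controls differ for "
            f"{', '.join(sig)} (p < {alpha:g}); both controls retained"
        )
        return GateResult("both", pvals, tuple(notes))
    return GateResult("solvent", pvals, tuple(notes))


def percent_of_control(treatment_mean: float, control_mean: float) -> float:
    """Treatment response as percent of the control; 100 − result is the
    inhibition."""
    if control_mean <= 0:
        raise DomainError("control mean must be > 0 for percent-of-control")
    return 100.0 * treatment_mean / control_mean


def analyze_test(jars: pd.DataFrame, alpha: float = 0.05, p_adjust: str = "holm",
                 treatment_order=None,
                 p_method: str = "auto") -> dict[str, EndpointReport]:
    """Full analysis of one reproduction test.

    Runs the validity check on the control jars and the control gate, then
    for each endpoint (survival, reproduction, size) a Kruskal-Wallis
    omnibus over the gated control plus all treatments, and Dunn's
    comparisons of each treatment against that control.  A failed validity
    check does not stop the analysis; the reports are marked invalid.
    Missing size data skips the size report with a warning.
    """
    if "treatment" not in jars.columns:
        raise InvalidDesignError("jar table must have a 'treatment' column")
    levels = list(dict.fromkeys(jars["treatment"]))
    treatments = [t for t in levels if t not in CONTROL_LEVELS]
    if treatment_order:
        treatments = [t for t in treatment_order if t in treatments] + [
            t for t in treatments if t not in treatment_order
        ]
    if not treatments:
        raise InvalidDesignError("no treatment levels present")
    neg = jars[jars["treatment"] == NEGATIVE_CONTROL]
    solv = jars[jars["treatment"] == SOLVENT_CONTROL]
    gate = control_gate(neg if len(neg) else None, solv if len(solv) else None,
                        alpha=alpha)
    ref = solv if gate.control_used in ("solvent", "both") else neg
    ref_label = SOLVENT_CONTROL if gate.control_used in ("solvent", "both") else NEGATIVE_CONTROL
    validity = validity_check(ref)

    reports: dict[str, EndpointReport] = {}
    for ep in ENDPOINTS:
        notes = list(gate.warnings)
        control_vals = _jar_endpoint_values(ref, ep)
        group_vals = [_jar_endpoint_values(jars[jars["treatment"] == t], ep)
                      for t in treatments]
        if ep == "size" and (control_vals.size == 0 or all(g.size == 0 for g in group_vals)):
            warnings.warn("no adult size data; size endpoint skipped")
            continue
        usable = [(t, g) for t, g in zip(treatments, group_vals) if g.size > 0]
        dropped = [t for t, g in zip(treatments, group_vals) if g.size == 0]
        if dropped:
            notes.append(f"{ep}: no observations for {dropped}; level(s) skipped")
        if not usable or control_vals.size == 0:
            warnings.warn(f"endpoint {ep!r} has no analyzable groups; skipped")
            continue
        labels = [ref_label] + [t for t, _ in usable]
        groups = [control_vals] + [g for _, g in usable]
        # the retained negative control joins the omnibus only; Dunn's
        # comparisons stay on the gated control + treatments so a second
        # control group cannot dilute the treatment-vs-control rank contrast
        omnibus_groups = list(groups)
        if gate.control_used == "both" and len(neg):
            omnibus_groups.append(_jar_endpoint_values(neg, ep))
        omnibus = kruskal_wallis(omnibus_groups, method=p_method)
        comps = dunn_posthoc(groups, control_index=0, adjust=p_adjust, alpha=alpha,
                             method=p_method, labels=labels)
        ctrl_mean = float(control_vals.mean())
        rows = [{
            "treatment": ref_label, "n": control_vals.size, "mean": ctrl_mean,
            "percent_of_control": 100.0, "z": 0.0, "p_adjusted": 1.0,
            "significant": False,
        }]
        for (t, g), c in zip(usable, comps):
            rows.append({
                "treatment": t, "n": g.size, "mean": float(g.mean()),
                "percent_of_control": percent_of_control(float(g.mean()), ctrl_mean),
                "z": c.z, "p_adjusted": c.p_adjusted, "significant": c.significant,
            })
        if not validity.overall:
            notes.append("validity criteria not met; results are non-reportable")
        reports[ep] = EndpointReport(
            endpoint=ep,
            control_used=gate.control_used,
            valid=validity.overall,
            omnibus=omnibus,
            table=pd.DataFrame(rows),
            comparisons=comps,
            warnings=notes,
        )
    return reports
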