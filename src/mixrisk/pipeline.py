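"""The step-wise pipeline: prioritize → design → assess → analyze → classify.

``run_pipeline`` either simulates a full campaign (monitoring, hazard
database, pesticide properties, reproduction tests) from a single seed or
consumes user-supplied CSV tables, and produces one JSON-serializable
report per site plus a summary table.  Reports embed the configuration
hash and seed; identical inputs produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import exposure as _exp
from . import io as _io
from . import prioritization as _prio
from . import risk as _risk
from . import stats as _stats
from . import synthetic as _syn
from .config import PipelineConfig
from .errors import StageError, UndefinedMECError


@dataclass
class ReportBundle:
    config: dict
    config_hash: str
    seed: int
    sites: dict[str, dict]
    summary: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "warnings": self.warnings,
            "sites": sorted(self.sites),
        }
        (out / "bundle.json").write_text(
            json.dumps(_io.jsonify(header), indent=2, sort_keys=True) + "\n")
        for site, report in sorted(self.sites.items()):
            payload = dict(report)
            payload["config_hash"] = self.config_hash
            payload["seed"] = self.seed
            (out / f"site_{site}.json").write_text(
                json.dumps(_io.jsonify(payload), indent=2, sort_keys=True) + "\n")
        self.summary.to_csv(out / "summary.csv", index=False)
        return out


def _endpoints_from_df(ecotox: pd.DataFrame) -> dict[str, list[_prio.EcotoxEndpoint]]:
    out: dict[str, list[_prio.EcotoxEndpoint]] = {}
    for row in ecotox.itertuples(index=False):
        ep = _prio.EcotoxEndpoint(
            pesticide=row.pesticide, species=row.species,
            endpoint_type=row.endpoint_type, value=float(row.value),
            effect=getattr(row, "effect", "other"),
            soil_om_percent=(float(row.soil_om_percent)
                             if getattr(row, "soil_om_percent", None) is not None
                             and not pd.isna(row.soil_om_percent) else None),
            source=str(getattr(row, "source", "")),
        )
        out.setdefault(row.pesticide, []).append(ep)
    return out


def _infos_from_df(info: pd.DataFrame) -> dict[str, _prio.PesticideInfo]:
    def _opt(v):
        return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else v

    out = {}
    for row in info.to_dict(orient="records"):
        end = _opt(row.get("approval_end_date"))
        out[row["name"]] = _prio.PesticideInfo(
            name=row["name"],
            pesticide_class=_opt(row.get("class")) or "fungicide",
            log_pow=_opt(row.get("log_pow")),
            dt50_days=_opt(row.get("dt50_days")),
            approval_end_date=str(end) if end is not None else None,
            application_rate=_opt(row.get("application_rate")),
        )
    return out


def _reproduction_noecs(ecotox: pd.DataFrame,
                        infos: dict[str, _prio.PesticideInfo],
                        config: PipelineConfig) -> dict[str, float | None]:
    """Springtail-reproduction NOEC per pesticide, log Pow-corrected.

    Distinct from the multi-invertebrate hazard minimum used in screening.
    Pesticides without such a NOEC map to None (→ lower-bound ∑RQ).
    """
    noecs: dict[str, float | None] = {}
    mask = ((ecotox["endpoint_type"] == "NOEC")
            & (ecotox["effect"] == "reproduction")
            & (ecotox["species"].str.lower().str.contains("folsomia")))
    for pest, sub in ecotox[mask].groupby("pesticide"):
        row = sub.loc[sub["value"].idxmin()]
        info = infos.get(pest)
        om = row.get("soil_om_percent")
        om = None if om is None or pd.isna(om) else float(om)
        value, _ = _risk.correct_noec(
            float(row["value"]), info.log_pow if info else None, om,
            factor=config.noec_correction_factor)
        noecs[pest] = value
    return noecs


def run_pipeline(config: PipelineConfig | None = None,
                 sim: _syn.SimConfig | None = None,
                 inputs: dict | None = None,
                 simulate: bool = False) -> ReportBundle:
    """Execute the full pipeline.

    Either ``simulate=True`` (tables and reproduction tests generated from
    ``config.seed``) or ``inputs`` mapping table names
    (monitoring/ecotox/pesticide_info and optionally reproduction) to CSV
    paths.  Returns the report bundle; stage failures raise
    :class:`StageError` naming the stage.
    """
    config = config or PipelineConfig()
    notes: list[str] = []

    if simulate:
        sim = (sim or _syn.SimConfig(seed=config.seed)).replace(seed=config.seed)
        truth = _syn.draw_true_state(sim)
        monitoring = _syn.gen_monitoring(sim, truth)
        ecotox = _syn.gen_ecotox_db(sim, truth)
        info = _syn.gen_pesticide_info(sim, truth)
        jars_by_site = None  # generated per site after exposure design
    else:
        if not inputs:
            raise StageError("inputs", "either simulate=True or input paths required")
        for required in ("monitoring", "ecotox", "pesticide_info"):
            if required not in inputs:
                raise StageError("prioritization", f"missing {required} table")
        monitoring = _io.read_table(inputs["monitoring"], "monitoring")
        ecotox = _io.read_table(inputs["ecotox"], "ecotox")
        info = _io.read_table(inputs["pesticide_info"], "pesticide_info")
        truth = None
        jars_by_site = {}
        if "reproduction" in inputs:
            jars = _io.read_table(inputs["reproduction"], "reproduction")
            jars_by_site = {s: g for s, g in jars.groupby("site")}

    endpoints = _endpoints_from_df(ecotox)
    infos = _infos_from_df(info)
    pec_by_pesticide = {
        name: _exp.pec_from_rate(i.application_rate, config.soil_depth_cm,
                                 config.bulk_density_g_cm3)
        for name, i in infos.items() if i.application_rate is not None
    }
    noec_table = _reproduction_noecs(ecotox, infos, config)

    site_reports: dict[str, dict] = {}
    summary_rows = []
    for site in sorted(monitoring["site"].unique()):
        site_monitoring = monitoring[monitoring["site"] == site]
        try:
            selection = _prio.screen_site(
                site, site_monitoring, endpoints, pec_by_pesticide, infos,
                k=config.top_k, ban_cutoff=config.ban_cutoff_date,
                af_acute=config.assessment_factor_acute,
                af_chronic=config.assessment_factor_chronic)
        except Exception as exc:  # noqa: BLE001 — re-raise with stage tag
            raise StageError("prioritization", f"site {site}: {exc}") from exc

        mec, pec = {}, {}
        for pest in selection.selected:
            rows = site_monitoring[site_monitoring["pesticide"] == pest]
            try:
                mec[pest] = _exp.mec_from_monitoring(
                    rows["concentration"], rows["below_loq"])
            except UndefinedMECError:
                mec[pest] = 0.0
                notes.append(f"{site}: no detects for {pest}; MEC set to 0")
            pec[pest] = pec_by_pesticide.get(pest, 0.0)
        exposure_set = _exp.ExposureSet.from_pec(
            site, mec, pec, worst_case_factor=config.worst_case_factor)

        if simulate:
            jars = _syn.gen_reproduction_test(exposure_set, truth, sim, site=site)
        else:
            jars = jars_by_site.get(site) if jars_by_site else None

        endpoint_summary, repro_table = {}, None
        if jars is not None and len(jars):
            reports = _stats.analyze_test(jars, alpha=config.alpha,
                                          p_adjust=config.p_adjust)
            for ep, rep in reports.items():
                endpoint_summary[ep] = {
                    "valid": rep.valid,
                    "control_used": rep.control_used,
                    "H": rep.omnibus.statistic,
                    "df": rep.omnibus.df,
                    "pvalue": rep.omnibus.pvalue,
                    "treatments": rep.table,
                    "warnings": rep.warnings,
                }
            if "reproduction" in reports:
                repro_table = reports["reproduction"].table.set_index("treatment")

        assessments = {}
        for level in _exp.EXPOSURE_LEVELS:
            assessment = _risk.sum_rq(exposure_set.level(level), noec_table,
                                      site=site, level=level)
            significant = inhibition = None
            if repro_table is not None and level in repro_table.index:
                significant = bool(repro_table.loc[level, "significant"])
                inhibition = 100.0 - float(repro_table.loc[level, "percent_of_control"])
            _risk.classify_outcome(
                assessment, significant, inhibition,
                severe_inhibition_threshold=config.severe_inhibition_threshold,
                severe_rq_threshold=config.severe_rq_threshold)
            assessments[level] = assessment
            summary_rows.append({
                "site": site, "level": level,
                "sum_rq": assessment.sum_rq,
                "sum_rq_is_lower_bound": assessment.any_missing,
                "significant": significant,
                "inhibition_percent": inhibition,
                "classification": assessment.classification,
            })

        site_reports[site] = {
            "site": site,
            "selection": selection.to_frame(),
            "shortfall": selection.shortfall,
            "exposure": {
                "pesticides": list(exposure_set.pesticides),
                "mec": exposure_set.mec, "pec": exposure_set.pec,
                "five_pec": exposure_set.five_pec,
            },
            "assessments": {
                lvl: {
                    "sum_rq": a.sum_rq,
                    "any_missing": a.any_missing,
                    "components": a.component_frame(),
                    "significant_effect": a.significant_effect,
                    "observed_inhibition_percent": a.observed_inhibition_percent,
                    "classification": a.classification,
                    "thresholds": {
                        "severe_inhibition_percent": config.severe_inhibition_threshold,
                        "severe_sum_rq": config.severe_rq_threshold,
                    },
                } for lvl, a in assessments.items()
            },
            "endpoints": endpoint_summary,
        }

    summary = pd.DataFrame(summary_rows)
    return ReportBundle(
        config=config.to_dict(), config_hash=config.hash(), seed=config.seed,
        sites=site_reports, summary=summary, warnings=notes,
    )


def render_report(bundle: ReportBundle) -> str:
    """Human-readable per-site summary of a report bundle."""
    lines = [
        "mixture risk assessment report",
        f"config {bundle.config_hash}  seed {bundle.seed}",
        "",
    ]
    for site, rep in sorted(bundle.sites.items()):
        lines.append(f"=== {site} ===")
        sel = rep["selection"]
        chosen = sel[sel["selected"]]["pesticide"].tolist() if len(sel) else []
        lines.append(f"selected mixture: {', '.join(chosen) or '(none)'}"
                     + ("  [shortfall]" if rep.get("shortfall") else ""))
        for lvl, a in rep["assessments"].items():
            bound = " (lower bound: missing NOEC)" if a["any_missing"] else ""
            sig = a["significant_effect"]
            sig_txt = "n/a" if sig is None else ("significant" if sig else "n.s.")
            inh = a["observed_inhibition_percent"]
            inh_txt = "n/a" if inh is None else f"{inh:.1f}%"
            line = (f"  {lvl:>4}: sum RQ = {a['sum_rq']:.3g}{bound}; effect {sig_txt}; "
                    f"inhibition {inh_txt}; -> {a['classification']}")
            if a["classification"] == "greater-than-expected":
                t = a["thresholds"]
                line += (f" (thresholds: inhibition >= {t['severe_inhibition_percent']:g}%"
                         f" at sum RQ < {t['severe_sum_rq']:g})")
            lines.append(line)
        for ep, summ in rep.get("endpoints", {}).items():
            lines.append(
                f"  {ep}: H = {summ['H']:.3g} (df {summ['df']}), p = {summ['pvalue']:.3g}, "
                f"control = {summ['control_used']}, valid = {summ['valid']}")
        lines.append("")
    if bundle.warnings:
        lines.append("warnings:")
        lines += [f"  - {w}" for w in bundle.warnings]
    return "\n".join(lines)
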