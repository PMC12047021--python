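"""Run the whole step-wise pipeline on a simulated campaign.

One seed drives everything: monitoring tables, hazard database,
pesticide properties, per-site mixture selection, MEC/PEC/5PEC design,
reproduction tests, ∑RQ assessment and outcome classification.  The
rendered report shows, per site, the selected mixture, the ∑RQ at each
level and how the observed outcome compares with the additivity screen.
"""

from mixrisk import PipelineConfig, SimConfig, render_report, run_pipeline

config = PipelineConfig(seed=5)
sim = SimConfig(n_sites=3, n_pesticides=10, seed=5)
bundle = run_pipeline(config, sim=sim, simulate=True)

print(render_report(bundle))
print(bundle.summary.round(3).to_string(index=False))
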