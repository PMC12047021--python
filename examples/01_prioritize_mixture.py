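"""Rank pesticides at one site and select the test mixture.

Builds a tiny synthetic monitoring campaign, screens every detected
pesticide (detection frequency × relative risk quotient) and prints the
ranked table.  The five highest-priority, non-banned substances form the
mixture that would go into the reproduction tests.
"""

from mixrisk import (
    SimConfig,
    draw_true_state,
    gen_ecotox_db,
    gen_monitoring,
    gen_pesticide_info,
    pec_from_rate,
    screen_site,
)
from mixrisk.pipeline import _endpoints_from_df, _infos_from_df

config = SimConfig(n_sites=1, n_pesticides=10, n_samples_per_site=20, seed=42)
truth = draw_true_state(config)
monitoring = gen_monitoring(config, truth)
endpoints = _endpoints_from_df(gen_ecotox_db(config, truth))
infos = _infos_from_df(gen_pesticide_info(config, truth))
pecs = {n: pec_from_rate(i.application_rate) for n, i in infos.items()}

selection = screen_site("site_01", monitoring, endpoints, pecs, infos, k=5)
print(selection.to_frame().round(3).to_string(index=False))
print()
print("selected mixture:", ", ".join(selection.selected))
# priority = detection frequency (%) × RQ relative to the site maximum (%);
# the top five eligible rows are the mixture taken forward to testing.
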