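"""Scoring TMB and MSI on one synthetic specimen.

TMB counts eligible somatic variants (>=5% VAF, coding consequence,
non-germline, outside HLA-A/B/C) per megabase sequenced; MSI is the
unstable fraction of qualified homopolymer sites.
"""

import numpy as np

from cgpval import (
    SimulationConfig,
    compute_msi,
    compute_tmb,
    make_truth_sample,
    simulate_msi_sites,
    simulate_variant_table,
)

rng = np.random.default_rng(11)
config = SimulationConfig(seed=11, n_decoy_loci=100)
truth = make_truth_sample("DEMO", rng, purity=0.7, tmb_rate=18.0, msi_status="MSI-High")

table = simulate_variant_table(truth, config, rng)
tmb = compute_tmb(table, covered_mb=config.panel_mb)
print(f"true mutation rate {truth.tmb_rate} mut/Mb")
print(f"TMB: {tmb.eligible_count} eligible variants / {tmb.covered_mb} Mb "
      f"= {tmb.tmb:.2f} mut/Mb -> {tmb.classification}")

sites = simulate_msi_sites(truth, config, rng)
msi = compute_msi(sites)
print(f"MSI: {msi.unstable_sites}/{msi.evaluable_sites} unstable sites "
      f"(score {msi.score:.2f}) -> {msi.classification}")
# TMB-High needs >=10 mut/Mb; MSI-High needs >20% unstable sites over at
# least 40 sites covered by >=60 reads.
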