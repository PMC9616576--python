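"""Quality-control a noisy single-EV count matrix with the chi residual filter.

EVs showing implausibly many proteins are dropped, then each count is compared
with its expectation under row/column independence; only cells whose Pearson
residual (D - E)/sqrt(E) reaches the 95th percentile survive. On pure noise
this keeps ~5% of nonzero cells; planted protein co-occurrence survives
preferentially because those cells exceed their independence expectation.
"""

from evlink.denoise import ChiFilterConfig, denoise_matrix
from evlink.panel import ProteinPanel
from evlink.pba import parse_reads
from evlink.synthdata import EVPopulationModel, generate_ev_sample

panel = ProteinPanel.default(size=113, n_markers=12)
model = EVPopulationModel(panel=panel, n_evs=10_000, noise_rate=0.1, seed=2)
sample = generate_ev_sample(model, "donor1")
matrix = parse_reads(sample.reads, panel, "donor1")

report = denoise_matrix(matrix, ChiFilterConfig(max_proteins_per_ev=5, quantile=0.95))
print(f"EVs in: {report.n_evs_input}")
print(f"after protein-count cap (<= 5 proteins): {report.n_evs_after_protein_filter}")
print(f"EVs out: {report.n_evs_output}")
print(f"residual cutoff (95th percentile of chi over nonzero cells): "
      f"{report.cutoff:.3f}")
print(f"surviving nonzero-cell fraction: {report.surviving_cell_fraction:.3f} "
      "(close to 0.05 by construction of the quantile threshold)")
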